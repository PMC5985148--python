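"""Phanerozoic period-level time scale and binned CV time series.

The analysis bins species into the nine geological periods from the
Ordovician to the Cainozoic and represents each bin by a single mid-age in
Ma before present.  Two presets are shipped:

``ics2012_midpoints``
    Arithmetic midpoints of the period boundaries of the 2012 International
    Chronostratigraphic time scale.
``paper_printed``
    Same, but with the Carboniferous mid-age set to 323 Ma and the Permian
    to 272 Ma, the values conventionally quoted for those bins in the
    crinoid-variation literature this package reproduces.

Model fitting works on *elapsed* time (Ma since the oldest retained bin,
increasing toward the present) so the oldest bin is the origin of the
series.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PERIOD_NAMES",
    "GeoBin",
    "GeoTimeScale",
    "BinSeries",
    "default_timescale",
    "build_bin_series",
]

#: Canonical period names, oldest to youngest.
PERIOD_NAMES = (
    "Ordovician",
    "Silurian",
    "Devonian",
    "Carboniferous",
    "Permian",
    "Triassic",
    "Jurassic",
    "Cretaceous",
    "Cainozoic",
)

# ICS 2012 period boundary ages (Ma), oldest to youngest.
_ICS2012_BOUNDS = {
    "Ordovician": (485.4, 443.4),
    "Silurian": (443.4, 419.2),
    "Devonian": (419.2, 358.9),
    "Carboniferous": (358.9, 298.9),
    "Permian": (298.9, 252.2),
    "Triassic": (252.2, 201.3),
    "Jurassic": (201.3, 145.0),
    "Cretaceous": (145.0, 66.0),
    "Cainozoic": (66.0, 0.0),
}

_ALIASES = {"cenozoic": "Cainozoic", "cainozoic": "Cainozoic"}


def canonical_period(name: str) -> str:
    """Map a period name (case-insensitive, Cenozoic/Cainozoic synonyms)
    onto its canonical form; raise ``ValueError`` for unknown names."""
    key = name.strip().lower()
    if key in _ALIASES:
        return _ALIASES[key]
    for canon in PERIOD_NAMES:
        if key == canon.lower():
            return canon
    raise ValueError(f"unknown geological period: {name!r}")


@dataclass(frozen=True)
class GeoBin:
    name: str
    start_ma: float  # older boundary
    end_ma: float    # younger boundary
    mid_ma: float

    def __post_init__(self) -> None:
        if not self.start_ma > self.end_ma:
            raise ValueError(f"{self.name}: start_ma must exceed end_ma")
        if not (self.end_ma <= self.mid_ma <= self.start_ma):
            raise ValueError(f"{self.name}: mid_ma outside [end, start]")


@dataclass(frozen=True)
class GeoTimeScale:
    """Ordered (oldest→youngest) sequence of period bins."""

    bins: tuple[GeoBin, ...]

    def __post_init__(self) -> None:
        starts = [b.start_ma for b in self.bins]
        if any(a <= b for a, b in zip(starts, starts[1:])):
            raise ValueError("bins must be ordered oldest to youngest")

    def mid_age(self, period: str) -> float:
        period = canonical_period(period)
        for b in self.bins:
            if b.name == period:
                return b.mid_ma
        raise KeyError(period)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(b.name for b in self.bins)


def default_timescale(
    preset: str = "paper_printed",
    overrides: dict[str, float] | None = None,
) -> GeoTimeScale:
    """Build the nine-period time scale.

    Parameters
    ----------
    preset : {"ics2012_midpoints", "paper_printed"}
        ``ics2012_midpoints`` uses boundary midpoints of the 2012 time
        scale; ``paper_printed`` overrides Carboniferous → 323 Ma and
        Permian → 272 Ma.
    overrides : dict, optional
        Per-period mid-age replacements (Ma), applied after the preset.
    """
    if preset not in ("ics2012_midpoints", "paper_printed"):
        raise ValueError(f"unknown timescale preset: {preset!r}")
    mids = {p: 0.5 * (s + e) for p, (s, e) in _ICS2012_BOUNDS.items()}
    if preset == "paper_printed":
        mids["Carboniferous"] = 323.0
        mids["Permian"] = 272.0
    if overrides:
        for name, mid in overrides.items():
            mids[canonical_period(name)] = float(mid)
    bins = tuple(
        GeoBin(p, _ICS2012_BOUNDS[p][0], _ICS2012_BOUNDS[p][1], mids[p])
        for p in PERIOD_NAMES
    )
    return GeoTimeScale(bins)


@dataclass
class BinSeries:
    """Per-bin CV moments, oldest to youngest.

    Attributes
    ----------
    names : bin (period) names of the retained bins
    t : mid-age of each bin, Ma before present (decreasing)
    elapsed : time since the oldest retained bin, Ma (t[0] → 0, increasing)
    m : mean of species CVs in the bin
    v : sample (n−1) variance of species CVs
    n : number of species
    eps : sampling variance of the bin mean, v/n
    v_imputed : True where v was imputed because the bin held one species
    """

    names: list[str]
    t: np.ndarray
    elapsed: np.ndarray
    m: np.ndarray
    v: np.ndarray
    n: np.ndarray
    eps: np.ndarray
    v_imputed: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.elapsed = np.asarray(self.elapsed, dtype=float)
        self.m = np.asarray(self.m, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        self.n = np.asarray(self.n, dtype=int)
        self.eps = np.asarray(self.eps, dtype=float)
        if self.v_imputed is None:
            self.v_imputed = np.zeros(len(self.m), dtype=bool)
        self.v_imputed = np.asarray(self.v_imputed, dtype=bool)
        if np.any(np.diff(self.elapsed) <= 0):
            raise ValueError("elapsed must be strictly increasing")
        if np.any(self.eps < 0) or np.any(self.n < 1):
            raise ValueError("eps must be >= 0 and n >= 1")

    def __len__(self) -> int:
        return len(self.m)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "bin": self.names,
                "mid_ma": self.t,
                "elapsed": self.elapsed,
                "m": self.m,
                "v": self.v,
                "n": self.n,
                "eps": self.eps,
                "v_imputed": self.v_imputed,
            }
        )


def build_bin_series(
    summaries,
    scale: GeoTimeScale | None = None,
    min_n_policy: str = "impute",
    zero_variance_policy: str = "keep",
) -> BinSeries:
    """Aggregate per-species CVs into the per-period series of mean CV,
    CV variance, species count and sampling variance.

    Parameters
    ----------
    summaries : iterable of SpeciesSummary
        Typically the ≥5-specimen subset.
    scale : GeoTimeScale
        Defaults to ``default_timescale("paper_printed")``.
    min_n_policy : {"impute", "drop"}
        Bins with a single species have undefined sample variance.  Under
        ``impute`` the pooled (df-weighted) variance of CVs across all
        multi-species bins is substituted and the bin flagged; under
        ``drop`` such bins are discarded with a warning.
    zero_variance_policy : {"keep", "pool"}
        A bin whose species are all invariant has sample variance exactly 0
        and hence sampling variance eps = 0, which asserts that its mean is
        known with infinite precision and lets the model likelihoods spike
        degenerately.  ``keep`` retains the literal v = 0; ``pool``
        substitutes the df-weighted pooled variance across the non-zero
        bins (the variance-pooling practice of sampled-trait ML fitting)
        and flags the bin.
    """
    if scale is None:
        scale = default_timescale()
    if min_n_policy not in ("impute", "drop"):
        raise ValueError(f"unknown min_n_policy: {min_n_policy!r}")
    if zero_variance_policy not in ("keep", "pool"):
        raise ValueError(f"unknown zero_variance_policy: {zero_variance_policy!r}")

    by_bin: dict[str, list[float]] = {p: [] for p in scale.names}
    for s in summaries:
        period = canonical_period(s.period)
        if period not in by_bin:
            raise ValueError(f"period {period!r} not in time scale")
        by_bin[period].append(s.cv)

    names, t, m, v, n, imputed = [], [], [], [], [], []
    for b in scale.bins:
        cvs = np.asarray(by_bin[b.name], dtype=float)
        if cvs.size == 0:
            warnings.warn(f"bin {b.name!r} has no species; dropped", stacklevel=2)
            continue
        names.append(b.name)
        t.append(b.mid_ma)
        m.append(cvs.mean())
        v.append(cvs.var(ddof=1) if cvs.size > 1 else np.nan)
        n.append(cvs.size)
        imputed.append(cvs.size == 1)
    if not names:
        raise ValueError("no bins with data")

    v = np.asarray(v, dtype=float)
    n_arr = np.asarray(n, dtype=int)
    singletons = np.isnan(v)
    if singletons.any():
        if min_n_policy == "drop":
            warnings.warn(
                f"dropping single-species bins: {[names[i] for i in np.flatnonzero(singletons)]}",
                stacklevel=2,
            )
            keep = ~singletons
            names = [nm for nm, k in zip(names, keep) if k]
            t = [x for x, k in zip(t, keep) if k]
            m = [x for x, k in zip(m, keep) if k]
            v, n_arr, imputed = v[keep], n_arr[keep], []
            singletons = np.zeros(len(names), dtype=bool)
        else:
            df = n_arr[~singletons] - 1
            if df.sum() == 0:
                raise ValueError("cannot impute variance: no multi-species bins")
            pooled = float(np.sum(v[~singletons] * df) / df.sum())
            warnings.warn(
                f"imputed pooled CV variance {pooled:.4g} for single-species "
                f"bins {[names[i] for i in np.flatnonzero(singletons)]}",
                stacklevel=2,
            )
            v = np.where(singletons, pooled, v)

    if zero_variance_policy == "pool":
        zero = v == 0.0
        nonzero = v > 0
        if zero.any() and nonzero.any():
            df = n_arr[nonzero] - 1
            pooled = float(np.sum(v[nonzero] * df) / df.sum())
            warnings.warn(
                f"pooled variance {pooled:.4g} substituted for zero-variance "
                f"bins {[names[i] for i in np.flatnonzero(zero)]}",
                stacklevel=2,
            )
            v = np.where(zero, pooled, v)
            singletons = singletons | zero

    t = np.asarray(t, dtype=float)
    m = np.asarray(m, dtype=float)
    elapsed = t[0] - t
    eps = v / n_arr
    return BinSeries(
        names=names, t=t, elapsed=elapsed, m=m, v=v, n=n_arr, eps=eps,
        v_imputed=singletons,
    )
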