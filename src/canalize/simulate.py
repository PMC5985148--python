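"""Synthetic specimen tables and model-simulated CV series.

Two generators stand in for the museum dataset:

``simulate_populations``
    Emits a specimen-level arm-count table with a configured per-period
    composition.  Each species is invariant (every arm shows its modal
    count) with probability ``invariant_fraction``; variant species draw
    per-arm counts from a two-point mixture {b, b+k} whose parameters are
    tuned so the expected CV approximates a drawn target.  Primibrachial
    counts are small integers, so achievable CVs are discrete and targets
    are approximate by construction.

``simulate_cv_series``
    Generative twin of the trait-evolution likelihoods: a latent bin-mean
    path follows Stasis, URW or GRW on elapsed time; each bin then yields
    ``n_per_bin`` species-level values around the latent mean with spread
    ``within_bin_sd``, from which the observed bin mean, variance and
    sampling variance are computed exactly as the analysis would.

``table1_template`` reproduces the nine-period composition of the
≥5-specimen subset of the source compilation: 91 species and 1,018
specimens, with the Carboniferous drawing its CV targets from the upper
tail (the bin with the historically highest intraspecific variation,
CV up to 0.6).

All randomness flows from a single seed through named
``numpy.random.SeedSequence`` substreams, so identical seeds give
bit-identical outputs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import Dataset, SpecimenRecord
from .timescale import BinSeries, GeoTimeScale, default_timescale

__all__ = [
    "PeriodConfig",
    "PopulationSimConfig",
    "SeriesSimConfig",
    "table1_template",
    "simulate_populations",
    "simulate_cv_series",
]

# Table-style per-period composition of the >=5-specimen subset:
# (species, specimens), Ordovician -> Cainozoic.
_TEMPLATE_COMPOSITION = {
    "Ordovician": (10, 126),
    "Silurian": (8, 96),
    "Devonian": (8, 91),
    "Carboniferous": (27, 205),
    "Permian": (4, 27),
    "Triassic": (4, 81),
    "Jurassic": (6, 147),
    "Cretaceous": (1, 11),
    "Cainozoic": (23, 234),
}

#: periods in which only articulate crinoids survive
_POST_PALEOZOIC = ("Triassic", "Jurassic", "Cretaceous", "Cainozoic")


@dataclass
class PeriodConfig:
    name: str
    n_species: int
    n_specimens: int                       # total, distributed over species
    cv_target_range: tuple[float, float]   # uniform draw for variant species
    min_specimens_per_species: int = 5

    def __post_init__(self) -> None:
        if self.n_species < 1 or self.n_specimens < self.n_species * self.min_specimens_per_species:
            raise ValueError(f"{self.name}: infeasible species/specimen totals")
        lo, hi = self.cv_target_range
        if not (0 < lo <= hi):
            raise ValueError(f"{self.name}: invalid cv_target_range")


@dataclass
class PopulationSimConfig:
    periods: list[PeriodConfig]
    invariant_fraction: float = 0.70
    base_count_weights: dict[int, float] = field(
        default_factory=lambda: {1: 0.10, 2: 0.20, 3: 0.30, 4: 0.25, 5: 0.15}
    )
    arms_per_specimen: tuple[int, int] = (2, 6)   # inclusive uniform range
    assign_clades: bool = True
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.invariant_fraction <= 1.0:
            raise ValueError("invariant_fraction must be in [0, 1]")
        if any(b < 1 for b in self.base_count_weights):
            raise ValueError("base counts must be >= 1")
        if self.arms_per_specimen[0] < 1:
            raise ValueError("arms_per_specimen must be >= 1")


def table1_template(seed: int | None = None) -> PopulationSimConfig:
    """Composition matching the ≥5-specimen subset of the reference
    compilation (91 species, 1,018 specimens over nine periods), ~70%
    invariant species, CV targets capped at 0.6 with the Carboniferous
    drawn from the upper tail."""
    periods = []
    for name, (n_sp, n_spec) in _TEMPLATE_COMPOSITION.items():
        rng_cv = (0.30, 0.60) if name == "Carboniferous" else (0.05, 0.45)
        periods.append(PeriodConfig(name, n_sp, n_spec, rng_cv))
    return PopulationSimConfig(periods=periods, invariant_fraction=0.70, seed=seed)


_MIX_SPREADS = (1, 2, 3, 4)
_MIX_PS = np.linspace(0.02, 0.98, 97)


def _two_point_mixture(base: int, cv_target: float):
    """Pick spread k and upper-point probability p of the mixture
    {base, base+k} whose CV best matches cv_target.

    CV(p, k, b) = k*sqrt(p(1-p)) / (b + k*p).  Returns (k, p)."""
    best = (1, 0.5, np.inf)
    for k in _MIX_SPREADS:
        cvs = k * np.sqrt(_MIX_PS * (1 - _MIX_PS)) / (base + k * _MIX_PS)
        i = int(np.argmin(np.abs(cvs - cv_target)))
        err = abs(float(cvs[i]) - cv_target)
        if err < best[2]:
            best = (k, float(_MIX_PS[i]), err)
    k, p, err = best
    if err > 0.05:
        warnings.warn(
            f"cv_target {cv_target:.3f} infeasible for base count {base}; "
            f"best achievable error {err:.3f}", stacklevel=2,
        )
    return k, p


def _max_mixture_cv(base: int) -> float:
    return max(
        float(np.max(k * np.sqrt(_MIX_PS * (1 - _MIX_PS)) / (base + k * _MIX_PS)))
        for k in _MIX_SPREADS
    )


def _feasible_base(bases, base_w, cv_target: float, rng) -> int:
    """Counts are small integers, so large modal counts cannot reach high
    CV targets with a bounded spread; restrict the modal-count draw to
    feasible values (relative variation is highest on small counts)."""
    ok = np.array([_max_mixture_cv(int(b)) >= cv_target - 0.02 for b in bases])
    if not ok.any():
        return int(bases[int(np.argmax([_max_mixture_cv(int(b)) for b in bases]))])
    w = base_w * ok
    return int(rng.choice(bases, p=w / w.sum()))


def _assign_clade(period: str, rng) -> tuple[str, str]:
    """Coarse subclass/subclade labels: post-Palaeozoic crinoids are
    articulate pentacrinoids; Palaeozoic species split between camerates
    and non-camerate pentacrinoids."""
    if period in _POST_PALEOZOIC:
        return "Pentacrinoidea", "Articulata"
    if rng.random() < 0.35:
        return "Camerata", rng.choice(["Monobathrida", "Diplobathrida"])
    return "Pentacrinoidea", rng.choice(["Cyathoformes", "Flexibilia", "Disparida"])


def simulate_populations(cfg: PopulationSimConfig, seed: int | None = None) -> tuple[Dataset, dict]:
    """Generate a specimen-level Dataset plus a truth dict of generating
    parameters (per-species invariance, base counts, CV targets)."""
    root = np.random.SeedSequence(cfg.seed if seed is None else seed)
    rng = np.random.default_rng(root.spawn(1)[0])

    bases = np.array(sorted(cfg.base_count_weights))
    base_w = np.array([cfg.base_count_weights[b] for b in bases], dtype=float)
    base_w = base_w / base_w.sum()
    lo_arms, hi_arms = cfg.arms_per_specimen

    records: list[SpecimenRecord] = []
    truth: dict = {"species": {}, "invariant_fraction": cfg.invariant_fraction}
    sp_idx, spec_idx = 0, 0
    for pc in cfg.periods:
        # distribute specimens over species: minimum each, remainder multinomial
        n_extra = pc.n_specimens - pc.n_species * pc.min_specimens_per_species
        extra = rng.multinomial(n_extra, np.full(pc.n_species, 1.0 / pc.n_species))
        per_species = pc.min_specimens_per_species + extra
        for j in range(pc.n_species):
            sp_idx += 1
            name = f"Genus_{sp_idx:03d} species_{sp_idx:03d}"
            invariant = bool(rng.random() < cfg.invariant_fraction)
            subclass, subclade = _assign_clade(pc.name, rng) if cfg.assign_clades else (None, None)
            cv_target = 0.0
            k = p = None
            if invariant:
                base = int(rng.choice(bases, p=base_w))
            else:
                cv_target = float(rng.uniform(*pc.cv_target_range))
                base = _feasible_base(bases, base_w, cv_target, rng)
                k, p = _two_point_mixture(base, cv_target)
            arm_counts_all: list[list[int]] = []
            for _ in range(int(per_species[j])):
                n_arms = int(rng.integers(lo_arms, hi_arms + 1))
                if invariant:
                    arm_counts_all.append([base] * n_arms)
                else:
                    arm_counts_all.append(
                        list(base + k * rng.binomial(1, p, size=n_arms))
                    )
            if not invariant:
                # a nominally variant species must actually vary: flip one arm
                flat = [c for arms in arm_counts_all for c in arms]
                if len(set(flat)) == 1:
                    arm_counts_all[0][0] = base + k if flat[0] == base else base
            for arms in arm_counts_all:
                spec_idx += 1
                sec = [int(2 * c + rng.integers(0, 3)) for c in arms]
                records.append(
                    SpecimenRecord(
                        specimen_id=f"SYN{spec_idx:05d}",
                        species=name,
                        period=pc.name,
                        arm_counts=tuple(int(c) for c in arms),
                        subclass=subclass,
                        subclade=subclade,
                        secundibrachial_counts=tuple(sec),
                    )
                )
            truth["species"][name] = {
                "period": pc.name,
                "invariant": invariant,
                "base_count": base,
                "cv_target": cv_target,
                "mixture": None if invariant else {"k": k, "p": p},
                "n_specimens": int(per_species[j]),
            }
    return Dataset(records, provenance="synthetic population simulation"), truth


@dataclass
class SeriesSimConfig:
    model: str                       # Stasis | URW | GRW
    params: dict[str, float]         # theta/omega or a/mu_s/sigma2_s
    n_per_bin: int = 20
    within_bin_sd: float = 0.05
    elapsed: np.ndarray | None = None     # bin times; default 50 bins x 10 Ma
    timescale: GeoTimeScale | None = None  # alternative to elapsed
    seed: int | None = None

    def resolve_elapsed(self) -> tuple[np.ndarray, list[str], np.ndarray]:
        if self.timescale is not None:
            t = np.array([b.mid_ma for b in self.timescale.bins])
            return t[0] - t, list(self.timescale.names), t
        e = (np.arange(50) * 10.0 if self.elapsed is None
             else np.asarray(self.elapsed, dtype=float))
        names = [f"bin{i:02d}" for i in range(len(e))]
        return e, names, e[-1] - e


def simulate_cv_series(cfg: SeriesSimConfig, seed: int | None = None) -> BinSeries:
    """Simulate a BinSeries whose latent bin means follow the chosen
    trait-evolution model, observed through per-bin species samples."""
    elapsed, names, t = cfg.resolve_elapsed()
    B = len(elapsed)
    rng = np.random.default_rng(
        np.random.SeedSequence(cfg.seed if seed is None else seed).spawn(1)[0]
    )
    p = cfg.params
    if cfg.model == "Stasis":
        omega = float(p["omega"])
        if omega < 0:
            raise ValueError("omega must be >= 0")
        latent = p["theta"] + math.sqrt(omega) * rng.standard_normal(B)
    elif cfg.model in ("URW", "GRW"):
        sigma2 = float(p["sigma2_s"])
        if sigma2 < 0:
            raise ValueError("sigma2_s must be >= 0")
        mu = float(p.get("mu_s", 0.0)) if cfg.model == "GRW" else 0.0
        dt = np.diff(elapsed)
        steps = mu * dt + np.sqrt(sigma2 * dt) * rng.standard_normal(B - 1)
        latent = float(p.get("a", 0.0)) + np.concatenate([[0.0], np.cumsum(steps)])
    else:
        raise ValueError(f"unknown model {cfg.model!r}")

    n = cfg.n_per_bin
    m = np.empty(B)
    v = np.empty(B)
    for i in range(B):
        vals = latent[i] + cfg.within_bin_sd * rng.standard_normal(n)
        m[i] = vals.mean()
        v[i] = vals.var(ddof=1) if n > 1 else 0.0
    return BinSeries(
        names=names, t=t, elapsed=elapsed, m=m, v=v,
        n=np.full(B, n), eps=v / n,
    )
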