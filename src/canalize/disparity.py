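"""Interspecific variation: pairwise character distances and per-bin MPD.

The character is the per-species range of primibrachial counts (computed
on all species, with no minimum-sample filter).  With a single character
the Euclidean distance between two species reduces to the absolute
difference of their ranges.  Disparity per time bin is the mean pairwise
distance (MPD) over the C(n,2) unordered within-bin species pairs,
diagonal excluded; bins with fewer than two species have undefined MPD and
are flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .timescale import GeoTimeScale, canonical_period, default_timescale

__all__ = ["DisparitySeries", "distance_matrix", "mpd_per_bin"]


@dataclass
class DisparitySeries:
    names: list[str]            # retained bins, oldest to youngest
    mid_ma: np.ndarray
    mpd: np.ndarray             # NaN where undefined
    n_species: np.ndarray
    defined: np.ndarray
    species: list[str]          # labels of the full distance matrix
    matrix: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin": self.names,
                "mid_ma": self.mid_ma,
                "n_species": self.n_species,
                "mpd": self.mpd,
                "defined": self.defined,
            }
        )


def distance_matrix(ranges) -> np.ndarray:
    """Pairwise |range_i - range_j| matrix (symmetric, zero diagonal)."""
    r = np.asarray(list(ranges), dtype=float)
    if r.size == 0:
        raise ValueError("need at least one species")
    return np.abs(r[:, None] - r[None, :])


def mpd_per_bin(
    matrix: np.ndarray,
    species: list[str],
    membership: dict[str, str],
    scale: GeoTimeScale | None = None,
) -> DisparitySeries:
    """Mean pairwise distance among the species of each time bin.

    Parameters
    ----------
    matrix : full species×species distance matrix
    species : row/column labels of ``matrix``
    membership : species → period name
    scale : bin order and mid-ages; defaults to the paper_printed preset
    """
    if scale is None:
        scale = default_timescale()
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape != (len(species), len(species)):
        raise ValueError("matrix shape does not match species labels")
    missing = [s for s in species if s not in membership]
    if missing:
        raise ValueError(f"membership missing species: {missing}")

    idx_of = {s: i for i, s in enumerate(species)}
    names, mids, mpds, ns, defined = [], [], [], [], []
    for b in scale.bins:
        members = [s for s in species if canonical_period(membership[s]) == b.name]
        if not members:
            continue
        names.append(b.name)
        mids.append(b.mid_ma)
        ns.append(len(members))
        if len(members) < 2:
            mpds.append(np.nan)
            defined.append(False)
            continue
        ii = np.array([idx_of[s] for s in members])
        sub = matrix[np.ix_(ii, ii)]
        iu = np.triu_indices(len(members), k=1)
        mpds.append(float(sub[iu].mean()))
        defined.append(True)
    return DisparitySeries(
        names=names,
        mid_ma=np.asarray(mids, dtype=float),
        mpd=np.asarray(mpds, dtype=float),
        n_species=np.asarray(ns, dtype=int),
        defined=np.asarray(defined, dtype=bool),
        species=list(species),
        matrix=matrix,
    )
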