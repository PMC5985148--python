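"""Per-species summary statistics of primibrachial counts.

Counts are pooled at the arm level: the counts of every arm of every
specimen of a species form one multiset, and the mean, sample standard
deviation (n−1 denominator), range (max−min) and coefficient of variation
CV = sd/mean are computed on it.  Counts are ≥ 1, so the mean is ≥ 1 and
the CV is always defined; CV = 0 exactly when every pooled count is equal.

The intraspecific-variation analyses use only species sampled by at least
five individuals (specimens, not arms); the per-species range used for the
disparity analysis is computed on all species with no such filter.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .io import SpecimenRecord

__all__ = [
    "SpeciesSummary",
    "pooled_counts",
    "summarize_species",
    "summarize_dataset",
    "filter_min_individuals",
    "species_range_character",
]


@dataclass(frozen=True)
class SpeciesSummary:
    species: str
    period: str
    n_specimens: int
    n_arms: int
    mean: float      # plates
    sd: float        # plates, n-1 denominator
    range: float     # plates, max - min
    cv: float        # dimensionless, sd / mean
    subclass: str | None = None
    subclade: str | None = None
    single_arm: bool = False  # flagged: sd defined as 0


def pooled_counts(records: Sequence[SpecimenRecord]) -> np.ndarray:
    """Concatenate the arm counts of all records (one species) in record
    order; the result is treated as an unordered multiset downstream."""
    records = list(records)
    if not records:
        raise ValueError("no records to pool")
    species = {r.species for r in records}
    if len(species) != 1:
        raise ValueError(f"records span multiple species: {sorted(species)}")
    return np.concatenate([np.asarray(r.arm_counts, dtype=float) for r in records])


def summarize_species(records: Sequence[SpecimenRecord]) -> SpeciesSummary:
    """Mean, SD, range and CV of the pooled arm counts of one species."""
    records = list(records)
    counts = pooled_counts(records)
    mean = float(counts.mean())
    sd = float(counts.std(ddof=1)) if counts.size > 1 else 0.0
    rng = float(counts.max() - counts.min())
    r0 = records[0]
    return SpeciesSummary(
        species=r0.species,
        period=r0.period,
        subclass=r0.subclass,
        subclade=r0.subclade,
        n_specimens=len(records),
        n_arms=int(counts.size),
        mean=mean,
        sd=sd,
        range=rng,
        cv=sd / mean,
        single_arm=counts.size == 1,
    )


def summarize_dataset(records: Iterable[SpecimenRecord]) -> list[SpeciesSummary]:
    """One :class:`SpeciesSummary` per species, in order of first
    appearance."""
    by_species: dict[str, list[SpecimenRecord]] = {}
    for r in records:
        by_species.setdefault(r.species, []).append(r)
    return [summarize_species(recs) for recs in by_species.values()]


def filter_min_individuals(
    summaries: Sequence[SpeciesSummary], threshold: int = 5
) -> list[SpeciesSummary]:
    """Keep species with at least ``threshold`` specimens, preserving
    order."""
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    return [s for s in summaries if s.n_specimens >= threshold]


def species_range_character(records: Sequence[SpecimenRecord]) -> float:
    """Range (max−min) of pooled arm counts for one species; the single
    character of the disparity analysis.  Applied to all species — the
    ≥5-specimen filter is deliberately not applied here."""
    counts = pooled_counts(records)
    return float(counts.max() - counts.min())


def summaries_to_frame(summaries: Sequence[SpeciesSummary], threshold: int = 5):
    """Tabulate summaries with a ``passes_filter`` column."""
    import pandas as pd

    return pd.DataFrame(
        {
            "species": [s.species for s in summaries],
            "period": [s.period for s in summaries],
            "subclass": [s.subclass for s in summaries],
            "subclade": [s.subclade for s in summaries],
            "n_specimens": [s.n_specimens for s in summaries],
            "n_arms": [s.n_arms for s in summaries],
            "mean": [s.mean for s in summaries],
            "sd": [s.sd for s in summaries],
            "range": [s.range for s in summaries],
            "cv": [s.cv for s in summaries],
            "passes_filter": [s.n_specimens >= threshold for s in summaries],
        }
    )
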