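"""Reading, validating and writing specimen-level primibrachial count tables.

The interchange format is a long CSV, one row per arm, with columns
``specimen_id, species, period, subclass, subclade, arm_id,
primibrachials, secundibrachials`` (``subclass``, ``subclade`` and
``secundibrachials`` may be blank).  Counts are positive integers: every
arm carries at least the first axillary plate, so a primibrachial count of
zero is a recording error.

Secundibrachial counts are stored for provenance but never analysed.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

from .timescale import PERIOD_NAMES, canonical_period

logger = logging.getLogger(__name__)

__all__ = [
    "SpecimenRecord",
    "Dataset",
    "ValidationReport",
    "read_dataset",
    "validate_dataset",
    "write_dataset",
    "write_table",
]

REQUIRED_COLUMNS = ("specimen_id", "species", "period", "arm_id", "primibrachials")
OPTIONAL_COLUMNS = ("subclass", "subclade", "locality", "secundibrachials")


@dataclass(frozen=True)
class SpecimenRecord:
    """One individual with its per-arm primibrachial counts."""

    specimen_id: str
    species: str
    period: str
    arm_counts: tuple[int, ...]
    subclass: str | None = None
    subclade: str | None = None
    locality: str | None = None
    secundibrachial_counts: tuple[int | None, ...] | None = None

    def __post_init__(self) -> None:
        if not self.arm_counts:
            raise ValueError(f"{self.specimen_id}: arm_counts is empty")
        if any((not isinstance(c, (int,)) or c < 1) for c in self.arm_counts):
            raise ValueError(
                f"{self.specimen_id}: primibrachial counts must be integers >= 1"
            )
        object.__setattr__(self, "period", canonical_period(self.period))


@dataclass
class Dataset:
    """Specimen records plus a provenance note.

    Invariants (unique specimen ids, one period per species) are not
    enforced at construction; :func:`validate_dataset` reports violations
    and ``read_dataset(strict=True)`` refuses them.
    """

    records: list[SpecimenRecord]
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.records)

    @property
    def species(self) -> list[str]:
        return sorted({r.species for r in self.records})

    def split_multi_period_species(self) -> "Dataset":
        """Split species observed in more than one period into per-period
        pseudo-species named ``species@period``; single-period species keep
        their names."""
        periods_of: dict[str, set[str]] = {}
        for r in self.records:
            periods_of.setdefault(r.species, set()).add(r.period)
        out = []
        for r in self.records:
            if len(periods_of[r.species]) > 1:
                out.append(replace(r, species=f"{r.species}@{r.period}"))
            else:
                out.append(r)
        return Dataset(out, provenance=self.provenance)


@dataclass
class ValidationReport:
    """Report-only summary of a Dataset; mirrors the structure of a
    per-period species/specimen tally table."""

    n_species: int
    n_specimens: int
    per_period: pd.DataFrame  # columns: period, n_species, n_specimens, n_arms
    column_sum_species: int   # sum of the per-period species column
    column_sum_specimens: int
    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def to_dict(self) -> dict:
        return {
            "n_species": self.n_species,
            "n_specimens": self.n_specimens,
            "column_sum_species": self.column_sum_species,
            "column_sum_specimens": self.column_sum_specimens,
            "per_period": self.per_period.to_dict(orient="records"),
            "violations": list(self.violations),
        }


def _parse_count(value, what: str):
    if pd.isna(value) or value == "":
        return None
    f = float(value)
    i = int(f)
    if f != i:
        raise ValueError(f"non-integer {what} count: {value!r}")
    return i


def read_dataset(path, strict: bool = False, provenance: str | None = None) -> Dataset:
    """Read a long-format arm-count CSV into a :class:`Dataset`.

    Rows sharing a ``specimen_id`` are aggregated into one record, arms in
    file order.  In non-strict mode rows with invalid primibrachial counts
    are dropped with a warning; in strict mode they are fatal.  Unknown
    period names are always fatal.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    for c in OPTIONAL_COLUMNS:
        if c not in df.columns:
            df[c] = ""

    rows_ok, rows_dropped = 0, 0
    arms: dict[str, dict] = {}
    for idx, row in df.iterrows():
        try:
            count = _parse_count(row["primibrachials"], "primibrachial")
            if count is None or count < 1:
                raise ValueError(
                    f"row {idx}: primibrachial count must be an integer >= 1 "
                    f"(got {row['primibrachials']!r})"
                )
        except ValueError as exc:
            if strict:
                raise
            logger.warning("dropping row: %s", exc)
            rows_dropped += 1
            continue
        period = canonical_period(row["period"])  # unknown period -> ValueError
        sec = _parse_count(row["secundibrachials"], "secundibrachial")
        sid = row["specimen_id"]
        rec = arms.setdefault(
            sid,
            {
                "species": row["species"],
                "period": period,
                "subclass": row["subclass"] or None,
                "subclade": row["subclade"] or None,
                "locality": row["locality"] or None,
                "counts": [],
                "sec": [],
            },
        )
        rec["counts"].append(count)
        rec["sec"].append(sec)
        rows_ok += 1

    records = [
        SpecimenRecord(
            specimen_id=sid,
            species=r["species"],
            period=r["period"],
            arm_counts=tuple(r["counts"]),
            subclass=r["subclass"],
            subclade=r["subclade"],
            locality=r["locality"],
            secundibrachial_counts=tuple(r["sec"]),
        )
        for sid, r in arms.items()
    ]
    logger.info(
        "read %s: %d rows kept, %d dropped, %d specimens",
        path, rows_ok, rows_dropped, len(records),
    )
    if strict:
        periods_of: dict[str, set[str]] = {}
        for r in records:
            periods_of.setdefault(r.species, set()).add(r.period)
        multi = sorted(sp for sp, ps in periods_of.items() if len(ps) > 1)
        if multi:
            raise ValueError(f"species in more than one period: {multi}")
    return Dataset(records, provenance=provenance or str(path))


def validate_dataset(ds: Dataset) -> ValidationReport:
    """Tally species/specimens/arms per period and list invariant
    violations.  Never mutates the input.

    Species observed in more than one period are counted once per period in
    the per-period tallies (the tally columns therefore need not sum to the
    distinct-species total); both the column sums and the distinct-entity
    counts are reported.
    """
    violations: list[str] = []
    per_period_species: dict[str, set[str]] = {p: set() for p in PERIOD_NAMES}
    per_period_specimens: dict[str, int] = {p: 0 for p in PERIOD_NAMES}
    per_period_arms: dict[str, int] = {p: 0 for p in PERIOD_NAMES}
    species_periods: dict[str, set[str]] = {}

    seen_ids: Counter = Counter(r.specimen_id for r in ds.records)
    for sid, cnt in sorted(seen_ids.items()):
        if cnt > 1:
            violations.append(f"duplicate specimen_id {sid!r} ({cnt} records)")

    for r in ds.records:
        per_period_species[r.period].add(r.species)
        per_period_specimens[r.period] += 1
        per_period_arms[r.period] += len(r.arm_counts)
        species_periods.setdefault(r.species, set()).add(r.period)
        if any(c < 1 for c in r.arm_counts):
            violations.append(f"{r.specimen_id}: primibrachial count < 1")

    for sp, periods in sorted(species_periods.items()):
        if len(periods) > 1:
            violations.append(
                f"species {sp!r} appears in multiple periods: {sorted(periods)}"
            )

    per_period = pd.DataFrame(
        {
            "period": list(PERIOD_NAMES),
            "n_species": [len(per_period_species[p]) for p in PERIOD_NAMES],
            "n_specimens": [per_period_specimens[p] for p in PERIOD_NAMES],
            "n_arms": [per_period_arms[p] for p in PERIOD_NAMES],
        }
    )
    return ValidationReport(
        n_species=len(species_periods),
        n_specimens=len(ds.records),
        per_period=per_period,
        column_sum_species=int(per_period["n_species"].sum()),
        column_sum_specimens=int(per_period["n_specimens"].sum()),
        violations=violations,
    )


def write_dataset(ds: Dataset, path) -> None:
    """Write a Dataset back to the long CSV format (lossless round-trip)."""
    rows = []
    for r in ds.records:
        secs = r.secundibrachial_counts or (None,) * len(r.arm_counts)
        for arm_i, (c, s) in enumerate(zip(r.arm_counts, secs), start=1):
            rows.append(
                {
                    "specimen_id": r.specimen_id,
                    "species": r.species,
                    "period": r.period,
                    "subclass": r.subclass or "",
                    "subclade": r.subclade or "",
                    "locality": r.locality or "",
                    "arm_id": arm_i,
                    "primibrachials": c,
                    "secundibrachials": "" if s is None else s,
                }
            )
    cols = [
        "specimen_id", "species", "period", "subclass", "subclade",
        "locality", "arm_id", "primibrachials", "secundibrachials",
    ]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def write_table(rows, path) -> None:
    """Write any tabular result (DataFrame, list of dicts, or list of
    dataclasses) as CSV."""
    if isinstance(rows, pd.DataFrame):
        df = rows
    else:
        rows = list(rows)
        if rows and hasattr(rows[0], "__dataclass_fields__"):
            from dataclasses import asdict

            rows = [asdict(r) for r in rows]
        df = pd.DataFrame(rows)
    df.to_csv(path, index=False)
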