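"""End-to-end analysis: specimen table → variation, evolutionary mode,
disparity, trends and the intra/inter-specific correlation, overall and
per clade.

Stages, in order: read → validate → per-species summaries → ≥5-specimen
filter → binned CV series → three-model comparison → per-species ranges →
distance matrix → per-bin MPD → trend regressions (full, excluding
invariant species, excluding the Carboniferous) → sample-size diagnostics
→ generalized-differences correlation of mean CV against MPD → per-group
(subclass, subclade) regressions and model comparisons.  Groups with too
few usable bins get a structured insufficient-data row rather than a
model comparison.

All tables are CSV; the run report is a single JSON document whose
analysis payload is byte-reproducible for a fixed seed and input.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .disparity import distance_matrix, mpd_per_bin
from .evomodels import ModeComparison, compare_modes
from .io import Dataset, read_dataset, validate_dataset, write_table
from .timescale import build_bin_series, default_timescale
from .trends import (
    fit_loess,
    fit_ols,
    gen_diff_correlation,
    sample_size_diagnostics,
    subset_regressions,
)
from .variation import (
    filter_min_individuals,
    species_range_character,
    summaries_to_frame,
    summarize_dataset,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_analysis", "write_report", "validate_report"]


@dataclass
class RunConfig:
    input: str | Path | None = None        # CSV path; alternatively pass a Dataset
    seed: int = 0
    threshold: int = 5
    timescale_preset: str = "paper_printed"
    timescale_overrides: dict = field(default_factory=dict)
    min_n_policy: str = "impute"
    zero_variance_policy: str = "pool"
    parameterization: str = "joint"
    corr_method: str = "spearman"
    loess_span: float = 0.75
    loess_degree: int = 2
    subset_exclude_invariant: bool = True
    subset_exclude_bin: str | None = "Carboniferous"
    group_columns: tuple[str, ...] = ("subclass", "subclade")
    strict: bool = False
    outdir: str | Path | None = None

    def __post_init__(self) -> None:
        if self.threshold < 1:
            raise ValueError("threshold must be >= 1")


def _trend_row(fit, group: str = "all") -> dict:
    return {
        "group": group,
        "variant": fit.label,
        "slope": fit.slope,
        "intercept": fit.intercept,
        "r2": fit.r2,
        "adj_r2": fit.adj_r2,
        "p_slope": fit.p_slope,
        "n_points": fit.n_points,
    }


def _comparison_rows(comp: ModeComparison, group: str = "all") -> list[dict]:
    if comp.insufficient:
        return [{
            "group": group, "model": None, "parameterization": None,
            "a": None, "mu_s": None, "sigma2_s": None, "theta": None,
            "omega": None, "logL": None, "K": None, "n_obs": None,
            "aicc": None, "weight": None, "winner": False,
            "insufficient": True, "reason": comp.reason,
        }]
    rows = []
    for f in comp.fits:
        rows.append({
            "group": group,
            "model": f.model,
            "parameterization": f.parameterization,
            "a": f.params.get("a"),
            "mu_s": f.params.get("mu_s"),
            "sigma2_s": f.params.get("sigma2_s"),
            "theta": f.params.get("theta"),
            "omega": f.params.get("omega"),
            "logL": f.logL,
            "K": f.K,
            "n_obs": f.n_obs,
            "aicc": f.aicc,
            "weight": f.akaike_weight,
            "winner": f.model == comp.winner,
            "insufficient": False,
            "reason": None,
        })
    return rows


def _group_analysis(summaries, scale, cfg: RunConfig, seed: int) -> tuple[dict, list[dict]]:
    """Regression + model comparison for one species subset."""
    x = np.array([scale.mid_age(s.period) for s in summaries])
    y = np.array([s.cv for s in summaries])
    out: dict = {"n_species": len(summaries)}
    if len(summaries) >= 3 and np.ptp(x) > 0:
        fit = fit_ols(x, y)
        out["regression"] = _trend_row(fit)
    else:
        out["regression"] = None
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            series = build_bin_series(summaries, scale, cfg.min_n_policy,
                                      cfg.zero_variance_policy)
        comp = compare_modes(series, cfg.parameterization, seed=seed)
    except ValueError as exc:
        comp = ModeComparison(fits=[], winner=None, insufficient=True, reason=str(exc))
    out["mode"] = {
        "insufficient": comp.insufficient,
        "winner": comp.winner,
        "weights": None if comp.insufficient else {
            f.model: f.akaike_weight for f in comp.fits
        },
    }
    return out, comp


def run_analysis(cfg: RunConfig, dataset: Dataset | None = None) -> dict:
    """Run the full pipeline; returns the report dict (also written to
    ``cfg.outdir`` together with all tables when an output directory is
    configured)."""
    stage: list[str] = ["read"]
    captured: list[str] = []
    try:
        with warnings.catch_warnings(record=True) as wlist:
            warnings.simplefilter("always")
            results = _run_stages(cfg, dataset, captured, stage)
            captured.extend(f"{w.category.__name__}: {w.message}" for w in wlist)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage[0]!r}: {exc}") from exc

    report = {
        "meta": {
            "package": "canalize",
            "version": __version__,
            "timestamp": datetime.now(timezone.utc).isoformat(),
        },
        "config": {
            k: (str(v) if isinstance(v, Path) else list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(cfg).items()
        },
        "warnings": captured,
        "analysis": results,
    }
    if cfg.outdir is not None:
        write_report(report, Path(cfg.outdir) / "report.json")
    return report


def _run_stages(cfg: RunConfig, dataset: Dataset | None, captured: list[str],
                stage: list[str]) -> dict:
    outdir = Path(cfg.outdir) if cfg.outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)

    if dataset is None:
        if cfg.input is None:
            raise ValueError("RunConfig.input or an explicit Dataset is required")
        dataset = read_dataset(cfg.input, strict=cfg.strict)
    stage[0] = "validate"
    validation = validate_dataset(dataset)
    if any("multiple periods" in v for v in validation.violations):
        if cfg.strict:
            raise ValueError("species observed in multiple periods (strict mode)")
        dataset = dataset.split_multi_period_species()
        captured.append("split multi-period species into per-period pseudo-species")
        validation = validate_dataset(dataset)

    scale = default_timescale(cfg.timescale_preset, cfg.timescale_overrides or None)

    stage[0] = "summarize"
    summaries_all = summarize_dataset(dataset.records)
    summaries = filter_min_individuals(summaries_all, cfg.threshold)
    if not summaries:
        raise ValueError("no species pass filter")
    logger.info("summarize: %d species, %d pass >=%d filter",
                len(summaries_all), len(summaries), cfg.threshold)

    stage[0] = "bin_series"
    series = build_bin_series(summaries, scale, cfg.min_n_policy,
                              cfg.zero_variance_policy)
    stage[0] = "compare_modes"
    try:
        comp = compare_modes(series, cfg.parameterization, seed=cfg.seed)
    except ValueError as exc:
        comp = ModeComparison(fits=[], winner=None, insufficient=True,
                              reason=str(exc))

    stage[0] = "disparity"
    # disparity on ALL species (filter deliberately relaxed)
    by_species: dict[str, list] = {}
    for r in dataset.records:
        by_species.setdefault(r.species, []).append(r)
    sp_names = list(by_species)
    ranges = [species_range_character(by_species[s]) for s in sp_names]
    membership = {s: by_species[s][0].period for s in sp_names}
    dmat = distance_matrix(ranges)
    disp = mpd_per_bin(dmat, sp_names, membership, scale)

    stage[0] = "trends"
    # species-level trend regressions
    x_sp = np.array([scale.mid_age(s.period) for s in summaries])
    cv_sp = np.array([s.cv for s in summaries])
    periods_sp = [s.period for s in summaries]
    trends = [fit_ols(x_sp, cv_sp, label="full")]
    if cfg.subset_exclude_invariant:
        trends.append(subset_regressions(x_sp, cv_sp, "exclude_invariant"))
    if cfg.subset_exclude_bin:
        trends.append(
            subset_regressions(x_sp, cv_sp, "exclude_bin", periods=periods_sp,
                               exclude_bin=cfg.subset_exclude_bin)
        )
    loess = fit_loess(x_sp, cv_sp, span=cfg.loess_span, degree=cfg.loess_degree)
    try:
        diag1, diag2 = sample_size_diagnostics(summaries, series)
    except ValueError as exc:  # e.g. every species sampled equally often
        captured.append(f"sample-size diagnostics unavailable: {exc}")
        diag1 = diag2 = None

    stage[0] = "gen_diff"
    # intra vs inter correlation on bins where both series are defined
    common = [i for i, nm in enumerate(disp.names)
              if disp.defined[i] and nm in series.names]
    gd_info: dict | None = None
    if len(common) >= 4:
        mseries = {nm: series.m[j] for j, nm in enumerate(series.names)}
        y1 = np.array([mseries[disp.names[i]] for i in common])
        y2 = disp.mpd[common]
        tt = disp.mid_ma[common]
        dropped = [nm for nm in disp.names if nm not in [disp.names[i] for i in common]]
        try:
            gd = gen_diff_correlation(y1, y2, tt, method=cfg.corr_method)
            gd.dropped_bins = dropped
            gd_info = {
                "rho": gd.rho, "p": gd.p, "method": gd.method,
                "rho_resid_cv": gd.rho_resid[0], "rho_resid_mpd": gd.rho_resid[1],
                "n_transformed": int(gd.transformed[0].size),
                "dropped_bins": dropped,
            }
        except ValueError as exc:
            captured.append(f"gen_diff correlation unavailable: {exc}")
    else:
        captured.append("gen_diff correlation unavailable: fewer than 4 shared bins")
        gd = None

    stage[0] = "per_clade"
    # per-clade analyses
    groups: dict[str, dict] = {}
    group_rows: list[dict] = []
    trend_rows = [_trend_row(f) for f in trends]
    for col in cfg.group_columns:
        labels = sorted({getattr(s, col) for s in summaries if getattr(s, col)})
        for lbl in labels:
            subset = [s for s in summaries if getattr(s, col) == lbl]
            import zlib

            gseed = int(np.random.SeedSequence(
                (cfg.seed, zlib.crc32(lbl.encode()))
            ).generate_state(1)[0] % 2**31)
            ginfo, gcomp = _group_analysis(subset, scale, cfg, gseed)
            groups[f"{col}:{lbl}"] = ginfo
            group_rows.extend(_comparison_rows(gcomp, group=f"{col}:{lbl}"))
            if ginfo["regression"]:
                trend_rows.append({**ginfo["regression"], "group": f"{col}:{lbl}"})

    results = {
        "validation": validation.to_dict(),
        "n_species_all": len(summaries_all),
        "n_species_filtered": len(summaries),
        "n_specimens_filtered": int(sum(s.n_specimens for s in summaries)),
        "invariant_fraction_filtered": float(np.mean([s.cv == 0 for s in summaries])),
        "max_cv": float(max(s.cv for s in summaries)),
        "bin_series": series.to_frame().to_dict(orient="records"),
        "mode_comparison": _comparison_rows(comp),
        "disparity": disp.to_frame().to_dict(orient="records"),
        "trends": trend_rows,
        "loess": {
            "span": loess.span, "degree": loess.degree,
            "fitted": loess.fitted.tolist(), "se": loess.se.tolist(),
        },
        "sample_size_diagnostics": None if diag1 is None else {
            "cv_vs_n_specimens": _trend_row(diag1),
            "mean_cv_vs_n_species": _trend_row(diag2),
        },
        "gen_diff": gd_info,
        "groups": groups,
    }

    stage[0] = "write_outputs"
    if outdir is not None:
        write_table(summaries_to_frame(summaries_all, cfg.threshold),
                    outdir / "species_summaries.csv")
        write_table(series.to_frame(), outdir / "bin_series.csv")
        write_table(pd.DataFrame(_comparison_rows(comp) + group_rows),
                    outdir / "model_comparison.csv")
        write_table(disp.to_frame(), outdir / "disparity.csv")
        write_table(pd.DataFrame(trend_rows), outdir / "trends.csv")
        if gd_info is not None:
            gd_df = pd.DataFrame({
                "gd_cv": gd.transformed[0], "gd_mpd": gd.transformed[1],
            })
            gd_df["rho"] = gd.rho
            gd_df["p"] = gd.p
            write_table(gd_df, outdir / "gen_diff.csv")
    return results


# --------------------------------------------------------------------------
# report I/O

_SCHEMA_PATH = Path(__file__).with_name("report_schema.json")


def write_report(report: dict, path) -> None:
    """Write the run report as a single JSON document with stable key
    order; identical analyses produce byte-identical payloads (only
    ``meta.timestamp`` varies between runs)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, allow_nan=True)
        fh.write("\n")


def validate_report(report: dict) -> list[str]:
    """Check a report against the shipped schema (required keys and value
    types); returns a list of problems, empty when valid."""
    with open(_SCHEMA_PATH, encoding="utf-8") as fh:
        schema = json.load(fh)
    problems: list[str] = []

    def check(obj, spec, where):
        for key, kind in spec.items():
            if key not in obj:
                problems.append(f"{where}: missing key {key!r}")
                continue
            val = obj[key]
            if isinstance(kind, dict):
                if not isinstance(val, dict):
                    problems.append(f"{where}.{key}: expected object")
                else:
                    check(val, kind, f"{where}.{key}")
            elif kind == "array" and not isinstance(val, list):
                problems.append(f"{where}.{key}: expected array")
            elif kind == "number" and not isinstance(val, (int, float)):
                problems.append(f"{where}.{key}: expected number")
            elif kind == "string" and not isinstance(val, str):
                problems.append(f"{where}.{key}: expected string")

    check(report, schema["required"], "report")
    return problems
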