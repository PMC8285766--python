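"""End-to-end study orchestration.

``run_study`` reproduces the full validation flow from one configuration:
simulate (or load) a cohort; either refit the two GA models on a build split
and validate on the holdout, or apply externally supplied coefficient sets to
the whole cohort (the external-validation design); then emit every agreement
table and the preterm ROC block as one machine-readable report.

All randomness flows from named seeds in the configuration, so a rerun with
the same config yields a byte-identical JSON report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from contextlib import contextmanager
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .agreement import (
    ConcordanceTable,
    DiscrepancyTable,
    PrevalenceTable,
    concordance_table,
    prevalence_table,
    rmse,
    subgroup_metrics,
)
from .cohort import Cohort, RunConfig
from .errors import InputError, MetagaError
from .io import read_coefficients, read_cohort, write_coefficients
from .model import (
    CoefficientSet,
    PredictionSet,
    fit_model,
    predict_ga,
    screen_all,
    select_terms,
)
from .roc import bootstrap_ci, compare_roc, fixed_operating_point, roc_curve, youden, auc
from .simulate import SimConfig, generate_cohort

__all__ = ["StudyConfig", "StudyReport", "run_study", "split_cohort"]

logger = logging.getLogger("metaga.pipeline")

MODEL_METABOLITES = "metabolites"
MODEL_METABOLITES_BW = "metabolites_bw"


@dataclass
class StudyConfig:
    """One study run: cohort source, model source, and analysis settings."""

    sim: SimConfig | None = None
    cohort_path: str | None = None
    refit: bool = True
    split_fraction: float = 0.5
    split_seed: int = 7
    coefficients_metabolites: str | None = None
    coefficients_birthweight: str | None = None
    run: RunConfig = field(default_factory=RunConfig)
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if (self.sim is None) == (self.cohort_path is None):
            raise MetagaError("provide exactly one of sim / cohort_path")
        if self.refit and not 0 < self.split_fraction < 1:
            raise MetagaError("split_fraction must lie in (0, 1)")
        if not self.refit and not (
            self.coefficients_metabolites or self.coefficients_birthweight
        ):
            raise MetagaError("external mode needs at least one coefficient file")


@dataclass
class StudyReport:
    """Nested result structure; ``to_json`` is deterministic given the data."""

    metadata: dict
    models: dict

    def as_dict(self) -> dict:
        return {"metadata": self.metadata, "models": self.models}

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.as_dict(), sort_keys=True, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n", encoding="utf-8")
        return text


@contextmanager
def _stage(name: str, **counts):
    logger.info("stage %s: start %s", name, counts or "")
    try:
        yield
    except Exception as exc:
        logger.error("stage %s failed: %s", name, exc)
        if hasattr(exc, "add_note"):
            exc.add_note(f"pipeline stage: {name}")
        raise
    logger.info("stage %s: done", name)


def split_cohort(cohort: Cohort, fraction: float, seed: int) -> tuple[Cohort, Cohort]:
    """Disjoint, exhaustive, reproducible random build/validation split."""
    if not 0 < fraction < 1:
        raise MetagaError("fraction must lie in (0, 1)")
    n = len(cohort)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_build = int(np.floor(n * fraction + 0.5))
    build_idx = sorted(perm[:n_build].tolist())
    val_idx = sorted(perm[n_build:].tolist())
    build, val = cohort.subset(build_idx), cohort.subset(val_idx)
    for name, part in (("build", build), ("validation", val)):
        regions = {r.region for r in part.records}
        missing = {r.region for r in cohort.records} - regions
        if missing:
            logger.warning("split emptied region(s) %s in %s set", missing, name)
    return build, val


def _discrepancy_dict(t: DiscrepancyTable) -> dict:
    return {
        "counts": t.counts,
        "n": t.n,
        "percentages": t.percentages,
        "cumulative_percentages": t.cumulative,
    }


def _ci_dict(ci) -> dict:
    return {
        "estimate": ci.estimate,
        "lower": ci.lower,
        "upper": ci.upper,
        "replications": ci.replications,
        "seed": ci.seed,
        "level": ci.level,
    }


def _agreement_block(preds: PredictionSet, run: RunConfig) -> dict:
    block: dict = {
        "n": len(preds),
        "n_excluded": preds.n_excluded,
        "rmse": rmse(preds),
        "subgroups": {},
    }
    for axis in ("all", "region", "sga"):
        for name, m in subgroup_metrics(preds, by=axis, rounding=run.rounding).items():
            key = name if axis != "all" else "total"
            block["subgroups"][key] = {
                "n": m.n,
                "rmse": m.rmse,
                "discrepancy": _discrepancy_dict(m.discrepancy),
            }
    conc: ConcordanceTable = concordance_table(preds)
    prev: PrevalenceTable = prevalence_table(preds)
    block["concordance"] = {
        "counts": conc.counts.tolist(),
        "row_totals": conc.row_totals.tolist(),
        "diagonal_pct": conc.diagonal_pct,
    }
    block["prevalence"] = {
        "ultrasound_counts": prev.ultrasound_counts,
        "predicted_counts": prev.predicted_counts,
        "ultrasound_pct": prev.ultrasound_pct,
        "predicted_pct": prev.predicted_pct,
        "ultrasound_preterm_pct": prev.ultrasound_preterm_pct,
        "predicted_preterm_pct": prev.predicted_preterm_pct,
    }
    return block


def _roc_block(preds: PredictionSet, run: RunConfig) -> dict:
    cutoff = run.preterm_cutoff
    B, seed, level = run.bootstrap_replications, run.bootstrap_seed, run.level
    labels = preds.preterm
    if labels.all() or not labels.any():
        logger.warning("single-class validation set; ROC block omitted")
        return {"omitted": "single class"}
    curve = roc_curve(preds, cutoff)
    yj = youden(curve)
    block: dict = {
        "n_positive": curve.n_positive,
        "n_negative": curve.n_negative,
        "auc": auc(curve),
        "auc_ci": _ci_dict(bootstrap_ci(preds, "auc", B, seed, level, cutoff)),
        "youden": {
            "j": yj.j,
            "criterion": yj.criterion,
            "sensitivity": yj.sensitivity,
            "specificity": yj.specificity,
            "j_ci": _ci_dict(bootstrap_ci(preds, "youden_j", B, seed, level, cutoff)),
            "criterion_ci": _ci_dict(
                bootstrap_ci(preds, "criterion", B, seed, level, cutoff)
            ),
        },
        "fixed_operating_points": {},
    }
    for sens in run.fixed_sensitivities:
        op = fixed_operating_point(curve, "sensitivity", sens, preds, B, seed, level, cutoff)
        block["fixed_operating_points"][f"sensitivity={sens:g}"] = {
            "specificity": op.point.specificity,
            "criterion": op.point.criterion,
            "specificity_ci": _ci_dict(op.ci),
        }
    for spec in run.fixed_specificities:
        op = fixed_operating_point(curve, "specificity", spec, preds, B, seed, level, cutoff)
        block["fixed_operating_points"][f"specificity={spec:g}"] = {
            "sensitivity": op.point.sensitivity,
            "criterion": op.point.criterion,
            "sensitivity_ci": _ci_dict(op.ci),
        }
    regions = sorted(set(map(str, preds.region)))
    if len(regions) == 2:
        a, b = regions
        pa, pb = preds.subset(preds.region == a), preds.subset(preds.region == b)
        try:
            cmp = compare_roc(pa, pb, B, seed, level, cutoff)
            block["region_comparison"] = {
                "group_a": a,
                "group_b": b,
                "auc_a": cmp.auc_a,
                "auc_b": cmp.auc_b,
                "delta_auc": cmp.delta_auc,
                "delta_auc_pct": cmp.delta_auc_pct,
                "ci": _ci_dict(cmp.ci),
                "p_value": cmp.p_value,
            }
        except InputError as exc:
            logger.warning("region ROC comparison skipped: %s", exc)
            block["region_comparison"] = {"omitted": str(exc)}
    return block


def run_study(config: StudyConfig) -> StudyReport:
    """Execute the complete study and return (and optionally write) the report."""
    run = config.run
    logging.getLogger("metaga").setLevel(run.log_level)

    with _stage("cohort"):
        if config.sim is not None:
            cohort, _truth = generate_cohort(config.sim)
        else:
            cohort = read_cohort(config.cohort_path)
        if len(cohort) == 0:
            raise InputError("cohort is empty after validation")
        logger.info("cohort: %d records (%d dropped at read)", len(cohort),
                    cohort.n_dropped)

    coefsets: dict[str, CoefficientSet] = {}
    if config.refit:
        with _stage("split", n=len(cohort)):
            build, validation = split_cohort(
                cohort, config.split_fraction, config.split_seed
            )
        with _stage("model_building", n_build=len(build)):
            screen = screen_all(build, run.p_univariate)
            spec1 = select_terms(screen, build, run.p_retain)
            coefsets[MODEL_METABOLITES] = fit_model(build, spec1)
            coefsets[MODEL_METABOLITES_BW] = fit_model(build, spec1.with_birthweight())
    else:
        validation = cohort
        with _stage("coefficients"):
            if config.coefficients_metabolites:
                coefsets[MODEL_METABOLITES] = read_coefficients(
                    config.coefficients_metabolites, cohort.panel
                )
            if config.coefficients_birthweight:
                coefsets[MODEL_METABOLITES_BW] = read_coefficients(
                    config.coefficients_birthweight, cohort.panel
                )

    models: dict = {}
    for name, coefset in coefsets.items():
        with _stage(f"evaluate:{name}", n_validation=len(validation)):
            preds = predict_ga(
                validation, coefset, run.preterm_cutoff, clamp=run.clamp
            )
            entry = _agreement_block(preds, run)
            entry["roc"] = _roc_block(preds, run)
            entry["terms"] = [t.key for t in sorted(coefset.coefficients)]
            if coefset.diagnostics is not None:
                entry["fit"] = {
                    "n": coefset.diagnostics.n,
                    "residual_sd": coefset.diagnostics.residual_sd,
                }
            models[name] = entry

    metadata = {
        "n_cohort": len(cohort),
        "n_validation": len(validation),
        "dropped_at_read": cohort.dropped,
        "cohort_digest": cohort.digest(),
        "provenance": cohort.provenance,
        "refit": config.refit,
        "split_fraction": config.split_fraction if config.refit else None,
        "split_seed": config.split_seed if config.refit else None,
        "p_univariate": run.p_univariate,
        "p_retain": run.p_retain,
        "preterm_cutoff": run.preterm_cutoff,
        "bootstrap": {
            "replications": run.bootstrap_replications,
            "seed": run.bootstrap_seed,
        },
        "rounding": run.rounding,
        "sim_seed": config.sim.seed if config.sim is not None else None,
    }
    report = StudyReport(metadata=metadata, models=models)

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        report.to_json(out / "report.json")
        for name, coefset in coefsets.items():
            write_coefficients(coefset, out / f"coefficients_{name}.json")
        (out / "summary.txt").write_text(format_summary(report), encoding="utf-8")
        logger.info("report written to %s", out)
    return report


def format_summary(report: StudyReport) -> str:
    """Human-readable summary (RMSE to 2 dp, percentages to 1 dp)."""
    lines = []
    meta = report.metadata
    lines.append(f"cohort n={meta['n_cohort']}  validation n={meta['n_validation']}")
    for name, entry in report.models.items():
        lines.append("")
        lines.append(f"model: {name}  (terms: {len(entry['terms'])})")
        lines.append(f"  RMSE {entry['rmse']:.2f} wk  (n={entry['n']})")
        for sub, m in entry["subgroups"].items():
            d = m["discrepancy"]["cumulative_percentages"]
            lines.append(
                f"  {sub:<22} n={m['n']:<6} RMSE {m['rmse']:.2f}"
                f"  within 1 wk {d['1']:.1f}%  within 2 wk {d['2']:.1f}%"
            )
        prev = entry["prevalence"]
        lines.append(
            f"  preterm prevalence: predicted {prev['predicted_preterm_pct']:.1f}%"
            f" vs ultrasound {prev['ultrasound_preterm_pct']:.1f}%"
        )
        roc = entry["roc"]
        if "auc" in roc:
            ci = roc["auc_ci"]
            yj = roc["youden"]
            lines.append(
                f"  AUC {roc['auc']:.2f} (95% CI {ci['lower']:.2f}-{ci['upper']:.2f})"
                f"  Youden J {yj['j']:.2f} at {yj['criterion']:.2f} wk"
                f" (sens {100 * yj['sensitivity']:.1f}%, spec {100 * yj['specificity']:.1f}%)"
            )
    return "\n".join(lines) + "\n"
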