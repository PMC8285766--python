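"""Reading and writing cohort tables, coefficient sets and model specs.

File dialects are deliberately plain: comma-delimited UTF-8 with a fixed,
documented header for cohorts; JSON key→number maps for coefficient sets
(keys ``intercept``, ``<analyte>^<power>``, ``birthweight^1``, plus an
optional ``centers`` object recording the predictor centering constants of a
locally fitted model); a JSON list of term keys for model specs.

The no-imputation rule is enforced at the boundary: any row with a missing
metabolite value is dropped and counted, never filled.  Rows violating record
invariants are rejected with their line numbers.  Missing birthweight is
tolerated (such records serve the metabolites-only model and are excluded
from birthweight-model fits and predictions downstream).
"""

from __future__ import annotations

import json
import logging
import math
from pathlib import Path

import pandas as pd

from .cohort import Cohort, NewbornRecord
from .errors import CoefficientError, InputError, SchemaError
from .model import BIRTHWEIGHT, CoefficientSet, ModelSpec, Term
from .panel import STANDARD_PANEL, MetabolitePanel

__all__ = [
    "read_cohort",
    "write_cohort",
    "read_coefficients",
    "write_coefficients",
    "read_model_spec",
    "write_model_spec",
]

logger = logging.getLogger("metaga.io")

_META_COLUMNS = [
    "id",
    "region",
    "site",
    "sex",
    "ga_ultrasound_wk",
    "birthweight_g",
    "collection_age_h",
]
_OPTIONAL_COLUMNS = ["sga", "twin"]


def _as_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return False
    return str(value).strip().lower() in ("1", "true", "t", "yes")


def read_cohort(path: str | Path, panel: MetabolitePanel = STANDARD_PANEL) -> Cohort:
    """Read a cohort CSV into a validated :class:`Cohort`.

    Every panel analyte must appear as a column; non-schema extra columns are
    ignored with a warning.  Returns the surviving records together with
    per-reason dropped counts on ``cohort.dropped``.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    try:
        frame = pd.read_csv(path, dtype={"id": str, "site": str})
    except pd.errors.EmptyDataError as exc:
        raise InputError(f"empty cohort file: {path}") from exc
    if frame.empty and len(frame.columns) == 0:
        raise InputError(f"empty cohort file: {path}")

    for col in _META_COLUMNS:
        if col not in frame.columns:
            raise SchemaError(f"missing mandatory column {col!r}")
    for analyte in panel.analytes:
        if analyte not in frame.columns:
            raise SchemaError(f"missing analyte column {analyte!r}")
    known = set(_META_COLUMNS) | set(_OPTIONAL_COLUMNS) | set(panel.analytes)
    unknown = [c for c in frame.columns if c not in known]
    if unknown:
        logger.warning("ignoring unknown columns: %s", unknown)

    records: list[NewbornRecord] = []
    dropped: dict[str, int] = {}
    rejected_lines: list[int] = []
    for idx, row in frame.iterrows():
        lineno = int(idx) + 2  # header is line 1
        values = {a: row[a] for a in panel.analytes}
        if any(pd.isna(v) for v in values.values()):
            dropped["missing metabolite"] = dropped.get("missing metabolite", 0) + 1
            continue
        bw = row["birthweight_g"]
        record = NewbornRecord(
            id=str(row["id"]),
            region=str(row["region"]),
            site=str(row["site"]),
            sex=str(row["sex"]),
            ga_ultrasound=float(row["ga_ultrasound_wk"]),
            birthweight=None if pd.isna(bw) else float(bw),
            collection_age=float(row["collection_age_h"]),
            metabolites={a: float(v) for a, v in values.items()},
            sga=_as_bool(row["sga"]) if "sga" in frame.columns else False,
            twin=_as_bool(row["twin"]) if "twin" in frame.columns else False,
        )
        problems = record.validate(panel)
        if problems:
            dropped["invalid record"] = dropped.get("invalid record", 0) + 1
            rejected_lines.append(lineno)
            logger.warning("line %d rejected: %s", lineno, "; ".join(problems))
            continue
        records.append(record)
    if rejected_lines:
        logger.warning("rejected %d invalid rows at lines %s",
                       len(rejected_lines), rejected_lines)
    logger.info(
        "read %s: %d records kept, %d dropped", path, len(records),
        sum(dropped.values()),
    )
    return Cohort(records=records, panel=panel, provenance=str(path), dropped=dropped)


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort CSV with stable column order.

    Floats are written with 12 significant digits so a write→read round trip
    reproduces the cohort up to negligible formatting error.
    """
    if not cohort.records:
        raise InputError("refusing to write an empty cohort")
    frame = cohort.to_frame()
    frame.to_csv(path, index=False, float_format="%.12g")
    logger.info("wrote %d records to %s", len(cohort), path)


def _load_json_no_duplicates(path: Path):
    def hook(pairs):
        keys = [k for k, _ in pairs]
        if len(set(keys)) != len(keys):
            dups = sorted({k for k in keys if keys.count(k) > 1})
            raise CoefficientError(f"duplicate keys in {path}: {dups}")
        return dict(pairs)

    with open(path, encoding="utf-8") as fh:
        return json.load(fh, object_pairs_hook=hook)


def read_coefficients(
    path: str | Path, panel: MetabolitePanel = STANDARD_PANEL
) -> CoefficientSet:
    """Read a coefficient set and validate every term against the panel.

    A term with a power its analyte is not eligible for (per the panel's
    squared/cubic lists) is rejected.
    """
    path = Path(path)
    data = _load_json_no_duplicates(path)
    if not isinstance(data, dict):
        raise CoefficientError(f"{path}: expected a JSON object")
    intercept = float(data.pop("intercept", 0.0))
    centers = {
        str(k): float(v) for k, v in (data.pop("centers", None) or {}).items()
    }
    coefficients: dict[Term, float] = {}
    for key, value in data.items():
        term = Term.from_key(str(key))
        if term.analyte != BIRTHWEIGHT and not panel.allows(term.analyte, term.power):
            raise CoefficientError(
                f"{path}: term {term.key} not admissible — analyte unknown or "
                f"power exceeds the panel's squared/cubic eligibility"
            )
        coefficients[term] = float(value)
    cs = CoefficientSet(intercept=intercept, coefficients=coefficients, centers=centers)
    logger.info("read coefficient set with %d terms from %s", len(coefficients), path)
    return cs


def write_coefficients(coefficients: CoefficientSet, path: str | Path) -> None:
    data: dict = {"intercept": coefficients.intercept}
    for term in sorted(coefficients.coefficients):
        data[term.key] = coefficients.coefficients[term]
    if coefficients.centers:
        data["centers"] = {
            k: coefficients.centers[k] for k in sorted(coefficients.centers)
        }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(data, fh, indent=2, sort_keys=False)
        fh.write("\n")


def read_model_spec(
    path: str | Path, panel: MetabolitePanel = STANDARD_PANEL
) -> ModelSpec:
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        data = json.load(fh)
    if not isinstance(data, list):
        raise CoefficientError(f"{path}: expected a JSON list of term keys")
    terms = tuple(Term.from_key(str(k)) for k in data)
    spec = ModelSpec(terms)
    spec.validate_against(panel)
    return spec


def write_model_spec(spec: ModelSpec, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump([t.key for t in spec.terms], fh, indent=2)
        fh.write("\n")
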