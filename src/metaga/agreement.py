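"""Agreement statistics between predicted and ultrasound gestational age.

Covers the full validation battery: RMSE, the rounded-week discrepancy
distribution with cumulative percentages, gestational-age bin prevalence,
the 5×5 ultrasound×predicted concordance cross-tab with diagonal row
percentages, and subgroup (region / SGA) splits.

Conventions (configurable where noted):

* week discrepancy = |predicted − ultrasound| rounded half-up to an integer
  week, capped at the "≥4" category ("within 1 week" therefore means a
  difference below 1.5 weeks);
* GA bins are on completed weeks (floor): ≤34, 35–36, 37–38, 39–40, >40,
  consistent with the <37-week preterm cutoff;
* displayed percentages are rounded half-up to 1 decimal.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .errors import InputError
from .model import PredictionSet

__all__ = [
    "DISCREPANCY_CATEGORIES",
    "GA_BINS",
    "rmse",
    "ga_bin",
    "DiscrepancyTable",
    "ConcordanceTable",
    "PrevalenceTable",
    "discrepancy_table",
    "concordance_table",
    "prevalence_table",
    "subgroup_metrics",
    "SubgroupMetrics",
]

logger = logging.getLogger("metaga.agreement")

DISCREPANCY_CATEGORIES = ("0", "1", "2", "3", ">=4")
GA_BINS = ("<=34", "35-36", "37-38", "39-40", ">40")


def round_half_up(x: float, decimals: int = 0) -> float:
    """Round half away from zero-free: plain half-up for non-negative input."""
    scale = 10.0**decimals
    return math.floor(x * scale + 0.5) / scale


def _pct1(count: float, total: float) -> float:
    """Percentage to 1 decimal, half-up."""
    return round_half_up(100.0 * count / total, 1)


def rmse(predictions: PredictionSet) -> float:
    """Root mean square error between predicted and ultrasound GA, in weeks."""
    if len(predictions) == 0:
        raise InputError("rmse of an empty prediction set")
    d = predictions.ga_predicted - predictions.ga_ultrasound
    return float(np.sqrt(np.mean(d**2)))


def ga_bin(ga: float) -> str:
    """Completed-weeks GA bin label."""
    if not np.isfinite(ga):
        raise InputError(f"non-finite GA {ga}")
    w = math.floor(ga)
    if w <= 34:
        return "<=34"
    if w <= 36:
        return "35-36"
    if w <= 38:
        return "37-38"
    if w <= 40:
        return "39-40"
    return ">40"


def _bin_index(ga_values: np.ndarray) -> np.ndarray:
    w = np.floor(np.asarray(ga_values, dtype=float))
    return np.digitize(w, [34.5, 36.5, 38.5, 40.5])


@dataclass
class DiscrepancyTable:
    """Rounded-week discrepancy counts with (cumulative) percentages."""

    counts: dict[str, int]
    n: int
    percentages: dict[str, float]
    cumulative: dict[str, float]

    @classmethod
    def from_counts(cls, counts: dict[str, int]) -> "DiscrepancyTable":
        """Summarize printed or precomputed category counts."""
        full = {c: int(counts.get(c, 0)) for c in DISCREPANCY_CATEGORIES}
        n = sum(full.values())
        if n == 0:
            raise InputError("discrepancy table needs at least one record")
        pct = {c: _pct1(full[c], n) for c in DISCREPANCY_CATEGORIES}
        running = 0
        cum = {}
        for c in DISCREPANCY_CATEGORIES:
            running += full[c]
            cum[c] = _pct1(running, n)
        return cls(counts=full, n=n, percentages=pct, cumulative=cum)

    @classmethod
    def from_predictions(
        cls, predictions: PredictionSet, rounding: str = "half_up"
    ) -> "DiscrepancyTable":
        if len(predictions) == 0:
            raise InputError("discrepancy table of an empty prediction set")
        diffs = np.abs(predictions.ga_predicted - predictions.ga_ultrasound)
        if rounding == "half_up":
            cats = np.floor(diffs + 0.5)
        elif rounding == "floor":
            cats = np.floor(diffs)
        elif rounding == "ceiling":
            cats = np.ceil(diffs)
        else:
            raise InputError(f"unknown rounding mode {rounding!r}")
        cats = np.minimum(cats.astype(int), 4)
        counts = {
            c: int(np.sum(cats == i)) for i, c in enumerate(DISCREPANCY_CATEGORIES)
        }
        return cls.from_counts(counts)

    def within(self, weeks: int) -> float:
        """Cumulative percentage discrepant by at most ``weeks`` weeks."""
        return self.cumulative[DISCREPANCY_CATEGORIES[min(weeks, 4)]]


def discrepancy_table(
    predictions: PredictionSet, rounding: str = "half_up"
) -> DiscrepancyTable:
    return DiscrepancyTable.from_predictions(predictions, rounding)


@dataclass
class ConcordanceTable:
    """5×5 ultrasound×predicted GA-bin cross-tab with diagonal row percentages."""

    counts: np.ndarray  # (5, 5) int, ultrasound rows × predicted columns
    row_totals: np.ndarray
    diagonal_pct: dict[str, float | None]  # None for empty rows
    n: int

    @classmethod
    def from_counts(cls, counts: np.ndarray) -> "ConcordanceTable":
        counts = np.asarray(counts, dtype=int)
        if counts.shape != (5, 5):
            raise InputError("concordance table must be 5x5")
        row_totals = counts.sum(axis=1)
        diag = {
            b: (_pct1(counts[i, i], row_totals[i]) if row_totals[i] else None)
            for i, b in enumerate(GA_BINS)
        }
        return cls(counts=counts, row_totals=row_totals, diagonal_pct=diag,
                   n=int(counts.sum()))

    @classmethod
    def from_predictions(cls, predictions: PredictionSet) -> "ConcordanceTable":
        if len(predictions) == 0:
            raise InputError("concordance table of an empty prediction set")
        rows = _bin_index(predictions.ga_ultrasound)
        cols = _bin_index(predictions.ga_predicted)
        counts = np.zeros((5, 5), dtype=int)
        np.add.at(counts, (rows, cols), 1)
        return cls.from_counts(counts)


def concordance_table(predictions: PredictionSet) -> ConcordanceTable:
    return ConcordanceTable.from_predictions(predictions)


@dataclass
class PrevalenceTable:
    """Per-bin counts/percentages for ultrasound vs predicted GA, plus the
    aggregate <37-week (preterm) prevalence of each column."""

    ultrasound_counts: dict[str, int]
    predicted_counts: dict[str, int]
    ultrasound_pct: dict[str, float]
    predicted_pct: dict[str, float]
    ultrasound_preterm_pct: float
    predicted_preterm_pct: float
    n: int

    @classmethod
    def from_counts(
        cls, ultrasound: dict[str, int], predicted: dict[str, int]
    ) -> "PrevalenceTable":
        u = {b: int(ultrasound.get(b, 0)) for b in GA_BINS}
        p = {b: int(predicted.get(b, 0)) for b in GA_BINS}
        n = sum(u.values())
        if n == 0:
            raise InputError("prevalence table needs at least one record")
        if sum(p.values()) != n:
            raise InputError("ultrasound and predicted totals differ")
        return cls(
            ultrasound_counts=u,
            predicted_counts=p,
            ultrasound_pct={b: _pct1(u[b], n) for b in GA_BINS},
            predicted_pct={b: _pct1(p[b], n) for b in GA_BINS},
            ultrasound_preterm_pct=_pct1(u["<=34"] + u["35-36"], n),
            predicted_preterm_pct=_pct1(p["<=34"] + p["35-36"], n),
            n=n,
        )

    @classmethod
    def from_predictions(cls, predictions: PredictionSet) -> "PrevalenceTable":
        if len(predictions) == 0:
            raise InputError("prevalence table of an empty prediction set")
        u_idx = _bin_index(predictions.ga_ultrasound)
        p_idx = _bin_index(predictions.ga_predicted)
        u = {b: int(np.sum(u_idx == i)) for i, b in enumerate(GA_BINS)}
        p = {b: int(np.sum(p_idx == i)) for i, b in enumerate(GA_BINS)}
        return cls.from_counts(u, p)


def prevalence_table(predictions: PredictionSet) -> PrevalenceTable:
    return PrevalenceTable.from_predictions(predictions)


@dataclass
class SubgroupMetrics:
    n: int
    rmse: float
    discrepancy: DiscrepancyTable


def subgroup_metrics(
    predictions: PredictionSet, by: str = "all", rounding: str = "half_up"
) -> dict[str, SubgroupMetrics]:
    """RMSE and discrepancy table per subgroup (``region``, ``sga`` or ``all``).

    Empty subgroups are omitted with a warning; the subgroup sizes partition n.
    """
    if by == "all":
        masks = {"all": np.ones(len(predictions), dtype=bool)}
    elif by == "region":
        masks = {
            str(r): predictions.region == r for r in np.unique(predictions.region)
        }
    elif by == "sga":
        masks = {"sga": predictions.sga, "non_sga": ~predictions.sga}
    else:
        raise InputError(f"unknown subgroup axis {by!r}")
    out: dict[str, SubgroupMetrics] = {}
    for name, mask in masks.items():
        if not np.any(mask):
            logger.warning("subgroup %s is empty; omitted", name)
            continue
        sub = predictions.subset(mask)
        out[name] = SubgroupMetrics(
            n=len(sub),
            rmse=rmse(sub),
            discrepancy=DiscrepancyTable.from_predictions(sub, rounding),
        )
    return out
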