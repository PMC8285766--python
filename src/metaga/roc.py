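"""Preterm-discrimination statistics: ROC, AUC, Youden index, bootstrap CIs.

The classifier under study is the predicted gestational age itself: the
positive class is preterm birth (ultrasound GA below the cutoff, 37 weeks by
default) and a record tests positive when its predicted GA falls below a
criterion c — i.e. lower scores are more positive.  The ROC curve sweeps c
over every distinct predicted value (ties share a point, sentinels complete
the endpoints), AUC is the trapezoidal area (identically the Mann–Whitney
probability with ties counted half), and the Youden index is
J = max_c (sensitivity_c + specificity_c − 1).

Uncertainty is quantified by a nonparametric percentile bootstrap: records
are resampled whole and unstratified (stratified-by-class resampling is
available behind a flag), 2000 replications at a fixed seed of 20 by default.
Degenerate resamples containing a single class are redrawn (capped, logged).
Two ROC curves from independent groups are compared by bootstrapping the
AUC difference, with a two-sided tail p-value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats as _sps

from .errors import InputError, MetagaError
from .model import PredictionSet

__all__ = [
    "RocPoint",
    "RocCurve",
    "YoudenResult",
    "BootstrapCI",
    "OperatingPoint",
    "RocComparison",
    "roc_curve",
    "roc_curve_from_scores",
    "auc",
    "auc_from_scores",
    "youden",
    "bootstrap_ci",
    "fixed_operating_point",
    "compare_roc",
]

logger = logging.getLogger("metaga.roc")

_REDRAW_FACTOR = 10  # cap on degenerate-resample redraws, per bootstrap


@dataclass(frozen=True)
class RocPoint:
    criterion: float  # predicted-GA threshold c; positive ⇔ score < c
    sensitivity: float
    specificity: float


@dataclass
class RocCurve:
    points: list[RocPoint]
    n_positive: int
    n_negative: int
    #: orientation note: positive class = preterm; test positive ⇔ score < c
    orientation: str = "lower score is more positive"


@dataclass
class YoudenResult:
    j: float
    criterion: float
    sensitivity: float
    specificity: float


@dataclass
class BootstrapCI:
    estimate: float
    lower: float
    upper: float
    replications: int
    seed: int
    level: float = 0.95
    n_redraws: int = 0
    widened: bool = False


@dataclass
class OperatingPoint:
    point: RocPoint
    fixed: str  # "sensitivity" or "specificity"
    fixed_value: float
    ci: BootstrapCI | None = None


@dataclass
class RocComparison:
    delta_auc: float
    delta_auc_pct: float  # same quantity in percentage points
    auc_a: float
    auc_b: float
    ci: BootstrapCI
    p_value: float


def _scores_labels(predictions: PredictionSet, cutoff: float | None = None):
    labels = (
        predictions.ga_ultrasound < cutoff if cutoff is not None else predictions.preterm
    )
    return predictions.ga_predicted.astype(float), np.asarray(labels, dtype=bool)


def roc_curve_from_scores(scores: np.ndarray, labels: np.ndarray) -> RocCurve:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos, n_neg = int(labels.sum()), int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise InputError("ROC needs both classes present")
    pos = np.sort(scores[labels])
    neg = np.sort(scores[~labels])
    crits = np.unique(scores)
    sens = np.searchsorted(pos, crits, side="left") / n_pos
    spec = 1.0 - np.searchsorted(neg, crits, side="left") / n_neg
    points = [
        RocPoint(float(c), float(se), float(sp))
        for c, se, sp in zip(crits, sens, spec)
    ]
    points.append(RocPoint(np.inf, 1.0, 0.0))
    return RocCurve(points=points, n_positive=n_pos, n_negative=n_neg)


def roc_curve(predictions: PredictionSet, cutoff: float = 37.0) -> RocCurve:
    """ROC of predicted GA against the <cutoff-week preterm gold standard."""
    scores, labels = _scores_labels(predictions, cutoff)
    return roc_curve_from_scores(scores, labels)


def auc(curve: RocCurve) -> float:
    """Trapezoidal area under the curve (= Mann–Whitney with ties half)."""
    x = np.array([1.0 - p.specificity for p in curve.points])
    y = np.array([p.sensitivity for p in curve.points])
    order = np.argsort(x, kind="stable")
    return float(np.trapezoid(y[order], x[order]))


def auc_from_scores(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann–Whitney AUC: P(score_pos < score_neg) + ½·P(tie)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos, n_neg = int(labels.sum()), int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise InputError("AUC needs both classes present")
    ranks = _sps.rankdata(scores)
    u_pos = ranks[labels].sum() - n_pos * (n_pos + 1) / 2  # #(neg<pos) + ½ ties
    return float(1.0 - u_pos / (n_pos * n_neg))


def youden(curve: RocCurve) -> YoudenResult:
    """Exhaustive scan of J over every criterion; ties favour sensitivity."""
    best: RocPoint | None = None
    best_j = -np.inf
    for p in curve.points:
        j = p.sensitivity + p.specificity - 1.0
        if j > best_j + 1e-12 or (
            abs(j - best_j) <= 1e-12
            and best is not None
            and p.sensitivity > best.sensitivity
        ):
            best, best_j = p, j
    assert best is not None
    return YoudenResult(
        j=float(best_j),
        criterion=best.criterion,
        sensitivity=best.sensitivity,
        specificity=best.specificity,
    )


def _point_at_fixed(curve: RocCurve, fix: str, value: float) -> RocPoint:
    if fix == "sensitivity":
        cands = [p for p in curve.points if p.sensitivity >= value]
        if not cands:
            raise InputError(f"no point reaches sensitivity {value}")
        return max(cands, key=lambda p: (p.specificity, p.sensitivity))
    if fix == "specificity":
        cands = [p for p in curve.points if p.specificity >= value]
        if not cands:
            raise InputError(f"no point reaches specificity {value}")
        return max(cands, key=lambda p: (p.sensitivity, p.specificity))
    raise InputError("fix must be 'sensitivity' or 'specificity'")


# ---------------------------------------------------------------------------
# bootstrap machinery

_STATISTICS = ("auc", "youden_j", "criterion", "sens_at_spec", "spec_at_sens")


def _resolve_statistic(statistic, fixed_value: float | None):
    if callable(statistic):
        return statistic
    if statistic == "auc":
        return auc_from_scores
    if statistic == "youden_j":
        return lambda s, l: youden(roc_curve_from_scores(s, l)).j
    if statistic == "criterion":
        return lambda s, l: youden(roc_curve_from_scores(s, l)).criterion
    if statistic in ("sens_at_spec", "spec_at_sens"):
        if fixed_value is None:
            raise InputError(f"statistic {statistic!r} needs fixed_value")
        fix = "specificity" if statistic == "sens_at_spec" else "sensitivity"
        free = "sensitivity" if statistic == "sens_at_spec" else "specificity"
        return lambda s, l: getattr(
            _point_at_fixed(roc_curve_from_scores(s, l), fix, fixed_value), free
        )
    raise InputError(f"unknown statistic {statistic!r}; choose from {_STATISTICS}")


def _resample_indices(rng, labels, stratified):
    n = len(labels)
    if stratified:
        pos_idx = np.flatnonzero(labels)
        neg_idx = np.flatnonzero(~labels)
        return np.concatenate(
            [rng.choice(pos_idx, len(pos_idx)), rng.choice(neg_idx, len(neg_idx))]
        )
    return rng.integers(0, n, n)


def bootstrap_ci(
    predictions: PredictionSet,
    statistic: str = "auc",
    B: int = 2000,
    seed: int = 20,
    level: float = 0.95,
    cutoff: float = 37.0,
    fixed_value: float | None = None,
    stratified: bool = False,
) -> BootstrapCI:
    """Percentile bootstrap CI for a ROC statistic.

    Whole records are resampled with replacement; resamples with a single
    class are redrawn (up to ``10*B`` total redraws) so B effective
    replicates are always used.  Fully reproducible from ``seed``.
    """
    scores, labels = _scores_labels(predictions, cutoff)
    stat = _resolve_statistic(statistic, fixed_value)
    estimate = float(stat(scores, labels))
    rng = np.random.default_rng(seed)
    values = np.empty(B)
    redraws = 0
    for b in range(B):
        while True:
            idx = _resample_indices(rng, labels, stratified)
            lab = labels[idx]
            if 0 < lab.sum() < len(lab):
                break
            redraws += 1
            if redraws > _REDRAW_FACTOR * B:
                raise MetagaError("too many degenerate bootstrap resamples")
        values[b] = stat(scores[idx], lab)
    if redraws:
        logger.info("bootstrap redrew %d degenerate resamples", redraws)
    alpha = 1.0 - level
    lower, upper = np.quantile(values, [alpha / 2, 1 - alpha / 2])
    widened = False
    if not lower <= estimate <= upper:  # rare percentile-method pathology
        lower, upper = min(lower, estimate), max(upper, estimate)
        widened = True
        logger.warning("percentile CI widened to include the point estimate")
    return BootstrapCI(
        estimate=estimate,
        lower=float(lower),
        upper=float(upper),
        replications=B,
        seed=seed,
        level=level,
        n_redraws=redraws,
        widened=widened,
    )


def fixed_operating_point(
    curve: RocCurve,
    fix: str,
    value: float,
    predictions: PredictionSet | None = None,
    B: int = 2000,
    seed: int = 20,
    level: float = 0.95,
    cutoff: float = 37.0,
) -> OperatingPoint:
    """The achievable ROC point with the fixed coordinate ≥ ``value`` and the
    largest free coordinate; with ``predictions`` supplied, a bootstrap CI on
    the free coordinate is attached."""
    if not 0 < value < 1:
        raise InputError("fixed value must lie in (0, 1)")
    point = _point_at_fixed(curve, fix, value)
    ci = None
    if predictions is not None:
        statistic = "spec_at_sens" if fix == "sensitivity" else "sens_at_spec"
        ci = bootstrap_ci(
            predictions, statistic, B=B, seed=seed, level=level, cutoff=cutoff,
            fixed_value=value,
        )
    return OperatingPoint(point=point, fixed=fix, fixed_value=value, ci=ci)


def compare_roc(
    pred_a: PredictionSet,
    pred_b: PredictionSet,
    B: int = 2000,
    seed: int = 20,
    level: float = 0.95,
    cutoff: float = 37.0,
) -> RocComparison:
    """Bootstrap comparison of two independent ROC curves.

    ΔAUC = AUC_a − AUC_b with a percentile CI from independent resampling of
    each group, and a two-sided bootstrap tail p-value with +1 smoothing.
    """
    common = set(map(str, pred_a.ids)) & set(map(str, pred_b.ids))
    if common:
        raise InputError(
            f"groups share {len(common)} record ids; independent groups required"
        )
    s_a, l_a = _scores_labels(pred_a, cutoff)
    s_b, l_b = _scores_labels(pred_b, cutoff)
    auc_a = auc_from_scores(s_a, l_a)
    auc_b = auc_from_scores(s_b, l_b)
    delta = auc_a - auc_b
    rng = np.random.default_rng(seed)
    deltas = np.empty(B)
    redraws = 0
    for b in range(B):
        while True:
            ia = rng.integers(0, len(l_a), len(l_a))
            ib = rng.integers(0, len(l_b), len(l_b))
            if 0 < l_a[ia].sum() < len(ia) and 0 < l_b[ib].sum() < len(ib):
                break
            redraws += 1
            if redraws > _REDRAW_FACTOR * B:
                raise MetagaError("too many degenerate bootstrap resamples")
        deltas[b] = auc_from_scores(s_a[ia], l_a[ia]) - auc_from_scores(s_b[ib], l_b[ib])
    alpha = 1.0 - level
    lower, upper = np.quantile(deltas, [alpha / 2, 1 - alpha / 2])
    widened = False
    if not lower <= delta <= upper:
        lower, upper = min(lower, delta), max(upper, delta)
        widened = True
    p = 2.0 * min(
        (np.sum(deltas <= 0) + 1) / (B + 1), (np.sum(deltas >= 0) + 1) / (B + 1)
    )
    ci = BootstrapCI(
        estimate=float(delta), lower=float(lower), upper=float(upper),
        replications=B, seed=seed, level=level, n_redraws=redraws, widened=widened,
    )
    return RocComparison(
        delta_auc=float(delta),
        delta_auc_pct=float(100.0 * delta),
        auc_a=float(auc_a),
        auc_b=float(auc_b),
        ci=ci,
        p_value=float(min(p, 1.0)),
    )
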