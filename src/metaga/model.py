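"""Gestational-age regression models on the metabolite panel.

Two ordinary-least-squares models predict postnatal GA (decimal weeks) from
the dried-blood-spot screen:

* the *metabolites model* — polynomial terms (linear, squared, cubic, subject
  to panel eligibility) of the analyte concentrations;
* the *metabolites + birthweight model* — the same terms plus birthweight.

Model building follows a two-stage screen-and-retain procedure: each analyte
is first screened univariately (one polynomial OLS per analyte, marginal
t-test per power, keep terms with P below the screening threshold), then the
surviving terms enter one multivariable OLS which is pruned by backward
elimination until every remaining term has P below the retention threshold.
A cubic term is admitted or retained only while the same analyte's squared
term is present (the stated hierarchy rule; a full linear-squared-cubic
hierarchy is available behind a flag).

Predictors are mean-centered before powering to tame the collinearity of
x, x², x³; the centering constants travel with the fitted coefficients so
prediction is exact and externally supplied coefficient sets (centers zero)
evaluate raw powers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cohort import Cohort
from .errors import (
    CoefficientError,
    DegenerateInputError,
    InsufficientDataError,
    NoInformativeTermsError,
    RankDeficientError,
)
from .panel import MetabolitePanel

__all__ = [
    "BIRTHWEIGHT",
    "Term",
    "ModelSpec",
    "FitDiagnostics",
    "CoefficientSet",
    "ScreenRow",
    "PredictionSet",
    "enumerate_candidates",
    "univariate_screen",
    "screen_all",
    "select_terms",
    "fit_model",
    "predict_ga",
]

logger = logging.getLogger("metaga.model")

#: Pseudo-analyte name for the birthweight covariate (always power 1).
BIRTHWEIGHT = "birthweight"


@dataclass(frozen=True, order=True)
class Term:
    """One model term: an analyte (or birthweight) raised to a power."""

    analyte: str
    power: int

    def __post_init__(self) -> None:
        if self.power not in (1, 2, 3):
            raise CoefficientError(f"power must be 1, 2 or 3, got {self.power}")
        if self.analyte == BIRTHWEIGHT and self.power != 1:
            raise CoefficientError("birthweight enters linearly only")

    @property
    def key(self) -> str:
        return f"{self.analyte}^{self.power}"

    @classmethod
    def from_key(cls, key: str) -> "Term":
        analyte, sep, power = key.rpartition("^")
        if not sep or not analyte:
            raise CoefficientError(f"malformed term key {key!r}")
        try:
            p = int(power)
        except ValueError as exc:
            raise CoefficientError(f"malformed power in term key {key!r}") from exc
        return cls(analyte, p)


@dataclass(frozen=True)
class ModelSpec:
    """An ordered set of terms defining a GA model's design matrix."""

    terms: tuple[Term, ...]

    def __post_init__(self) -> None:
        if len(set(self.terms)) != len(self.terms):
            raise CoefficientError("duplicate terms in model spec")
        present = {(t.analyte, t.power) for t in self.terms}
        for t in self.terms:
            if t.power == 3 and (t.analyte, 2) not in present:
                raise CoefficientError(
                    f"hierarchy violation: {t.key} without {t.analyte}^2"
                )

    @property
    def includes_birthweight(self) -> bool:
        return any(t.analyte == BIRTHWEIGHT for t in self.terms)

    @property
    def analytes(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for t in self.terms:
            if t.analyte != BIRTHWEIGHT:
                seen.setdefault(t.analyte, None)
        return tuple(seen)

    def with_birthweight(self) -> "ModelSpec":
        if self.includes_birthweight:
            return self
        return ModelSpec(self.terms + (Term(BIRTHWEIGHT, 1),))

    def validate_against(self, panel: MetabolitePanel) -> None:
        for t in self.terms:
            if t.analyte == BIRTHWEIGHT:
                continue
            if not panel.allows(t.analyte, t.power):
                raise CoefficientError(
                    f"term {t.key} not admissible: analyte unknown or power "
                    f"exceeds its panel eligibility"
                )


@dataclass
class FitDiagnostics:
    n: int
    residual_sd: float
    pvalues: dict[Term, float]
    stderr: dict[Term, float]


@dataclass
class CoefficientSet:
    """A fitted (or externally supplied) GA model.

    Prediction evaluates ``intercept + sum(coef * (x - center)**power)``;
    centers default to zero so external coefficient files operate on raw
    analyte values.
    """

    intercept: float
    coefficients: dict[Term, float]
    centers: dict[str, float] = field(default_factory=dict)
    diagnostics: FitDiagnostics | None = None

    @property
    def spec(self) -> ModelSpec:
        """Companion model spec (raises if the terms violate the hierarchy
        rule, which a locally selected model never does)."""
        return ModelSpec(tuple(sorted(self.coefficients)))

    @property
    def required_analytes(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for t in sorted(self.coefficients):
            if t.analyte != BIRTHWEIGHT:
                seen.setdefault(t.analyte, None)
        return tuple(seen)

    @property
    def includes_birthweight(self) -> bool:
        return any(t.analyte == BIRTHWEIGHT for t in self.coefficients)

    def center(self, analyte: str) -> float:
        return self.centers.get(analyte, 0.0)


@dataclass(frozen=True)
class ScreenRow:
    """Univariate screening outcome for one (analyte, power) term."""

    analyte: str
    power: int
    pvalue: float
    passed: bool


@dataclass
class PredictionSet:
    """Paired predicted vs ultrasound GA with subgroup flags."""

    ids: np.ndarray
    ga_ultrasound: np.ndarray
    ga_predicted: np.ndarray
    region: np.ndarray
    sga: np.ndarray
    preterm_cutoff: float = 37.0
    n_excluded: int = 0

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids)
        self.ga_ultrasound = np.asarray(self.ga_ultrasound, dtype=float)
        self.ga_predicted = np.asarray(self.ga_predicted, dtype=float)
        self.region = np.asarray(self.region)
        self.sga = np.asarray(self.sga, dtype=bool)
        lens = {
            len(self.ids),
            len(self.ga_ultrasound),
            len(self.ga_predicted),
            len(self.region),
            len(self.sga),
        }
        if len(lens) != 1:
            raise ValueError("prediction-set arrays must share one length")
        if len(self.ga_ultrasound) and not (
            np.all(np.isfinite(self.ga_ultrasound))
            and np.all(np.isfinite(self.ga_predicted))
        ):
            raise ValueError("paired GA values must be finite")

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def preterm(self) -> np.ndarray:
        """True preterm label from the ultrasound gold standard."""
        return self.ga_ultrasound < self.preterm_cutoff

    def subset(self, mask: np.ndarray) -> "PredictionSet":
        mask = np.asarray(mask, dtype=bool)
        return PredictionSet(
            ids=self.ids[mask],
            ga_ultrasound=self.ga_ultrasound[mask],
            ga_predicted=self.ga_predicted[mask],
            region=self.region[mask],
            sga=self.sga[mask],
            preterm_cutoff=self.preterm_cutoff,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids,
                "ga_ultrasound_wk": self.ga_ultrasound,
                "ga_predicted_wk": self.ga_predicted,
                "region": self.region,
                "sga": self.sga,
                "preterm": self.preterm,
            }
        )


def enumerate_candidates(panel: MetabolitePanel) -> list[Term]:
    """All admissible metabolite terms: every analyte linearly, plus the
    squared and cubic terms of the eligible subsets."""
    return [
        Term(a, p) for a in panel.analytes for p in panel.eligible_powers(a)
    ]


# ---------------------------------------------------------------------------
# design-matrix helpers


def _term_column(frame: pd.DataFrame, term: Term, centers: dict[str, float]) -> np.ndarray:
    col = "birthweight_g" if term.analyte == BIRTHWEIGHT else term.analyte
    x = frame[col].to_numpy(dtype=float)
    return (x - centers.get(term.analyte, 0.0)) ** term.power


def _design(frame: pd.DataFrame, terms: list[Term], centers: dict[str, float]) -> np.ndarray:
    cols = [np.ones(len(frame))]
    cols.extend(_term_column(frame, t, centers) for t in terms)
    return np.column_stack(cols)


def _full_rank_subset(X: np.ndarray, tol: float = 1e-8) -> list[int]:
    """Indices of a maximal linearly independent column subset, greedily in
    column order (mirrors how aliased coefficients are dropped in standard
    regression software)."""
    n, k = X.shape
    Q = np.empty((n, 0))
    keep: list[int] = []
    for j in range(k):
        col = X[:, j].astype(float)
        norm0 = np.linalg.norm(col)
        if norm0 == 0:
            continue
        r = col - Q @ (Q.T @ col)
        r = r - Q @ (Q.T @ r)  # one reorthogonalization pass
        if np.linalg.norm(r) > tol * norm0:
            Q = np.hstack([Q, (r / np.linalg.norm(r))[:, None]])
            keep.append(j)
    return keep


def _safe_pvalues(results, n_terms: int) -> np.ndarray:
    """Term p-values, robust to a numerically perfect fit (residual ~ 0),
    where the usual t-statistics degenerate to 0/0."""
    tss = float(np.sum((results.model.endog - results.model.endog.mean()) ** 2))
    if results.ssr <= 1e-14 * max(tss, 1.0):
        params = np.asarray(results.params)[1:]
        scale = max(np.max(np.abs(params), initial=0.0), 1.0)
        return np.where(np.abs(params) > 1e-10 * scale, 0.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.asarray(results.pvalues)[1:]


def _complete_frame(cohort: Cohort, analytes: list[str], need_birthweight: bool) -> pd.DataFrame:
    frame = cohort.to_frame()
    cols = ["ga_ultrasound_wk", *analytes]
    if need_birthweight:
        cols.append("birthweight_g")
    mask = frame[cols].notna().all(axis=1)
    n_drop = int((~mask).sum())
    if n_drop:
        logger.info("excluding %d incomplete records from fit", n_drop)
    return frame[mask]


# ---------------------------------------------------------------------------
# screening and selection


def univariate_screen(
    cohort: Cohort, analyte: str, p_univariate: float = 0.01
) -> list[ScreenRow]:
    """Screen one analyte: OLS of ultrasound GA on its eligible centered
    powers, with a marginal two-sided t-test per power."""
    powers = cohort.panel.eligible_powers(analyte)
    frame = _complete_frame(cohort, [analyte], need_birthweight=False)
    x = frame[analyte].to_numpy(dtype=float)
    y = frame["ga_ultrasound_wk"].to_numpy(dtype=float)
    if len(x) <= len(powers) + 1:
        raise InsufficientDataError(
            f"{analyte}: {len(x)} records for {len(powers)} powers"
        )
    if np.ptp(x) == 0:
        raise DegenerateInputError(f"{analyte} is constant in this cohort")
    c = float(x.mean())
    X = np.column_stack([np.ones_like(x)] + [(x - c) ** p for p in powers])
    results = sm.OLS(y, X).fit()
    pvals = _safe_pvalues(results, len(powers))
    return [
        ScreenRow(analyte, p, float(pv), bool(pv < p_univariate))
        for p, pv in zip(powers, pvals)
    ]


def screen_all(
    cohort: Cohort, p_univariate: float = 0.01, on_degenerate: str = "skip"
) -> list[ScreenRow]:
    """Screen every panel analyte; constant analytes are skipped with a
    warning (or re-raised when ``on_degenerate='raise'``)."""
    rows: list[ScreenRow] = []
    for analyte in cohort.panel.analytes:
        try:
            rows.extend(univariate_screen(cohort, analyte, p_univariate))
        except DegenerateInputError:
            if on_degenerate == "raise":
                raise
            logger.warning("skipping constant analyte %s in screen", analyte)
    n_pass = sum(r.passed for r in rows)
    logger.info("screen: %d of %d terms pass P<%g", n_pass, len(rows), p_univariate)
    return rows


def _enforce_hierarchy(terms: list[Term], full: bool) -> list[Term]:
    present = {(t.analyte, t.power) for t in terms}
    out = []
    for t in terms:
        if t.power == 3 and (t.analyte, 2) not in present:
            continue
        if full and t.power == 2 and (t.analyte, 1) not in present:
            continue
        out.append(t)
    if len(out) != len(terms):  # cascaded removals (cubic after squared)
        return _enforce_hierarchy(out, full)
    return out


def select_terms(
    screen: list[ScreenRow],
    cohort: Cohort,
    p_retain: float = 0.05,
    full_hierarchy: bool = False,
) -> ModelSpec:
    """Backward-eliminate the screened-in terms down to a final model spec.

    Entry: terms that passed the univariate screen, with a cubic admitted only
    when its squared term also passed (and, under ``full_hierarchy``, a squared
    term only when the linear passed).  Then a multivariable OLS is refit
    repeatedly, each round removing the single worst term with P >=
    ``p_retain`` (ties broken by (analyte, power)) and re-enforcing the
    hierarchy, until every remaining term is retained.
    """
    passed = {(r.analyte, r.power) for r in screen if r.passed}
    candidates = [
        Term(a, p)
        for (a, p) in sorted(passed)
        if p == 1
        or (p == 2 and (not full_hierarchy or (a, 1) in passed))
        or (p == 3 and (a, 2) in passed and (not full_hierarchy or (a, 1) in passed))
    ]
    candidates = _enforce_hierarchy(sorted(candidates), full_hierarchy)
    if not candidates:
        raise NoInformativeTermsError("no informative terms passed the screen")

    frame = _complete_frame(
        cohort, sorted({t.analyte for t in candidates}), need_birthweight=False
    )
    y = frame["ga_ultrasound_wk"].to_numpy(dtype=float)
    centers = {a: float(frame[a].mean()) for a in {t.analyte for t in candidates}}

    # Drop aliased columns up front (deterministic, keeps earlier terms).
    X = _design(frame, candidates, centers)
    keep = _full_rank_subset(X)
    kept_terms = [candidates[j - 1] for j in keep if j != 0]
    if len(kept_terms) != len(candidates):
        dropped = sorted(set(candidates) - set(kept_terms))
        logger.warning(
            "dropping aliased candidate terms: %s", [t.key for t in dropped]
        )
    terms = _enforce_hierarchy(sorted(kept_terms), full_hierarchy)

    while terms:
        X = _design(frame, terms, centers)
        results = sm.OLS(y, X).fit()
        pvals = _safe_pvalues(results, len(terms))
        over = [
            (pv, t) for pv, t in zip(pvals, terms) if not pv < p_retain
        ]
        if not over:
            break
        worst_p = max(pv for pv, _ in over)
        worst = min(t for pv, t in over if pv == worst_p)
        terms = _enforce_hierarchy([t for t in terms if t != worst], full_hierarchy)
        logger.debug("eliminated %s (P=%.4g), %d terms left", worst.key, worst_p, len(terms))
    if not terms:
        raise NoInformativeTermsError("backward elimination removed every term")
    return ModelSpec(tuple(sorted(terms)))


# ---------------------------------------------------------------------------
# fitting and prediction


def fit_model(cohort: Cohort, spec: ModelSpec) -> CoefficientSet:
    """Fit the OLS model implied by ``spec`` on the cohort's complete records.

    Returns the fitted coefficient set on the centered scale (centering
    constants included) with per-term p-values and the residual SD.
    Raises :class:`RankDeficientError` naming the collinear terms when the
    design matrix is not full rank.
    """
    spec.validate_against(cohort.panel)
    terms = list(spec.terms)
    frame = _complete_frame(
        cohort, list(spec.analytes), need_birthweight=spec.includes_birthweight
    )
    if len(frame) < len(terms) + 2:
        raise InsufficientDataError(
            f"{len(frame)} complete records for {len(terms)} terms"
        )
    y = frame["ga_ultrasound_wk"].to_numpy(dtype=float)
    centers = {a: float(frame[a].mean()) for a in spec.analytes}
    if spec.includes_birthweight:
        centers[BIRTHWEIGHT] = float(frame["birthweight_g"].mean())
    X = _design(frame, terms, centers)
    keep = _full_rank_subset(X)
    if len(keep) != X.shape[1]:
        aliased = [terms[j - 1].key for j in range(X.shape[1]) if j not in keep]
        raise RankDeficientError(aliased)
    results = sm.OLS(y, X).fit()
    pvals = _safe_pvalues(results, len(terms))
    with np.errstate(divide="ignore", invalid="ignore"):
        bse = np.asarray(results.bse)[1:]
    diagnostics = FitDiagnostics(
        n=len(frame),
        residual_sd=float(np.sqrt(max(results.ssr, 0.0) / max(results.df_resid, 1))),
        pvalues={t: float(pv) for t, pv in zip(terms, pvals)},
        stderr={t: float(se) for t, se in zip(terms, bse)},
    )
    logger.info(
        "fit: n=%d, %d terms, residual sd %.4f wk",
        len(frame), len(terms), diagnostics.residual_sd,
    )
    return CoefficientSet(
        intercept=float(results.params[0]),
        coefficients={t: float(b) for t, b in zip(terms, results.params[1:])},
        centers=centers,
        diagnostics=diagnostics,
    )


def predict_ga(
    cohort: Cohort,
    coefficients: CoefficientSet,
    preterm_cutoff: float = 37.0,
    clamp: tuple[float, float] | None = None,
) -> PredictionSet:
    """Apply a coefficient set to every record with complete required inputs.

    Records missing any referenced analyte (or birthweight, for the
    birthweight model) are excluded and counted, never imputed.  Predictions
    are raw model output by default; ``clamp=(lo, hi)`` optionally truncates
    them to a plausible GA window.
    """
    for a in coefficients.required_analytes:
        if a not in cohort.panel:
            raise CoefficientError(f"coefficient set references analyte {a!r} "
                                   "absent from the cohort panel")
    frame = cohort.to_frame()
    cols = list(coefficients.required_analytes)
    if coefficients.includes_birthweight:
        cols.append("birthweight_g")
    mask = frame[cols].notna().all(axis=1) if cols else pd.Series(True, index=frame.index)
    sub = frame[mask]
    pred = np.full(len(sub), coefficients.intercept, dtype=float)
    for term, beta in coefficients.coefficients.items():
        pred += beta * _term_column(sub, term, coefficients.centers)
    if clamp is not None:
        pred = np.clip(pred, clamp[0], clamp[1])
    n_excluded = int((~mask).sum())
    if n_excluded:
        logger.info("prediction excluded %d incomplete records", n_excluded)
    return PredictionSet(
        ids=sub["id"].to_numpy(),
        ga_ultrasound=sub["ga_ultrasound_wk"].to_numpy(dtype=float),
        ga_predicted=pred,
        region=sub["region"].to_numpy(),
        sga=sub["sga"].to_numpy(dtype=bool),
        preterm_cutoff=preterm_cutoff,
        n_excluded=n_excluded,
    )
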