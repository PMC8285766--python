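"""Synthetic newborn-screening cohorts with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes, with every parameter exposed and defaults read off the validation
cohort's marginals:

* gestational age: a two-component mixture — a term component,
  N(39.1, 1.1²) truncated to [37, 44.9) weeks, and a preterm component,
  N(34.8, 1.6²) truncated to [26, 36.9], mixed with preterm weight 11.4%;
* region: sub-Saharan Africa 56.1% / South Asia 43.9%; sex: 47.3% male;
* birthweight: Normal around a linear-in-GA, sex-offset mean
  (3300 g at 40 weeks, 180 g per week, ±60 g by sex, SD 380 g), redrawn in
  the rare case of a non-positive draw;
* SGA: birthweight below the analytic 10th percentile of its own conditional
  Normal — so SGA prevalence is 10% by construction in every sex×GA stratum;
* analytes: each concentration is a degree-≤3 polynomial in GA plus additive
  Gaussian noise.  Six analytes are informative by default (nonzero GA
  coefficients, chosen across the linear-only / squared / cubic eligibility
  classes) and the remaining 38 are pure noise, giving term selection a known
  oracle.  The informative slope-to-noise ratios are calibrated so that the
  metabolites model's designed hold-out prediction RMSE is ≈ 1.5 weeks
  (see docs/methods.md for the derivation).

All randomness flows from the config seed; the same config yields a
byte-identical cohort.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .cohort import Cohort, NewbornRecord
from .errors import MetagaError
from .panel import STANDARD_PANEL, MetabolitePanel

__all__ = [
    "AnalyteModel",
    "SimConfig",
    "TruthRecord",
    "default_analyte_models",
    "generate_cohort",
    "sga_threshold",
]

#: 10th-percentile z-score of the standard Normal.
Z10 = float(stats.norm.ppf(0.10))

_SITES = {"sub_saharan_africa": "pemba", "south_asia": "karachi_sylhet"}


@dataclass(frozen=True)
class AnalyteModel:
    """Conditional model for one analyte: value = β0 + β1·GA + β2·GA² + β3·GA³ + N(0, sd²)."""

    beta0: float
    beta1: float = 0.0
    beta2: float = 0.0
    beta3: float = 0.0
    sd: float = 1.0

    def mean(self, ga: np.ndarray) -> np.ndarray:
        ga = np.asarray(ga, dtype=float)
        return self.beta0 + self.beta1 * ga + self.beta2 * ga**2 + self.beta3 * ga**3

    @property
    def informative(self) -> bool:
        return any((self.beta1, self.beta2, self.beta3))


def _centered(a0: float, a1: float, a2: float, a3: float, sd: float,
              center: float = 38.5) -> AnalyteModel:
    """Build an AnalyteModel from a polynomial written about ``center`` weeks
    (raw coefficients are the binomial expansion)."""
    c = center
    return AnalyteModel(
        beta0=a0 - a1 * c + a2 * c**2 - a3 * c**3,
        beta1=a1 - 2 * a2 * c + 3 * a3 * c**2,
        beta2=a2 - 3 * a3 * c,
        beta3=a3,
        sd=sd,
    )


def default_analyte_models(panel: MetabolitePanel = STANDARD_PANEL) -> dict[str, AnalyteModel]:
    """Six informative analytes + pure-noise remainder.

    The informative set spans the eligibility classes (Tyrosine linear-only,
    Arginine squared-eligible, the rest cubic-eligible) so selection exercises
    every hierarchy rule.  Each informative slope-to-noise ratio is 0.161 per
    week, jointly targeting a ≈1.5-week conditional prediction SD.
    """
    informative = {
        "Tyrosine": _centered(60.0, 1.2, 0.0, 0.0, sd=7.45),
        "Alanine": _centered(300.0, 1.0, 0.02, 0.002, sd=6.21),
        "C2": _centered(25.0, -1.0, 0.03, -0.002, sd=6.21),
        "C5": _centered(40.0, 0.8, -0.02, 0.002, sd=4.97),
        "TSH": _centered(80.0, -1.2, 0.04, 0.0, sd=7.45),
        "Arginine": _centered(50.0, 0.9, 0.03, 0.0, sd=5.59),
    }
    models: dict[str, AnalyteModel] = {}
    for i, analyte in enumerate(panel.analytes):
        if analyte in informative:
            models[analyte] = informative[analyte]
        else:
            models[analyte] = AnalyteModel(beta0=5.0 + 0.5 * i, sd=1.0)
    return models


@dataclass
class SimConfig:
    """Generator parameters; defaults mirror the validation cohort marginals."""

    n: int = 1311
    seed: int = 20
    preterm_fraction: float = 0.114
    region_mix: dict[str, float] = field(
        default_factory=lambda: {"sub_saharan_africa": 0.561, "south_asia": 0.439}
    )
    male_fraction: float = 0.473
    ga_term_mean: float = 39.1      # weeks
    ga_term_sd: float = 1.1
    ga_term_bounds: tuple[float, float] = (37.0, 44.9)
    ga_preterm_mean: float = 34.8
    ga_preterm_sd: float = 1.6
    ga_preterm_bounds: tuple[float, float] = (26.0, 36.9)
    bw_intercept: float = 3300.0    # grams at 40 weeks, sex-neutral
    bw_slope_per_week: float = 180.0
    bw_sex_offset: float = 60.0     # +offset male, -offset female
    bw_sd: float = 380.0
    collection_age_mean: float = 49.0  # hours
    collection_age_sd: float = 16.2
    collection_age_bounds: tuple[float, float] = (24.0, 72.0)
    analyte_models: dict[str, AnalyteModel] = field(default_factory=default_analyte_models)
    #: optional per-analyte, per-region additive mean shift
    region_shift: dict[str, dict[str, float]] = field(default_factory=dict)
    #: optional per-analyte linear drift per hour of collection age (about 48 h)
    collection_age_drift: dict[str, float] = field(default_factory=dict)
    panel: MetabolitePanel = field(default_factory=lambda: STANDARD_PANEL)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise MetagaError("n must be >= 1")
        if not 0 <= self.preterm_fraction <= 1:
            raise MetagaError("preterm_fraction must lie in [0, 1]")
        if not 0 <= self.male_fraction <= 1:
            raise MetagaError("male_fraction must lie in [0, 1]")
        if abs(sum(self.region_mix.values()) - 1.0) > 1e-9:
            raise MetagaError("region_mix proportions must sum to 1")
        if any(p < 0 or p > 1 for p in self.region_mix.values()):
            raise MetagaError("region_mix proportions must lie in [0, 1]")
        for name in ("ga_term_sd", "ga_preterm_sd", "bw_sd", "collection_age_sd"):
            if getattr(self, name) <= 0:
                raise MetagaError(f"{name} must be > 0")
        for a, m in self.analyte_models.items():
            if m.sd < 0:
                raise MetagaError(f"analyte {a}: noise sd must be >= 0")

    def with_zero_noise(self) -> "SimConfig":
        """Copy with every analyte noise SD set to zero (means kept)."""
        models = {
            a: dataclasses.replace(m, sd=0.0) for a, m in self.analyte_models.items()
        }
        return dataclasses.replace(self, analyte_models=models)

    @property
    def ga_support(self) -> tuple[float, float]:
        return (self.ga_preterm_bounds[0], self.ga_term_bounds[1])


@dataclass(frozen=True)
class TruthRecord:
    """Latent ground truth behind one generated record."""

    id: str
    ga_true: float
    preterm: bool
    sga: bool
    bw_mean: float
    analyte_means: dict[str, float]


def sga_threshold(ga: float | np.ndarray, sex: str, config: SimConfig) -> float | np.ndarray:
    """Analytic 10th-percentile birthweight for (GA, sex) under the generator.

    threshold = conditional mean + z₀.₁₀·bw_sd; monotone increasing in GA.
    """
    ga_arr = np.asarray(ga, dtype=float)
    lo, hi = config.ga_support
    if np.any(ga_arr < lo) or np.any(ga_arr > hi):
        raise MetagaError(f"ga outside generator support [{lo}, {hi}]")
    if sex not in ("male", "female"):
        raise MetagaError(f"sex must be 'male' or 'female', got {sex!r}")
    offset = config.bw_sex_offset if sex == "male" else -config.bw_sex_offset
    mean = config.bw_intercept + config.bw_slope_per_week * (ga_arr - 40.0) + offset
    out = mean + Z10 * config.bw_sd
    return float(out) if np.isscalar(ga) else out


def _truncnorm(rng, mean, sd, bounds, size):
    a, b = (bounds[0] - mean) / sd, (bounds[1] - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_cohort(config: SimConfig) -> tuple[Cohort, list[TruthRecord]]:
    """Draw a cohort from the generator; returns the cohort and its truth."""
    rng = np.random.default_rng(config.seed)
    n = config.n
    panel = config.panel

    is_preterm = rng.random(n) < config.preterm_fraction
    ga_term = _truncnorm(rng, config.ga_term_mean, config.ga_term_sd,
                         config.ga_term_bounds, n)
    ga_pre = _truncnorm(rng, config.ga_preterm_mean, config.ga_preterm_sd,
                        config.ga_preterm_bounds, n)
    ga = np.where(is_preterm, ga_pre, ga_term)

    regions = list(config.region_mix)
    region = rng.choice(regions, size=n, p=[config.region_mix[r] for r in regions])
    sex = np.where(rng.random(n) < config.male_fraction, "male", "female")
    coll_age = _truncnorm(rng, config.collection_age_mean, config.collection_age_sd,
                          config.collection_age_bounds, n)

    offset = np.where(sex == "male", config.bw_sex_offset, -config.bw_sex_offset)
    bw_mean = config.bw_intercept + config.bw_slope_per_week * (ga - 40.0) + offset
    bw = bw_mean + rng.normal(0.0, config.bw_sd, size=n)
    bad = bw <= 0
    while np.any(bad):  # redraw the rare non-positive draws
        bw[bad] = bw_mean[bad] + rng.normal(0.0, config.bw_sd, size=int(bad.sum()))
        bad = bw <= 0
    sga = bw < (bw_mean + Z10 * config.bw_sd)

    analyte_values: dict[str, np.ndarray] = {}
    analyte_means: dict[str, np.ndarray] = {}
    for analyte in panel.analytes:
        model = config.analyte_models.get(analyte, AnalyteModel(beta0=0.0, sd=0.0))
        mean = model.mean(ga)
        shift = config.region_shift.get(analyte)
        if shift:
            mean = mean + np.array([shift.get(r, 0.0) for r in region])
        drift = config.collection_age_drift.get(analyte, 0.0)
        if drift:
            mean = mean + drift * (coll_age - 48.0)
        value = mean + rng.normal(0.0, model.sd, size=n) if model.sd > 0 else mean.copy()
        analyte_means[analyte] = mean
        analyte_values[analyte] = value

    records: list[NewbornRecord] = []
    truth: list[TruthRecord] = []
    for i in range(n):
        rid = f"S{i + 1:06d}"
        records.append(
            NewbornRecord(
                id=rid,
                region=str(region[i]),
                site=_SITES.get(str(region[i]), str(region[i])),
                sex=str(sex[i]),
                ga_ultrasound=float(ga[i]),
                birthweight=float(bw[i]),
                collection_age=float(coll_age[i]),
                metabolites={a: float(analyte_values[a][i]) for a in panel.analytes},
                sga=bool(sga[i]),
                twin=False,
            )
        )
        truth.append(
            TruthRecord(
                id=rid,
                ga_true=float(ga[i]),
                preterm=bool(is_preterm[i]),
                sga=bool(sga[i]),
                bw_mean=float(bw_mean[i]),
                analyte_means={a: float(analyte_means[a][i]) for a in panel.analytes},
            )
        )
    provenance = f"simulated(seed={config.seed}, n={n})"
    return Cohort(records=records, panel=panel, provenance=provenance), truth
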