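"""Core data containers: one newborn record, a cohort, and run configuration.

A :class:`NewbornRecord` is the atomic observation of the study — the infant's
metadata (region, sex, ultrasound-dated gestational age, birthweight, age at
heel-prick collection) plus its measured metabolite panel.  A :class:`Cohort`
is a list of records that share one :class:`~metaga.panel.MetabolitePanel`.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import pandas as pd

from .errors import MetagaError
from .panel import STANDARD_PANEL, MetabolitePanel

__all__ = ["NewbornRecord", "Cohort", "RunConfig", "REGIONS", "SEXES"]

#: Canonical region labels; the field itself accepts any non-empty string.
REGIONS = ("sub_saharan_africa", "south_asia")
SEXES = ("male", "female")

GA_BOUNDS = (20.0, 45.0)  # plausible ultrasound GA range, exclusive


@dataclass(frozen=True)
class NewbornRecord:
    """One infant: metadata plus the measured metabolite concentrations.

    ``birthweight`` may be ``None`` (the record is then usable by the
    metabolites-only model but excluded from any birthweight model).
    Metabolite units are carried opaquely; the models are unit-consistent as
    long as training and scoring use the same assay scale.
    """

    id: str
    region: str
    site: str
    sex: str
    ga_ultrasound: float  # decimal weeks
    birthweight: float | None  # grams
    collection_age: float  # hours after birth
    metabolites: dict[str, float]
    sga: bool = False
    twin: bool = False

    def validate(self, panel: MetabolitePanel) -> list[str]:
        """Return a list of invariant violations (empty when valid)."""
        problems: list[str] = []
        if not self.id:
            problems.append("empty id")
        if not self.region:
            problems.append("empty region")
        if self.sex not in SEXES:
            problems.append(f"sex must be one of {SEXES}, got {self.sex!r}")
        if not GA_BOUNDS[0] < self.ga_ultrasound < GA_BOUNDS[1]:
            problems.append(
                f"ga_ultrasound {self.ga_ultrasound} outside {GA_BOUNDS}"
            )
        if self.birthweight is not None and not self.birthweight > 0:
            problems.append(f"birthweight {self.birthweight} not positive")
        if not self.collection_age >= 0:
            problems.append(f"collection_age {self.collection_age} negative")
        unknown = set(self.metabolites) - set(panel.analytes)
        if unknown:
            problems.append(f"metabolites not in panel: {sorted(unknown)}")
        return problems


@dataclass
class Cohort:
    """A validated set of newborn records sharing one analyte panel.

    ``dropped`` records how many input rows were excluded at read time and
    why (the no-imputation rule: rows with any missing metabolite are dropped,
    never filled).  A cohort may be empty after filtering; operations that
    need data enforce their own minimum sizes.
    """

    records: list[NewbornRecord]
    panel: MetabolitePanel = field(default_factory=lambda: STANDARD_PANEL)
    provenance: str = ""
    dropped: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def n_dropped(self) -> int:
        return sum(self.dropped.values())

    def subset(self, indices) -> "Cohort":
        recs = [self.records[i] for i in indices]
        return Cohort(records=recs, panel=self.panel, provenance=self.provenance)

    def to_frame(self) -> pd.DataFrame:
        """Tabular view: metadata columns then one column per panel analyte."""
        rows = []
        for r in self.records:
            row = {
                "id": r.id,
                "region": r.region,
                "site": r.site,
                "sex": r.sex,
                "ga_ultrasound_wk": r.ga_ultrasound,
                "birthweight_g": r.birthweight,
                "collection_age_h": r.collection_age,
                "sga": r.sga,
                "twin": r.twin,
            }
            for a in self.panel.analytes:
                row[a] = r.metabolites.get(a)
            rows.append(row)
        cols = [
            "id",
            "region",
            "site",
            "sex",
            "ga_ultrasound_wk",
            "birthweight_g",
            "collection_age_h",
            "sga",
            "twin",
            *self.panel.analytes,
        ]
        return pd.DataFrame(rows, columns=cols)

    def digest(self) -> str:
        """Stable content digest, used to stamp report provenance."""
        payload = self.to_frame().to_csv(index=False, float_format="%.12g")
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunConfig:
    """Analysis thresholds and reproducibility knobs.

    Defaults follow the study conventions: term screening at P < 0.01,
    retention at P < 0.05, preterm cutoff at 37 completed weeks, and
    percentile bootstrap with 2000 replications at a fixed seed of 20.
    """

    p_univariate: float = 0.01
    p_retain: float = 0.05
    bootstrap_replications: int = 2000
    bootstrap_seed: int = 20
    rounding: str = "half_up"  # week-discrepancy rounding mode
    preterm_cutoff: float = 37.0
    level: float = 0.95
    fixed_sensitivities: tuple[float, ...] = (0.9,)
    fixed_specificities: tuple[float, ...] = (0.9,)
    clamp: tuple[float, float] | None = None  # optional prediction clamp, weeks
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        for name in ("p_univariate", "p_retain"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise MetagaError(f"{name} must lie in (0, 1), got {v}")
        if self.bootstrap_replications < 1:
            raise MetagaError("bootstrap_replications must be >= 1")
        if self.rounding not in ("half_up", "floor", "ceiling"):
            raise MetagaError(f"unknown rounding mode {self.rounding!r}")
        if not 0 < self.level < 1:
            raise MetagaError("confidence level must lie in (0, 1)")


def with_metabolites(record: NewbornRecord, metabolites: dict[str, float]) -> NewbornRecord:
    return replace(record, metabolites=metabolites)
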