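"""Analyte panel for the newborn dried-blood-spot metabolic screen.

The gestational-age models operate on a fixed panel of 44 analytes measured by
tandem mass spectrometry on heel-prick cards: amino acids, acylcarnitines and
three enzyme/hormone markers.  Nonlinearity between analyte concentration and
gestational age is handled with squared and cubic terms, but only a published
subset of analytes is eligible for each higher power.  The panel object carries
the analyte list plus those eligibility sets and is the single source of truth
for which (analyte, power) terms a model may contain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["MetabolitePanel", "STANDARD_PANEL", "standard_panel"]

# Amino acids (the combined isoleucine+leucine channel is one analyte).
_AMINO_ACIDS = (
    "Alanine",
    "Arginine",
    "Citrulline",
    "Glycine",
    "IleLeu",
    "Methionine",
    "Ornithine",
    "Phenylalanine",
    "Proline",
    "Tyrosine",
    "Valine",
)

# Acylcarnitines by carbon chain; C4 is the combined butyryl+isobutyryl channel.
_ACYLCARNITINES = (
    "C0",
    "C2",
    "C3",
    "C3-DC",
    "C4",
    "C4-DC",
    "C5",
    "C5:1",
    "C5-OH",
    "C5-DC",
    "C6",
    "C6-DC",
    "C8",
    "C8:1",
    "C10",
    "C10:1",
    "C12",
    "C12:1",
    "C14",
    "C14:1",
    "C14-OH",
    "C16",
    "C16:1",
    "C16-OH",
    "C16:1-OH",
    "C18",
    "C18:1",
    "C18:1-OH",
    "C18:2",
)

# Galactose-1-phosphate uridyl transferase, 17-hydroxyprogesterone, thyroid
# stimulating hormone, succinylacetone.
_OTHER = ("GALT", "17OHP", "TSH", "SUAC")

_ANALYTES = _AMINO_ACIDS + _ACYLCARNITINES + _OTHER

# Analytes whose squared term may enter a model (29 names).
_SQUARED = (
    "Alanine",
    "Arginine",
    "IleLeu",
    "Methionine",
    "Phenylalanine",
    "Valine",
    "C2",
    "C5",
    "C4-DC",
    "C5-DC",
    "C6",
    "C8",
    "C8:1",
    "C10",
    "C12",
    "C12:1",
    "C6-DC",
    "C14",
    "C16",
    "C16:1",
    "C18",
    "C18:1",
    "C18:2",
    "C14-OH",
    "C16-OH",
    "C16:1-OH",
    "GALT",
    "TSH",
    "17OHP",
)

# Analytes whose cubic term may enter (21 names, a subset of the squared set).
_CUBIC = (
    "Alanine",
    "IleLeu",
    "Methionine",
    "Phenylalanine",
    "Valine",
    "C2",
    "C5",
    "C4-DC",
    "C5-DC",
    "C8",
    "C8:1",
    "C10",
    "C12",
    "C12:1",
    "C16",
    "C16:1",
    "C18",
    "C18:1",
    "C18:2",
    "C16-OH",
    "TSH",
)


@dataclass(frozen=True)
class MetabolitePanel:
    """An ordered analyte list with squared/cubic term eligibility.

    Invariants (checked at construction): analyte names are unique, and
    ``cubic_eligible`` is a subset of ``squared_eligible``, itself a subset of
    ``analytes``.
    """

    analytes: tuple[str, ...]
    squared_eligible: frozenset[str] = field(default_factory=frozenset)
    cubic_eligible: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        names = set(self.analytes)
        if len(names) != len(self.analytes):
            raise ValueError("panel analyte names must be unique")
        if not self.squared_eligible <= names:
            extra = sorted(self.squared_eligible - names)
            raise ValueError(f"squared-eligible analytes not in panel: {extra}")
        if not self.cubic_eligible <= self.squared_eligible:
            extra = sorted(self.cubic_eligible - self.squared_eligible)
            raise ValueError(
                f"cubic-eligible analytes must also be squared-eligible: {extra}"
            )

    def __contains__(self, analyte: str) -> bool:
        return analyte in self.analytes

    def max_power(self, analyte: str) -> int:
        """Highest polynomial power the panel allows for ``analyte``."""
        if analyte not in self.analytes:
            raise KeyError(f"unknown analyte {analyte!r}")
        if analyte in self.cubic_eligible:
            return 3
        if analyte in self.squared_eligible:
            return 2
        return 1

    def eligible_powers(self, analyte: str) -> tuple[int, ...]:
        return tuple(range(1, self.max_power(analyte) + 1))

    def allows(self, analyte: str, power: int) -> bool:
        """Whether the (analyte, power) term is admissible under this panel."""
        if analyte not in self.analytes or power not in (1, 2, 3):
            return False
        return power <= self.max_power(analyte)


def standard_panel() -> MetabolitePanel:
    """The default 44-analyte screen panel with published term eligibility."""
    return MetabolitePanel(
        analytes=_ANALYTES,
        squared_eligible=frozenset(_SQUARED),
        cubic_eligible=frozenset(_CUBIC),
    )


STANDARD_PANEL = standard_panel()
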