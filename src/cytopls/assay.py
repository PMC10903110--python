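"""Deterministic concentration arithmetic for peptide treatment and uptake
bookkeeping: volumetric dilution, percent internalization, molar↔mass
conversion, and immunoassay dilution-range checking.

All operations are pure and exact for rational inputs. The default molecular
weight is that of the Aβ42 monomer (4514.1 g/mol); the default assay range is
a sandwich-ELISA sensitivity window of 15.6–1000 pg/mL, with both bounds
treated as inclusive.
"""

from __future__ import annotations

import dataclasses
from typing import NamedTuple

ABETA42_MW = 4514.1  # g/mol, Aβ42 monomer
DEFAULT_ASSAY_RANGE = (15.6, 1000.0)  # pg/mL


class AssayError(ValueError):
    pass


@dataclasses.dataclass
class DilutionScenario:
    """A treatment/measurement scenario in nM.

    ``dilution_factor`` is the volumetric fold-dilution: a 1:1 mix of equal
    volumes is factor 2.
    """

    dose: float  # treatment concentration, nM
    residual: float  # measured concentration after incubation, nM
    dilution_factor: float = 2.0
    molecular_weight: float = ABETA42_MW  # g/mol
    assay_range: tuple[float, float] = DEFAULT_ASSAY_RANGE  # pg/mL

    def __post_init__(self) -> None:
        if self.dose <= 0:
            raise AssayError("dose must be positive")
        if self.residual < 0:
            raise AssayError("residual must be non-negative")
        if self.residual > self.dose:
            raise AssayError("residual cannot exceed dose")
        if self.dilution_factor < 1:
            raise AssayError("dilution_factor must be >= 1")


class PercentInternalized(NamedTuple):
    raw: float  # percent, unrounded
    rounded: int  # nearest whole percent


class RangeCheck(NamedTuple):
    in_range: bool
    back_calculated: float  # measured-in-well value × dilution factor


def diluted_concentration(scenario: DilutionScenario) -> float:
    """Concentration after volumetric dilution: residual / dilution_factor."""
    return scenario.residual / scenario.dilution_factor


def percent_internalized(scenario: DilutionScenario) -> PercentInternalized:
    """Percent of the dose removed from the medium: 100 × (1 − residual/dose)."""
    raw = 100.0 * (1.0 - scenario.residual / scenario.dose)
    return PercentInternalized(raw=raw, rounded=int(round(raw)))


def percent_of_dose(concentration: float, dose: float) -> float:
    """100 × concentration / dose."""
    if dose <= 0:
        raise AssayError("dose must be positive")
    if concentration < 0:
        raise AssayError("concentration must be non-negative")
    return 100.0 * concentration / dose


def nm_to_ng_per_ml(concentration_nm: float, molecular_weight: float = ABETA42_MW) -> float:
    """Convert nM to ng/mL: c[nM] × MW[g/mol] / 1000."""
    if concentration_nm <= 0 or molecular_weight <= 0:
        raise AssayError("concentration and molecular weight must be positive")
    return concentration_nm * molecular_weight / 1000.0


def check_assay_range(
    measured_in_well: float,
    dilution_factor: float,
    assay_range: tuple[float, float] = DEFAULT_ASSAY_RANGE,
) -> RangeCheck:
    """Check an in-well (post-dilution) measurement against the kit range.

    Returns whether the in-well value sits inside the inclusive sensitivity
    window, and the back-calculated sample concentration
    (measured × dilution factor).
    """
    low, high = assay_range
    if low >= high:
        raise AssayError("assay range must satisfy low < high")
    if measured_in_well < 0 or dilution_factor < 1:
        raise AssayError("measurement must be >= 0 and dilution_factor >= 1")
    return RangeCheck(
        in_range=low <= measured_in_well <= high,
        back_calculated=measured_in_well * dilution_factor,
    )


def in_well_concentration(sample_concentration: float, dilution_factor: float) -> float:
    """Expected in-well value after diluting a sample by ``dilution_factor``."""
    if dilution_factor < 1:
        raise AssayError("dilution_factor must be >= 1")
    return sample_concentration / dilution_factor
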