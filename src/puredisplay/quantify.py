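"""Display-efficiency, coverage and PCR-quantification arithmetic.

The bookkeeping layer of a ribosome-display campaign: how many input mRNA
molecules are needed to cover a library at a given display efficiency, how
many functional ribosome-mRNA-protein (RMP) complexes a clone forms, and
how band intensities after a known number of PCR doubling cycles convert
back to template amounts and spike-in proportions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

__all__ = [
    "EfficiencyRecord",
    "PcrModel",
    "CoverageSpec",
    "display_efficiency",
    "required_input",
    "expected_complexes",
    "prob_displayed",
    "pcr_amplify",
    "initial_template",
    "spike_proportion",
    "detection_cycles",
]


@dataclass(frozen=True)
class PcrModel:
    """Exponential PCR amplification with a gel-detection threshold.

    ``per_cycle_factor`` defaults to 2 (perfect doubling, the assumption
    behind back-calculating a template as product / 2**cycles); values in
    (1, 2] model sub-exponential efficiency as 1 + E.
    ``detection_threshold_mass`` is the product mass (ng) at which a band
    becomes visible on a gel.
    """

    per_cycle_factor: float = 2.0
    detection_threshold_mass: float = 10.0

    def __post_init__(self) -> None:
        if not 1.0 < self.per_cycle_factor <= 2.0:
            raise ValueError("per_cycle_factor must lie in (1, 2]")
        if self.detection_threshold_mass <= 0:
            raise ValueError("detection threshold must be positive")


@dataclass(frozen=True)
class EfficiencyRecord:
    """One measured display-efficiency data point."""

    input_molecules: float
    eluted_molecules: float

    @property
    def efficiency(self) -> float:
        return display_efficiency(self.input_molecules, self.eluted_molecules)


@dataclass(frozen=True)
class CoverageSpec:
    """Input requirement for covering a library at a target redundancy."""

    diversity: float
    efficiency: float
    complexes_per_member: float

    @property
    def input_required(self) -> int:
        return required_input(self.diversity, self.efficiency, self.complexes_per_member)


def display_efficiency(input_molecules: float, eluted_molecules: float) -> float:
    """Fraction of input mRNA recovered in the elution fraction."""
    if input_molecules <= 0:
        raise ValueError("input_molecules must be positive")
    if eluted_molecules < 0:
        raise ValueError("eluted_molecules must be non-negative")
    if eluted_molecules > input_molecules:
        warnings.warn(
            "eluted exceeds input; efficiency > 1 suggests measurement noise",
            stacklevel=2,
        )
    return eluted_molecules / input_molecules


def _ceil_stable(x: float) -> int:
    # Guard the exact-arithmetic cases (e.g. 1e11 * 4 / 0.04) against float
    # representation error before taking the ceiling.
    return math.ceil(float(f"{x:.12g}"))


def required_input(
    diversity: float, efficiency: float, complexes_per_member: float = 4.0
) -> int:
    """Input molecules needed so each member forms the target complex count.

    diversity x complexes_per_member / efficiency, rounded up.
    """
    if not 0.0 < efficiency <= 1.0:
        raise ValueError("efficiency must lie in (0, 1]")
    if diversity < 1 or complexes_per_member < 1:
        raise ValueError("diversity and complexes_per_member must be >= 1")
    return _ceil_stable(diversity * complexes_per_member / efficiency)


def expected_complexes(copies: float, efficiency: float) -> float:
    """Mean number of functional RMP complexes formed by a clone."""
    if copies < 0:
        raise ValueError("copies must be non-negative")
    if not 0.0 <= efficiency <= 1.0:
        raise ValueError("efficiency must lie in [0, 1]")
    return copies * efficiency


def prob_displayed(mean_complexes: float) -> float:
    """Probability a clone forms at least one complex, Poisson(mean)."""
    if mean_complexes < 0:
        raise ValueError("mean must be non-negative")
    return -math.expm1(-mean_complexes)


def pcr_amplify(mass0_ng: float, cycles: int, model: PcrModel = PcrModel()) -> float:
    """Product mass after ``cycles`` rounds of exponential amplification."""
    if cycles < 0:
        raise ValueError("cycles must be non-negative")
    return mass0_ng * model.per_cycle_factor**cycles


def initial_template(mass_ng: float, cycles: int, model: PcrModel = PcrModel()) -> float:
    """Back-calculate the template mass before amplification."""
    if cycles < 0:
        raise ValueError("cycles must be non-negative")
    return mass_ng / model.per_cycle_factor**cycles


def spike_proportion(spike_mass0_ng: float, total_mass_ng: float) -> float:
    """Spike template mass as a fraction of the total template mass."""
    if total_mass_ng <= 0:
        raise ValueError("total mass must be positive")
    if spike_mass0_ng < 0:
        raise ValueError("spike mass must be non-negative")
    return spike_mass0_ng / total_mass_ng


def detection_cycles(mass0_ng: float, model: PcrModel = PcrModel()) -> int:
    """Smallest cycle count at which the product reaches the detection mass."""
    if mass0_ng <= 0:
        raise ValueError("template mass must be positive")
    threshold = model.detection_threshold_mass
    if mass0_ng >= threshold:
        return 0
    f = model.per_cycle_factor
    c = max(0, math.ceil(math.log(threshold / mass0_ng) / math.log(f)))
    # correct for float error around the boundary
    while mass0_ng * f**c < threshold:
        c += 1
    while c > 0 and mass0_ng * f ** (c - 1) >= threshold:
        c -= 1
    return c
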