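"""Energy-balance scoring of cerebrospinal fluid.

The Coefficient of Energy Balance (CEB) summarises the glucose/lactate pair
of a CSF sample as the average number of ATP molecules obtained per molecule
of glucose under the current mix of aerobic and anaerobic glycolysis:

    CEB = 38 - 18 * lactate_CSF / glucose_CSF      [mmol/L over mmol/L]

Fully aerobic metabolism yields 38 ATP per glucose (lactate -> 0, CEB -> 38);
every mole of lactate produced per mole of glucose consumed forfeits 18 ATP,
so intense anaerobic turnover (the oxidative burst of professional
phagocytes) drives the score to low or strongly negative values.  The score
is bounded above by 38 and unbounded below.

Three metabolic bands are used for interpretation: CEB >= 28.00 is the
aerobic reference range, 10.00 < CEB < 28.00 corresponds to serous (mildly
anaerobic) inflammation, and CEB <= 10.00 marks the oxidative burst.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Optional

#: ATP yield per glucose under fully aerobic glycolysis (score upper bound).
ATP_AEROBIC: float = 38.0
#: ATP forfeited per unit lactate/glucose ratio (aerobic 38 minus anaerobic 2,
#: spread over the two lactate molecules produced per glucose).
ATP_ANAEROBIC_PENALTY: float = 18.0
#: Offset used by the variance-stabilising transform log(40 - CEB); chosen
#: above the score's upper bound so the argument is always >= 2.
TRANSFORM_OFFSET: float = 40.0

#: Default band cutoffs: (oxidative-burst upper cutoff, lower reference limit).
DEFAULT_BAND_CUTOFFS: tuple[float, float] = (10.0, 28.0)
#: Glucose below this concentration (mmol/L) is treated as unquantifiable.
DEFAULT_GLUCOSE_FLOOR: float = 0.01


class Band(str, Enum):
    """Metabolic stratum of a CEB value."""

    OXIDATIVE_BURST = "OXIDATIVE_BURST"
    SEROUS = "SEROUS"
    REFERENCE = "REFERENCE"


class UnquantifiableGlucoseError(ValueError):
    """CSF glucose at or below the quantification floor.

    A lactate/glucose ratio against a near-zero denominator is measurement
    noise, not information; callers receive this error together with a
    qualitative flag instead of an infinite score.
    """

    qualitative_flag = "extreme anaerobic"

    def __init__(self, glucose_csf: float, floor: float):
        self.glucose_csf = glucose_csf
        self.floor = floor
        super().__init__(
            f"CSF glucose {glucose_csf} mmol/L is at or below the "
            f"quantification floor {floor} mmol/L; CEB is unquantifiable "
            f"(qualitative finding: {self.qualitative_flag})"
        )


@dataclass(frozen=True)
class EnergyInputs:
    """Energy-metabolism analytes of one CSF sample (all mmol/L)."""

    lactate_csf: float
    glucose_csf: float
    glucose_serum: Optional[float] = None

    def __post_init__(self) -> None:
        if self.lactate_csf < 0:
            raise ValueError(f"negative CSF lactate: {self.lactate_csf}")
        if self.glucose_csf < 0:
            raise ValueError(f"negative CSF glucose: {self.glucose_csf}")
        if self.glucose_serum is not None and self.glucose_serum <= 0:
            raise ValueError(f"non-positive serum glucose: {self.glucose_serum}")


@dataclass(frozen=True)
class EnergyProfile:
    """Derived energy quantities and band assignment for one sample."""

    ceb: float
    q_glu: Optional[float]
    ceb_transf: float
    band: Band


def compute_ceb(inputs: EnergyInputs, *, glucose_floor: float = DEFAULT_GLUCOSE_FLOOR) -> float:
    """Return the unrounded CEB score for one sample.

    Raises
    ------
    UnquantifiableGlucoseError
        If CSF glucose is at or below ``glucose_floor`` (default 0.01 mmol/L);
        carries the qualitative "extreme anaerobic" flag.
    ValueError
        If CSF lactate is negative.
    """
    if inputs.lactate_csf < 0:
        raise ValueError(f"negative CSF lactate: {inputs.lactate_csf}")
    if inputs.glucose_csf <= glucose_floor:
        raise UnquantifiableGlucoseError(inputs.glucose_csf, glucose_floor)
    return ATP_AEROBIC - ATP_ANAEROBIC_PENALTY * inputs.lactate_csf / inputs.glucose_csf


def compute_q_glu(inputs: EnergyInputs) -> Optional[float]:
    """CSF-to-serum glucose quotient; ``None`` when serum glucose is absent."""
    if inputs.glucose_serum is None:
        return None
    if inputs.glucose_csf <= 0:
        raise ValueError(f"non-positive CSF glucose: {inputs.glucose_csf}")
    return inputs.glucose_csf / inputs.glucose_serum


def transform_ceb(ceb: float, *, log_base: float = 10.0) -> float:
    """Variance-stabilising transform ``log(40 - CEB)`` (base 10 by default).

    Defined for every admissible score (CEB <= 38 implies 40 - CEB >= 2).
    """
    if ceb > ATP_AEROBIC:
        raise ValueError(f"CEB {ceb} exceeds the aerobic maximum {ATP_AEROBIC}")
    return math.log(TRANSFORM_OFFSET - ceb, log_base)


def inverse_transform_ceb(value: float, *, log_base: float = 10.0) -> float:
    """Inverse of :func:`transform_ceb`: ``40 - base**value``."""
    return TRANSFORM_OFFSET - log_base**value


def stratify_ceb(ceb: float, *, cutoffs: tuple[float, float] = DEFAULT_BAND_CUTOFFS) -> Band:
    """Assign a CEB value to its metabolic band.

    Closure follows the interpretation scheme's inequality signs: values equal
    to the burst cutoff (10.00) belong to OXIDATIVE_BURST, values equal to the
    lower reference limit (28.00) belong to REFERENCE.
    """
    burst_cutoff, reference_limit = cutoffs
    if ceb > ATP_AEROBIC:
        raise ValueError(f"CEB {ceb} exceeds the aerobic maximum {ATP_AEROBIC}")
    if ceb <= burst_cutoff:
        return Band.OXIDATIVE_BURST
    if ceb >= reference_limit:
        return Band.REFERENCE
    return Band.SEROUS


def energy_profile(
    inputs: EnergyInputs,
    *,
    glucose_floor: float = DEFAULT_GLUCOSE_FLOOR,
    log_base: float = 10.0,
    cutoffs: tuple[float, float] = DEFAULT_BAND_CUTOFFS,
) -> EnergyProfile:
    """Compute CEB, Q_glu, the transformed score and the band for one sample."""
    ceb = compute_ceb(inputs, glucose_floor=glucose_floor)
    return EnergyProfile(
        ceb=ceb,
        q_glu=compute_q_glu(inputs),
        ceb_transf=transform_ceb(ceb, log_base=log_base),
        band=stratify_ceb(ceb, cutoffs=cutoffs),
    )
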