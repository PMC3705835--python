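"""Rule engine combining the metabolic band with the cytological syndrome.

The engine emits suspicion *patterns*, never diagnoses: each pattern is
backed by an auditable rule id and the triggering values, and every report
ends with the reminder that CSF interpretation is an adjunct to all clinical
and laboratory findings taken comprehensively.

Rules (evaluated in order, first match wins):

==========  =============================================  ==========================
rule id     condition                                      pattern
==========  =============================================  ==========================
R1          REFERENCE band, CONTROL                        NORMAL
R2          OXIDATIVE_BURST band, GP                       NEUTROPHIL_BURST
R3          OXIDATIVE_BURST band, GO                       NEUTROPHIL_BURST (low-
                                                           cellularity caveat; our
                                                           convention)
R4          OXIDATIVE_BURST band, MP/MO/LP/LO/TO/TP        MACROPHAGE_BURST
R5          SEROUS band, LP/LO/MP/MO/GO                    SEROUS_INFLAMMATION
R6          GP or LP outside the burst band                PREVENTIVE_NEUROPROTECTION_
                                                           SUSPECT
R7          anything else                                  INDETERMINATE
==========  =============================================  ==========================

A MACROPHAGE_BURST pattern flags suspicion of intracellular bacteria, fungi
or malignant meningeal infiltration; PREVENTIVE_NEUROPROTECTION_SUSPECT
covers inflammation-like cytology without oxidative-burst energetics (early
serous neuroinfection, systemic infection by neurotropic pathogens, or
artificial blood admixture).  An artificial-blood-admixture flag never
changes the pattern; it appends a confound note to the narrative.  A burst
band can never yield NORMAL: the anaerobic shift always marks pathology.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

from .classify import LabelFlag, Syndrome, SyndromeLabel
from .metrics import Band, EnergyProfile


class Pattern(str, Enum):
    NORMAL = "NORMAL"
    SEROUS_INFLAMMATION = "SEROUS_INFLAMMATION"
    NEUTROPHIL_BURST = "NEUTROPHIL_BURST"
    MACROPHAGE_BURST = "MACROPHAGE_BURST"
    PREVENTIVE_NEUROPROTECTION_SUSPECT = "PREVENTIVE_NEUROPROTECTION_SUSPECT"
    BLOOD_ADMIXTURE_CONFOUND = "BLOOD_ADMIXTURE_CONFOUND"
    INDETERMINATE = "INDETERMINATE"


#: Closing sentence of every report.
COMPREHENSIVE_CONTEXT = (
    "This pattern is an adjunct finding; diagnosis must rest on all clinical "
    "and laboratory findings comprehensively."
)

_MACROPHAGE_LABELS = {Syndrome.MP, Syndrome.MO, Syndrome.LP, Syndrome.LO,
                      Syndrome.TO, Syndrome.TP}
_SEROUS_LABELS = {Syndrome.LP, Syndrome.LO, Syndrome.MP, Syndrome.MO, Syndrome.GO}

_NARRATIVES = {
    "R1": "Aerobic energy balance with a fully normal CSF panel.",
    "R2": "Granulocyte pleocytosis with oxidative-burst energetics: "
          "purulent-type process (neutrophil burst) suspected.",
    "R3": "Granulocyte-type composition at normal cell count with "
          "oxidative-burst energetics: neutrophil burst suspected despite low "
          "cellularity (consider secondary infection with blunted cellular response).",
    "R4": "Oxidative-burst energetics with non-granulocytic cytology: "
          "macrophage burst suspected (intracellular bacteria, fungi, or "
          "malignant meningeal infiltration).",
    "R5": "Moderately anaerobic energy balance with inflammatory cytology: "
          "serous inflammation pattern.",
    "R6": "Inflammation-like cytology without oxidative-burst energetics: "
          "possible early-stage serous neuroinfection or preventive "
          "neuroprotection (systemic infection by neurotropic pathogens).",
    "R7": "No established band/cytology pattern; indeterminate.",
    "ADMIX": "Erythrocyte count above 100/uL: artificial blood admixture may "
             "confound cytology and energy findings.",
}


@dataclass(frozen=True)
class Interpretation:
    pattern: Pattern
    narrative: str
    supporting_facts: tuple[tuple[str, str], ...] = field(default_factory=tuple)


def _match(band: Band, label: Syndrome) -> tuple[str, Pattern]:
    if band == Band.REFERENCE and label == Syndrome.CONTROL:
        return "R1", Pattern.NORMAL
    if band == Band.OXIDATIVE_BURST:
        if label == Syndrome.GP:
            return "R2", Pattern.NEUTROPHIL_BURST
        if label == Syndrome.GO:
            return "R3", Pattern.NEUTROPHIL_BURST
        if label in _MACROPHAGE_LABELS:
            return "R4", Pattern.MACROPHAGE_BURST
    if band == Band.SEROUS and label in _SEROUS_LABELS:
        return "R5", Pattern.SEROUS_INFLAMMATION
    if label in (Syndrome.GP, Syndrome.LP) and band != Band.OXIDATIVE_BURST:
        return "R6", Pattern.PREVENTIVE_NEUROPROTECTION_SUSPECT
    return "R7", Pattern.INDETERMINATE


def interpret_record(profile: EnergyProfile, label: SyndromeLabel) -> Interpretation:
    """Map one (band, syndrome) pair to its suspicion pattern.

    Deterministic and total: every band x label x admixture combination
    yields exactly one pattern, and a burst band never yields NORMAL.
    """
    rule_id, pattern = _match(profile.band, label.label)
    facts: list[tuple[str, str]] = [
        (rule_id, f"band={profile.band.value}, label={label.label.value}, "
                  f"ceb={profile.ceb:.2f}"),
    ]
    sentences = [_NARRATIVES[rule_id]]
    if LabelFlag.ARTIFICIAL_BLOOD_ADMIXTURE in label.flags:
        facts.append(("ADMIX", Pattern.BLOOD_ADMIXTURE_CONFOUND.value))
        sentences.append(_NARRATIVES["ADMIX"])
    if label.annotation:
        sentences.append(f"Note: {label.annotation}.")
    sentences.append(COMPREHENSIVE_CONTEXT)
    return Interpretation(pattern=pattern, narrative=" ".join(sentences),
                          supporting_facts=tuple(facts))


def format_report(record_id: str, profile: EnergyProfile, label: SyndromeLabel,
                  interp: Interpretation) -> str:
    """Plain-text clinician summary for one record (scores shown to 2 dp)."""
    lines = [
        f"CSF energy report — record {record_id}",
        f"  CEB: {profile.ceb:.2f}  (band: {profile.band.value})",
    ]
    if profile.q_glu is not None:
        lines.append(f"  Q_glu: {profile.q_glu:.2f}")
    lines.append(f"  Cytological syndrome: {label.label.value}"
                 + (f"  [{', '.join(sorted(f.value for f in label.flags))}]" if label.flags else ""))
    lines.append(f"  Pattern: {interp.pattern.value}")
    lines.append(f"  {interp.narrative}")
    return "\n".join(lines)
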