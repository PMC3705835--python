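"""Cytological syndrome classification of CSF records.

Records are assigned to one of nine syndromes: CONTROL, or a combination of
predominant cell class (G granulocyte, M monocyte, L lymphocyte, T tumorous)
with cellularity (O oligocytosis — leukocytes in the reference range up to
4/µL but with a pathological composition; P pleocytosis — leukocytes above
4/µL).  Tumorous labels take precedence: any presence of malignant cells
makes the record TO or TP regardless of the differential composition.

"Pathological composition" at a normal cell count is operationalised
against the normal lymphocyte:monocyte balance of 7:3 — a granulocyte
fraction above 0.1, a monocyte fraction above 0.5, or a lymphocyte fraction
above 0.9 each marks the composition as pathological, labelled by the
triggering class.  The tolerances are configurable.

Records with a normal cytology that fail the control confirmation (any
flagged analyte out of range, or nonzero intrathecal synthesis) cannot be
CONTROL; they are labelled MO with a "barrier/immune abnormality only"
annotation, mirroring how monocyte oligocytosis absorbs chemically abnormal
but cytologically bland samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

from .reference import FLAGGED_PARAMETERS, Flag

_FRACTION_SUM_TOL = 1e-9


class Syndrome(str, Enum):
    CONTROL = "CONTROL"
    GO = "GO"
    GP = "GP"
    LO = "LO"
    LP = "LP"
    MO = "MO"
    MP = "MP"
    TO = "TO"
    TP = "TP"


class LabelFlag(str, Enum):
    AMBIGUOUS_PREDOMINANCE = "AMBIGUOUS_PREDOMINANCE"
    ARTIFICIAL_BLOOD_ADMIXTURE = "ARTIFICIAL_BLOOD_ADMIXTURE"


#: Annotation attached to chemically abnormal records with bland cytology.
BARRIER_IMMUNE_ONLY = "barrier/immune abnormality only"


@dataclass(frozen=True)
class Cytology:
    """Cell-count portion of one record (counts per µL, fractions of leukocytes)."""

    leukocytes: float
    erythrocytes: float = 0.0
    fraction_lymphocyte: float = 0.0
    fraction_monocyte: float = 0.0
    fraction_granulocyte: float = 0.0
    malignant_cells_present: bool = False

    def __post_init__(self) -> None:
        if self.leukocytes < 0 or self.erythrocytes < 0:
            raise ValueError("negative cell count")
        for f in (self.fraction_lymphocyte, self.fraction_monocyte, self.fraction_granulocyte):
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"fraction outside [0, 1]: {f}")
        total = self.fraction_lymphocyte + self.fraction_monocyte + self.fraction_granulocyte
        if total > 1.0 + _FRACTION_SUM_TOL:
            raise ValueError(f"cytology fractions sum to {total} > 1")


@dataclass(frozen=True)
class SyndromeLabel:
    label: Syndrome
    flags: frozenset[LabelFlag] = frozenset()
    annotation: Optional[str] = None


@dataclass(frozen=True)
class ClassifierConfig:
    """Tunable thresholds of the syndrome cascade."""

    pleocytosis_threshold: float = 4.0       # leukocytes/µL; above = pleocytosis
    granulocyte_tolerance: float = 0.1       # fraction above which composition is pathological
    monocyte_tolerance: float = 0.5
    lymphocyte_tolerance: float = 0.9
    admixture_erythrocytes: float = 100.0    # /µL; above = artificial blood admixture


# Tie priority: granulocytic findings carry the highest urgency.
_PRIORITY = (Syndrome.GP, Syndrome.MP, Syndrome.LP)
_CLASS_LETTERS = {"granulocyte": "G", "monocyte": "M", "lymphocyte": "L"}


def _predominant(fractions: dict[str, float]) -> tuple[str, bool]:
    """Largest-fraction cell class; ties broken granulocyte > monocyte > lymphocyte."""
    order = ("granulocyte", "monocyte", "lymphocyte")
    best = max(order, key=lambda c: fractions[c])
    tied = [c for c in order if fractions[c] == fractions[best]]
    winner = next(c for c in order if c in tied)
    return winner, len(tied) > 1


def classify_cytology(
    cyt: Cytology,
    flags: dict[str, Flag],
    intrathecal_synthesis: Sequence[Optional[float]] = (None, None, None),
    config: ClassifierConfig = ClassifierConfig(),
) -> SyndromeLabel:
    """Assign exactly one syndrome label to a record.

    Cascade: malignant cells force TO/TP; pleocytosis is labelled by the
    predominant class; oligocytosis with a pathological composition is
    labelled by the triggering class; the remainder is CONTROL only when the
    whole flagged panel is in range and intrathecal synthesis of IgG, IgA
    and IgM is zero, otherwise MO with the barrier/immune annotation.
    """
    fractions = {
        "lymphocyte": cyt.fraction_lymphocyte,
        "monocyte": cyt.fraction_monocyte,
        "granulocyte": cyt.fraction_granulocyte,
    }
    label_flags: set[LabelFlag] = set()
    if cyt.erythrocytes > config.admixture_erythrocytes:
        label_flags.add(LabelFlag.ARTIFICIAL_BLOOD_ADMIXTURE)

    pleocytosis = cyt.leukocytes > config.pleocytosis_threshold

    if cyt.malignant_cells_present:
        return SyndromeLabel(Syndrome.TP if pleocytosis else Syndrome.TO,
                             frozenset(label_flags))

    if pleocytosis:
        winner, ambiguous = _predominant(fractions)
        if ambiguous:
            label_flags.add(LabelFlag.AMBIGUOUS_PREDOMINANCE)
        return SyndromeLabel(Syndrome(_CLASS_LETTERS[winner] + "P"), frozenset(label_flags))

    # normal count: pathological composition -> oligocytosis by triggering class
    triggered = {}
    if fractions["granulocyte"] > config.granulocyte_tolerance:
        triggered["granulocyte"] = fractions["granulocyte"]
    if fractions["monocyte"] > config.monocyte_tolerance:
        triggered["monocyte"] = fractions["monocyte"]
    if fractions["lymphocyte"] > config.lymphocyte_tolerance:
        triggered["lymphocyte"] = fractions["lymphocyte"]
    if triggered:
        order = ("granulocyte", "monocyte", "lymphocyte")
        best_value = max(triggered.values())
        tied = [c for c in order if triggered.get(c) == best_value]
        if len(tied) > 1:
            label_flags.add(LabelFlag.AMBIGUOUS_PREDOMINANCE)
        return SyndromeLabel(Syndrome(_CLASS_LETTERS[tied[0]] + "O"), frozenset(label_flags))

    # cytologically bland: CONTROL only on full chemical/immunological normality
    synthesis_zero = (
        len(intrathecal_synthesis) == 3
        and all(v is not None and v == 0 for v in intrathecal_synthesis)
    )
    panel_in_range = all(
        flags.get(name, Flag.NOT_EVALUABLE) == Flag.IN_RANGE for name in FLAGGED_PARAMETERS
    )
    if panel_in_range and synthesis_zero:
        return SyndromeLabel(Syndrome.CONTROL, frozenset(label_flags))
    return SyndromeLabel(Syndrome.MO, frozenset(label_flags), annotation=BARRIER_IMMUNE_ONLY)


def classify_record(record, table=None, config: ClassifierConfig = ClassifierConfig()) -> SyndromeLabel:
    """Classify a :class:`~csfenergy.records.CSFRecord` end to end."""
    from .reference import flag_record, load_reference_table

    if table is None:
        table = load_reference_table()
    cyt = Cytology(
        leukocytes=record.leukocytes or 0.0,
        erythrocytes=record.erythrocytes or 0.0,
        fraction_lymphocyte=record.fraction_lymphocyte or 0.0,
        fraction_monocyte=record.fraction_monocyte or 0.0,
        fraction_granulocyte=record.fraction_granulocyte or 0.0,
        malignant_cells_present=record.malignant_cells_present,
    )
    flags = flag_record(record, table)
    return classify_cytology(
        cyt, flags, (record.it_igg, record.it_iga, record.it_igm), config
    )
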