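"""Syndrome cascade: pleocytosis threshold, composition rules, control gate."""

import dataclasses

import pytest
from hypothesis import given
from hypothesis import strategies as st

from csfenergy.classify import (
    BARRIER_IMMUNE_ONLY,
    ClassifierConfig,
    Cytology,
    LabelFlag,
    Syndrome,
    classify_cytology,
    classify_record,
)
from csfenergy.reference import FLAGGED_PARAMETERS, Flag

ALL_IN_RANGE = {name: Flag.IN_RANGE for name in FLAGGED_PARAMETERS}
ZERO_SYNTHESIS = (0.0, 0.0, 0.0)


def cyt(leuko, lymph, mono, gran, malignant=False, ery=0.0):
    return Cytology(leuko, ery, lymph, mono, gran, malignant)


@pytest.mark.parametrize(
    "cytology, expected",
    [
        (cyt(120, 0.05, 0.10, 0.85), Syndrome.GP),    # granulocyte pleocytosis
        (cyt(2, 0.6, 0.3, 0.1, malignant=True), Syndrome.TO),
        (cyt(200, 0.6, 0.3, 0.1, malignant=True), Syndrome.TP),
        (cyt(1, 0.3, 0.1, 0.6), Syndrome.GO),
        (cyt(3, 0.7, 0.3, 0.0), Syndrome.CONTROL),    # exact 7:3 balance
        (cyt(50, 0.2, 0.7, 0.1), Syndrome.MP),
        (cyt(900, 0.8, 0.15, 0.05), Syndrome.LP),
        (cyt(2, 0.3, 0.7, 0.0), Syndrome.MO),         # monocyte shift at normal count
        (cyt(4, 0.95, 0.05, 0.0), Syndrome.LO),       # lymphocyte shift at normal count
        (cyt(4.0, 0.7, 0.3, 0.0), Syndrome.CONTROL),  # 4/uL is still normal count
    ],
)
def test_cascade_examples(cytology, expected):
    label = classify_cytology(cytology, ALL_IN_RANGE, ZERO_SYNTHESIS)
    assert label.label is expected


def test_failed_control_confirmation_is_annotated_mo():
    flags = dict(ALL_IN_RANGE, beta2m_csf=Flag.HIGH)
    label = classify_cytology(cyt(2, 0.7, 0.3, 0.0), flags, ZERO_SYNTHESIS)
    assert label.label is Syndrome.MO
    assert label.annotation == BARRIER_IMMUNE_ONLY


def test_nonzero_intrathecal_synthesis_blocks_control():
    label = classify_cytology(cyt(2, 0.7, 0.3, 0.0), ALL_IN_RANGE, (5.0, 0.0, 0.0))
    assert label.label is Syndrome.MO
    label = classify_cytology(cyt(2, 0.7, 0.3, 0.0), ALL_IN_RANGE, (None, 0.0, 0.0))
    assert label.label is Syndrome.MO


def test_blood_admixture_flag():
    label = classify_cytology(cyt(120, 0.05, 0.10, 0.85, ery=250.0),
                              ALL_IN_RANGE, ZERO_SYNTHESIS)
    assert label.label is Syndrome.GP
    assert LabelFlag.ARTIFICIAL_BLOOD_ADMIXTURE in label.flags
    label = classify_cytology(cyt(120, 0.05, 0.10, 0.85, ery=100.0),
                              ALL_IN_RANGE, ZERO_SYNTHESIS)
    assert LabelFlag.ARTIFICIAL_BLOOD_ADMIXTURE not in label.flags


def test_predominance_tie_is_flagged():
    label = classify_cytology(cyt(50, 0.45, 0.45, 0.10), ALL_IN_RANGE, ZERO_SYNTHESIS)
    # tie broken monocyte over lymphocyte (granulocyte > monocyte > lymphocyte)
    assert label.label is Syndrome.MP
    assert LabelFlag.AMBIGUOUS_PREDOMINANCE in label.flags


def test_fraction_validation():
    with pytest.raises(ValueError):
        Cytology(10, 0, 0.7, 0.7, 0.2)


@given(
    leuko=st.floats(min_value=0, max_value=5000),
    lymph=st.floats(min_value=0, max_value=1),
    mono=st.floats(min_value=0, max_value=1),
    gran=st.floats(min_value=0, max_value=1),
    malignant=st.booleans(),
    ery=st.floats(min_value=0, max_value=10000),
    bad_flag=st.sampled_from([None, "beta2m_csf", "tp_csf", "q_glu"]),
)
def test_partition_totality(leuko, lymph, mono, gran, malignant, ery, bad_flag):
    """Every valid record gets exactly one of the nine labels, never an error."""
    total = lymph + mono + gran
    if total > 1:
        lymph, mono, gran = lymph / total, mono / total, gran / total
    flags = dict(ALL_IN_RANGE)
    if bad_flag:
        flags[bad_flag] = Flag.HIGH
    label = classify_cytology(cyt(leuko, lymph, mono, gran, malignant, ery),
                              flags, ZERO_SYNTHESIS)
    assert label.label in Syndrome


@given(
    lymph=st.floats(min_value=0, max_value=1),
    gran=st.floats(min_value=0.2, max_value=1),
    below=st.floats(min_value=0.0, max_value=4.0),
    above=st.floats(min_value=4.0001, max_value=5000.0),
)
def test_pleocytosis_threshold_changes_only_cellularity_letter(lymph, gran, below, above):
    """Crossing 4/uL flips O<->P but keeps the predominant-class letter."""
    total = lymph + gran
    if total > 1:
        lymph, gran = lymph / total, gran / total
    mono = max(0.0, 1.0 - lymph - gran)
    low = classify_cytology(cyt(below, lymph, mono, gran), ALL_IN_RANGE, ZERO_SYNTHESIS)
    high = classify_cytology(cyt(above, lymph, mono, gran), ALL_IN_RANGE, ZERO_SYNTHESIS)
    if low.label is not Syndrome.CONTROL and low.label.value[1] == "O":
        assert high.label.value[1] == "P"
        # the class letter survives when the oligocytosis trigger is predominant
        if low.label.value[0] == max(
            [("G", gran), ("M", mono), ("L", lymph)], key=lambda t: t[1]
        )[0]:
            assert high.label.value[0] == low.label.value[0]


@given(
    leuko=st.floats(min_value=0, max_value=5000),
    lymph=st.floats(min_value=0, max_value=1),
)
def test_malignant_cells_dominate(leuko, lymph):
    label = classify_cytology(cyt(leuko, lymph, 1 - lymph, 0, malignant=True),
                              ALL_IN_RANGE, ZERO_SYNTHESIS)
    assert label.label in (Syndrome.TO, Syndrome.TP)
    assert (label.label is Syndrome.TP) == (leuko > 4)


def test_classify_record_end_to_end(reference_table, control_record):
    assert classify_record(control_record, reference_table).label is Syndrome.CONTROL
    sick = dataclasses.replace(control_record, leukocytes=300.0,
                               fraction_lymphocyte=0.1, fraction_monocyte=0.1,
                               fraction_granulocyte=0.8)
    assert classify_record(sick, reference_table).label is Syndrome.GP


def test_configurable_tolerances():
    strict = ClassifierConfig(granulocyte_tolerance=0.02)
    label = classify_cytology(cyt(2, 0.9, 0.05, 0.05), ALL_IN_RANGE,
                              ZERO_SYNTHESIS, strict)
    assert label.label is Syndrome.GO
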