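"""Descriptives, rank tests against independent oracles, band frequencies."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from csfenergy.cohortstats import (
    band_frequencies,
    compare_cohort,
    describe_groups,
    dunn_posthoc,
    groups_from_cohort,
    kruskal_wallis,
    ks_normality,
    percent1,
    tier,
)
from csfenergy.synthcohort import load_default_specs, sample_ceb
from csfenergy.classify import Syndrome


def _frame(groups):
    return pd.DataFrame(
        [(name, v) for name, values in groups.items() for v in values],
        columns=["group", "ceb"],
    )


# --- descriptives -----------------------------------------------------------

def test_describe_small_group_quantiles():
    table = describe_groups(_frame({"a": [1, 2, 3, 4, 5]}), decimals=None)
    row = table.loc["a"]
    assert (row["median"], row["q1"], row["q3"]) == (3, 2, 4)
    assert (row["min"], row["max"], row["n"]) == (1, 5, 5)


def test_describe_singleton_group():
    row = describe_groups(_frame({"a": [4.2]}), decimals=None).loc["a"]
    assert set(row.drop("n")) == {4.2}
    assert row["n"] == 1


def test_describe_empty_group_named_in_error():
    frame = pd.DataFrame({"group": ["a"], "ceb": [np.nan]})
    with pytest.raises(ValueError, match="a"):
        describe_groups(frame)


def test_describe_ordering_invariant(small_cohort):
    table = describe_groups(small_cohort.frame, group_col="group_true", decimals=None)
    for _, row in table.iterrows():
        assert (row["min"] <= row["p2_5"] <= row["q1"] <= row["median"]
                <= row["q3"] <= row["p97_5"] <= row["max"])


def test_describe_synthetic_controls_median():
    specs, _ = load_default_specs()
    spec = specs[Syndrome.CONTROL]
    values = sample_ceb(spec, spec.n, 1)
    table = describe_groups(_frame({"CONTROL": values}))
    assert table.loc["CONTROL", "median"] == pytest.approx(31.31, abs=0.3)


# --- normality screening ----------------------------------------------------

def test_ks_normality_null_case():
    rng = np.random.default_rng(12)
    stat, p = ks_normality(rng.normal(size=5000))
    assert p > 0.01


def test_ks_normality_rejects_skewed_ceb():
    specs, _ = load_default_specs()
    values = sample_ceb(specs[Syndrome.GP], specs[Syndrome.GP].n, 4)
    stat, p = ks_normality(values)
    assert p < 0.001
    # oracle: max ECDF distance against the moment-fitted normal
    mu, sigma = values.mean(), values.std(ddof=1)
    grid = np.sort(values)
    ecdf_hi = np.arange(1, len(grid) + 1) / len(grid)
    ecdf_lo = np.arange(0, len(grid)) / len(grid)
    cdf = stats.norm.cdf(grid, mu, sigma)
    d_oracle = max(np.max(ecdf_hi - cdf), np.max(cdf - ecdf_lo))
    assert stat == pytest.approx(d_oracle, abs=1e-12)


def test_ks_normality_not_evaluable():
    assert ks_normality([1.0, 1.0, 1.0, 1.0, 1.0, 1.0]) is None
    assert ks_normality([1.0, 2.0]) is None


# --- Kruskal-Wallis vs. enumeration oracle ----------------------------------

def _h_statistic(groups):
    """Oracle H: rank formula computed from scratch (no ties assumed)."""
    pooled = np.concatenate(groups)
    n = len(pooled)
    ranks = stats.rankdata(pooled)
    start, h = 0, 0.0
    for g in groups:
        r = ranks[start:start + len(g)]
        h += len(g) * (r.mean() - (n + 1) / 2) ** 2
        start += len(g)
    return 12.0 / (n * (n + 1)) * h


def test_kw_matches_exact_permutation_distribution():
    """Brute-force enumeration of all 20 assignments of {1..6} into two triples."""
    a, b = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
    h_obs, p_chi2 = kruskal_wallis({"a": a, "b": b})
    assert h_obs == pytest.approx(_h_statistic([a, b]), abs=1e-12)

    pooled = a + b
    h_perm = []
    for idx in itertools.combinations(range(6), 3):
        g1 = [pooled[i] for i in idx]
        g2 = [pooled[i] for i in range(6) if i not in idx]
        h_perm.append(_h_statistic([g1, g2]))
    p_perm = np.mean([h >= h_obs - 1e-12 for h in h_perm])
    # the chi-square approximation is documentedly coarse at n=6; measure it
    assert p_perm == pytest.approx(2 / 20)
    assert abs(p_chi2 - p_perm) < 0.06


def test_kw_tie_correction_hand_computed():
    """{1,1,2} vs {2,3,3}: H = 3.047619/0.9142857 = 10/3 exactly."""
    h, _ = kruskal_wallis({"a": [1.0, 1.0, 2.0], "b": [2.0, 3.0, 3.0]})
    assert h == pytest.approx(10.0 / 3.0, abs=1e-9)


def test_kw_degenerate_cases():
    assert kruskal_wallis({"a": [2.0, 2.0], "b": [2.0, 2.0]}) == (0.0, 1.0)
    h, _ = kruskal_wallis({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
    assert h == pytest.approx(0.0, abs=1e-12)
    with pytest.raises(ValueError):
        kruskal_wallis({"a": [1.0]})
    with pytest.raises(ValueError):
        kruskal_wallis({"a": [1.0], "b": []})


def test_kw_invariant_under_monotone_transform():
    rng = np.random.default_rng(3)
    groups = {k: rng.normal(loc, 1.0, 40) for k, loc in [("a", 0), ("b", 0.5), ("c", 1)]}
    h1, p1 = kruskal_wallis(groups)
    transformed = {k: np.exp(v / 3.0) + 7.0 for k, v in groups.items()}
    h2, p2 = kruskal_wallis(transformed)
    assert h1 == pytest.approx(h2, abs=1e-9)
    assert p1 == pytest.approx(p2, abs=1e-12)


# --- Dunn post hoc ----------------------------------------------------------

def test_dunn_two_group_identity_with_kw():
    """For two groups Dunn's z on joint ranks satisfies z^2 = H (tie-corrected)."""
    rng = np.random.default_rng(8)
    groups = {"a": rng.normal(0, 1, 30), "b": rng.normal(0.8, 1, 25)}
    h, _ = kruskal_wallis(groups)
    p_adj = dunn_posthoc(groups).loc["a", "b"]  # single pair: no multiplicity
    z = stats.norm.isf(p_adj / 2.0)
    assert z**2 == pytest.approx(h, rel=1e-9)


def test_dunn_with_ties_two_group_identity():
    groups = {"a": np.array([1.0, 1.0, 2.0, 4.0]), "b": np.array([2.0, 3.0, 3.0, 5.0])}
    h, _ = kruskal_wallis(groups)
    z = stats.norm.isf(dunn_posthoc(groups).loc["a", "b"] / 2.0)
    assert z**2 == pytest.approx(h, rel=1e-9)


def test_dunn_identical_groups_no_difference():
    groups = {"a": [1.0, 2.0, 3.0, 4.0], "b": [1.0, 2.0, 3.0, 4.0]}
    assert dunn_posthoc(groups).loc["a", "b"] == pytest.approx(1.0)
    assert tier(dunn_posthoc(groups).loc["a", "b"]) == "No difference"


def test_dunn_matrix_shape_and_symmetry(small_cohort):
    groups = groups_from_cohort(small_cohort.frame, group_col="group_true")
    table = dunn_posthoc(groups)
    assert np.allclose(table.values, table.values.T)
    assert np.allclose(np.diag(table.values), 1.0)
    assert ((table.values >= 0) & (table.values <= 1)).all()


def test_bonferroni_vs_holm_ordering(small_cohort):
    """Holm is uniformly at most as large as Bonferroni."""
    groups = groups_from_cohort(small_cohort.frame, group_col="group_true")
    bonf = dunn_posthoc(groups, adjust="bonferroni")
    holm = dunn_posthoc(groups, adjust="holm")
    assert (holm.values <= bonf.values + 1e-15).all()


def test_constant_shift_leaves_comparison_unchanged():
    rng = np.random.default_rng(21)
    groups = {k: rng.normal(loc, 1, 30) for k, loc in [("a", 0), ("b", 1), ("c", 2)]}
    shifted = {k: v + 1234.5 for k, v in groups.items()}
    base, moved = compare_cohort(groups), compare_cohort(shifted)
    assert base.kw_h == pytest.approx(moved.kw_h, abs=1e-9)
    pd.testing.assert_frame_equal(base.pairwise, moved.pairwise)
    pd.testing.assert_frame_equal(base.tiers, moved.tiers)


def test_tier_thresholds():
    assert tier(5e-4) == "P < 0.001"
    assert tier(5e-3) == "P < 0.01"
    assert tier(0.5) == "No difference"
    assert tier(0.01) == "No difference"  # boundary goes to the weaker tier


# --- band frequencies -------------------------------------------------------

def test_band_frequencies_printed_fractions():
    """The published counts reproduce the published percentages exactly."""
    assert percent1(443, 766) == 57.8
    assert percent1(237, 1457) == 16.3
    assert percent1(93, 1610) == 5.8
    assert percent1(259, 766) == 33.8


def test_band_frequencies_sum_to_one(small_cohort):
    table = band_frequencies(small_cohort.frame, group_col="group_true")
    frac_cols = [c for c in table.columns if c.startswith("frac_")]
    assert np.allclose(table[frac_cols].sum(axis=1), 1.0, atol=1e-9)


def test_band_frequencies_single_band_group():
    frame = _frame({"x": [30.0, 31.0, 35.0]})
    table = band_frequencies(frame)
    assert table.loc["x", "frac_REFERENCE"] == 1.0
    assert table.loc["x", "frac_OXIDATIVE_BURST"] == 0.0
    assert table.loc["x", "frac_SEROUS"] == 0.0
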