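"""Cohort-level statistics of CEB across cytological syndromes.

Reproduces the reference study's analysis stack: per-group descriptive
statistics (median, quartiles, 2.5th/97.5th percentiles, extremes),
Kolmogorov-Smirnov normality screening (which justifies the nonparametric
route), Kruskal-Wallis ANOVA with tie correction, Dunn's pairwise z-tests
on the joint ranks with multiplicity adjustment, and the relative frequency
of the three metabolic bands per group.

Quantiles use linear interpolation between order statistics (Hyndman-Fan
definition 7, the numpy/pandas default).  The post hoc method is Dunn with
Bonferroni adjustment by default (Holm available); adjusted p-values are
reported in the study's three tiers: "P < 0.001", "P < 0.01", and
"No difference".  The tumorous groups TO and TP are pooled as "TO + TP"
for comparisons, as in the reference study.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .classify import Syndrome
from .metrics import Band, stratify_ceb

#: Display order of the pooled comparison groups.
COMPARISON_GROUPS = ("CONTROL", "GO", "GP", "LO", "LP", "MO", "MP", "TO + TP")

TIER_STRONG = "P < 0.001"
TIER_MODERATE = "P < 0.01"
TIER_NONE = "No difference"

#: Published post hoc tier pattern of the reference cohort (28 pairs).
PUBLISHED_TIER_PATTERN: dict[frozenset, str] = {
    frozenset(p): t for p, t in [
        (("GO", "GP"), TIER_MODERATE),
        (("GO", "MO"), TIER_NONE),
        (("GO", "MP"), TIER_MODERATE),
        (("GO", "LO"), TIER_MODERATE),
        (("GO", "LP"), TIER_NONE),
        (("GO", "TO + TP"), TIER_MODERATE),
        (("GO", "CONTROL"), TIER_MODERATE),
        (("GP", "MO"), TIER_STRONG),
        (("GP", "MP"), TIER_STRONG),
        (("GP", "LO"), TIER_STRONG),
        (("GP", "LP"), TIER_STRONG),
        (("GP", "TO + TP"), TIER_MODERATE),
        (("GP", "CONTROL"), TIER_STRONG),
        (("MO", "MP"), TIER_STRONG),
        (("MO", "LO"), TIER_MODERATE),
        (("MO", "LP"), TIER_MODERATE),
        (("MO", "TO + TP"), TIER_STRONG),
        (("MO", "CONTROL"), TIER_MODERATE),
        (("MP", "LO"), TIER_STRONG),
        (("MP", "LP"), TIER_STRONG),
        (("MP", "TO + TP"), TIER_NONE),
        (("MP", "CONTROL"), TIER_STRONG),
        (("LO", "LP"), TIER_STRONG),
        (("LO", "TO + TP"), TIER_STRONG),
        (("LO", "CONTROL"), TIER_NONE),
        (("LP", "TO + TP"), TIER_MODERATE),
        (("LP", "CONTROL"), TIER_STRONG),
        (("TO + TP", "CONTROL"), TIER_STRONG),
    ]
}


@dataclass(frozen=True)
class CohortComparison:
    """Omnibus and pairwise comparison of CEB across groups."""

    kw_h: float
    kw_p: float
    pairwise: pd.DataFrame   # symmetric adjusted p-values, unit diagonal
    tiers: pd.DataFrame      # symmetric tier labels


def pool_tumorous(labels: Iterable[str]) -> list[str]:
    """Replace TO and TP labels by the pooled "TO + TP" comparison group."""
    return ["TO + TP" if l in ("TO", "TP") else l for l in labels]


def describe_groups(
    cohort: pd.DataFrame,
    group_col: str = "group",
    value_col: str = "ceb",
    decimals: Optional[int] = 2,
) -> pd.DataFrame:
    """Per-group descriptives of CEB in the reference study's column order.

    Columns: n, median, min, max, q1, q3, p2_5, p97_5.  Quantiles are linear
    interpolation between order statistics (Hyndman-Fan 7).  Raises on an
    empty group, naming it.
    """
    rows = {}
    for name, sub in cohort.groupby(group_col, sort=False):
        values = np.asarray(sub[value_col], dtype=float)
        if len(values) == 0 or np.isnan(values).all():
            raise ValueError(f"empty group: {name!r}")
        q = np.quantile(values, [0.5, 0.25, 0.75, 0.025, 0.975])  # HF7 default
        rows[name] = {
            "n": len(values),
            "median": q[0], "min": values.min(), "max": values.max(),
            "q1": q[1], "q3": q[2], "p2_5": q[3], "p97_5": q[4],
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    table["n"] = table["n"].astype(int)
    if decimals is not None:
        for col in table.columns.drop("n"):
            table[col] = table[col].round(decimals)
    return table


def ks_normality(values: Sequence[float]) -> Optional[tuple[float, float]]:
    """One-sample KS test against a moment-fitted normal.

    Returns ``None`` (not evaluable) for n < 5 or a degenerate (constant)
    sample.  Used only to justify the nonparametric route.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 5:
        return None
    mu, sigma = values.mean(), values.std(ddof=1)
    if sigma == 0 or not np.isfinite(sigma):
        return None
    stat, p = stats.kstest(values, "norm", args=(mu, sigma))
    return float(stat), float(p)


def kruskal_wallis(groups: Mapping[str, Sequence[float]]) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H with chi-square p (k-1 df).

    A fully degenerate pooled sample (all values identical) returns
    (0.0, 1.0) instead of failing in the tie correction.
    """
    arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    if any(len(a) == 0 for a in arrays):
        raise ValueError("every group must be nonempty")
    pooled = np.concatenate(arrays)
    if len(pooled) < 3:
        raise ValueError("need at least three observations in total")
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*arrays)
    return float(h), float(p)


def dunn_posthoc(
    groups: Mapping[str, Sequence[float]],
    adjust: str = "bonferroni",
) -> pd.DataFrame:
    """Dunn's pairwise z-tests on the joint ranks, with tie correction.

    For groups i, j with mean joint ranks R̄_i, R̄_j over N pooled values,

        z_ij = (R̄_i - R̄_j) / sqrt((N(N+1)/12 - T)(1/n_i + 1/n_j)),
        T = Σ(t³ - t) / (12(N - 1))  over tie groups of size t,

    two-sided p from the standard normal, adjusted over all pairs
    ("bonferroni" or "holm").  Returns a symmetric DataFrame of adjusted
    p-values with ones on the diagonal.
    """
    names = list(groups)
    arrays = [np.asarray(groups[k], dtype=float) for k in names]
    sizes = np.array([len(a) for a in arrays])
    pooled = np.concatenate(arrays)
    n_total = len(pooled)
    ranks = stats.rankdata(pooled)
    mean_ranks = {}
    start = 0
    for name, size in zip(names, sizes):
        mean_ranks[name] = ranks[start:start + size].mean()
        start += size
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (12.0 * (n_total - 1))
    variance_base = n_total * (n_total + 1) / 12.0 - tie_term

    pairs = list(itertools.combinations(names, 2))
    raw = []
    for a, b in pairs:
        n_a, n_b = len(groups[a]), len(groups[b])
        se = np.sqrt(variance_base * (1.0 / n_a + 1.0 / n_b))
        if se == 0:
            raw.append(1.0)
            continue
        z = (mean_ranks[a] - mean_ranks[b]) / se
        raw.append(2.0 * stats.norm.sf(abs(z)))
    if adjust not in ("bonferroni", "holm"):
        raise ValueError(f"unknown adjustment: {adjust!r}")
    adjusted = multipletests(raw, method=adjust)[1] if pairs else np.array([])

    table = pd.DataFrame(np.ones((len(names), len(names))), index=names, columns=names)
    for (a, b), p in zip(pairs, adjusted):
        table.loc[a, b] = table.loc[b, a] = p
    return table


def tier(p: float, thresholds: tuple[float, float] = (0.001, 0.01)) -> str:
    """Map an adjusted p-value to the study's three significance tiers."""
    strong, moderate = thresholds
    if p < strong:
        return TIER_STRONG
    if p < moderate:
        return TIER_MODERATE
    return TIER_NONE


def compare_cohort(
    groups: Mapping[str, Sequence[float]],
    adjust: str = "bonferroni",
    tier_thresholds: tuple[float, float] = (0.001, 0.01),
) -> CohortComparison:
    """Kruskal-Wallis omnibus plus Dunn post hoc with tiered significance."""
    h, p = kruskal_wallis(groups)
    pairwise = dunn_posthoc(groups, adjust=adjust)
    tiers = pairwise.map(lambda v: tier(v, tier_thresholds))
    for name in pairwise.index:
        tiers.loc[name, name] = ""
    return CohortComparison(kw_h=h, kw_p=p, pairwise=pairwise, tiers=tiers)


def groups_from_cohort(
    cohort: pd.DataFrame,
    group_col: str = "group",
    value_col: str = "ceb",
    pool_tumorous_groups: bool = True,
) -> dict[str, np.ndarray]:
    """Split a labelled cohort into per-group CEB arrays in display order."""
    labels = cohort[group_col].astype(str)
    if pool_tumorous_groups:
        labels = labels.replace({"TO": "TO + TP", "TP": "TO + TP"})
    out = {}
    for name in COMPARISON_GROUPS:
        mask = labels == name
        if mask.any():
            out[name] = np.asarray(cohort.loc[mask, value_col], dtype=float)
    for name in labels.unique():
        if name not in out:
            out[name] = np.asarray(cohort.loc[labels == name, value_col], dtype=float)
    return out


def tier_pattern_matches(tiers: pd.DataFrame) -> tuple[int, list[tuple[str, str, str, str]]]:
    """Compare a tier matrix with the published 28-pair pattern.

    Returns the number of matching pairs and the list of mismatches as
    (group_a, group_b, observed, published).
    """
    matches = 0
    mismatches = []
    for pair, published in PUBLISHED_TIER_PATTERN.items():
        a, b = sorted(pair)
        if a not in tiers.index or b not in tiers.columns:
            mismatches.append((a, b, "absent", published))
            continue
        observed = tiers.loc[a, b]
        if observed == published:
            matches += 1
        else:
            mismatches.append((a, b, observed, published))
    return matches, mismatches


def band_frequencies(
    cohort: pd.DataFrame,
    group_col: str = "group",
    value_col: str = "ceb",
    cutoffs: tuple[float, float] = (10.0, 28.0),
) -> pd.DataFrame:
    """Per-group counts and relative frequencies of the three CEB bands.

    Fractions per group sum to 1; the ``pct_*`` columns carry percentages
    rounded to one decimal, the study's display convention.
    """
    bands = [stratify_ceb(v, cutoffs=cutoffs).value for v in cohort[value_col]]
    table = (
        pd.crosstab(cohort[group_col], pd.Categorical(bands, categories=[b.value for b in Band]))
        .reindex(columns=[b.value for b in Band], fill_value=0)
    )
    table.columns.name = None
    total = table.sum(axis=1)
    out = table.copy()
    for band in table.columns:
        out[f"frac_{band}"] = table[band] / total
        out[f"pct_{band}"] = (100.0 * table[band] / total).round(1)
    out["n"] = total
    return out


def percent1(count: int, total: int) -> float:
    """Percentage to one decimal, as the study prints (443/766 -> 57.8)."""
    return round(100.0 * count / total, 1)


def plot_ceb_transf_boxes(cohort: pd.DataFrame, path: str,
                          group_col: str = "group", value_col: str = "ceb") -> None:
    """Box-and-whisker plot of log10(40 - CEB) per group (display twin)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .metrics import transform_ceb

    groups = groups_from_cohort(cohort, group_col, value_col)
    data = [[transform_ceb(v) for v in values] for values in groups.values()]
    fig, ax = plt.subplots(figsize=(8, 4.5))
    ax.boxplot(data, tick_labels=list(groups))
    ax.set_ylabel("log10(40 - CEB)")
    ax.set_xlabel("cytological syndrome")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
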