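"""Expression-shift analysis of RBP target subsets within GO terms.

Given matched mRNA and protein log2 ratios, this module quantifies how
the targets of an RNA-binding protein inside a functional (GO) group
shift relative to all measured features and to the non-targets of the
same group (Mann-Whitney U plus Welch t companion), correlates mRNA with
protein changes, tests target overrepresentation among changed genes,
and formats the percentage-style summaries used throughout the analysis.
"""

from __future__ import annotations

from collections import namedtuple
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from itertools import combinations
from typing import Optional

import numpy as np
from scipy import stats

from .enrichment import Chi2Result, chi_square_2x2
from .io_formats import ExpressionTable, GeneSet, ValidationError

__all__ = [
    "ShiftTestResult",
    "CorrelationResult",
    "subset_shift_test",
    "mann_whitney_p",
    "mrna_protein_correlation",
    "changed_set_overrepresentation",
    "percent_value",
    "percent_report",
    "boxplot_summary",
    "stars",
]

BoxplotSummary = namedtuple("BoxplotSummary", "median q1 q3 p10 p90 mean")


@dataclass(frozen=True)
class ShiftTestResult:
    """Distribution shift of targets-in-term vs reference distributions."""

    go_term: str
    value_column: str
    n: int
    summary: BoxplotSummary
    mw_p_vs_all: float
    mw_p_vs_nontargets: Optional[float]
    welch_p_vs_all: float
    stars: str
    underpowered: bool


@dataclass(frozen=True)
class CorrelationResult:
    n_pairs: int
    pearson_r: float


def stars(p: float) -> str:
    """Significance stars; boundary values fall into the weaker category."""
    if np.isnan(p):
        return "ns"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def mann_whitney_p(x, y) -> float:
    """Two-sided Mann-Whitney U p-value.

    Exact enumeration when both groups have <= 8 values and no ties span
    the groups; otherwise the tie-corrected normal approximation with
    0.5 continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("Mann-Whitney needs non-empty groups")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if x.size <= 8 and y.size <= 8 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    return float(stats.mannwhitneyu(x, y, alternative="two-sided",
                                    method=method, use_continuity=True).pvalue)


def exact_mann_whitney_p(x, y) -> float:
    """Brute-force two-sided p by enumerating all rank assignments."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    n, m = x.size, y.size
    ranks = stats.rankdata(pooled)
    u_obs = ranks[:n].sum() - n * (n + 1) / 2
    mu = n * m / 2
    dev_obs = abs(u_obs - mu)
    count = 0
    total = 0
    for idx in combinations(range(n + m), n):
        u = ranks[list(idx)].sum() - n * (n + 1) / 2
        if abs(u - mu) >= dev_obs - 1e-12:
            count += 1
        total += 1
    return count / total


def boxplot_summary(values) -> BoxplotSummary:
    """Median, quartiles, 10th/90th percentiles and mean.

    Percentiles use linear interpolation between order statistics
    (inclusive), the convention behind 10-90% whisker plots.
    """
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        raise ValidationError("boxplot_summary needs at least one value")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    p10, p90 = np.percentile(v, [10, 90])
    return BoxplotSummary(float(med), float(q1), float(q3), float(p10), float(p90),
                          float(v.mean()))


def subset_shift_test(table: ExpressionTable, go_term: str, target_set: GeneSet,
                      value_column: str, include_subset_in_background: bool = True) -> ShiftTestResult:
    """Shift of targets-in-term values vs all features and vs non-targets.

    ``value_column`` is "mrna" or "protein".  The "vs all" background
    includes the subset's own members by default (global reference
    distribution); pass ``include_subset_in_background=False`` for the
    exclusive variant.  Subsets with fewer than 3 values are flagged
    underpowered but still tested where possible.
    """
    values = table.values(value_column)
    term_genes = table.genes_with_term(go_term)
    if not term_genes:
        raise ValidationError(f"GO term {go_term!r} absent from the table annotations")
    targets = set(target_set.members)
    subset_genes = [g for g in values.index if g in term_genes and g in targets]
    nontarget_genes = [g for g in values.index if g in term_genes and g not in targets]
    subset = values.loc[subset_genes].to_numpy()
    if subset.size == 0:
        raise ValidationError(f"no measured targets in term {go_term!r}")
    if include_subset_in_background:
        background = values.to_numpy()
    else:
        background = values.drop(index=subset_genes).to_numpy()
    underpowered = subset.size < 3

    mw_all = mann_whitney_p(subset, background)
    mw_nt = mann_whitney_p(subset, values.loc[nontarget_genes].to_numpy()) if nontarget_genes else None
    welch = float(stats.ttest_ind(subset, background, equal_var=False).pvalue)
    return ShiftTestResult(go_term, value_column, int(subset.size),
                           boxplot_summary(subset), mw_all, mw_nt, welch,
                           stars(mw_all), underpowered)


def mrna_protein_correlation(table: ExpressionTable) -> CorrelationResult:
    """Pearson r between mRNA and protein log2 changes over complete pairs."""
    df = table.data[["mrna_log2", "protein_log2"]].dropna()
    if len(df) < 3:
        raise ValidationError("need at least 3 complete mRNA/protein pairs")
    r = stats.pearsonr(df["mrna_log2"], df["protein_log2"]).statistic
    return CorrelationResult(int(len(df)), float(r))


@dataclass(frozen=True)
class ChangedSetResult:
    direction_label: str
    n_changed: int
    n_targets_in_changed: int
    percent: str
    chi2: Chi2Result


def changed_set_overrepresentation(changed: GeneSet, direction_label: str,
                                   target_set: GeneSet, universe: GeneSet) -> ChangedSetResult:
    """Chi-square overrepresentation of targets among changed genes.

    Builds the 2x2 (changed vs not) x (target vs not) table over the
    universe and reports the integer percent of targets among the
    changed set.
    """
    uni = set(universe.members)
    ch = set(changed.members)
    if not ch <= uni:
        raise ValidationError("changed set is not contained in the universe")
    tg = set(target_set.members) & uni
    a = len(ch & tg)
    b = len(ch - tg)
    c = len(tg - ch)
    d = len(uni) - a - b - c
    chi2 = chi_square_2x2([[a, b], [c, d]])
    return ChangedSetResult(direction_label, len(ch), a, percent_report(a, len(ch), 0), chi2)


# ---------------------------------------------------------------------------
# percentage reports
# ---------------------------------------------------------------------------

def percent_value(numerator: int, denominator: int, decimals: int) -> float:
    """100*numerator/denominator, rounded half-away-from-zero."""
    if denominator <= 0:
        raise ValidationError("denominator must be positive")
    if not 0 <= numerator <= denominator:
        raise ValidationError("numerator must lie in [0, denominator]")
    quant = Decimal(1).scaleb(-decimals)
    value = (Decimal(100) * Decimal(numerator) / Decimal(denominator)).quantize(
        quant, rounding=ROUND_HALF_UP
    )
    return float(value)


def percent_report(numerator: int, denominator: int, decimals: int) -> str:
    """Formatted percentage string, e.g. percent_report(1102, 8132, 1) -> '13.6%'."""
    value = percent_value(numerator, denominator, decimals)
    return f"{value:.{decimals}f}%"
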