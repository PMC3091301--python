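"""Two-class SAM-style permutation FDR and fold-change calling.

RBP-associated transcripts are called from two-color ratio matrices by a
moderated relative difference d = (mean_IP - mean_mock) / (s + s0), with
s the pooled two-sample standard error, s0 a small positive fudge chosen
by the standard percentile search, and per-feature q-values estimated by
permuting the class labels.  The companion one-sample fold-change test
implements the "at least 1.5-fold (|mean log2| >= 0.585) with p < 0.05"
calling rule for expression profiling.

Quality filtering and per-array median centering are applied upstream of
the statistic, as in the original two-color workflow.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from math import comb
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GeneSet, RatioMatrix, ValidationError

__all__ = [
    "SamConfig",
    "SamResult",
    "DEResult",
    "filter_features",
    "median_center",
    "sam_two_class",
    "call_targets",
    "one_sample_fold_change_test",
]

FOLD_15_LOG2 = 0.585  # log2(1.5) rounded as conventionally quoted


@dataclass
class SamConfig:
    """Configuration for the two-class permutation analysis.

    ``side`` selects the calling direction: "positive" (enriched in
    class 1, the default for affinity-isolation data), "negative" or
    "both".  ``pi0_mode`` "one" disables the pi0 shrinkage (useful for
    oracle comparisons).
    """

    n_permutations: object = "all"  # "all" or an int >= 100
    side: str = "positive"
    s0_method: str = "percentile_search"  # or "fixed"
    s0_fixed: float = 0.0
    fdr_cutoff: float = 0.05
    pi0_mode: str = "estimate"  # or "one"
    seed: int = 0

    def __post_init__(self):
        if self.side not in ("positive", "negative", "both"):
            raise ValidationError(f"unknown side {self.side!r}")
        if self.s0_method not in ("percentile_search", "fixed"):
            raise ValidationError(f"unknown s0_method {self.s0_method!r}")
        if self.pi0_mode not in ("estimate", "one"):
            raise ValidationError(f"unknown pi0_mode {self.pi0_mode!r}")
        if not 0 < self.fdr_cutoff < 1:
            raise ValidationError("fdr_cutoff must lie in (0, 1)")
        if self.n_permutations != "all":
            self.n_permutations = int(self.n_permutations)
            if self.n_permutations < 100:
                raise ValidationError("sampled permutations require n_permutations >= 100")


@dataclass
class SamResult:
    feature_ids: List[str]
    d_score: np.ndarray
    s: np.ndarray
    q_value: np.ndarray
    s0: float
    pi0: float
    permutation_count: int
    side: str
    excluded: List[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "feature_id": self.feature_ids,
            "d": self.d_score,
            "s": self.s,
            "q": self.q_value,
        })


@dataclass
class DEResult:
    """Per-gene fold-change calls from the one-sample t-test rule."""

    table: pd.DataFrame  # gene_id, mean_log2, p_value, called, degenerate

    def called(self, direction: str) -> List[str]:
        return list(self.table.loc[self.table["called"] == direction, "gene_id"])


# ---------------------------------------------------------------------------
# quality filtering and normalization
# ---------------------------------------------------------------------------

def filter_features(matrix: RatioMatrix, snr_min: float, snr_channels: str = "input_only",
                    regression_max: Optional[float] = None):
    """Mask cells failing QC; drop features measurable on <2 arrays per class.

    RIP mode: ``snr_min=1.8, snr_channels="input_only"`` keeps cells with
    signal-over-background above the threshold in the total-RNA channel.
    Expression mode: ``snr_min=1.5, snr_channels="both",
    regression_max=0.5`` additionally keeps only cells whose regression
    correlation is below ``regression_max``.

    Returns ``(filtered RatioMatrix, removal-count dict)``.
    """
    if snr_min <= 0:
        raise ValidationError("snr_min must be positive")
    if snr_channels not in ("input_only", "both"):
        raise ValidationError(f"unknown snr_channels {snr_channels!r}")
    out = matrix.copy()
    removed = {"snr": 0, "regression": 0, "features_dropped": 0}
    present_before = out.log2.notna()

    keep = pd.DataFrame(True, index=out.log2.index, columns=out.log2.columns)
    if out.snr1 is not None:
        keep &= out.snr1 > snr_min
    if snr_channels == "both" and out.snr2 is not None:
        keep &= out.snr2 > snr_min
    removed["snr"] = int((present_before & ~keep).sum().sum())
    if regression_max is not None and out.regression is not None:
        rc_ok = out.regression < regression_max
        removed["regression"] = int((present_before & keep & ~rc_ok).sum().sum())
        keep &= rc_ok
    out.log2 = out.log2.where(keep)

    counts_ok = pd.Series(True, index=out.log2.index)
    for lab in out.class_labels:
        arrays = [a for a in out.array_ids if out.classes[a] == lab]
        counts_ok &= out.log2[arrays].notna().sum(axis=1) >= 2
    removed["features_dropped"] = int((~counts_ok).sum())
    out.log2 = out.log2.loc[counts_ok]
    for name in ("snr1", "snr2", "regression"):
        qc = getattr(out, name)
        if qc is not None:
            setattr(out, name, qc.loc[counts_ok])
    if out.log2.empty:
        raise ValidationError("no features pass filters")
    return out, removed


def median_center(matrix: RatioMatrix) -> RatioMatrix:
    """Subtract each array's median over its non-missing values."""
    out = matrix.copy()
    for a in out.array_ids:
        col = out.log2[a]
        if col.isna().all():
            raise ValidationError(f"array {a!r} has no non-missing values")
        out.log2[a] = col - col.median()
    return out


# ---------------------------------------------------------------------------
# SAM statistic
# ---------------------------------------------------------------------------

def _d_stats(X: np.ndarray, mask1: np.ndarray, s0: float):
    """Relative difference and pooled SE for one class-label assignment.

    Means and sums of squares run over present (non-NaN) cells only.
    """
    present = ~np.isnan(X)
    Xz = np.where(present, X, 0.0)
    in1 = present & mask1
    in2 = present & ~mask1
    c1 = in1.sum(axis=1)
    c2 = in2.sum(axis=1)
    m1 = np.where(c1 > 0, (Xz * mask1).sum(axis=1) / np.maximum(c1, 1), np.nan)
    m2 = np.where(c2 > 0, (Xz * ~mask1).sum(axis=1) / np.maximum(c2, 1), np.nan)
    ss1 = ((Xz - m1[:, None]) ** 2 * in1).sum(axis=1)
    ss2 = ((Xz - m2[:, None]) ** 2 * in2).sum(axis=1)
    dof = c1 + c2 - 2
    with np.errstate(invalid="ignore", divide="ignore"):
        s = np.sqrt((1.0 / c1 + 1.0 / c2) * (ss1 + ss2) / dof)
        d = (m1 - m2) / (s + s0)
    return d, s, m1 - m2


def _choose_s0(s: np.ndarray, mdiff: np.ndarray) -> float:
    """Percentile search: candidate s0 at every 5th percentile of s.

    Pick the candidate minimizing the coefficient of variation of
    window-wise median absolute deviations of d across 100 s-quantile
    windows.
    """
    order = np.argsort(s, kind="stable")
    n_windows = min(100, s.size)
    windows = np.array_split(order, n_windows)
    candidates = np.percentile(s, np.arange(0, 101, 5))
    best_s0, best_cv = candidates[0], np.inf
    for s0c in candidates:
        with np.errstate(invalid="ignore", divide="ignore"):
            d = mdiff / (s + s0c)
        mads = np.array([
            np.median(np.abs(d[w] - np.median(d[w]))) for w in windows if w.size
        ])
        mean = mads.mean()
        if mean == 0:
            continue
        cv = mads.std() / mean
        if cv < best_cv - 1e-15:
            best_cv, best_s0 = cv, float(s0c)
    return best_s0


def _signed_score(d: np.ndarray, side: str) -> np.ndarray:
    if side == "positive":
        return d
    if side == "negative":
        return -d
    return np.abs(d)


def sam_two_class(matrix: RatioMatrix, config: SamConfig) -> SamResult:
    """Two-class SAM: moderated d, permutation FDR, per-feature q-values.

    All distinct label assignments are enumerated when their count does
    not exceed ``n_permutations`` (or it is "all"); otherwise assignments
    are drawn uniformly with the configured seed.  q_i is the minimum
    estimated FDR over the score thresholds at which feature i is called,
    scaled by the pi0 estimate.
    """
    labels = matrix.classes
    class_order = matrix.class_labels
    lab1, lab2 = class_order[0], class_order[1]
    arrays = matrix.array_ids
    mask1_obs = np.array([labels[a] == lab1 for a in arrays])
    n1, n2 = int(mask1_obs.sum()), int((~mask1_obs).sum())
    if n1 < 2 or n2 < 2:
        raise ValidationError("SAM needs at least 2 arrays per class")

    X_all = matrix.log2.to_numpy(dtype=float)
    present = ~np.isnan(X_all)
    ok = (present[:, mask1_obs].sum(axis=1) >= 2) & (present[:, ~mask1_obs].sum(axis=1) >= 2)
    excluded = [f for f, o in zip(matrix.feature_ids, ok) if not o]
    if excluded:
        warnings.warn(f"{len(excluded)} feature(s) with <2 present values per class excluded",
                      stacklevel=2)
    X = X_all[ok]
    feature_ids = [f for f, o in zip(matrix.feature_ids, ok) if o]
    if X.shape[0] == 0:
        raise ValidationError("no features with enough present values")

    # observed statistic and s0
    _, s, mdiff = _d_stats(X, mask1_obs, 0.0)
    if config.s0_method == "fixed":
        s0 = float(config.s0_fixed)
    else:
        s0 = _choose_s0(s, mdiff)
    if np.nanmax(s) == 0 and s0 == 0:
        raise ValidationError("all features have zero variance; set s0 > 0")
    d_obs, s, _ = _d_stats(X, mask1_obs, s0)

    # label assignments
    n = len(arrays)
    total = comb(n, n1)
    if config.n_permutations == "all" or total <= config.n_permutations:
        assignments = list(combinations(range(n), n1))
    else:
        rng = np.random.default_rng(config.seed)
        assignments = [tuple(np.sort(rng.choice(n, size=n1, replace=False)))
                       for _ in range(config.n_permutations)]
    perm_d = np.empty((len(assignments), X.shape[0]))
    for i, idx in enumerate(assignments):
        mask = np.zeros(n, dtype=bool)
        mask[list(idx)] = True
        perm_d[i], _, _ = _d_stats(X, mask, s0)

    # pi0 from the central 50% range of the permuted d distribution
    if config.pi0_mode == "one":
        pi0 = 1.0
    else:
        q25, q75 = np.nanpercentile(perm_d, [25, 75])
        pi0 = min(1.0, ((d_obs >= q25) & (d_obs <= q75)).sum() / (0.5 * d_obs.size))

    # permutation FDR over decreasing score thresholds
    score_obs = _signed_score(d_obs, config.side)
    score_perm = _signed_score(perm_d, config.side)
    order = np.argsort(-score_obs, kind="stable")
    sorted_scores = score_obs[order]
    flat = np.sort(score_perm.ravel())
    m = score_obs.size
    groups = []  # (i, j, fdr) per tie-shared threshold, descending scores
    i = 0
    while i < m:
        j = i
        while j + 1 < m and sorted_scores[j + 1] == sorted_scores[i]:
            j += 1
        thresh = sorted_scores[i]
        n_obs_called = j + 1
        n_perm_called = flat.size - np.searchsorted(flat, thresh, side="left")
        exp_calls = n_perm_called / len(assignments)
        groups.append((i, j, min(1.0, pi0 * exp_calls / n_obs_called)))
        i = j + 1
    # q_i = min FDR over thresholds at which i is called (its own and weaker)
    q = np.empty(m)
    running = np.inf
    for gi, gj, fdr in reversed(groups):
        running = min(running, fdr)
        q[gi:gj + 1] = running
    q_value = np.empty(m)
    q_value[order] = q

    return SamResult(feature_ids, d_obs, s, q_value, s0, pi0,
                     len(assignments), config.side, excluded)


def call_targets(result: SamResult, fdr_cutoff: float = 0.05,
                 name: str = "sam_targets"):
    """Features with q below the cutoff on the analysis side.

    Returns ``(GeneSet or None, count, share-of-analyzed string)``.
    """
    from .regulon import percent_report

    if not 0 <= fdr_cutoff <= 1:
        raise ValidationError("fdr_cutoff must lie in [0, 1]")
    called = [f for f, qv in zip(result.feature_ids, result.q_value) if qv < fdr_cutoff]
    share = percent_report(len(called), len(result.feature_ids), 1)
    gene_set = GeneSet(name, f"SAM calls at FDR<{fdr_cutoff}", frozenset(called)) if called else None
    return gene_set, len(called), share


# ---------------------------------------------------------------------------
# one-sample fold-change test
# ---------------------------------------------------------------------------

def one_sample_fold_change_test(replicate_log2: Dict[str, Sequence[float]],
                                fold_threshold: float = 1.5,
                                alpha: float = 0.05) -> DEResult:
    """Two-sided one-sample t-test against 0 with a fold-change gate.

    A gene is called up (down) only if its mean log2 ratio is >= (<=-)
    log2(fold_threshold) AND the t-test p-value is below alpha.
    Zero-variance genes have an undefined p; they are flagged degenerate
    and never called.
    """
    log2_cut = float(np.log2(fold_threshold))
    rows = []
    for gene, values in replicate_log2.items():
        v = np.asarray([x for x in values if not (x is None or np.isnan(x))], dtype=float)
        if v.size < 2:
            raise ValidationError(f"{gene}: need >= 2 replicates for the t-test")
        mean = float(v.mean())
        degenerate = float(v.std(ddof=1)) == 0.0
        if degenerate:
            p = np.nan
        else:
            p = float(stats.ttest_1samp(v, 0.0).pvalue)
        called = "unchanged"
        if not degenerate and p < alpha:
            if mean >= log2_cut:
                called = "up"
            elif mean <= -log2_cut:
                called = "down"
        rows.append({"gene_id": gene, "mean_log2": mean, "p_value": p,
                     "called": called, "degenerate": degenerate})
    return DEResult(pd.DataFrame(rows))
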