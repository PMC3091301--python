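"""Shared fixtures and independent oracles used across the suite."""

from __future__ import annotations

from itertools import combinations
from math import comb, isnan, sqrt

import numpy as np
import pytest

from regulonscan.io_formats import GeneSet, TranscriptRecord
from regulonscan.motifs import IUPAC_CODES


@pytest.fixture
def simple_record():
    # 9 nt CDS of (GAA)x3, no UTRs
    return TranscriptRecord.build("t1", "GAAGAAGAA", (0, 0), (0, 9), (9, 9))


@pytest.fixture
def gene_universe():
    ids = [f"g{i:04d}" for i in range(200)]
    return ids, GeneSet("universe", "test universe", frozenset(ids))


# ---------------------------------------------------------------------------
# independent oracles (never share code with the implementation paths)
# ---------------------------------------------------------------------------

def oracle_scan_runs(sequence: str, triplet: str, min_run: int):
    """Greedy sliding-window scan: check every start, extend in steps of 3."""
    seq = sequence.upper().replace("T", "U")
    sets = [set(IUPAC_CODES[c]) for c in triplet]

    def match(i):
        if i + 3 > len(seq):
            return False
        return all(seq[i + j] in sets[j] and seq[i + j] != "N" for j in range(3))

    runs = []
    for start in range(len(seq)):
        if not match(start):
            continue
        if start - 3 >= 0 and match(start - 3):
            continue  # not maximal on the left
        length = 0
        i = start
        while match(i):
            length += 1
            i += 3
        if length >= min_run:
            runs.append((start, length))
    return sorted(runs)


def oracle_hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """P(overlap >= k) by enumerating all C(N, n) draws (N small)."""
    hits = 0
    total = 0
    reference = set(range(K))
    for draw in combinations(range(N), n):
        total += 1
        if len(reference & set(draw)) >= k:
            hits += 1
    return hits / total


def oracle_sam(X, mask1, s0, pi0_mode="one", side="positive"):
    """Full-enumeration SAM q-values with plain Python loops."""
    X = np.asarray(X, dtype=float)
    n_arrays = X.shape[1]
    n1 = int(np.sum(mask1))

    def d_stats(mask):
        ds = []
        for row in X:
            g1 = [v for v, m in zip(row, mask) if m and not isnan(v)]
            g2 = [v for v, m in zip(row, mask) if not m and not isnan(v)]
            m1 = sum(g1) / len(g1)
            m2 = sum(g2) / len(g2)
            ss = sum((v - m1) ** 2 for v in g1) + sum((v - m2) ** 2 for v in g2)
            s = sqrt((1 / len(g1) + 1 / len(g2)) * ss / (len(g1) + len(g2) - 2))
            ds.append((m1 - m2) / (s + s0))
        return ds

    def score(ds):
        if side == "positive":
            return list(ds)
        if side == "negative":
            return [-d for d in ds]
        return [abs(d) for d in ds]

    d_obs = d_stats(np.asarray(mask1, dtype=bool))
    perms = list(combinations(range(n_arrays), n1))
    perm_d = []
    for idx in perms:
        mask = np.zeros(n_arrays, dtype=bool)
        mask[list(idx)] = True
        perm_d.append(d_stats(mask))
    if pi0_mode == "one":
        pi0 = 1.0
    else:
        flat_d = [d for row in perm_d for d in row]
        q25, q75 = np.percentile(flat_d, [25, 75])
        pi0 = min(1.0, sum(q25 <= d <= q75 for d in d_obs) / (0.5 * len(d_obs)))

    s_obs = score(d_obs)
    s_perm = [score(row) for row in perm_d]

    def fdr(threshold):
        n_obs = sum(s >= threshold for s in s_obs)
        exp = sum(s >= threshold for row in s_perm for s in row) / len(perms)
        return min(1.0, pi0 * exp / n_obs)

    q = []
    for s_i in s_obs:
        q.append(min(fdr(t) for t in s_obs if t <= s_i))
    return np.array(d_obs), np.array(q), pi0


def oracle_chi2(table):
    """Textbook Pearson chi-square: sum (O-E)^2 / E."""
    t = np.asarray(table, dtype=float)
    row = t.sum(axis=1)
    col = t.sum(axis=0)
    total = t.sum()
    stat = 0.0
    for i in range(2):
        for j in range(2):
            e = row[i] * col[j] / total
            stat += (t[i, j] - e) ** 2 / e
    return stat


def oracle_mhg(indicator, stat_fn):
    """Exhaustive mHG p: fraction of placements with statistic <= observed."""
    indicator = np.asarray(indicator)
    N = indicator.size
    B = int(indicator.sum())
    observed = stat_fn(indicator)
    hits = 0
    total = 0
    for idx in combinations(range(N), B):
        vec = np.zeros(N, dtype=np.int64)
        vec[list(idx)] = 1
        total += 1
        if stat_fn(vec) <= observed * (1 + 1e-12):
            hits += 1
    return observed, hits / total, comb(N, B)
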