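#!/usr/bin/env python
"""Regulon expression analysis on the matched mRNA/protein tables.

Correlates mRNA with protein changes, tests the planted GO subsets for
target-specific shifts (Mann-Whitney with Welch companion), and checks
target overrepresentation among 1.5-fold up-regulated features.
"""

import argparse
from pathlib import Path

import pandas as pd

from regulonscan.io_formats import GeneSet, read_expression_table, read_gene_sets
from regulonscan.regulon import (changed_set_overrepresentation, mrna_protein_correlation,
                                 subset_shift_test)
from regulonscan.sam import FOLD_15_LOG2

ROOT = Path(__file__).resolve().parents[1]


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--study", type=Path, default=ROOT / "results" / "study")
    args = parser.parse_args()
    data = args.study / "data"

    expr = read_expression_table(data / "expression.tsv")
    go_map = {gs.name: gs for gs in read_gene_sets(data / "go.gmt")}
    targets_tsv = pd.read_csv(args.study / "targets.tsv", sep="\t")
    called = set(targets_tsv.loc[targets_tsv["called"], "feature_id"]) & set(expr.gene_ids)
    target_set = GeneSet("targets", "", frozenset(called))

    corr = mrna_protein_correlation(expr)
    print(f"mRNA vs protein changes: Pearson r={corr.pearson_r:.3f} "
          f"over {corr.n_pairs} complete pairs")

    truth = (data / "truth_expression.tsv").read_text()
    shifted_terms = [l.split("\t")[1] for l in truth.splitlines() if l.startswith("# shift")]
    rows = []
    for term in shifted_terms:
        for column in ("mrna", "protein"):
            res = subset_shift_test(expr, term, target_set, column)
            rows.append({"go_term": term, "value": column, "n": res.n,
                         "mean_log2": res.summary.mean, "median": res.summary.median,
                         "mw_p_vs_all": res.mw_p_vs_all,
                         "mw_p_vs_nontargets": res.mw_p_vs_nontargets,
                         "welch_p_vs_all": res.welch_p_vs_all, "stars": res.stars})
            print(f"{term} [{column}]: n={res.n}, mean log2={res.summary.mean:+.2f}, "
                  f"MW p vs all={res.mw_p_vs_all:.2g} {res.stars}")
    pd.DataFrame(rows).to_csv(args.study / "fig6.tsv", sep="\t", index=False)

    for column in ("mrna", "protein"):
        values = expr.values(column)
        up = {g for g, v in values.items() if v >= FOLD_15_LOG2}
        if not up:
            continue
        measured = GeneSet("measured", "", frozenset(values.index))
        res = changed_set_overrepresentation(GeneSet("up", "", frozenset(up)),
                                             f"up_{column}", target_set, measured)
        print(f"up-regulated {column}: {res.n_targets_in_changed} of {res.n_changed} "
              f"are targets ({res.percent}), chi-square p={res.chi2.p_value:.3g}")


if __name__ == "__main__":
    main()
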