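#!/usr/bin/env python
"""Set-level statistics on the called targets.

Runs hypergeometric GO-term enrichment over the explicit transcript
universe, minimum-hypergeometric enrichment on the SAM-score-ranked
list, and the Bonferroni-corrected overlap matrix against the synthetic
RBP target collections.
"""

import argparse
from pathlib import Path

import pandas as pd

from regulonscan.enrichment import go_enrichment, overlap_matrix, ranked_enrichment_mhg
from regulonscan.io_formats import GeneSet, read_gene_sets, read_transcripts
from regulonscan.pipeline import derive_seed
from regulonscan.regulon import percent_report

ROOT = Path(__file__).resolve().parents[1]


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--study", type=Path, default=ROOT / "results" / "study")
    args = parser.parse_args()
    data = args.study / "data"

    records = read_transcripts(data / "transcripts.fa", data / "regions.tsv")
    universe = GeneSet("universe", "", frozenset(r.transcript_id for r in records))
    go_map = read_gene_sets(data / "go.gmt")
    rbp_sets = read_gene_sets(data / "rbp.gmt")
    targets_tsv = pd.read_csv(args.study / "targets.tsv", sep="\t")
    called = set(targets_tsv.loc[targets_tsv["called"], "feature_id"]) & set(universe.members)
    query = GeneSet("targets", "", frozenset(called))

    go_res = go_enrichment(query, go_map, universe)
    pd.DataFrame([r.__dict__ for r in go_res]).to_csv(args.study / "enrich.tsv",
                                                      sep="\t", index=False)
    top = go_res[0]
    print(f"top GO term {top.query_name}: {top.overlap_count}/{top.reference_size} "
          f"members among {top.query_size} targets, Bonferroni p={top.p_bonferroni:.3g}")

    ranked = (targets_tsv.sort_values("d", ascending=False)["feature_id"].tolist())
    mhg_rows = []
    for term in go_map:
        if not set(term.members) & set(ranked):
            continue
        r = ranked_enrichment_mhg(ranked, term, seed=derive_seed(42, "mhg"))
        mhg_rows.append({"term": r.term_name, "n_star": r.n_star, "b_star": r.b_star,
                         "mhg_stat": r.mhg_stat, "p_exact": r.p_exact,
                         "enrichment_ratio": r.enrichment_ratio})
    mhg_df = pd.DataFrame(mhg_rows).sort_values("p_exact")
    mhg_df.to_csv(args.study / "mhg.tsv", sep="\t", index=False)
    best = mhg_df.iloc[0]
    print(f"ranked-list mHG: {best.term} p={best.p_exact:.3g} "
          f"(b*={best.b_star} of n*={best.n_star}, ratio={best.enrichment_ratio:.2f})")

    overlaps = overlap_matrix(query, rbp_sets, universe)
    pd.DataFrame([o.__dict__ for o in overlaps]).to_csv(args.study / "overlap.tsv",
                                                        sep="\t", index=False)
    for o in overlaps:
        share = percent_report(o.overlap_count, o.query_size, 1)
        print(f"{o.query_name}: {o.overlap_count} of {o.query_size} targets shared "
              f"({share}), Bonferroni p={o.p_bonferroni:.3g}")


if __name__ == "__main__":
    main()
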