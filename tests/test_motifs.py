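"""Triplet-run scanner, frame analysis, count tables and motif discovery."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from regulonscan.io_formats import GeneSet, TranscriptRecord, ValidationError
from regulonscan.motifs import (MotifHit, TripletPattern, discover_repeat_motifs,
                                frame_distribution, motif_gene_set, region_count_table,
                                scan_runs, scan_transcript)
from regulonscan.synthetic_data import PlantSpec, simulate_transcriptome

from conftest import oracle_scan_runs


GWW = TripletPattern("GWW")
GAN = TripletPattern("GAN")


class TestScanRuns:
    def test_gaugaa_repeat_is_one_ten_triplet_run(self):
        # ten consecutive GWW triplets: GAU GAA GAU GAA ...
        assert scan_runs("GAUGAA" * 5, GWW, 3) == [(0, 10)]

    def test_guggug_repeat_never_matches_gww(self):
        # third position G never matches W = A/U
        assert scan_runs("GUGGUG" * 5, GWW, 1) == []

    def test_gaa7_with_breaking_flanks(self):
        seq = "CC" + "GAA" * 7 + "CC"
        assert scan_runs(seq, GAN, 7) == [(2, 7)]

    def test_phase_completeness_off_frame_run_found(self):
        # (GAA)3 starting at offset 1: runs need not start at offset 0
        assert scan_runs("AGAAGAAGAAG", GAN, 3) == [(1, 3)]

    def test_sequence_n_matches_nothing(self):
        assert scan_runs("GANGAA", GAN, 1) == [(3, 1)]

    def test_invalid_pattern_code_rejected(self):
        with pytest.raises(ValidationError):
            TripletPattern("GXW")

    @pytest.mark.parametrize("triplet", ["GWW", "GAN", "GSS", "NNN"])
    def test_matches_sliding_window_oracle(self, triplet):
        rng = np.random.default_rng(17)
        bases = np.array(list("ACGUN"))
        pat = TripletPattern(triplet)
        for _ in range(60):
            seq = "".join(bases[rng.integers(5, size=rng.integers(3, 80))])
            assert scan_runs(seq, pat, 2) == oracle_scan_runs(seq, triplet, 2)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGU", min_size=0, max_size=60), st.integers(1, 4))
    def test_property_runs_are_maximal_and_sorted(self, seq, min_run):
        runs = scan_runs(seq, GWW, min_run)
        assert runs == sorted(runs)
        assert runs == oracle_scan_runs(seq, "GWW", min_run)


class TestScanTranscript:
    def _record(self, utr5, cds, utr3):
        seq = utr5 + cds + utr3
        a, b = len(utr5), len(utr5) + len(cds)
        return TranscriptRecord.build("t", seq, (0, a), (a, b), (b, len(seq)))

    @pytest.mark.parametrize("offset,frame", [(12, 0), (13, 1), (14, 2)])
    def test_cds_frame_is_start_mod_3(self, offset, frame):
        cds = list("C" * 33)
        cds[offset:offset + 9] = "GAAGAUGAA"
        rec = self._record("", "".join(cds), "")
        hits = scan_transcript(rec, GWW, 3)
        assert [(h.start, h.frame) for h in hits] == [(offset, frame)]

    def test_utr_hits_have_no_frame(self):
        rec = self._record("GAAGAAGAA", "C" * 9, "GAUGAUGAU")
        hits = scan_transcript(rec, GWW, 3)
        assert {(h.region, h.frame) for h in hits} == {("utr5", None), ("utr3", None)}

    def test_region_boundary_splits_runs(self):
        # six GAA triplets straddling the CDS/3'UTR junction: 4 in CDS, 2 in UTR
        rec = self._record("", "C" * 3 + "GAA" * 4, "GAA" * 2 + "CC")
        hits = scan_transcript(rec, GAN, 1)
        assert [(h.region, h.start, h.run_length) for h in hits] == [
            ("cds", 3, 4), ("utr3", 0, 2)]


class TestRegionCountTable:
    def _planted(self, run_lengths, n=10):
        recs = []
        for i, L in enumerate(run_lengths):
            cds = "C" * 3 + "GAA" * L + "CC" + "C" * 13
            cds = cds[: 3 * (len(cds) // 3)]
            recs.append(TranscriptRecord.build(f"t{i}", cds, (0, 0),
                                               (0, len(cds)), (len(cds), len(cds))))
        return recs

    def test_counts_monotone_and_forced_values(self):
        recs = self._planted([5] * 10)
        ids = [r.transcript_id for r in recs]
        uni = GeneSet("u", "", frozenset(ids))
        tgt = GeneSet("t", "", frozenset(ids[:4]))
        table = region_count_table(recs, GAN, [3, 4, 5, 6], tgt, uni)
        cds = table[table.region == "cds"].set_index("k")
        assert list(cds.loc[[3, 4, 5], "n_transcripts_with_motif"]) == [10, 10, 10]
        assert list(cds.loc[[3, 4, 5], "n_motif_occurrences"]) == [10, 10, 10]
        assert cds.loc[6, "n_transcripts_with_motif"] == 0
        # monotone non-increasing in k
        assert (np.diff(cds["n_transcripts_with_motif"]) <= 0).all()

    def test_two_runs_one_transcript_counting_mode(self):
        cds = "GAA" * 4 + "CCC" + "GAA" * 6
        rec = TranscriptRecord.build("t0", cds, (0, 0), (0, len(cds)), (len(cds), len(cds)))
        uni = GeneSet("u", "", frozenset(["t0"]))
        table = region_count_table([rec], GAN, [4], uni, uni)
        row = table[(table.k == 4) & (table.region == "cds")].iloc[0]
        assert row["n_transcripts_with_motif"] == 1
        assert row["n_motif_occurrences"] == 2

    def test_planted_truth_counts_exact(self):
        recs, truth = simulate_transcriptome(
            40, length_model={"utr5": 30, "cds": 300, "utr3": 60},
            plant_spec=PlantSpec(run_lengths=(5,), fraction_planted=0.5), seed=5)
        uni = GeneSet("u", "", frozenset(r.transcript_id for r in recs))
        tgt = GeneSet("t", "", frozenset(truth.planted_target_ids))
        table = region_count_table(recs, TripletPattern("GWW"), [5], tgt, uni)
        for region in ("utr5", "cds", "utr3"):
            row = table[(table.k == 5) & (table.region == region)].iloc[0]
            expected = {h.transcript_id for h in truth.planted_hits if h.region == region}
            assert row["n_transcripts_with_motif"] == len(expected)

    def test_target_outside_universe_rejected(self):
        recs = self._planted([5])
        uni = GeneSet("u", "", frozenset(["t0"]))
        tgt = GeneSet("t", "", frozenset(["elsewhere"]))
        with pytest.raises(ValidationError):
            region_count_table(recs, GAN, [3], tgt, uni)


class TestFrameDistribution:
    def test_printed_ratio_93_percent(self):
        hits = [MotifHit("t", "cds", 0, 4, 0)] * 416 + [MotifHit("t", "cds", 1, 4, 1)] * 30
        dist = frame_distribution(hits)
        assert dist[0] == (416, 93.0)

    def test_all_frame_zero_is_100(self):
        dist = frame_distribution([MotifHit("t", "cds", 3, 4, 0)] * 7)
        assert dist[0] == (7, 100.0) and dist[1][0] == 0

    def test_empty_input_percentages_undefined(self):
        dist = frame_distribution([])
        assert all(c == 0 and p is None for c, p in dist.values())

    def test_utr_hits_rejected(self):
        with pytest.raises(ValueError):
            frame_distribution([MotifHit("t", "utr3", 0, 4, None)])


class TestMotifGeneSet:
    def test_k_beyond_any_run_is_empty(self):
        recs, _ = simulate_transcriptome(10, plant_spec=PlantSpec(run_lengths=(4,)),
                                         length_model={"cds": 300}, seed=0)
        assert motif_gene_set(recs, GWW, 50) is None

    def test_gss_on_gww_planted_transcriptome_empty(self):
        recs, _ = simulate_transcriptome(
            20, length_model={"utr5": 20, "cds": 240, "utr3": 30},
            plant_spec=PlantSpec(pattern="GWW", run_lengths=(6,), fraction_planted=0.5),
            seed=1)
        assert motif_gene_set(recs, TripletPattern("GSS"), 4) is None

    def test_gan_k7_recovers_planted_transcripts(self):
        recs, truth = simulate_transcriptome(
            30, length_model={"utr5": 20, "cds": 300, "utr3": 30},
            plant_spec=PlantSpec(pattern="GAN", run_lengths=(7, 8),
                                 region_probs={"cds": 1.0}, fraction_planted=0.4),
            seed=2)
        gs = motif_gene_set(recs, GAN, 7, region="cds")
        assert set(gs.members) == truth.planted_target_ids


class TestDiscovery:
    def _planted(self, seed=9):
        recs, truth = simulate_transcriptome(
            60, length_model={"utr5": 30, "cds": 450, "utr3": 60},
            plant_spec=PlantSpec(pattern="GAN", run_lengths=(7, 8),
                                 region_probs={"cds": 1.0}, fraction_planted=0.3),
            seed=seed)
        targets = [r for r in recs if r.transcript_id in truth.planted_target_ids]
        return targets, recs

    def test_planted_pattern_recovered_top_ranked(self):
        targets, background = self._planted(seed=9)
        ranked = discover_repeat_motifs(targets, background, 7)
        top = ranked[0][0].triplet
        # tie-break favors the most specific pattern consistent with the plant
        assert top == "GAN"

    def test_background_equals_targets_no_enrichment(self):
        targets, _ = self._planted()
        ranked = discover_repeat_motifs(targets, targets, 7)
        assert all(p >= 0.999 for _, p in ranked)

    def test_empty_targets_rejected(self):
        _, background = self._planted()
        with pytest.raises(ValidationError):
            discover_repeat_motifs([], background, 7)

    def test_null_no_bonferroni_significant_candidate(self):
        alphabet = (tuple("G"), tuple("ACGUW"), tuple("ACGUWN"))
        ok = 0
        n_seeds = 12
        for seed in range(n_seeds):
            recs, _ = simulate_transcriptome(
                40, length_model={"utr5": 20, "cds": 300, "utr3": 40},
                plant_spec=PlantSpec(fraction_planted=0.0), seed=100 + seed)
            rng = np.random.default_rng(seed)
            idx = rng.choice(len(recs), size=12, replace=False)
            targets = [recs[i] for i in idx]
            ranked = discover_repeat_motifs(targets, recs, 4, candidate_alphabet=alphabet)
            m = len(ranked)
            if all(min(1.0, m * p) >= 0.05 for _, p in ranked):
                ok += 1
        assert ok >= n_seeds - 1
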