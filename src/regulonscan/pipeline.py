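"""End-to-end orchestration: simulate -> SAM -> scan -> enrich -> regulon.

A pipeline run is configured by a single YAML file, uses one global seed
fanned out to per-stage seeds by stage-name hashing (adding a stage never
perturbs earlier stages' random streams), and writes only diffable
plain-text outputs: ``targets.tsv``, ``hits.tsv``, ``table1.tsv``,
``enrich.tsv``, ``overlap.tsv``, ``fig6.tsv``, ``report.txt`` and a
``manifest.txt`` recording versions, seeds and the config hash.  Reruns
with the same config and seed are byte-identical.
"""

from __future__ import annotations

import hashlib
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .enrichment import go_enrichment, overlap_matrix, ranked_enrichment_mhg
from .io_formats import (GeneSet, ValidationError, read_expression_table, read_gene_sets,
                         read_ratio_matrix, read_transcripts, write_expression_table,
                         write_gene_sets, write_ratio_matrix, write_transcripts)
from .motifs import TripletPattern, frame_distribution, region_count_table, scan_transcript
from .regulon import (changed_set_overrepresentation, mrna_protein_correlation,
                      percent_report, subset_shift_test)
from .sam import SamConfig, call_targets, filter_features, median_center, sam_two_class
from .synthetic_data import (PlantSpec, simulate_expression, simulate_ripchip,
                             simulate_transcriptome, write_sim_truth)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "make_demo", "derive_seed"]

logger = logging.getLogger(__name__)


def derive_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed from the global seed and stage name."""
    return (zlib.crc32(f"{stage}:{global_seed}".encode()) ^ global_seed) % (2 ** 31)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, original: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (see ``make_demo`` for an example)."""

    seed: int
    outdir: str
    transcripts_fasta: str
    regions: str
    ratios: str
    design: str
    expression: str
    go_sets: str
    rbp_sets: str
    fdr_cutoff: float = 0.05
    n_permutations: object = "all"
    snr_min: float = 1.8
    patterns: List[dict] = field(default_factory=lambda: [
        {"pattern": "GWW", "k_values": [3, 4, 5, 6, 7, 8]},
        {"pattern": "GAN", "k_values": [7]},
    ])
    shift_terms: List[str] = field(default_factory=list)
    change_threshold_log2: float = 0.585
    report_decimals: int = 1

    @staticmethod
    def from_yaml(path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        cfg = PipelineConfig(**raw)
        base = Path(path).parent
        for attr in ("outdir", "transcripts_fasta", "regions", "ratios", "design",
                     "expression", "go_sets", "rbp_sets"):
            p = Path(getattr(cfg, attr))
            if not p.is_absolute():
                setattr(cfg, attr, str(base / p))
        return cfg

    def config_hash(self) -> str:
        """Hash of the analytic configuration; paths enter by basename only,
        so the same analysis run from a different directory hashes alike."""
        canon = {}
        for key, value in self.__dict__.items():
            if key in ("outdir", "transcripts_fasta", "regions", "ratios", "design",
                       "expression", "go_sets", "rbp_sets"):
                canon[key] = Path(value).name
            else:
                canon[key] = value
        return hashlib.sha256(yaml.safe_dump(canon, sort_keys=True).encode()).hexdigest()[:16]


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                logger.info("stage %s: start", name)
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - rewrap with stage name
                raise PipelineError(name, exc) from exc
        return inner
    return wrap


def run_pipeline(config: PipelineConfig) -> Dict[str, object]:
    """Execute every stage; returns the in-memory report bundle."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report_lines: List[str] = []
    bundle: Dict[str, object] = {}

    @_stage("load")
    def load():
        records = read_transcripts(config.transcripts_fasta, config.regions)
        matrix = read_ratio_matrix(config.ratios, config.design)
        go_map = read_gene_sets(config.go_sets)
        rbp_sets = read_gene_sets(config.rbp_sets)
        expr = read_expression_table(config.expression)
        return records, matrix, go_map, rbp_sets, expr

    records, matrix, go_map, rbp_sets, expr = load()
    universe = GeneSet("universe", "all loaded transcripts",
                       frozenset(r.transcript_id for r in records))

    @_stage("sam")
    def sam_stage():
        filtered, removed = filter_features(matrix, snr_min=config.snr_min,
                                            snr_channels="input_only")
        logger.info("QC removed %s cells (snr), dropped %s features",
                    removed["snr"], removed["features_dropped"])
        centered = median_center(filtered)
        sam_cfg = SamConfig(n_permutations=config.n_permutations,
                            fdr_cutoff=config.fdr_cutoff,
                            seed=derive_seed(config.seed, "sam"))
        result = sam_two_class(centered, sam_cfg)
        targets, n_called, share = call_targets(result, config.fdr_cutoff)
        frame = result.to_frame()
        frame["called"] = frame["q"] < config.fdr_cutoff
        frame.to_csv(outdir / "targets.tsv", sep="\t", index=False)
        report_lines.append(
            f"SAM: {n_called} of {len(result.feature_ids)} analyzed features at "
            f"FDR<{config.fdr_cutoff:g} ({share}) [removed: snr={removed['snr']}, "
            f"dropped={removed['features_dropped']}]"
        )
        return result, targets

    sam_result, target_set = sam_stage()
    if target_set is None:
        target_set = GeneSet("sam_targets", "empty fallback", frozenset(["__none__"]))

    @_stage("scan")
    def scan_stage():
        tables = []
        hits_rows = []
        for spec in config.patterns:
            pattern = TripletPattern(spec["pattern"])
            k_values = list(spec["k_values"])
            for rec in records:
                for h in scan_transcript(rec, pattern, min(k_values)):
                    hits_rows.append({
                        "pattern": pattern.label, "transcript_id": h.transcript_id,
                        "region": h.region, "start": h.start,
                        "run_length": h.run_length,
                        "frame": "" if h.frame is None else h.frame,
                    })
            target_members = frozenset(set(target_set.members) & set(universe.members))
            table_targets = (GeneSet(target_set.name, target_set.description, target_members)
                             if target_members else
                             GeneSet("no_targets", "placeholder",
                                     frozenset([next(iter(universe.members))])))
            tables.append(region_count_table(records, pattern, k_values,
                                             table_targets, universe))
        pd.DataFrame(hits_rows).to_csv(outdir / "hits.tsv", sep="\t", index=False)
        table1 = pd.concat(tables, ignore_index=True)
        table1.to_csv(outdir / "table1.tsv", sep="\t", index=False)

        first = TripletPattern(config.patterns[0]["pattern"])
        cds_hits = [h for rec in records
                    for h in scan_transcript(rec, first, min(config.patterns[0]["k_values"]))
                    if h.region == "cds" and rec.transcript_id in target_set.members]
        dist = frame_distribution(cds_hits)
        n_total = sum(c for c, _ in dist.values())
        if n_total:
            c0 = dist[0][0]
            report_lines.append(
                f"Frame: {c0} ({percent_report(c0, n_total, 0)}) of {n_total} "
                f"{first.label} CDS runs in targets start at the first codon position"
            )
        return table1

    table1 = scan_stage()

    @_stage("enrich")
    def enrich_stage():
        target_members = set(target_set.members) & set(universe.members)
        rows = []
        if target_members:
            query = GeneSet("targets", "SAM targets", frozenset(target_members))
            for r in go_enrichment(query, go_map, universe):
                rows.append(r.__dict__)
        pd.DataFrame(rows).to_csv(outdir / "enrich.tsv", sep="\t", index=False)

        ranked = [f for _, f in sorted(zip(-sam_result.d_score, sam_result.feature_ids))]
        mhg_rows = []
        for term in go_map:
            if not set(term.members) & set(ranked):
                continue
            res = ranked_enrichment_mhg(ranked, term,
                                        seed=derive_seed(config.seed, "mhg"))
            mhg_rows.append({
                "term": res.term_name, "N": res.N, "B": res.B, "n_star": res.n_star,
                "b_star": res.b_star, "mhg_stat": res.mhg_stat, "p_exact": res.p_exact,
                "enrichment_ratio": res.enrichment_ratio,
            })
        pd.DataFrame(mhg_rows).to_csv(outdir / "mhg.tsv", sep="\t", index=False)

        overlaps = overlap_matrix(GeneSet("targets", "", frozenset(target_members))
                                  if target_members else target_set,
                                  rbp_sets, universe)
        pd.DataFrame([o.__dict__ for o in overlaps]).to_csv(
            outdir / "overlap.tsv", sep="\t", index=False)
        for o in overlaps:
            report_lines.append(
                f"Overlap: {o.overlap_count} of {o.query_size} {o.query_name} targets "
                f"({percent_report(o.overlap_count, o.query_size, config.report_decimals)}), "
                f"Bonferroni p={o.p_bonferroni:.3g}"
            )

    enrich_stage()

    @_stage("regulon")
    def regulon_stage():
        corr = mrna_protein_correlation(expr)
        report_lines.append(
            f"Correlation: Pearson r={corr.pearson_r:.3f} over {corr.n_pairs} "
            "mRNA/protein pairs"
        )
        target_members = set(target_set.members) & set(expr.gene_ids)
        fig6_rows = []
        if target_members:
            tset = GeneSet("targets", "", frozenset(target_members))
            for term in config.shift_terms:
                for column in ("mrna", "protein"):
                    try:
                        res = subset_shift_test(expr, term, tset, column)
                    except ValidationError:
                        continue
                    fig6_rows.append({
                        "go_term": res.go_term, "value": res.value_column, "n": res.n,
                        "median": res.summary.median, "mean": res.summary.mean,
                        "q1": res.summary.q1, "q3": res.summary.q3,
                        "p10": res.summary.p10, "p90": res.summary.p90,
                        "mw_p_vs_all": res.mw_p_vs_all,
                        "mw_p_vs_nontargets": res.mw_p_vs_nontargets,
                        "welch_p_vs_all": res.welch_p_vs_all, "stars": res.stars,
                    })
            for column in ("mrna", "protein"):
                values = expr.values(column)
                up = {g for g, v in values.items() if v >= config.change_threshold_log2}
                if not up:
                    continue
                meas_universe = GeneSet("measured", "", frozenset(values.index))
                res = changed_set_overrepresentation(
                    GeneSet(f"up_{column}", "", frozenset(up)), f"up_{column}",
                    tset, meas_universe)
                report_lines.append(
                    f"Changed: {res.n_targets_in_changed} of {res.n_changed} up-regulated "
                    f"{column} features are targets ({res.percent}), chi-square "
                    f"p={res.chi2.p_value:.3g}"
                )
        pd.DataFrame(fig6_rows).to_csv(outdir / "fig6.tsv", sep="\t", index=False)

    regulon_stage()

    (outdir / "report.txt").write_text("\n".join(report_lines) + "\n", encoding="utf-8")
    manifest = [
        f"regulonscan version: {__version__}",
        f"config hash: {config.config_hash()}",
        f"global seed: {config.seed}",
        *(f"stage seed {s}: {derive_seed(config.seed, s)}" for s in ("sam", "mhg")),
    ]
    (outdir / "manifest.txt").write_text("\n".join(manifest) + "\n", encoding="utf-8")
    bundle["report_lines"] = report_lines
    bundle["table1"] = table1
    bundle["target_set"] = target_set
    return bundle


# ---------------------------------------------------------------------------
# bundled demo dataset
# ---------------------------------------------------------------------------

def make_demo(config_out, seed: int = 42, n_transcripts: int = 1000,
              n_go_terms: int = 20, n_rbp_sets: int = 5) -> PipelineConfig:
    """Write a self-contained synthetic dataset plus its pipeline config.

    The demo couples the stages the way the biology does: the RIP-chip
    target set equals the motif-planted transcripts, GO terms partition
    the transcriptome with two terms carrying planted expression shifts,
    and RBP query sets overlap the targets to varying degrees.
    """
    config_out = Path(config_out)
    data_dir = config_out.parent / "data"
    data_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(derive_seed(seed, "demo"))

    records, truth = simulate_transcriptome(
        n_transcripts, plant_spec=PlantSpec(), seed=derive_seed(seed, "transcriptome"))
    write_transcripts(records, data_dir / "transcripts.fa", data_dir / "regions.tsv")
    write_sim_truth(truth, data_dir / "truth_transcriptome.tsv")
    ids = [r.transcript_id for r in records]
    planted = truth.planted_target_ids

    matrix, rip_truth = simulate_ripchip(
        feature_ids=ids, target_ids=planted, seed=derive_seed(seed, "ripchip"))
    write_ratio_matrix(matrix, data_dir / "ratios.tsv", data_dir / "design.tsv")
    write_sim_truth(rip_truth, data_dir / "truth_ripchip.tsv")

    # GO map: random terms; the first two are enriched for planted targets
    planted_list = sorted(planted)
    other_list = sorted(set(ids) - planted)
    term_size = max(10, n_transcripts // 20)
    go_sets = []
    for i in range(n_go_terms):
        name = f"GO:{7000000 + i}"
        if i < 2:
            n_in = min(len(planted_list), max(3, int(0.6 * term_size)))
            members = (list(rng.choice(planted_list, size=n_in, replace=False))
                       + list(rng.choice(other_list, size=term_size - n_in, replace=False)))
        else:
            members = list(rng.choice(ids, size=term_size, replace=False))
        go_sets.append(GeneSet(name, f"synthetic GO term {i}", frozenset(members)))
    write_gene_sets(go_sets, data_dir / "go.gmt")

    rbp_sets = []
    for i, frac in enumerate(np.linspace(0.6, 0.05, n_rbp_sets)):
        size = int(rng.integers(max(9, n_transcripts // 16), max(10, n_transcripts // 5)))
        n_in = min(len(planted_list), int(round(frac * size)))
        members = (list(rng.choice(planted_list, size=n_in, replace=False))
                   + list(rng.choice(other_list, size=size - n_in, replace=False)))
        rbp_sets.append(GeneSet(f"RBP{i + 1}", f"synthetic RBP targets, overlap {frac:.2f}",
                                frozenset(members)))
    write_gene_sets(rbp_sets, data_dir / "rbp.gmt")

    shifts = {go_sets[0].name: (0.0, 0.9),    # protein-only up (motor-activity-like)
              go_sets[1].name: (-0.5, -0.4)}  # repressed at both levels
    targets_gs = GeneSet("planted_targets", "motif-planted transcripts", frozenset(planted))
    expr, expr_truth = simulate_expression(
        ids, go_sets, targets_gs, shifts, seed=derive_seed(seed, "expression"))
    write_expression_table(expr, data_dir / "expression.tsv")
    write_sim_truth(expr_truth, data_dir / "truth_expression.tsv")

    cfg = PipelineConfig(
        seed=seed,
        outdir=str(config_out.parent / "out"),
        transcripts_fasta=str(data_dir / "transcripts.fa"),
        regions=str(data_dir / "regions.tsv"),
        ratios=str(data_dir / "ratios.tsv"),
        design=str(data_dir / "design.tsv"),
        expression=str(data_dir / "expression.tsv"),
        go_sets=str(data_dir / "go.gmt"),
        rbp_sets=str(data_dir / "rbp.gmt"),
        shift_terms=[go_sets[0].name, go_sets[1].name],
    )
    config_out.write_text(yaml.safe_dump(cfg.__dict__, sort_keys=True), encoding="utf-8")
    return cfg
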