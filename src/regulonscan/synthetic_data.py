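"""Seeded generators for synthetic study inputs with exact ground truth.

The generators emulate the statistical structure of a RIP-chip study of
a triplet-repeat-binding protein: a transcriptome with 5'UTR/CDS/3'UTR
structure and plantable in-frame triplet repeats, a 3-IP-vs-5-mock
two-color ratio matrix with planted enrichment, matched mRNA/protein
fold-change tables with GO-linked target-specific shifts, and gene-set
collections with exact pairwise overlaps.

Background sequence is i.i.d. uniform over A,C,G,U, which makes chance
run rates analytically checkable.  Planted runs are isolated with
run-breaking flanking bases, and a cleanup pass breaks any chance
background run reaching the plant's minimum length, so the scanner's
recovery of the planted hits is exact by construction.  Every draw flows
from one seeded generator per call; the same seed gives byte-identical
outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .io_formats import ExpressionTable, GeneSet, RatioMatrix, TranscriptRecord, ValidationError
from .motifs import IUPAC_CODES, MotifHit, TripletPattern, scan_runs

__all__ = [
    "SimTruth",
    "PlantSpec",
    "simulate_transcriptome",
    "simulate_ripchip",
    "simulate_expression",
    "simulate_geneset_overlap",
    "write_sim_truth",
]

_BASES = np.array(list("ACGU"))


@dataclass
class SimTruth:
    """Ground truth emitted alongside every simulated dataset."""

    seed: int
    planted_target_ids: set = field(default_factory=set)
    planted_hits: List[MotifHit] = field(default_factory=list)
    planted_shifts: Dict[str, Tuple[float, float]] = field(default_factory=dict)
    extras: dict = field(default_factory=dict)


@dataclass
class PlantSpec:
    """What to plant: pattern, run lengths, regions, frame bias, coverage.

    Defaults mirror the study conditions: a GWW consensus planted mostly
    in coding sequence, strongly biased to the first codon position, in
    about a quarter of transcripts.
    """

    pattern: object = "GWW"
    run_lengths: Sequence[int] = (4, 5, 6, 7, 8)
    run_length_probs: Optional[Sequence[float]] = None
    region_probs: Dict[str, float] = field(
        default_factory=lambda: {"utr5": 0.05, "cds": 0.85, "utr3": 0.10}
    )
    in_frame_probability: float = 0.93
    fraction_planted: float = 0.25

    def __post_init__(self):
        if not isinstance(self.pattern, TripletPattern):
            self.pattern = TripletPattern(str(self.pattern))
        total = sum(self.region_probs.get(r, 0.0) for r in ("utr5", "cds", "utr3"))
        if abs(total - 1.0) > 1e-9:
            raise ValidationError("region probabilities must sum to 1")
        if not 0.0 <= self.in_frame_probability <= 1.0:
            raise ValidationError("in_frame_probability must lie in [0, 1]")
        if not 0.0 <= self.fraction_planted <= 1.0:
            raise ValidationError("fraction_of_transcripts_planted must lie in [0, 1]")
        if all(len(IUPAC_CODES[c]) == 4 for c in self.pattern.triplet):
            raise ValidationError("an all-N pattern cannot be isolated with run-breaking flanks")


DEFAULT_LENGTH_MODEL = {"utr5": 60, "cds": 1200, "utr3": 120}


def _complement_base(rng, pattern_set: frozenset) -> str:
    choices = sorted(set("ACGU") - pattern_set)
    return choices[rng.integers(len(choices))]


def _breaker_position(pattern: TripletPattern, preferred: Sequence[int]) -> Optional[int]:
    sets = pattern.position_sets()
    for j in preferred:
        if len(sets[j]) < 4:
            return j
    return None


def _plant_run(rng, region_seq: np.ndarray, start: int, length: int,
               pattern: TripletPattern) -> None:
    """Stamp a run instance and run-breaking flanks into a region array."""
    sets = pattern.position_sets()
    for t in range(length):
        for j in range(3):
            bases = sorted(sets[j])
            region_seq[start + 3 * t + j] = bases[rng.integers(len(bases))]
    # left flank: kill the extension triplet at start-3 (nearest position first)
    if start - 3 >= 0:
        j = _breaker_position(pattern, (2, 1, 0))
        region_seq[start - 3 + j] = _complement_base(rng, sets[j])
    end = start + 3 * length
    if end + 3 <= region_seq.size:
        j = _breaker_position(pattern, (0, 1, 2))
        region_seq[end + j] = _complement_base(rng, sets[j])


def _break_chance_run(rng, region_seq: np.ndarray, run: Tuple[int, int],
                      pattern: TripletPattern, protected: List[Tuple[int, int]]) -> bool:
    """Mutate one base inside an unplanned run, avoiding planted intervals."""
    sets = pattern.position_sets()
    start, length = run
    for t in range(length):
        for j in range(3):
            pos = start + 3 * t + j
            if len(sets[j]) == 4:
                continue
            if any(a <= pos < b for a, b in protected):
                continue
            region_seq[pos] = _complement_base(rng, sets[j])
            return True
    return False


def simulate_transcriptome(n_transcripts: int, length_model: Optional[dict] = None,
                           plant_spec: Optional[PlantSpec] = None, seed: int = 0):
    """Uniform-background transcriptome with exactly known planted repeats.

    Returns ``(records, SimTruth)``.  Planted transcripts form the
    ground-truth target set; each carries one planted run whose region,
    length and codon frame are drawn from ``plant_spec``.
    """
    rng = np.random.default_rng(seed)
    lengths = {**DEFAULT_LENGTH_MODEL, **(length_model or {})}
    spec = plant_spec if plant_spec is not None else PlantSpec()
    pattern = spec.pattern
    min_run = min(spec.run_lengths)

    n_planted = int(round(spec.fraction_planted * n_transcripts))
    planted_idx = set(rng.choice(n_transcripts, size=n_planted, replace=False).tolist())
    region_names = ("utr5", "cds", "utr3")
    region_p = np.array([spec.region_probs.get(r, 0.0) for r in region_names])
    run_p = (np.asarray(spec.run_length_probs, dtype=float)
             if spec.run_length_probs is not None
             else np.full(len(spec.run_lengths), 1.0 / len(spec.run_lengths)))

    records, truth_hits, planted_ids = [], [], set()
    for i in range(n_transcripts):
        tid = f"t{i + 1:05d}"
        lens = {
            "utr5": int(rng.poisson(lengths["utr5"])),
            "cds": 3 * max(30, int(rng.poisson(lengths["cds"] / 3))),
            "utr3": int(rng.poisson(lengths["utr3"])),
        }
        region_arrays = {
            r: _BASES[rng.integers(4, size=lens[r])].copy() for r in region_names
        }
        planted_here: Dict[str, List[Tuple[int, int]]] = {r: [] for r in region_names}
        if i in planted_idx:
            region = region_names[rng.choice(3, p=region_p)]
            L = int(np.asarray(spec.run_lengths)[rng.choice(len(spec.run_lengths), p=run_p)])
            region_len = lens[region]
            if 3 * L > region_len:
                raise ValidationError(
                    f"{tid}: planted run of {L} triplets does not fit region {region} "
                    f"(length {region_len})"
                )
            if region == "cds":
                frame = 0 if rng.random() < spec.in_frame_probability else int(rng.integers(1, 3))
            else:
                frame = None
            offsets = [
                s for s in range(0, region_len - 3 * L + 1)
                if frame is None or s % 3 == frame
            ]
            start = int(offsets[rng.integers(len(offsets))])
            _plant_run(rng, region_arrays[region], start, L, pattern)
            planted_here[region].append((start, L))
            truth_hits.append(MotifHit(tid, region, start, L,
                                       start % 3 if region == "cds" else None))
            planted_ids.add(tid)

        # cleanup: break chance runs reaching the plant's minimum length
        for r in region_names:
            protected = [(s, s + 3 * L) for s, L in planted_here[r]]
            for _ in range(50):
                runs = scan_runs("".join(region_arrays[r]), pattern, min_run)
                extra = [run for run in runs if run not in planted_here[r]]
                if not extra:
                    break
                for run in extra:
                    if not _break_chance_run(rng, region_arrays[r], run, pattern, protected):
                        raise RuntimeError(f"{tid}: could not isolate planted runs in {r}")
            else:
                raise RuntimeError(f"{tid}: cleanup did not converge in region {r}")

        seq = "".join("".join(region_arrays[r]) for r in region_names)
        u5 = (0, lens["utr5"])
        cds = (u5[1], u5[1] + lens["cds"])
        u3 = (cds[1], cds[1] + lens["utr3"])
        records.append(TranscriptRecord.build(tid, seq, u5, cds, u3))

    truth = SimTruth(seed=seed, planted_target_ids=planted_ids, planted_hits=truth_hits,
                     extras={"pattern": pattern.triplet, "min_run": min_run})
    return records, truth


# ---------------------------------------------------------------------------
# RIP-chip ratio matrices
# ---------------------------------------------------------------------------

def _default_snr_model(rng, size):
    # mostly well above the 1.8 signal/background filter, with a weak tail below
    return rng.lognormal(mean=np.log(6.0), sigma=0.8, size=size)


def simulate_ripchip(n_features: int = 1000, n_ip: int = 3, n_mock: int = 5,
                     target_fraction: float = 0.136, effect_size_delta: float = 2.0,
                     noise_sd: float = 0.5,
                     snr_model: Optional[Callable] = None, seed: int = 0,
                     target_ids: Optional[Sequence[str]] = None,
                     feature_ids: Optional[Sequence[str]] = None):
    """Two-class ratio matrix with planted IP enrichment.

    Non-target log2 ratios are i.i.d. Normal(0, noise_sd) in both
    classes; target features are shifted by ``effect_size_delta`` on the
    IP arrays.  Per-cell signal-over-background values come from
    ``snr_model`` so the >1.8 QC filter removes a controllable fraction.
    """
    if n_ip < 2 or n_mock < 2:
        raise ValidationError("need at least 2 arrays per class")
    if not 0.0 <= target_fraction <= 1.0:
        raise ValidationError("target_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    snr_model = snr_model or _default_snr_model

    if feature_ids is None:
        feature_ids = [f"f{i + 1:05d}" for i in range(n_features)]
    feature_ids = list(feature_ids)
    n_features = len(feature_ids)
    if target_ids is None:
        n_targets = int(round(target_fraction * n_features))
        t_idx = rng.choice(n_features, size=n_targets, replace=False)
        target_ids = {feature_ids[i] for i in t_idx}
    else:
        target_ids = set(target_ids)
    is_target = np.array([f in target_ids for f in feature_ids])

    arrays = [f"ip{i + 1}" for i in range(n_ip)] + [f"mock{i + 1}" for i in range(n_mock)]
    classes = pd.Series(["IP"] * n_ip + ["mock"] * n_mock, index=arrays)
    X = rng.normal(0.0, noise_sd, size=(n_features, n_ip + n_mock))
    X[is_target, :n_ip] += effect_size_delta
    shape = (n_features, n_ip + n_mock)
    snr1 = pd.DataFrame(snr_model(rng, shape), index=feature_ids, columns=arrays)
    snr2 = pd.DataFrame(snr_model(rng, shape), index=feature_ids, columns=arrays)
    regression = pd.DataFrame(rng.uniform(0.0, 0.6, size=shape),
                              index=feature_ids, columns=arrays)
    matrix = RatioMatrix(pd.DataFrame(X, index=feature_ids, columns=arrays),
                         classes, snr1, snr2, regression)
    truth = SimTruth(seed=seed, planted_target_ids=set(target_ids),
                     extras={"effect_size_delta": effect_size_delta, "noise_sd": noise_sd})
    return matrix, truth


# ---------------------------------------------------------------------------
# matched mRNA / protein expression tables
# ---------------------------------------------------------------------------

def simulate_expression(gene_ids: Sequence[str], go_map: Sequence[GeneSet],
                        target_set: GeneSet,
                        planted_shifts: Dict[str, Tuple[float, float]],
                        noise_sd: float = 0.3, protein_coverage: float = 0.27,
                        seed: int = 0, shift_targets_only: bool = True):
    """mRNA/protein log2 tables with GO-linked target-specific shifts.

    ``planted_shifts`` maps GO-term name to (mrna_shift, protein_shift)
    in log2 units, added to genes carrying the term (intersected with
    the target set unless ``shift_targets_only`` is False).  Protein
    values are observed for a ``protein_coverage`` Bernoulli fraction of
    genes; genes given a nonzero protein shift are always observed so
    the planted signal is measurable.
    """
    if not 0.0 < protein_coverage <= 1.0:
        raise ValidationError("protein_coverage must lie in (0, 1]")
    terms = {gs.name: set(gs.members) for gs in go_map}
    unknown = set(planted_shifts) - set(terms)
    if unknown:
        raise ValidationError(f"planted_shifts refer to unknown GO term(s) {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    gene_ids = list(gene_ids)
    n = len(gene_ids)
    targets = set(target_set.members)
    mrna = rng.normal(0.0, noise_sd, size=n)
    protein = rng.normal(0.0, noise_sd, size=n)
    protein_present = rng.random(n) < protein_coverage

    index = {g: i for i, g in enumerate(gene_ids)}
    for term, (m_shift, p_shift) in planted_shifts.items():
        shifted = terms[term] & set(gene_ids)
        if shift_targets_only:
            shifted &= targets
        for g in shifted:
            i = index[g]
            mrna[i] += m_shift
            protein[i] += p_shift
            if p_shift != 0.0:
                protein_present[i] = True

    annotations = [
        {name for name, members in terms.items() if g in members} for g in gene_ids
    ]
    df = pd.DataFrame({
        "gene_id": gene_ids,
        "mrna_log2": mrna,
        "protein_log2": np.where(protein_present, protein, np.nan),
        "is_target": [g in targets for g in gene_ids],
        "annotations": annotations,
    })
    truth = SimTruth(seed=seed, planted_target_ids=targets & set(gene_ids),
                     planted_shifts=dict(planted_shifts),
                     extras={"noise_sd": noise_sd, "protein_coverage": protein_coverage})
    return ExpressionTable(df), truth


# ---------------------------------------------------------------------------
# gene-set collections with exact overlaps
# ---------------------------------------------------------------------------

def simulate_geneset_overlap(universe_size: int, ref_set_size: int,
                             query_sizes: Sequence[int],
                             overlap_fractions: Sequence[float], seed: int = 0):
    """Reference and query sets with exactly realized overlap counts.

    ``overlap_fractions[i] * query_sizes[i]`` is rounded to the planted
    integer overlap.  Returns ``(reference, queries, universe, SimTruth)``.
    """
    if ref_set_size > universe_size:
        raise ValidationError("reference set larger than the universe")
    if len(query_sizes) != len(overlap_fractions):
        raise ValidationError("query_sizes and overlap_fractions differ in length")
    rng = np.random.default_rng(seed)
    ids = np.array([f"g{i + 1:06d}" for i in range(universe_size)])
    ref_ids = set(rng.choice(ids, size=ref_set_size, replace=False).tolist())
    nonref = np.array(sorted(set(ids) - ref_ids))
    ref_arr = np.array(sorted(ref_ids))

    queries, overlaps = [], []
    for qi, (size, frac) in enumerate(zip(query_sizes, overlap_fractions), start=1):
        count = int(round(frac * size))
        if size > universe_size or count > min(size, ref_set_size) \
                or size - count > universe_size - ref_set_size:
            raise ValidationError(
                f"query {qi}: overlap {count} of size {size} infeasible "
                f"(reference {ref_set_size}, universe {universe_size})"
            )
        inside = rng.choice(ref_arr, size=count, replace=False).tolist()
        outside = rng.choice(nonref, size=size - count, replace=False).tolist()
        queries.append(GeneSet(f"query{qi}", f"planted overlap {count}",
                               frozenset(inside + outside)))
        overlaps.append(count)
    reference = GeneSet("reference", "planted reference set", frozenset(ref_ids))
    universe = GeneSet("universe", "simulation universe", frozenset(ids.tolist()))
    truth = SimTruth(seed=seed, planted_target_ids=ref_ids,
                     extras={"overlap_counts": overlaps})
    return reference, queries, universe, truth


def write_sim_truth(truth: SimTruth, path) -> None:
    """Serialize ground truth as a TSV with a structured-text header."""
    lines = [
        f"# seed={truth.seed}",
        f"# n_planted_targets={len(truth.planted_target_ids)}",
    ]
    for key, value in sorted(truth.extras.items()):
        lines.append(f"# {key}={value}")
    for term, (m, p) in sorted(truth.planted_shifts.items()):
        lines.append(f"# shift\t{term}\t{m}\t{p}")
    lines.append("# targets\t" + ",".join(sorted(truth.planted_target_ids)))
    lines.append("transcript_id\tregion\tstart\trun_length\tframe")
    for h in truth.planted_hits:
        frame = "" if h.frame is None else h.frame
        lines.append(f"{h.transcript_id}\t{h.region}\t{h.start}\t{h.run_length}\t{frame}")
    from pathlib import Path
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
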