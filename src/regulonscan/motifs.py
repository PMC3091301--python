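"""Degenerate trinucleotide-repeat scanning and codon-frame analysis.

An RNA-binding protein built from tandem zinc knuckles reads runs of a
short triplet consensus (e.g. GWW with W = A/U, or GAN with N = any
base).  This module finds *maximal runs* of consecutive matching
triplets at every phase offset of a sequence, assigns CDS hits a codon
frame (0 = first codon position), tallies region-by-run-length count
tables, derives motif-bearing gene sets, and ranks candidate triplet
consensi by target enrichment as a motif-discovery stand-in.

Matching rules: sequences are over A,C,G,U,N where sequence N matches no
pattern position; pattern N matches any base except sequence N.  Runs
are maximal within their phase; overlapping runs in different phases are
reported separately.  Regions are scanned independently, so a repeat
spanning a region boundary is split.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .enrichment import hypergeom_tail
from .io_formats import GeneSet, TranscriptRecord, ValidationError

__all__ = [
    "IUPAC_CODES",
    "TripletPattern",
    "MotifHit",
    "scan_runs",
    "scan_transcript",
    "region_count_table",
    "frame_distribution",
    "motif_gene_set",
    "discover_repeat_motifs",
]

IUPAC_CODES = {
    "A": "A", "C": "C", "G": "G", "U": "U",
    "W": "AU", "S": "CG", "R": "AG", "Y": "CU", "K": "GU", "M": "AC",
    "B": "CGU", "D": "AGU", "H": "ACU", "V": "ACG",
    "N": "ACGU",
}

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "U": 3, "N": 4}


@dataclass(frozen=True)
class TripletPattern:
    """A three-letter IUPAC consensus such as GWW, GAN or GSS."""

    triplet: str
    label: str = ""

    def __post_init__(self):
        trip = self.triplet.upper().replace("T", "U")
        if len(trip) != 3 or any(c not in IUPAC_CODES for c in trip):
            raise ValidationError(f"invalid triplet pattern {self.triplet!r}")
        object.__setattr__(self, "triplet", trip)
        if not self.label:
            object.__setattr__(self, "label", trip)

    def position_sets(self) -> List[frozenset]:
        return [frozenset(IUPAC_CODES[c]) for c in self.triplet]

    def degeneracy(self) -> int:
        """Total number of concrete triplets matched (specificity tie-break)."""
        n = 1
        for c in self.triplet:
            n *= len(IUPAC_CODES[c])
        return n

    def lookup_tables(self) -> List[np.ndarray]:
        """Per-position boolean tables over the 5-letter encoded alphabet."""
        tables = []
        for c in self.triplet:
            tab = np.zeros(5, dtype=bool)
            for b in IUPAC_CODES[c]:
                tab[_BASE_INDEX[b]] = True
            # sequence N (index 4) never matches
            tables.append(tab)
        return tables


@dataclass(frozen=True)
class MotifHit:
    """One maximal triplet-repeat run inside a transcript region.

    ``start`` is the 0-based nucleotide offset within the region;
    ``run_length`` the number of consecutive matching triplets; ``frame``
    is ``start mod 3`` for CDS hits (0 = first codon position) and
    ``None`` for UTR hits.
    """

    transcript_id: str
    region: str
    start: int
    run_length: int
    frame: Optional[int]


def encode_sequence(seq: str) -> np.ndarray:
    return np.fromiter((_BASE_INDEX[c] for c in seq), dtype=np.int8, count=len(seq))


def _match_positions(encoded: np.ndarray, pattern: TripletPattern) -> np.ndarray:
    """Boolean array: does a matching triplet start at each position?"""
    if encoded.size < 3:
        return np.zeros(0, dtype=bool)
    t1, t2, t3 = pattern.lookup_tables()
    return t1[encoded[:-2]] & t2[encoded[1:-1]] & t3[encoded[2:]]


def runs_from_matches(match: np.ndarray, min_run: int) -> List[Tuple[int, int]]:
    """Maximal per-phase runs of consecutive triplet matches (start, length)."""
    out = []
    for phase in range(3):
        idx = np.arange(phase, match.size, 3)
        if idx.size == 0:
            continue
        m = match[idx]
        # run boundaries on the phase-sliced boolean vector
        padded = np.concatenate(([False], m, [False]))
        diff = np.diff(padded.astype(np.int8))
        starts = np.flatnonzero(diff == 1)
        ends = np.flatnonzero(diff == -1)
        for s, e in zip(starts, ends):
            length = int(e - s)
            if length >= min_run:
                out.append((int(idx[s]), length))
    out.sort()
    return out


def scan_runs(sequence: str, pattern: TripletPattern, min_run: int) -> List[Tuple[int, int]]:
    """All maximal runs of >= ``min_run`` matching triplets, any phase.

    Returns ``(start, run_length)`` pairs in ascending start order.
    """
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    if not isinstance(pattern, TripletPattern):
        pattern = TripletPattern(str(pattern))
    seq = sequence.upper().replace("T", "U")
    bad = set(seq) - set(_BASE_INDEX)
    if bad:
        raise ValidationError(f"sequence contains illegal characters {sorted(bad)}")
    return runs_from_matches(_match_positions(encode_sequence(seq), pattern), min_run)


def scan_transcript(record: TranscriptRecord, pattern: TripletPattern, min_run: int) -> List[MotifHit]:
    """Scan each region independently; CDS hits get a codon frame."""
    hits = []
    for region in ("utr5", "cds", "utr3"):
        for start, length in scan_runs(record.region_sequence(region), pattern, min_run):
            frame = start % 3 if region == "cds" else None
            hits.append(MotifHit(record.transcript_id, region, start, length, frame))
    return hits


def region_count_table(records, pattern, k_values, target_set: GeneSet, universe: GeneSet):
    """Region x run-length count table with target enrichment.

    For each ``(k, region)``: the number of transcripts carrying at least
    one run of >= k triplets in that region, the number of such maximal
    runs, the intersection with ``target_set``, and a hypergeometric
    upper-tail enrichment p over ``universe``.  One maximal run of
    length L contributes to every row with k <= L.
    """
    import pandas as pd

    if sorted(k_values) != list(k_values):
        raise ValueError("k_values must be sorted ascending")
    if not set(target_set.members) <= set(universe.members):
        raise ValidationError("target set is not contained in the universe")
    min_k = min(k_values)
    per_region_hits = {r: [] for r in ("utr5", "cds", "utr3")}
    for rec in records:
        for hit in scan_transcript(rec, pattern, min_k):
            per_region_hits[hit.region].append(hit)
    rows = []
    for k in k_values:
        for region in ("cds", "utr3", "utr5"):
            hits = [h for h in per_region_hits[region] if h.run_length >= k]
            transcripts = {h.transcript_id for h in hits}
            in_targets = transcripts & set(target_set.members)
            p = hypergeom_tail(
                len(in_targets), len(target_set), len(transcripts), len(universe)
            ) if transcripts else 1.0
            rows.append({
                "pattern": pattern.label if isinstance(pattern, TripletPattern) else str(pattern),
                "k": k,
                "region": region,
                "n_transcripts_with_motif": len(transcripts),
                "n_motif_occurrences": len(hits),
                "n_in_target_set": len(in_targets),
                "enrichment_p": p,
            })
    return pd.DataFrame(rows)


def frame_distribution(hits: Iterable[MotifHit]):
    """Frame -> (count, integer percent) over CDS hits.

    Percentages use half-away-from-zero integer rounding; with no hits
    the counts are zero and percentages ``None``.
    """
    from .regulon import percent_value

    hits = list(hits)
    if any(h.region != "cds" for h in hits):
        raise ValueError("frame_distribution expects CDS hits only")
    counts = {f: 0 for f in (0, 1, 2)}
    for h in hits:
        counts[h.frame] += 1
    total = sum(counts.values())
    return {
        f: (c, percent_value(c, total, 0) if total else None)
        for f, c in counts.items()
    }


def motif_gene_set(records, pattern, k: int, region: str = "any",
                   name: str = None) -> Optional[GeneSet]:
    """Transcripts with >= 1 run of >= k triplets in ``region`` (or any).

    Returns ``None`` when no transcript qualifies (a GeneSet cannot be
    empty).  Applied to another species' transcript set this is the
    cross-species target-prediction step.
    """
    if region not in ("utr5", "cds", "utr3", "any"):
        raise ValueError(f"unknown region {region!r}")
    members = set()
    for rec in records:
        for hit in scan_transcript(rec, pattern, k):
            if region == "any" or hit.region == region:
                members.add(rec.transcript_id)
                break
    if not members:
        return None
    label = pattern.label if isinstance(pattern, TripletPattern) else str(pattern)
    return GeneSet(name or f"({label}){k}_{region}", f"transcripts with ({label})>={k} in {region}", members)


# ---------------------------------------------------------------------------
# motif discovery stand-in
# ---------------------------------------------------------------------------

def _concatenate(records) -> Tuple[np.ndarray, np.ndarray, List[str]]:
    """Concatenate full sequences with NNN separators (match nothing)."""
    parts, bounds, ids = [], [0], []
    sep = np.full(3, _BASE_INDEX["N"], dtype=np.int8)
    for rec in records:
        enc = encode_sequence(rec.sequence)
        parts.extend([enc, sep])
        bounds.append(bounds[-1] + enc.size + 3)
        ids.append(rec.transcript_id)
    if not parts:
        return np.zeros(0, dtype=np.int8), np.array(bounds), ids
    return np.concatenate(parts), np.array(bounds), ids


def _bearing_transcripts(concat, bounds, ids, pattern, min_run) -> set:
    match = _match_positions(concat, pattern)
    bearing = set()
    for start, _length in runs_from_matches(match, min_run):
        i = int(np.searchsorted(bounds, start, side="right")) - 1
        bearing.add(ids[i])
    return bearing


def candidate_patterns(alphabet: Sequence[Sequence[str]] = None) -> List[TripletPattern]:
    default = tuple("ACGUWSRYN")
    alphabet = alphabet or (default, default, default)
    out = []
    for a in alphabet[0]:
        for b in alphabet[1]:
            for c in alphabet[2]:
                if (a, b, c) == ("N", "N", "N"):
                    continue
                out.append(TripletPattern(a + b + c))
    return out


def discover_repeat_motifs(target_records, background_records, min_run: int,
                           candidate_alphabet=None) -> List[Tuple[TripletPattern, float]]:
    """Rank candidate triplet consensi by target enrichment.

    Every triplet over the supplied per-position IUPAC codes (default
    {A,C,G,U,W,S,R,Y,N}^3 minus NNN) is scored by the hypergeometric
    enrichment of motif-bearing transcripts among targets versus the
    background transcript set (which must contain the targets); ranked
    ascending by p, ties broken by specificity (fewer concrete triplets
    matched) then lexicographically.
    """
    targets = list(target_records)
    background = list(background_records)
    if not targets:
        raise ValidationError("empty target set")
    target_ids = {r.transcript_id for r in targets}
    bg_ids = {r.transcript_id for r in background}
    if not target_ids <= bg_ids:
        raise ValidationError("target transcripts must be part of the background set")
    concat, bounds, ids = _concatenate(background)
    n_universe = len(bg_ids)
    scored = []
    for pat in candidate_patterns(candidate_alphabet):
        bearing = _bearing_transcripts(concat, bounds, ids, pat, min_run)
        k = len(bearing & target_ids)
        p = hypergeom_tail(k, len(target_ids), len(bearing), n_universe) if bearing else 1.0
        scored.append((pat, p))
    scored.sort(key=lambda t: (t[1], t[0].degeneracy(), t[0].triplet))
    return scored
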