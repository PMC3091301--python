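"""Readers and writers for every external representation the pipeline touches.

Formats
-------
* FASTA for transcript sequences (Biopython), always paired with a
  tab-delimited *region table* giving 0-based half-open 5'UTR/CDS/3'UTR
  spans on the spliced transcript.
* GMT for gene sets (``name<TAB>description<TAB>member...``).
* Tab-delimited tables for two-color ratio matrices (plus a design file
  mapping array id to class) and for matched mRNA/protein expression
  tables.

Every table written by this module starts with a ``# n_records=N`` line
and must end with a newline; readers verify both so that a file truncated
at an arbitrary byte is rejected rather than silently half-loaded.
Coordinates are transcript-local, 0-based, half-open.  ``T`` and ``U``
are interchangeable on input; the canonical internal alphabet is
``A, C, G, U, N`` (sense strand only).
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "ValidationError",
    "TranscriptRecord",
    "GeneSet",
    "RatioMatrix",
    "ExpressionTable",
    "read_transcripts",
    "write_transcripts",
    "read_gene_sets",
    "write_gene_sets",
    "read_ratio_matrix",
    "write_ratio_matrix",
    "read_expression_table",
    "write_expression_table",
]

_ALPHABET = set("ACGUN")
_COUNT_PREFIX = "# n_records="
_REGION_COLUMNS = [
    "transcript_id",
    "utr5_start", "utr5_end",
    "cds_start", "cds_end",
    "utr3_start", "utr3_end",
]


class ValidationError(ValueError):
    """Raised when an input file or record violates a format invariant."""


# ---------------------------------------------------------------------------
# counted TSV helpers (truncation-safe round trips)
# ---------------------------------------------------------------------------

def _write_counted_tsv(df: pd.DataFrame, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"{_COUNT_PREFIX}{len(df)}\n")
        df.to_csv(fh, sep="\t", index=False, na_rep="")


def _read_counted_tsv(path, **read_csv_kwargs) -> pd.DataFrame:
    path = Path(path)
    raw = path.read_text(encoding="utf-8")
    if not raw:
        raise ValidationError(f"{path}: empty file")
    first, _, rest = raw.partition("\n")
    if not first.startswith(_COUNT_PREFIX):
        raise ValidationError(f"{path}: missing '{_COUNT_PREFIX}' header line")
    try:
        declared = int(first[len(_COUNT_PREFIX):])
    except ValueError as exc:
        raise ValidationError(f"{path}: malformed record-count header") from exc
    if not rest.endswith("\n"):
        raise ValidationError(f"{path}: file does not end with a newline (truncated?)")
    df = pd.read_csv(io.StringIO(rest), sep="\t", **read_csv_kwargs)
    if len(df) != declared:
        raise ValidationError(
            f"{path}: header declares {declared} records but {len(df)} were read (truncated?)"
        )
    return df


def normalize_sequence(seq: str, *, context: str = "sequence") -> str:
    """Uppercase, map T to U, and validate against the canonical alphabet."""
    canon = seq.upper().replace("T", "U")
    bad = set(canon) - _ALPHABET
    if bad:
        raise ValidationError(f"{context}: illegal characters {sorted(bad)}")
    return canon


# ---------------------------------------------------------------------------
# transcripts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TranscriptRecord:
    """One spliced transcript with 5'UTR / CDS / 3'UTR spans.

    Spans are 0-based half-open intervals on the transcript; they are
    ordered, disjoint and jointly cover ``[0, len(sequence))``.  UTRs may
    be empty.  ``cds_not_triplet`` flags a CDS whose length is zero or
    not a multiple of three (frame analysis is then unavailable).
    """

    transcript_id: str
    sequence: str
    utr5_span: tuple
    cds_span: tuple
    utr3_span: tuple
    cds_not_triplet: bool = field(default=False, compare=False)

    @staticmethod
    def build(transcript_id, sequence, utr5_span, cds_span, utr3_span) -> "TranscriptRecord":
        seq = normalize_sequence(sequence, context=transcript_id)
        spans = {"utr5": tuple(map(int, utr5_span)),
                 "cds": tuple(map(int, cds_span)),
                 "utr3": tuple(map(int, utr3_span))}
        for name, (a, b) in spans.items():
            if a < 0 or b < a or b > len(seq):
                raise ValidationError(
                    f"{transcript_id}: {name} span {(a, b)} out of range for length {len(seq)}"
                )
        u5, cds, u3 = spans["utr5"], spans["cds"], spans["utr3"]
        if not (u5[0] == 0 and u5[1] == cds[0] and cds[1] == u3[0] and u3[1] == len(seq)):
            raise ValidationError(
                f"{transcript_id}: spans must be contiguous utr5<cds<utr3 covering the transcript; "
                f"got utr5={u5}, cds={cds}, utr3={u3}, length={len(seq)}"
            )
        cds_len = cds[1] - cds[0]
        flag = cds_len == 0 or cds_len % 3 != 0
        if flag:
            warnings.warn(
                f"{transcript_id}: CDS length {cds_len} is not a positive multiple of 3; "
                "frame analysis unavailable",
                stacklevel=2,
            )
        return TranscriptRecord(transcript_id, seq, u5, cds, u3, flag)

    def region_span(self, region: str) -> tuple:
        return {"utr5": self.utr5_span, "cds": self.cds_span, "utr3": self.utr3_span}[region]

    def region_sequence(self, region: str) -> str:
        a, b = self.region_span(region)
        return self.sequence[a:b]


def read_transcripts(fasta_path, regions_path) -> list:
    """Load transcripts from a FASTA file plus its region table.

    Region-table ids absent from the FASTA are an error (the record
    cannot be validated); FASTA ids absent from the table are reported
    with a warning and skipped.
    """
    regions = _read_counted_tsv(regions_path, dtype={"transcript_id": str})
    missing_cols = [c for c in _REGION_COLUMNS if c not in regions.columns]
    if missing_cols:
        raise ValidationError(f"{regions_path}: missing columns {missing_cols}")
    if regions.empty:
        raise ValidationError(f"{regions_path}: no region rows")
    if regions["transcript_id"].duplicated().any():
        dup = regions.loc[regions["transcript_id"].duplicated(), "transcript_id"].iloc[0]
        raise ValidationError(f"{regions_path}: duplicate transcript_id {dup!r}")

    raw_fasta = Path(fasta_path).read_text(encoding="utf-8")
    if not raw_fasta:
        raise ValidationError(f"{fasta_path}: empty file")
    if not raw_fasta.endswith("\n"):
        raise ValidationError(f"{fasta_path}: file does not end with a newline (truncated?)")
    seqs = {}
    for rec in SeqIO.parse(io.StringIO(raw_fasta), "fasta"):
        seqs[rec.id] = str(rec.seq)
    if not seqs:
        raise ValidationError(f"{fasta_path}: no FASTA records")

    records = []
    for row in regions.itertuples(index=False):
        tid = row.transcript_id
        if tid not in seqs:
            raise ValidationError(f"{tid}: present in region table but missing from FASTA")
        records.append(TranscriptRecord.build(
            tid, seqs[tid],
            (row.utr5_start, row.utr5_end),
            (row.cds_start, row.cds_end),
            (row.utr3_start, row.utr3_end),
        ))
    extra = set(seqs) - set(regions["transcript_id"])
    if extra:
        warnings.warn(
            f"{len(extra)} FASTA record(s) without region annotation were skipped "
            f"(e.g. {sorted(extra)[:3]})",
            stacklevel=2,
        )
    return records


def write_transcripts(records, fasta_path, regions_path) -> None:
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.transcript_id, description="") for r in records
    ]
    with open(fasta_path, "w", encoding="utf-8", newline="\n") as fh:
        SeqIO.write(seq_records, fh, "fasta")
    rows = [
        {
            "transcript_id": r.transcript_id,
            "utr5_start": r.utr5_span[0], "utr5_end": r.utr5_span[1],
            "cds_start": r.cds_span[0], "cds_end": r.cds_span[1],
            "utr3_start": r.utr3_span[0], "utr3_end": r.utr3_span[1],
        }
        for r in records
    ]
    _write_counted_tsv(pd.DataFrame(rows, columns=_REGION_COLUMNS), regions_path)


# ---------------------------------------------------------------------------
# gene sets (GMT)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneSet:
    """A named set of gene / transcript identifiers."""

    name: str
    description: str
    members: frozenset

    def __post_init__(self):
        if not self.name:
            raise ValidationError("GeneSet name must be non-empty")
        object.__setattr__(self, "members", frozenset(self.members))
        if not self.members:
            raise ValidationError(f"GeneSet {self.name!r} has no members")

    def __len__(self):
        return len(self.members)

    def __contains__(self, item):
        return item in self.members


_GMT_PREFIX = "#gmt n_sets="


def read_gene_sets(gmt_path) -> list:
    """Parse a GMT file; duplicates within a set collapse with a warning.

    Files written by :func:`write_gene_sets` carry a ``#gmt n_sets=``
    header that is verified (truncation safety); plain external GMT files
    without the header are accepted as-is.
    """
    path = Path(gmt_path)
    raw = path.read_text(encoding="utf-8")
    if not raw.strip():
        raise ValidationError(f"{path}: empty file")
    declared = None
    body = raw
    if raw.startswith(_GMT_PREFIX):
        first, _, body = raw.partition("\n")
        try:
            declared = int(first[len(_GMT_PREFIX):])
        except ValueError as exc:
            raise ValidationError(f"{path}: malformed GMT count header") from exc
        if not body.endswith("\n"):
            raise ValidationError(f"{path}: file does not end with a newline (truncated?)")

    sets = []
    for lineno, line in enumerate(body.splitlines(), start=2 if declared is not None else 1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3 or not all(fields):
            raise ValidationError(f"{path}:{lineno}: malformed GMT line (need name, description, members)")
        name, description, members = fields[0], fields[1], fields[2:]
        if len(set(members)) < len(members):
            warnings.warn(f"{path}:{lineno}: duplicate members in set {name!r} collapsed", stacklevel=2)
        sets.append(GeneSet(name, description, frozenset(members)))
    if declared is not None and len(sets) != declared:
        raise ValidationError(
            f"{path}: header declares {declared} sets but {len(sets)} were read (truncated?)"
        )
    return sets


def write_gene_sets(gene_sets, gmt_path) -> None:
    lines = [f"{_GMT_PREFIX}{len(gene_sets)}"]
    for gs in gene_sets:
        lines.append("\t".join([gs.name, gs.description or ".", *sorted(gs.members)]))
    Path(gmt_path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# ratio matrices
# ---------------------------------------------------------------------------

@dataclass
class RatioMatrix:
    """Features x arrays log2 ratios with per-cell QC and a two-class design.

    ``log2`` is a features-by-arrays DataFrame (NaN = missing spot, never
    imputed).  ``classes`` maps array id to its class label (exactly two
    distinct labels, e.g. IP vs mock).  QC frames are aligned to ``log2``:
    ``snr1``/``snr2`` are per-channel signal-over-background values
    (channel 1 = total-RNA input channel) and ``regression`` the per-spot
    regression correlation.
    """

    log2: pd.DataFrame
    classes: pd.Series
    snr1: pd.DataFrame = None
    snr2: pd.DataFrame = None
    regression: pd.DataFrame = None

    def __post_init__(self):
        self.classes = pd.Series(self.classes)
        if list(self.classes.index) != list(self.log2.columns):
            raise ValidationError("design arrays do not match ratio-matrix columns")
        labels = sorted(set(self.classes))
        if len(labels) != 2:
            raise ValidationError(f"need exactly two classes, got {labels}")
        for lab in labels:
            if (self.classes == lab).sum() < 2:
                warnings.warn(f"class {lab!r} has fewer than 2 arrays; SAM will refuse", stacklevel=2)
        for qc in (self.snr1, self.snr2, self.regression):
            if qc is not None and (list(qc.index) != list(self.log2.index)
                                   or list(qc.columns) != list(self.log2.columns)):
                raise ValidationError("QC frame not aligned with ratio matrix")

    @property
    def feature_ids(self):
        return list(self.log2.index)

    @property
    def array_ids(self):
        return list(self.log2.columns)

    @property
    def class_labels(self):
        return sorted(set(self.classes))

    def copy(self) -> "RatioMatrix":
        return RatioMatrix(
            self.log2.copy(), self.classes.copy(),
            None if self.snr1 is None else self.snr1.copy(),
            None if self.snr2 is None else self.snr2.copy(),
            None if self.regression is None else self.regression.copy(),
        )


def read_ratio_matrix(tsv_path, design_path, allowed_classes=None) -> RatioMatrix:
    """Read a ratio matrix and its design file.

    The data TSV has a ``feature_id`` column, one ratio column per array
    and optional QC columns named ``<array>:snr1``, ``<array>:snr2`` and
    ``<array>:rc``.  Missing cells stay missing.
    """
    design = _read_counted_tsv(design_path, dtype=str)
    if not {"array_id", "class"} <= set(design.columns):
        raise ValidationError(f"{design_path}: need columns array_id, class")
    classes = pd.Series(design["class"].values, index=design["array_id"].values)
    if allowed_classes is not None:
        unknown = set(classes) - set(allowed_classes)
        if unknown:
            raise ValidationError(f"{design_path}: unknown class token(s) {sorted(unknown)}")

    df = _read_counted_tsv(tsv_path, dtype={"feature_id": str})
    if "feature_id" not in df.columns:
        raise ValidationError(f"{tsv_path}: missing feature_id column")
    df = df.set_index("feature_id")
    df.index.name = None
    ratio_cols = [c for c in df.columns if ":" not in c]
    undesigned = set(ratio_cols) - set(classes.index)
    if undesigned:
        raise ValidationError(f"{tsv_path}: arrays {sorted(undesigned)} absent from design file")
    missing_arrays = set(classes.index) - set(ratio_cols)
    if missing_arrays:
        raise ValidationError(f"{design_path}: arrays {sorted(missing_arrays)} absent from data file")
    arrays = [a for a in classes.index if a in ratio_cols]
    log2 = df[arrays].astype(float)

    def _qc(suffix):
        cols = {a: f"{a}:{suffix}" for a in arrays}
        if all(c in df.columns for c in cols.values()):
            out = df[[cols[a] for a in arrays]].astype(float)
            out.columns = arrays
            return out
        return None

    return RatioMatrix(log2, classes.loc[arrays], _qc("snr1"), _qc("snr2"), _qc("rc"))


def write_ratio_matrix(matrix: RatioMatrix, tsv_path, design_path) -> None:
    out = matrix.log2.copy()
    for suffix, qc in (("snr1", matrix.snr1), ("snr2", matrix.snr2), ("rc", matrix.regression)):
        if qc is not None:
            for a in matrix.array_ids:
                out[f"{a}:{suffix}"] = qc[a]
    out = out.reset_index().rename(columns={"index": "feature_id"})
    out.columns = ["feature_id", *out.columns[1:]]
    _write_counted_tsv(out, tsv_path)
    design = pd.DataFrame({"array_id": matrix.array_ids,
                           "class": [matrix.classes[a] for a in matrix.array_ids]})
    _write_counted_tsv(design, design_path)


# ---------------------------------------------------------------------------
# expression tables
# ---------------------------------------------------------------------------

@dataclass
class ExpressionTable:
    """Per-gene mRNA / protein log2 ratios with target flag and GO annotations.

    Backed by a DataFrame with columns ``gene_id``, ``mrna_log2``,
    ``protein_log2``, ``is_target`` and ``annotations`` (a set of GO term
    ids per row).  Every row carries at least one of the two log2 values.
    """

    data: pd.DataFrame

    def __post_init__(self):
        df = self.data
        needed = {"gene_id", "mrna_log2", "protein_log2", "is_target", "annotations"}
        if not needed <= set(df.columns):
            raise ValidationError(f"expression table needs columns {sorted(needed)}")
        if df["gene_id"].duplicated().any():
            raise ValidationError("duplicate gene_id in expression table")
        both_missing = df["mrna_log2"].isna() & df["protein_log2"].isna()
        if both_missing.any():
            raise ValidationError(
                f"{int(both_missing.sum())} gene(s) have neither mRNA nor protein value"
            )
        self.data = df.reset_index(drop=True)

    @property
    def gene_ids(self):
        return list(self.data["gene_id"])

    def values(self, column: str) -> pd.Series:
        """Non-missing log2 values for ``column`` in {'mrna','protein'}, indexed by gene."""
        col = {"mrna": "mrna_log2", "protein": "protein_log2"}[column]
        s = pd.Series(self.data[col].values, index=self.data["gene_id"].values)
        return s.dropna()

    def genes_with_term(self, term: str) -> set:
        mask = self.data["annotations"].map(lambda anns: term in anns)
        return set(self.data.loc[mask, "gene_id"])

    def target_ids(self) -> set:
        return set(self.data.loc[self.data["is_target"], "gene_id"])


def write_expression_table(table: ExpressionTable, path) -> None:
    df = table.data.copy()
    df["annotations"] = df["annotations"].map(lambda s: ";".join(sorted(s)))
    df["is_target"] = df["is_target"].map(int)
    _write_counted_tsv(df, path)


def read_expression_table(path) -> ExpressionTable:
    df = _read_counted_tsv(path, dtype={"gene_id": str})
    df["annotations"] = df["annotations"].fillna("").map(
        lambda s: set(filter(None, str(s).split(";")))
    )
    df["is_target"] = df["is_target"].astype(int).astype(bool)
    df["mrna_log2"] = pd.to_numeric(df["mrna_log2"], errors="coerce")
    df["protein_log2"] = pd.to_numeric(df["protein_log2"], errors="coerce")
    return ExpressionTable(df)
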