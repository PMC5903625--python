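"""Aligned-nucleotide quantification of ORF expression.

Expression of a gene is measured as the total number of nucleotides of mRNA
reads aligned within the gene's interval, and normalized per sample by the
total number of nucleotides mapped to any ORF of that sample. A read that
overlaps two ORFs contributes its overlap to each; only aligned
(match/mismatch) bases count — insertions, clips and skips contribute
nothing. Strand is ignored (unstranded double-stranded cDNA protocol).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import pysam

from .orfs import OrfCatalog

__all__ = [
    "AlignmentRecord",
    "ExpressionMatrix",
    "ZeroSampleError",
    "count_aligned_nucleotides",
    "normalize_per_sample",
    "aggregate_by",
    "read_sam",
    "read_alignment_tsv",
    "write_alignment_tsv",
]

logger = logging.getLogger(__name__)


class ZeroSampleError(ValueError):
    """A sample with no ORF-mapped nucleotides cannot be normalized."""


@dataclass(frozen=True)
class AlignmentRecord:
    """One read alignment, reduced to its aligned blocks on the contig.

    ``aligned_blocks`` are non-overlapping, sorted, 0-based half-open
    intervals of reference positions covered by match/mismatch operations.
    """

    read_id: str
    contig_id: str
    start: int
    aligned_blocks: tuple[tuple[int, int], ...]
    sample_id: str

    @property
    def aligned_length(self) -> int:
        return sum(e - s for s, e in self.aligned_blocks)


@dataclass
class ExpressionMatrix:
    """ORF × sample expression values.

    ``mode`` is ``"raw"`` (integer aligned-nucleotide counts) or
    ``"normalized"`` (per-sample fractions summing to 1). ``unassigned``
    records nucleotides aligned to contigs absent from the catalog,
    per sample.
    """

    values: pd.DataFrame
    mode: str = "raw"
    unassigned: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in ("raw", "normalized"):
            raise ValueError(f"unknown mode {self.mode!r}")

    @property
    def orf_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="orf_id")

    @classmethod
    def from_tsv(cls, path, mode: str = "raw") -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col="orf_id")
        return cls(values=df, mode=mode)


# --------------------------------------------------------------------- I/O


def read_sam(path, sample_id: Optional[str] = None) -> list[AlignmentRecord]:
    """Read alignments from a SAM file (one file per sample).

    Aligned blocks are derived from the CIGAR string via pysam's
    ``get_blocks`` — reference positions covered by M/=/X operations, so
    insertions, soft/hard clips and reference skips are excluded.
    """
    path = Path(path)
    if sample_id is None:
        sample_id = path.stem
    records = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped:
                continue
            blocks = tuple((int(s), int(e)) for s, e in aln.get_blocks())
            if not blocks:
                continue
            records.append(
                AlignmentRecord(
                    read_id=aln.query_name,
                    contig_id=aln.reference_name,
                    start=int(aln.reference_start),
                    aligned_blocks=blocks,
                    sample_id=sample_id,
                )
            )
    return records


_TSV_COLUMNS = ["read_id", "contig_id", "start0", "aligned_length", "sample_id"]


def read_alignment_tsv(path) -> list[AlignmentRecord]:
    """Read the simplified single-block alignment dialect.

    Columns: read_id, contig_id, start0 (0-based), aligned_length, sample_id.
    """
    df = pd.read_csv(path, sep="\t")
    missing = set(_TSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"alignment TSV missing columns: {sorted(missing)}")
    return [
        AlignmentRecord(
            read_id=str(r.read_id),
            contig_id=str(r.contig_id),
            start=int(r.start0),
            aligned_blocks=((int(r.start0), int(r.start0) + int(r.aligned_length)),),
            sample_id=str(r.sample_id),
        )
        for r in df.itertuples(index=False)
    ]


def write_alignment_tsv(records: Iterable[AlignmentRecord], path) -> None:
    """Write single-block records in the simplified TSV dialect."""
    rows = []
    for r in records:
        if len(r.aligned_blocks) != 1:
            raise ValueError("TSV dialect supports single-block alignments only")
        (s, e), = r.aligned_blocks
        rows.append((r.read_id, r.contig_id, s, e - s, r.sample_id))
    pd.DataFrame(rows, columns=_TSV_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------- counting


def count_aligned_nucleotides(
    alignments: Iterable[AlignmentRecord],
    catalog: OrfCatalog,
    samples: Optional[Sequence[str]] = None,
) -> ExpressionMatrix:
    """Enumerate the total nucleotides aligned within each ORF, per sample.

    Each aligned block contributes its base-level overlap with every ORF it
    intersects (a read spanning two ORFs counts toward both). Alignments to
    contigs not present in the catalog are tallied into a per-sample
    "unassigned" bucket and logged, never raised.

    Parameters
    ----------
    samples:
        Optional explicit sample order; samples seen in the alignments are
        appended if absent. Allows an all-zero full-shape matrix when no
        alignments are supplied.
    """
    sample_order: list[str] = list(samples) if samples is not None else []
    sample_index = {s: i for i, s in enumerate(sample_order)}
    # per-contig coordinate arrays for vectorized overlap
    contig_arrays: dict[str, tuple[np.ndarray, np.ndarray, list[int]]] = {}
    orf_index = {oid: i for i, oid in enumerate(catalog.orf_ids)}
    for contig in catalog.contig_ids:
        orfs = catalog.on_contig(contig)
        contig_arrays[contig] = (
            np.array([o.start for o in orfs], dtype=np.int64),
            np.array([o.end for o in orfs], dtype=np.int64),
            [orf_index[o.orf_id] for o in orfs],
        )

    triplets: list[tuple[int, int, int]] = []  # (orf_row, sample_col, bases)
    unassigned: dict[str, int] = {}
    n_records = 0
    for rec in alignments:
        n_records += 1
        if rec.sample_id not in sample_index:
            sample_index[rec.sample_id] = len(sample_order)
            sample_order.append(rec.sample_id)
        col = sample_index[rec.sample_id]
        arrays = contig_arrays.get(rec.contig_id)
        if arrays is None:
            unassigned[rec.sample_id] = unassigned.get(rec.sample_id, 0) + rec.aligned_length
            continue
        starts, ends, rows = arrays
        for bs, be in rec.aligned_blocks:
            overlap = np.minimum(ends, be) - np.maximum(starts, bs)
            for j in np.nonzero(overlap > 0)[0]:
                triplets.append((rows[j], col, int(overlap[j])))

    mat = np.zeros((len(catalog), len(sample_order)), dtype=np.int64)
    for r, c, v in triplets:
        mat[r, c] += v
    if unassigned:
        logger.warning(
            "alignments to %d unknown contig(s); unassigned nucleotides per sample: %s",
            len(unassigned),
            unassigned,
        )
    logger.info("counted %d alignment records into %d ORFs × %d samples",
                n_records, len(catalog), len(sample_order))
    values = pd.DataFrame(mat, index=pd.Index(catalog.orf_ids, name="orf_id"),
                          columns=sample_order)
    return ExpressionMatrix(values=values, mode="raw", unassigned=unassigned)


def normalize_per_sample(
    raw: ExpressionMatrix,
    catalog: Optional[OrfCatalog] = None,
    per_kilobase: bool = False,
) -> ExpressionMatrix:
    """Scale each gene by the total nucleotides mapped to ORFs of its sample.

    Every column of the result sums to 1. ``per_kilobase=True`` additionally
    divides each ORF by its length in kb before the per-sample scaling
    (off by default: the stated rule normalizes by sample total only, so
    longer genes legitimately carry more weight).
    """
    if raw.mode != "raw":
        raise ValueError("normalize_per_sample expects a raw-mode matrix")
    values = raw.values.astype(float)
    if per_kilobase:
        if catalog is None:
            raise ValueError("per_kilobase normalization requires the ORF catalog")
        lengths_kb = catalog.lengths().reindex(values.index) / 1000.0
        values = values.div(lengths_kb, axis=0)
    totals = values.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero) > 0:
        raise ZeroSampleError(
            f"sample(s) with no ORF-mapped nucleotides: {sorted(zero.index)}"
        )
    return ExpressionMatrix(values=values / totals, mode="normalized")


def aggregate_by(
    norm: ExpressionMatrix,
    grouping: Mapping[str, str],
    unassigned_label: str = "unassigned",
) -> pd.DataFrame:
    """Sum normalized ORF rows into group rows (KO, family, category …).

    ORFs absent from ``grouping`` are pooled under ``unassigned_label``;
    column sums are preserved exactly.
    """
    if norm.mode != "normalized":
        raise ValueError("aggregate_by expects a normalized matrix")
    labels = pd.Series(
        [grouping.get(oid, unassigned_label) for oid in norm.values.index],
        index=norm.values.index,
    )
    out = norm.values.groupby(labels).sum()
    out.index.name = "group"
    return out
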