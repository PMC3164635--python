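"""Sequence and annotation I/O plus interval algebra.

Genomes are held as :class:`Contig` records over the 5-letter alphabet
``{A, C, G, T, N}``.  Annotation features (genes, exons, CDS, repeats) are
reduced to :class:`Interval` sets, and :func:`partition_from_gff` derives the
feature-class partition (coding, non-coding, exon, intron, multigene, repeat)
that the RIP scanner summarizes class by class.

All internal coordinates are 0-based half-open.  GFF3 (1-based closed) is
converted at the boundary; BED passes through unshifted.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Contig",
    "Interval",
    "FeaturePartition",
    "read_fasta",
    "write_fasta",
    "read_bed",
    "read_id_list",
    "merge_intervals",
    "complement_intervals",
    "intersect_intervals",
    "subtract_intervals",
    "total_length",
    "extract_sequence",
    "partition_from_gff",
    "FEATURE_CLASSES",
]

VALID_RESIDUES = frozenset("ACGTN")

#: Feature classes recognized by the RIP per-class summary.
FEATURE_CLASSES = (
    "whole_genome",
    "coding",
    "noncoding",
    "exon",
    "intron",
    "multigene",
    "repeat",
)


@dataclass(frozen=True)
class Contig:
    """A genome sequence with a unique identifier.

    Residues are uppercase and restricted to ``A/C/G/T/N``.
    """

    id: str
    residues: str

    def __post_init__(self) -> None:
        bad = set(self.residues) - VALID_RESIDUES
        if bad:
            raise ValueError(
                f"contig {self.id!r}: invalid residues {sorted(bad)!r}; "
                "only A/C/G/T/N are accepted"
            )

    @property
    def length(self) -> int:
        return len(self.residues)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True, order=True)
class Interval:
    """A half-open genomic interval ``[start, end)`` on a contig."""

    contig_id: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.contig_id!r}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class FeaturePartition:
    """Class-labeled interval sets over a genome.

    ``class_intervals`` maps each label in :data:`FEATURE_CLASSES` to a
    merged, sorted interval list.  Absent classes map to empty lists.
    """

    class_intervals: dict[str, list[Interval]] = field(default_factory=dict)

    def intervals(self, label: str) -> list[Interval]:
        return self.class_intervals.get(label, [])


# ---------------------------------------------------------------------------
# FASTA / BED / id-list I/O
# ---------------------------------------------------------------------------

def read_fasta(path: str | os.PathLike) -> list[Contig]:
    """Read a FASTA file into :class:`Contig` records.

    Lowercase (masked) residues are uppercased.  Characters outside
    ``{A,C,G,T,N,a,c,g,t,n}`` and duplicate record ids raise ``ValueError``.
    """
    contigs: list[Contig] = []
    seen: set[str] = set()
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in seen:
            raise ValueError(f"duplicate FASTA record id {record.id!r} in {path}")
        seen.add(record.id)
        contigs.append(Contig(id=record.id, residues=str(record.seq).upper()))
    if not contigs:
        raise ValueError(f"no FASTA records found in {path}")
    return contigs


def write_fasta(contigs: Iterable[Contig], path: str | os.PathLike, width: int = 70) -> None:
    records = [SeqRecord(Seq(c.residues), id=c.id, description="") for c in contigs]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(records)


def read_bed(path: str | os.PathLike) -> list[Interval]:
    """Read 3+ column BED (0-based half-open, as stored) into intervals."""
    intervals: list[Interval] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: BED line has fewer than 3 columns")
            contig_id, start, end = parts[0], int(parts[1]), int(parts[2])
            strand = parts[5] if len(parts) >= 6 and parts[5] in "+-" else "."
            intervals.append(Interval(contig_id, start, end, strand))
    return intervals


def read_id_list(path: str | os.PathLike) -> list[str]:
    """Read a plain-text id list, one id per line; blank lines ignored."""
    with open(path) as handle:
        return [line.strip() for line in handle if line.strip()]


# ---------------------------------------------------------------------------
# Interval algebra (all per-contig aware, strand ignored)
# ---------------------------------------------------------------------------

def merge_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    """Merge overlapping or touching intervals; output sorted and disjoint."""
    by_contig: dict[str, list[Interval]] = {}
    for iv in intervals:
        by_contig.setdefault(iv.contig_id, []).append(iv)
    merged: list[Interval] = []
    for contig_id in sorted(by_contig):
        ivs = sorted(by_contig[contig_id], key=lambda iv: (iv.start, iv.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_end:
                cur_end = max(cur_end, iv.end)
            else:
                merged.append(Interval(contig_id, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        merged.append(Interval(contig_id, cur_start, cur_end))
    return merged


def complement_intervals(
    intervals: Iterable[Interval], contig_lengths: Mapping[str, int]
) -> list[Interval]:
    """Complement of an interval set within the given contigs.

    Contigs listed in ``contig_lengths`` but absent from ``intervals`` are
    returned whole.  Intervals beyond a contig's length raise ``ValueError``.
    """
    merged = merge_intervals(intervals)
    by_contig: dict[str, list[Interval]] = {}
    for iv in merged:
        if iv.contig_id not in contig_lengths:
            raise ValueError(f"unknown contig id {iv.contig_id!r}")
        if iv.end > contig_lengths[iv.contig_id]:
            raise ValueError(
                f"interval [{iv.start}, {iv.end}) exceeds length "
                f"{contig_lengths[iv.contig_id]} of contig {iv.contig_id!r}"
            )
        by_contig.setdefault(iv.contig_id, []).append(iv)
    out: list[Interval] = []
    for contig_id in sorted(contig_lengths):
        length = contig_lengths[contig_id]
        pos = 0
        for iv in by_contig.get(contig_id, []):
            if iv.start > pos:
                out.append(Interval(contig_id, pos, iv.start))
            pos = iv.end
        if pos < length:
            out.append(Interval(contig_id, pos, length))
    return out


def intersect_intervals(a: Iterable[Interval], b: Iterable[Interval]) -> list[Interval]:
    """Intersection of two interval sets."""
    a_merged = merge_intervals(a)
    b_by_contig: dict[str, list[Interval]] = {}
    for iv in merge_intervals(b):
        b_by_contig.setdefault(iv.contig_id, []).append(iv)
    out: list[Interval] = []
    for iv in a_merged:
        for other in b_by_contig.get(iv.contig_id, []):
            lo, hi = max(iv.start, other.start), min(iv.end, other.end)
            if lo < hi:
                out.append(Interval(iv.contig_id, lo, hi))
    return out


def subtract_intervals(
    a: Iterable[Interval], b: Iterable[Interval], contig_lengths: Mapping[str, int]
) -> list[Interval]:
    """Set difference a − b, restricted to contigs in ``contig_lengths``."""
    b_complement = complement_intervals(b, contig_lengths)
    return intersect_intervals(a, b_complement)


def total_length(intervals: Iterable[Interval]) -> int:
    """Total covered length of the union of intervals."""
    return sum(iv.length for iv in merge_intervals(intervals))


def extract_sequence(contig: Contig, interval: Interval) -> str:
    """Residues of ``contig`` under a half-open interval."""
    if interval.contig_id != contig.id:
        raise ValueError(
            f"interval is on {interval.contig_id!r}, not contig {contig.id!r}"
        )
    if interval.end > contig.length:
        raise ValueError(
            f"interval [{interval.start}, {interval.end}) exceeds contig "
            f"{contig.id!r} of length {contig.length}"
        )
    return contig.residues[interval.start : interval.end]


# ---------------------------------------------------------------------------
# GFF3 → feature partition
# ---------------------------------------------------------------------------

def _gff_interval(feature: "gffutils.Feature") -> Interval:
    # GFF3 is 1-based closed; convert to 0-based half-open.
    return Interval(feature.seqid, feature.start - 1, feature.end, feature.strand or ".")


def partition_from_gff(
    contigs: Sequence[Contig],
    gff3_path: str | os.PathLike,
    repeats_bed: str | os.PathLike | None = None,
    multigene_ids: Iterable[str] | None = None,
) -> FeaturePartition:
    """Derive the feature-class partition from annotation.

    Classes:

    * ``exon`` — union of exon features;
    * ``intron`` — gene spans minus exons;
    * ``coding`` — union of CDS features;
    * ``noncoding`` — genome complement of gene spans (intergenic);
    * ``multigene`` — spans of genes whose ids are in ``multigene_ids``;
    * ``repeat`` — BED intervals as supplied;
    * ``whole_genome`` — every contig end to end.

    Overlapping intervals within a class are merged.  Coordinates outside
    contig bounds or on unknown contigs raise ``ValueError``.
    """
    lengths = {c.id: c.length for c in contigs}
    multigene_ids = set(multigene_ids or ())

    try:
        db = gffutils.create_db(
            str(gff3_path),
            dbfn=":memory:",
            merge_strategy="create_unique",
            keep_order=True,
        )
    except gffutils.exceptions.EmptyInputError:
        db = None

    gene_spans: list[Interval] = []
    multigene_spans: list[Interval] = []
    exons: list[Interval] = []
    cds: list[Interval] = []
    per_gene_exons: dict[str, list[Interval]] = {}

    def check_bounds(iv: Interval, what: str) -> None:
        if iv.contig_id not in lengths:
            raise ValueError(f"{what} on unknown contig id {iv.contig_id!r}")
        if iv.end > lengths[iv.contig_id]:
            raise ValueError(
                f"{what} [{iv.start}, {iv.end}) out of bounds for contig "
                f"{iv.contig_id!r} (length {lengths[iv.contig_id]})"
            )

    genes = list(db.features_of_type("gene")) if db is not None else []
    for gene in genes:
        span = _gff_interval(gene)
        check_bounds(span, f"gene {gene.id!r}")
        gene_spans.append(span)
        if gene.id in multigene_ids:
            multigene_spans.append(span)
        gene_exons: list[Interval] = []
        for child in db.children(gene, featuretype=("exon", "CDS")):
            iv = _gff_interval(child)
            check_bounds(iv, f"{child.featuretype} under gene {gene.id!r}")
            if child.featuretype == "exon":
                gene_exons.append(iv)
                exons.append(iv)
            else:
                cds.append(iv)
        per_gene_exons[gene.id] = gene_exons or []
        # A gene with CDS but no explicit exon features: treat CDS as exonic
        # so introns are still derivable.
        if not gene_exons:
            for iv in [_gff_interval(c) for c in db.children(gene, featuretype="CDS")]:
                exons.append(iv)
                per_gene_exons[gene.id].append(iv)

    introns: list[Interval] = []
    for gene in genes:
        span = _gff_interval(gene)
        gene_exons = per_gene_exons.get(gene.id, [])
        if gene_exons:
            introns.extend(
                subtract_intervals([span], gene_exons, {span.contig_id: lengths[span.contig_id]})
            )

    repeats = read_bed(repeats_bed) if repeats_bed is not None else []
    for iv in repeats:
        check_bounds(iv, "repeat interval")

    whole = [Interval(c.id, 0, c.length) for c in contigs if c.length > 0]
    noncoding = complement_intervals(gene_spans, lengths)

    return FeaturePartition(
        class_intervals={
            "whole_genome": merge_intervals(whole) if whole else [],
            "coding": merge_intervals(cds) if cds else [],
            "noncoding": noncoding,
            "exon": merge_intervals(exons) if exons else [],
            "intron": merge_intervals(introns) if introns else [],
            "multigene": merge_intervals(multigene_spans) if multigene_spans else [],
            "repeat": merge_intervals(repeats) if repeats else [],
        }
    )
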