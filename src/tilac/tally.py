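"""Per-read mutation tallying from SAM alignments.

Turns aligned reads into :class:`~tilac.core.ReadTally` records: filters to
properly paired, uniquely mapped reads; assigns each read to a gene by
interval overlap; and counts reference-T and reference-G positions together
with T-to-C and G-to-A mismatches in transcript-strand space, excluding
known SNP positions, low-quality bases, insertions and soft clips.

For a gene on the minus strand the transcript-strand logic applies the
reverse complement: a genomic reference A with a read G is a T-to-C event
on the transcript, and a genomic reference C with a read T is a G-to-A
event.  Where paired mates overlap, overlapped positions are counted once
(first mate encountered wins).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd
import pysam
from intervaltree import IntervalTree

from .core import ReadTally, tallies_to_frame

__all__ = [
    "SnpMask",
    "GeneModel",
    "GeneIndex",
    "filter_alignment",
    "count_mismatches",
    "assign_gene",
    "tally_sam",
    "load_gene_models",
    "load_snp_mask",
]

#: SAM flags of a properly paired, primary, uniquely oriented read pair
ALLOWED_FLAGS = frozenset({83, 163, 99, 147})
MIN_MAPQ = 2
DEFAULT_BASEQ = 20


@dataclass(frozen=True)
class SnpMask:
    """Known variant positions to exclude from mutation counting.

    Positions are stored 0-based per contig; a mismatch at a masked position
    contributes to neither the mutation numerator nor the site denominator.
    """

    positions: frozenset[tuple[str, int]] = frozenset()

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, int]], one_based: bool = False) -> "SnpMask":
        off = 1 if one_based else 0
        return cls(frozenset((c, p - off) for c, p in pairs))

    def __contains__(self, key: tuple[str, int]) -> bool:
        return key in self.positions

    def __len__(self) -> int:
        return len(self.positions)


@dataclass
class GeneModel:
    """A gene's span and exon structure, 0-based half-open internally."""

    gene_id: str
    contig: str
    strand: str
    exons: list[tuple[int, int]]
    span: tuple[int, int] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"gene {self.gene_id}: strand must be + or -, got {self.strand}")
        self.exons = sorted((int(a), int(b)) for a, b in self.exons)
        for a, b in self.exons:
            if b <= a:
                raise ValueError(f"gene {self.gene_id}: degenerate exon [{a}, {b})")
        if self.span is None:
            self.span = (self.exons[0][0], self.exons[-1][1])
        if not (self.span[0] <= self.exons[0][0] and self.exons[-1][1] <= self.span[1]):
            raise ValueError(f"gene {self.gene_id}: exons fall outside the gene span")


class GeneIndex:
    """Interval lookup of gene models, per contig."""

    def __init__(self, genes: Iterable[GeneModel]):
        self.genes = {g.gene_id: g for g in genes}
        self._trees: dict[str, IntervalTree] = {}
        for g in self.genes.values():
            tree = self._trees.setdefault(g.contig, IntervalTree())
            tree[g.span[0] : g.span[1]] = g.gene_id

    def overlapping(self, contig: str, start: int, end: int) -> list[GeneModel]:
        tree = self._trees.get(contig)
        if tree is None:
            return []
        return sorted(
            (self.genes[iv.data] for iv in tree.overlap(start, end)),
            key=lambda g: g.gene_id,
        )


def filter_alignment(record: pysam.AlignedSegment) -> bool:
    """Keep a read iff its FLAG marks a proper unique pair and MAPQ >= 2."""
    return record.flag in ALLOWED_FLAGS and record.mapping_quality >= MIN_MAPQ


def assign_gene(
    record: pysam.AlignedSegment, genes: GeneIndex
) -> tuple[str | None, str]:
    """Assign a read to a gene and feature class by interval overlap.

    Fully inside the exons of exactly one gene -> (gene, 'exonic'); touching
    that gene's non-exonic sequence (or extending past its span) ->
    (gene, 'intronic'); overlapping two or more genes -> (None, 'ambiguous');
    no gene -> (None, 'none').
    """
    start, end = record.reference_start, record.reference_end
    hits = genes.overlapping(record.reference_name, start, end)
    if not hits:
        return None, "none"
    if len(hits) > 1:
        return None, "ambiguous"
    gene = hits[0]
    blocks = record.get_blocks()
    exonic = all(
        any(ex[0] <= s and e <= ex[1] for ex in gene.exons) for s, e in blocks
    )
    return gene.gene_id, "exonic" if exonic else "intronic"


# transcript-strand site/mismatch encoding: (reference base, read base)
_PLUS = {"site_U": "T", "site_G": "G", "tc": ("T", "C"), "ga": ("G", "A")}
_MINUS = {"site_U": "A", "site_G": "C", "tc": ("A", "G"), "ga": ("C", "T")}


def count_mismatches(
    record: pysam.AlignedSegment,
    reference: "pysam.FastaFile | None",
    mask: SnpMask | None = None,
    strand: str = "+",
    min_baseq: int = DEFAULT_BASEQ,
    skip_positions: set[int] | None = None,
) -> tuple[int, int, int, int]:
    """Count (n_U, n_G, y_TC, y_GA) for one read in transcript-strand space.

    Reference bases come from the alignment's MD tag when present, else from
    ``reference`` (a pysam FastaFile).  Masked SNP positions, positions in
    ``skip_positions`` (mate-overlap suppression), insertions, soft clips and
    bases below ``min_baseq`` are excluded from numerator and denominator
    alike.
    """
    mask = mask or SnpMask()
    contig = record.reference_name
    try:
        pairs = record.get_aligned_pairs(matches_only=True, with_seq=True)
        have_md = True
    except ValueError:
        have_md = False
    if not have_md:
        if reference is None:
            raise ValueError(
                f"read {record.query_name}: no MD tag and no reference FASTA supplied"
            )
        if contig not in reference.references:
            raise KeyError(f"contig {contig!r} absent from the reference FASTA")
        ref_seq = reference.fetch(contig, record.reference_start, record.reference_end)
        off = record.reference_start
        pairs = [
            (q, r, ref_seq[r - off])
            for q, r in record.get_aligned_pairs(matches_only=True)
        ]
    enc = _PLUS if strand == "+" else _MINUS
    quals = record.query_qualities
    seq = record.query_sequence
    n_U = n_G = y_TC = y_GA = 0
    for qpos, rpos, ref_base in pairs:
        if ref_base is None:
            continue
        if (contig, rpos) in mask:
            continue
        if skip_positions is not None and rpos in skip_positions:
            continue
        if quals is not None and quals[qpos] < min_baseq:
            continue
        ref_base = ref_base.upper()
        read_base = seq[qpos].upper()
        if ref_base == enc["site_U"]:
            n_U += 1
            if read_base == enc["tc"][1]:
                y_TC += 1
        elif ref_base == enc["site_G"]:
            n_G += 1
            if read_base == enc["ga"][1]:
                y_GA += 1
    return n_U, n_G, y_TC, y_GA


# ---------------------------------------------------------------------------
# Annotation and mask loading


def load_gene_models(path: str | Path) -> list[GeneModel]:
    """Read gene models from GTF/GFF (via gffutils) or BED12.

    GTF/GFF coordinates are 1-based closed and converted to 0-based
    half-open; BED12 is already 0-based half-open.
    """
    path = Path(path)
    if path.suffix.lower() in {".bed", ".bed12"}:
        return _load_bed12(path)
    return _load_gtf(path)


def _load_gtf(path: Path) -> list[GeneModel]:
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    genes: dict[str, GeneModel] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    spans: dict[str, tuple[str, str, int, int]] = {}
    for feat in db.all_features():
        gid = feat.attributes.get("gene_id", [feat.id])[0]
        start, end = feat.start - 1, feat.end  # to 0-based half-open
        if feat.featuretype == "gene":
            spans[gid] = (feat.seqid, feat.strand, start, end)
        elif feat.featuretype == "exon":
            exons.setdefault(gid, []).append((start, end))
            if gid not in spans:
                spans[gid] = (feat.seqid, feat.strand, start, end)
            else:
                c, s, a, b = spans[gid]
                spans[gid] = (c, s, min(a, start), max(b, end))
    out = []
    for gid, (contig, strand, a, b) in spans.items():
        ex = _merge_intervals(exons.get(gid, [(a, b)]))
        out.append(GeneModel(gid, contig, strand, ex, (a, b)))
    return sorted(out, key=lambda g: g.gene_id)


def _load_bed12(path: Path) -> list[GeneModel]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"{path}: BED12 requires 12 columns, got {len(f)}")
            contig, start, name, strand = f[0], int(f[1]), f[3], f[5]
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = [(start + s, start + s + sz) for s, sz in zip(starts, sizes)]
            out.append(GeneModel(name, contig, strand, exons, (int(f[1]), int(f[2]))))
    return sorted(out, key=lambda g: g.gene_id)


def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for a, b in sorted(intervals):
        if merged and a <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], b))
        else:
            merged.append((a, b))
    return merged


def load_snp_mask(path: str | Path) -> SnpMask:
    """Collect (contig, position) pairs from a VCF into a mask."""
    pairs = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            pairs.append((rec.contig, rec.start))  # pysam start is 0-based
    return SnpMask(frozenset(pairs))


# ---------------------------------------------------------------------------
# Driver


def tally_sam(
    sam_path: str | Path,
    sample_id: str,
    annotation: "str | Path | GeneIndex",
    fasta_path: str | Path | None = None,
    vcf_path: str | Path | None = None,
    min_baseq: int = DEFAULT_BASEQ,
    strandedness: str = "unstranded",
) -> pd.DataFrame:
    """Tally one SAM file into the canonical per-read mutation table.

    ``strandedness`` in {'unstranded', 'forward', 'reverse'} controls whether
    gene assignment requires the fragment orientation to match the gene
    strand ('forward': fragment strand equals transcript strand, 'reverse':
    opposite, as in typical dUTP protocols).  Reads failing the alignment
    filter, or without a unique gene assignment, are dropped; in overlapping
    mate pairs the overlapped positions count once.
    """
    if strandedness not in {"unstranded", "forward", "reverse"}:
        raise ValueError(f"unknown strandedness {strandedness!r}")
    genes = annotation if isinstance(annotation, GeneIndex) else GeneIndex(load_gene_models(annotation))
    mask = load_snp_mask(vcf_path) if vcf_path else SnpMask()
    fasta = pysam.FastaFile(str(fasta_path)) if fasta_path else None
    tallies: list[ReadTally] = []
    seen_mates: dict[str, set[int]] = {}
    try:
        with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as sam:
            for rec in sam:
                if not filter_alignment(rec):
                    continue
                gene_id, feature_class = assign_gene(rec, genes)
                if gene_id is None:
                    continue
                gene = genes.genes[gene_id]
                if strandedness != "unstranded":
                    frag_plus = rec.flag in (99, 147)
                    tx_plus = frag_plus if strandedness == "forward" else not frag_plus
                    if (gene.strand == "+") != tx_plus:
                        continue
                skip = None
                if rec.is_paired:
                    key = f"{rec.query_name}\0{rec.reference_name}"
                    if key in seen_mates:
                        skip = seen_mates.pop(key)
                    else:
                        seen_mates[key] = set(
                            r for _, r in rec.get_aligned_pairs(matches_only=True)
                        )
                n_U, n_G, y_TC, y_GA = count_mismatches(
                    rec, fasta, mask, gene.strand, min_baseq, skip
                )
                tallies.append(
                    ReadTally(
                        read_id=rec.query_name,
                        sample_id=sample_id,
                        gene_id=gene_id,
                        feature_class=feature_class,
                        n_U=n_U,
                        n_G=n_G,
                        y_TC=y_TC,
                        y_GA=y_GA,
                    )
                )
    finally:
        if fasta is not None:
            fasta.close()
    return tallies_to_frame(tallies)
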