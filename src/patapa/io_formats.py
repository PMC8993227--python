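"""Readers and writers for the pipeline's file formats.

Genome FASTA, GFF3 gene models, aligned poly(A) tags (SAM/BAM or BED6),
sample sheets, PAC tables (BED6 + TSV) and per-sample bedGraph coverage.

All internal coordinates are 0-based, half-open.  Conversions to and from
the 1-based closed GFF3 convention happen only inside this module, at the
file boundary.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import gffutils
import pandas as pd
import pysam
from Bio import SeqIO

from .pac_calling import PAC, PolyATag

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: label used for poly(A) clusters recovered in the downstream extension
REGIONS = ("UTR3", "CDS", "INTRON", "UTR5", "EXTENDED_UTR3", "INTERGENIC", "AMB")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (A/C/G/T/N, case kept)."""
    return seq.translate(_COMPLEMENT)[::-1]


class GenomeSeq:
    """In-memory genome with strand-aware, bounds-clipped window access.

    Suitable for the compact genomes this pipeline targets; sequences are
    held as plain uppercase strings keyed by chromosome name.
    """

    def __init__(self, sequences: dict[str, str]):
        self._seqs = {name: s.upper() for name, s in sequences.items()}

    @classmethod
    def from_fasta(cls, path: str | os.PathLike) -> "GenomeSeq":
        records = SeqIO.parse(str(path), "fasta")
        return cls({rec.id: str(rec.seq) for rec in records})

    @property
    def chrom_names(self) -> list[str]:
        return list(self._seqs)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def length(self, chrom: str) -> int:
        return len(self._seqs[chrom])

    def fetch(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        """Sequence of ``[start, end)`` on ``chrom``.

        Windows are clipped to chromosome bounds: bases outside the
        chromosome are absent from the result, never fabricated.  For the
        minus strand the reverse complement is returned, i.e. the string
        reads 5'->3' in transcriptional orientation.
        """
        if chrom not in self._seqs:
            raise KeyError(f"chromosome {chrom!r} not present in genome")
        seq = self._seqs[chrom]
        lo, hi = max(0, start), min(len(seq), end)
        if hi <= lo:
            return ""
        window = seq[lo:hi]
        return revcomp(window) if strand == "-" else window


Interval = tuple[int, int]


@dataclass
class GeneModel:
    """One gene with its representative transcript's substructure.

    ``utr3_extension`` is the downstream rescue window appended past the
    annotated 3' end: ``ext_bp`` (default 200) when a 3' UTR is annotated,
    ``ext_bp + fallback_bp`` (default 200 + 218) when it is not.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    utr3_intervals: list[Interval] = field(default_factory=list)
    cds_intervals: list[Interval] = field(default_factory=list)
    utr5_intervals: list[Interval] = field(default_factory=list)
    exon_intervals: list[Interval] = field(default_factory=list)
    intron_intervals: list[Interval] = field(default_factory=list)
    utr3_extension: Interval = (0, 0)

    @property
    def has_annotated_utr3(self) -> bool:
        return bool(self.utr3_intervals)

    @property
    def utr3_anchor(self) -> int:
        """Coordinate of the first 3' UTR base in transcriptional orientation.

        For genes without an annotated 3' UTR the anchor is the first base
        past the gene's 3' end, i.e. the start of the extension window.
        """
        if self.strand == "+":
            return min(s for s, _ in self.utr3_intervals) if self.utr3_intervals else self.end
        return max(e for _, e in self.utr3_intervals) - 1 if self.utr3_intervals else self.start - 1

    def utr3_length_to(self, pos: int) -> int:
        """Genomic distance (nt, inclusive) from the 3' UTR start to ``pos``."""
        if self.strand == "+":
            return pos - self.utr3_anchor + 1
        return self.utr3_anchor - pos + 1


@dataclass
class SampleEntry:
    sample_id: str
    path: str
    condition: str
    replicate: int


@dataclass
class SampleSheet:
    """Sample design: one row per library, mapping file to condition/replicate."""

    entries: list[SampleEntry]

    def __post_init__(self) -> None:
        ids = [e.sample_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("sample_ids must be unique")
        by_cond: dict[str, int] = {}
        for e in self.entries:
            by_cond[e.condition] = by_cond.get(e.condition, 0) + 1
        if len(by_cond) < 1 or any(n < 1 for n in by_cond.values()):
            raise ValueError("need at least one sample per condition")
        self.conditions = sorted(by_cond)

    @property
    def sample_ids(self) -> list[str]:
        return [e.sample_id for e in self.entries]

    def samples_for(self, condition: str) -> list[str]:
        return [e.sample_id for e in self.entries if e.condition == condition]

    def design_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "condition": [e.condition for e in self.entries],
                "replicate": [e.replicate for e in self.entries],
            },
            index=pd.Index(self.sample_ids, name="sample_id"),
        )


def read_sample_sheet(path: str | os.PathLike) -> SampleSheet:
    """Read a TSV sample sheet with columns sample_id, path, condition, replicate.

    Relative file paths are resolved against the sheet's own directory.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "path", "condition", "replicate"}
    if not required.issubset(df.columns):
        raise ValueError(f"sample sheet must have columns {sorted(required)}")
    base = os.path.dirname(os.path.abspath(path))
    entries = []
    for row in df.itertuples(index=False):
        p = row.path if os.path.isabs(row.path) else os.path.join(base, row.path)
        entries.append(SampleEntry(row.sample_id, p, row.condition, int(row.replicate)))
    return SampleSheet(entries)


# ---------------------------------------------------------------------------
# poly(A) tag input


def read_tags(
    path: str | os.PathLike,
    format: str,
    sample_id: str,
    min_mapq: int = 10,
) -> list[PolyATag]:
    """Read one sample's poly(A) tags from SAM/BAM alignments or a BED6 file.

    The cleavage coordinate is the 3'-most *aligned* base of each read in
    transcriptional orientation: the (0-based) last reference-consuming
    base for plus-strand alignments, the alignment start for minus-strand
    ones.  Soft-clipped bases (oligo(dT)/adaptor remnants) never count.
    Alignments below ``min_mapq`` are dropped (SAM/BAM only).
    """
    fmt = format.lower()
    if fmt in ("sam", "bam"):
        tags = _read_tags_alignment(path, fmt, sample_id, min_mapq)
    elif fmt == "bed":
        tags = _read_tags_bed(path, sample_id)
    else:
        raise ValueError(f"unknown tag format {format!r}; expected sam, bam or bed")
    logger.info("read %d tags from %s (%s)", len(tags), path, sample_id)
    return tags


def _read_tags_alignment(path, fmt, sample_id, min_mapq) -> list[PolyATag]:
    mode = "rb" if fmt == "bam" else "r"
    kept: list[PolyATag] = []
    dropped = 0
    with pysam.AlignmentFile(str(path), mode) as fh:
        for aln in fh:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                dropped += 1
                continue
            if aln.mapping_quality < min_mapq:
                dropped += 1
                continue
            if aln.is_reverse:
                strand, pos = "-", aln.reference_start
            else:
                strand, pos = "+", aln.reference_end - 1
            kept.append(PolyATag(aln.reference_name, strand, pos, sample_id))
    logger.info("%s: kept %d tags, dropped %d", sample_id, len(kept), dropped)
    return kept


def _read_tags_bed(path, sample_id) -> list[PolyATag]:
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        dtype={0: str},
    )
    if df.shape[1] < 6:
        raise ValueError(f"{path}: BED tag input must be 6-column with strand")
    tags = []
    for chrom, start, strand in zip(df[0], df[1], df[5]):
        if strand not in ("+", "-"):
            raise ValueError(f"{path}: invalid strand {strand!r}")
        tags.append(PolyATag(chrom, strand, int(start), sample_id))
    return tags


# ---------------------------------------------------------------------------
# GFF3 annotation

_TRANSCRIPT_TYPES = ("mRNA", "transcript")


def read_annotation(
    path: str | os.PathLike,
    ext_bp: int = 200,
    fallback_bp: int = 218,
) -> list[GeneModel]:
    """Read gene models from GFF3 and append the 3' UTR rescue extension.

    Genes with an annotated 3' UTR get a downstream window of ``ext_bp``
    nt anchored at the annotated 3' UTR end; genes without one get
    ``ext_bp + fallback_bp`` nt anchored at the gene's 3' end (the extra
    term standing in for the genome's average 3' UTR length).  When a gene
    carries several transcripts the representative is the one with the
    longest annotated 3' UTR, falling back to the longest transcript.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    genes: list[GeneModel] = []
    seen: set[str] = set()
    for g in db.features_of_type("gene"):
        gene_id = g.attributes.get("ID", [g.id])[0]
        if gene_id in seen:
            raise ValueError(f"duplicate gene_id {gene_id!r} in annotation")
        seen.add(gene_id)
        if g.strand not in ("+", "-"):
            logger.warning("gene %s has no strand; skipped", gene_id)
            continue
        rep = _representative_transcript(db, g)
        model = _build_model(db, g, gene_id, rep, ext_bp, fallback_bp)
        genes.append(model)
    return genes


def _utr3_total(db, tx) -> int:
    return sum(
        f.end - f.start + 1 for f in db.children(tx, featuretype="three_prime_UTR")
    )


def _representative_transcript(db, gene):
    txs = [t for ft in _TRANSCRIPT_TYPES for t in db.children(gene, featuretype=ft)]
    if not txs:
        return gene
    txs.sort(key=lambda t: (_utr3_total(db, t), t.end - t.start), reverse=True)
    return txs[0]


def _child_intervals(db, parent, featuretype) -> list[Interval]:
    ivs = [(f.start - 1, f.end) for f in db.children(parent, featuretype=featuretype)]
    return sorted(ivs)


def _build_model(db, gene, gene_id, rep, ext_bp, fallback_bp) -> GeneModel:
    start, end = gene.start - 1, gene.end
    utr3 = _child_intervals(db, rep, "three_prime_UTR")
    utr5 = _child_intervals(db, rep, "five_prime_UTR")
    cds = _child_intervals(db, rep, "CDS")
    exons = _child_intervals(db, rep, "exon")
    if not exons:
        exons = [(start, end)]
    introns = [
        (exons[i][1], exons[i + 1][0])
        for i in range(len(exons) - 1)
        if exons[i + 1][0] > exons[i][1]
    ]
    ext_len = ext_bp if utr3 else ext_bp + fallback_bp
    if gene.strand == "+":
        anchor = max(e for _, e in utr3) if utr3 else end
        extension = (anchor, anchor + ext_len)
    else:
        anchor = min(s for s, _ in utr3) if utr3 else start
        extension = (max(0, anchor - ext_len), anchor)
    return GeneModel(
        gene_id=gene_id,
        chrom=gene.seqid,
        strand=gene.strand,
        start=start,
        end=end,
        utr3_intervals=utr3,
        cds_intervals=cds,
        utr5_intervals=utr5,
        exon_intervals=exons,
        intron_intervals=introns,
        utr3_extension=extension,
    )


# ---------------------------------------------------------------------------
# PAC tables

_PAC_FIXED_COLS = ["pac_id", "chrom", "strand", "start", "end", "summit", "gene_id", "region"]


def pacs_to_frame(pacs: Sequence[PAC], sample_ids: Sequence[str]) -> pd.DataFrame:
    rows = []
    for p in pacs:
        row = {
            "pac_id": p.pac_id,
            "chrom": p.chrom,
            "strand": p.strand,
            "start": p.start,
            "end": p.end,
            "summit": p.summit,
            "gene_id": p.gene_id if p.gene_id is not None else ".",
            "region": p.region if p.region is not None else ".",
        }
        for s in sample_ids:
            row[s] = int(p.counts.get(s, 0))
        rows.append(row)
    return pd.DataFrame(rows, columns=_PAC_FIXED_COLS + list(sample_ids))


def frame_to_pacs(df: pd.DataFrame) -> list[PAC]:
    sample_cols = [c for c in df.columns if c not in _PAC_FIXED_COLS]
    pacs = []
    for row in df.itertuples(index=False):
        counts = {s: int(getattr(row, s)) for s in sample_cols}
        pacs.append(
            PAC(
                pac_id=row.pac_id,
                chrom=str(row.chrom),
                strand=row.strand,
                start=int(row.start),
                end=int(row.end),
                summit=int(row.summit),
                counts=counts,
                gene_id=None if row.gene_id == "." else row.gene_id,
                region=None if row.region == "." else row.region,
            )
        )
    return pacs


def write_pacs(
    pacs: Sequence[PAC],
    bed_path: str | os.PathLike,
    tsv_path: str | os.PathLike,
    sample_ids: Sequence[str],
) -> None:
    """Write PACs as BED6 (score = total tag count, capped at 1000) plus a TSV.

    The TSV round-trips: ``read_pacs(tsv_path)`` reproduces the table
    cell-for-cell.
    """
    df = pacs_to_frame(pacs, sample_ids)
    with open(bed_path, "w") as bed:
        for p in pacs:
            score = min(1000, p.total_count())
            bed.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.pac_id}\t{score}\t{p.strand}\n")
    df.to_csv(tsv_path, sep="\t", index=False)


def read_pacs(tsv_path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(tsv_path, sep="\t", dtype={"chrom": str, "gene_id": str, "region": str})


# ---------------------------------------------------------------------------
# coverage export


def write_coverage(
    tags: Iterable[PolyATag],
    sample_id: str,
    path: str | os.PathLike,
) -> None:
    """Write a strand-collapsed bedGraph of per-base tag-end counts.

    Adjacent positions with equal counts are merged into one interval
    (standard bedGraph compaction); output is sorted by chrom then start.
    """
    counts: dict[tuple[str, int], int] = {}
    for t in tags:
        key = (t.chrom, t.pos)
        counts[key] = counts.get(key, 0) + 1
    with open(path, "w") as out:
        if not counts:
            return
        out.write(f'track type=bedGraph name="{sample_id}"\n')
        run_chrom, run_start, run_end, run_val = None, 0, 0, 0
        for (chrom, pos), val in sorted(counts.items()):
            if chrom == run_chrom and pos == run_end and val == run_val:
                run_end = pos + 1
                continue
            if run_chrom is not None:
                out.write(f"{run_chrom}\t{run_start}\t{run_end}\t{run_val}\n")
            run_chrom, run_start, run_end, run_val = chrom, pos, pos + 1, val
        out.write(f"{run_chrom}\t{run_start}\t{run_end}\t{run_val}\n")
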