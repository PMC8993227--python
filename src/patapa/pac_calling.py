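"""Poly(A) cluster (PAC) calling.

Pipeline order is fixed: internal-priming filtering of single-nucleotide
poly(A) tags, single-linkage clustering of tags within a gap window into
PACs, summit-based assignment of PACs to genes and genomic regions, and a
minimum-support filter on the pooled tag count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence, TYPE_CHECKING

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

if TYPE_CHECKING:  # pragma: no cover
    from .io_formats import GeneModel, GenomeSeq

logger = logging.getLogger(__name__)


class PolyATag(NamedTuple):
    """One observed cleavage event.

    ``pos`` is the 0-based coordinate of the last transcribed base — the
    base after which the poly(A) tail begins.  ``ip_checked`` records that
    the tag has passed through the internal-priming filter.
    """

    chrom: str
    strand: str
    pos: int
    sample_id: str
    ip_checked: bool = False


@dataclass
class PAC:
    """A poly(A) cluster: one called poly(A) site supported by member tags."""

    pac_id: str
    chrom: str
    strand: str
    start: int
    end: int  # half-open span covering member tag positions
    summit: int  # position with the most tags; ties break distal
    counts: dict[str, int] = field(default_factory=dict)
    gene_id: str | None = None
    region: str | None = None

    def total_count(self) -> int:
        return int(sum(self.counts.values()))


@dataclass
class CallingParams:
    """Tunable PAC-calling parameters.

    cluster_window: maximum gap (nt) between neighbouring tags in one PAC.
    min_pats: minimum pooled tag support for a PAC to be kept.
    ip_window: length (nt) of the downstream genomic window scanned for
        internal-priming evidence.
    ip_max_a: A count in the window at or above which a tag is an artifact.
    ip_run_a: length of a leading A run that alone marks an artifact.
    """

    cluster_window: int = 24
    min_pats: int = 10
    ip_window: int = 10
    ip_max_a: int = 7
    ip_run_a: int = 6

    def __post_init__(self) -> None:
        for name in ("cluster_window", "min_pats", "ip_window", "ip_max_a", "ip_run_a"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")


def tags_to_frame(tags: Sequence[PolyATag]) -> pd.DataFrame:
    if len(tags) == 0:
        return pd.DataFrame(columns=["chrom", "strand", "pos", "sample_id", "ip_checked"])
    return pd.DataFrame(tags, columns=["chrom", "strand", "pos", "sample_id", "ip_checked"])


# ---------------------------------------------------------------------------
# internal-priming filter


def is_internal_priming(window: str, ip_max_a: int = 7, ip_run_a: int = 6) -> bool:
    """Internal-priming rule on a downstream window read in sense orientation.

    True iff the window contains >= ``ip_max_a`` A overall, or begins with
    a run of >= ``ip_run_a`` consecutive A.  An oligo(dT) primer annealing
    to such a genomic tract mimics a poly(A) tail, so tags upstream of it
    are unreliable.
    """
    w = window.upper()
    if w.count("A") >= ip_max_a:
        return True
    run = len(w) - len(w.lstrip("A"))
    return run >= ip_run_a


def filter_internal_priming(
    tags: Sequence[PolyATag],
    genome: "GenomeSeq",
    params: CallingParams | None = None,
) -> tuple[list[PolyATag], list[PolyATag]]:
    """Split tags into (kept, removed) by the downstream A-richness rule.

    The window of ``ip_window`` nt immediately downstream of the cleavage
    position is read in transcriptional orientation (reverse-complemented
    for minus-strand tags); windows truncated by a chromosome end use only
    the available bases.  Kept tags are marked ``ip_checked``.
    """
    params = params or CallingParams()
    for chrom in {t.chrom for t in tags}:
        if chrom not in genome:
            raise KeyError(f"tag chromosome {chrom!r} absent from genome")
    verdict: dict[tuple[str, str, int], bool] = {}
    kept: list[PolyATag] = []
    removed: list[PolyATag] = []
    w = params.ip_window
    for t in tags:
        key = (t.chrom, t.strand, t.pos)
        if key not in verdict:
            if t.strand == "+":
                window = genome.fetch(t.chrom, t.pos + 1, t.pos + 1 + w, "+")
            else:
                window = genome.fetch(t.chrom, t.pos - w, t.pos, "-")
            verdict[key] = is_internal_priming(window, params.ip_max_a, params.ip_run_a)
        if verdict[key]:
            removed.append(t)
        else:
            kept.append(t._replace(ip_checked=True))
    logger.info(
        "internal-priming filter: kept %d, removed %d tags", len(kept), len(removed)
    )
    return kept, removed


# ---------------------------------------------------------------------------
# clustering


def cluster_tags(
    tags: Sequence[PolyATag],
    params: CallingParams | None = None,
    require_filtered: bool = False,
) -> list[PAC]:
    """Single-linkage gap clustering of tags into PACs, per (chrom, strand).

    Sorted positions are split wherever the gap to the previous position
    exceeds ``cluster_window``; the partition is therefore independent of
    input order.  Counts are tallied per sample; the summit is the member
    position with the most tags, ties broken toward the most distal
    position in transcriptional orientation (downstream-conservative).

    With ``require_filtered`` the call refuses tags that have not passed
    the internal-priming filter, enforcing the fixed pipeline order.
    """
    params = params or CallingParams()
    if require_filtered and any(not t.ip_checked for t in tags):
        raise ValueError(
            "strict mode: tags must pass filter_internal_priming before clustering"
        )
    df = tags_to_frame(tags)
    if df.empty:
        return []
    pacs: list[PAC] = []
    for (chrom, strand), grp in df.groupby(["chrom", "strand"], sort=True):
        pos = np.sort(grp["pos"].to_numpy())
        # cluster id per sorted tag: new cluster when gap > window
        breaks = np.diff(pos) > params.cluster_window
        cid_sorted = np.concatenate([[0], np.cumsum(breaks)])
        order = np.argsort(grp["pos"].to_numpy(), kind="stable")
        cid = np.empty(len(grp), dtype=int)
        cid[order] = cid_sorted
        sub = grp.assign(_cid=cid)
        for c, members in sub.groupby("_cid", sort=True):
            pacs.append(_make_pac(chrom, strand, members))
    for i, p in enumerate(sorted(pacs, key=lambda p: (p.chrom, p.start, p.strand))):
        p.pac_id = f"PAC{i + 1:05d}"
    return sorted(pacs, key=lambda p: (p.chrom, p.start, p.strand))


def _make_pac(chrom: str, strand: str, members: pd.DataFrame) -> PAC:
    pos = members["pos"].to_numpy()
    vals, freq = np.unique(pos, return_counts=True)
    best = freq == freq.max()
    summit = int(vals[best].max() if strand == "+" else vals[best].min())
    counts = members.groupby("sample_id")["pos"].size().to_dict()
    return PAC(
        pac_id="",
        chrom=chrom,
        strand=strand,
        start=int(pos.min()),
        end=int(pos.max()) + 1,
        summit=summit,
        counts={k: int(v) for k, v in counts.items()},
    )


# ---------------------------------------------------------------------------
# gene/region assignment

_ASSIGN_REGIONS = (
    ("utr3_intervals", "UTR3"),
    ("cds_intervals", "CDS"),
    ("intron_intervals", "INTRON"),
    ("utr5_intervals", "UTR5"),
)


def _region_trees(genes: Sequence["GeneModel"]) -> dict[tuple[str, str], IntervalTree]:
    trees: dict[tuple[str, str], IntervalTree] = {}
    for g in genes:
        tree = trees.setdefault((g.chrom, g.strand), IntervalTree())
        for attr, label in _ASSIGN_REGIONS:
            for s, e in getattr(g, attr):
                if e > s:
                    tree.addi(s, e, (g.gene_id, label))
        s, e = g.utr3_extension
        if e > s:
            tree.addi(s, e, (g.gene_id, "EXTENDED_UTR3"))
    return trees


def assign_pacs(pacs: Sequence[PAC], genes: Sequence["GeneModel"]) -> list[PAC]:
    """Assign each PAC to a gene and genomic region by its summit.

    Exactly one (gene, region) hit gives that assignment; hits in more
    than one region or gene give the ambiguous label AMB (keeping the
    gene of a 3' UTR hit when there is one); no hit gives INTERGENIC.
    Assignment mutates and returns the input PACs.
    """
    trees = _region_trees(genes)
    for p in pacs:
        tree = trees.get((p.chrom, p.strand))
        hits = sorted({iv.data for iv in tree.at(p.summit)}) if tree is not None else []
        if not hits:
            p.gene_id, p.region = None, "INTERGENIC"
        elif len(hits) == 1:
            p.gene_id, p.region = hits[0]
        else:
            p.region = "AMB"
            p.gene_id = None
            for priority in ("UTR3", "EXTENDED_UTR3"):
                cand = [g for g, r in hits if r == priority]
                if cand:
                    p.gene_id = cand[0]
                    break
    return list(pacs)


def filter_min_support(pacs: Sequence[PAC], params: CallingParams | None = None) -> list[PAC]:
    """Keep PACs whose pooled tag count across all samples >= min_pats."""
    params = params or CallingParams()
    kept = [p for p in pacs if p.total_count() >= params.min_pats]
    logger.info("support filter: kept %d / %d PACs", len(kept), len(pacs))
    return kept


def apa_gene_table(pacs: Sequence[PAC]) -> pd.DataFrame:
    """Per-gene PAC counts and the APA call (is_apa = more than one PAC).

    Only PACs with a gene assignment count; AMB PACs count for their
    assigned gene when one was resolved, intergenic PACs never count.
    """
    rows: dict[str, int] = {}
    for p in pacs:
        if p.gene_id is not None and p.region != "INTERGENIC":
            rows[p.gene_id] = rows.get(p.gene_id, 0) + 1
    df = pd.DataFrame(
        {"gene_id": list(rows), "n_pacs": list(rows.values())}
    ).sort_values("gene_id", ignore_index=True)
    df["is_apa"] = df["n_pacs"] > 1
    return df
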