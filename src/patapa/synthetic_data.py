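"""Synthetic PAT-seq study generator with planted ground truth.

Builds a toy genome of well-separated gene loci, a matching GFF3, and
per-sample poly(A)-tag BED libraries for a two-condition (CK vs ST)
design with replicates.  Genes carry planted APA architectures and
condition effects — 3' UTR lengthening and shortening, PAC switching,
ST-specific PACs and ST-inducible APA — plus genomic A-rich tracts that
produce internal-priming artifact tags, so every pipeline stage can be
scored against known truth.

Counts are generated hierarchically: a gene's library-j total is drawn
NB(gene mean, dispersion) and allocated to the gene's PACs by a
multinomial with condition-specific usage shares.  Each PAC's marginal
count then has mean mu = share x gene mean and variance mu + d mu^2
(the NB moment structure at the same dispersion d), while usage
conditional on the total is exactly multinomial — which keeps the
chi-square usage test calibrated under the null.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# fixed locus architecture (nt)
UTR5_LEN = 80
CDS1_LEN = 300
INTRON_LEN = 120
CDS2_LEN = 300
UTR3_LEN = 300
SPACER = 1300
LEFT_MARGIN = 700
GENES_PER_CHROM = 250

# site offsets (nt) from the first 3' UTR base, proximal -> distal
_OFFSETS_UTR = (60, 160, 260, 360, 460)  # last two fall in the 200-nt extension
_OFFSETS_NOUTR = (40, 130, 220, 310, 400)  # all within the 418-nt fallback window

_ARTIFACT_TRACT = 15  # planted A-tract length
_ARTIFACT_MEAN = 25.0  # artifact tags per sample
_ARTIFACT_JITTER = 2.0

LABELS = ("LENGTHEN", "SHORTEN", "SWITCH", "SPECIFIC", "INDUCIBLE", "NULL")


@dataclass
class SimConfig:
    """Study conditions for the generator.

    Event fractions are fractions of all genes; events requiring >= 2
    PACs must fit inside ``apa_fraction``.  ``mean_expression`` is the
    expected tag yield per gene per library; ``dispersion`` the NB
    dispersion of library totals.  ``usage_shift`` is the absolute usage
    share moved from the proximal to the distal PAC (or back) under ST
    for planted lengthening (shortening) genes.  ``jitter_sd`` is the
    positional noise (nt) of tag ends around the true cleavage site, and
    ``ip_tract_rate`` the per-gene rate of planted intergenic A-rich
    tracts emitting internal-priming artifact tags.
    """

    n_genes: int = 1000
    apa_fraction: float = 0.5
    pacs_per_apa_gene: dict = field(
        default_factory=lambda: {2: 0.4, 3: 0.3, 4: 0.2, 5: 0.1}
    )
    mean_expression: float = 200.0
    dispersion: float = 0.1
    n_reps_per_condition: int = 3
    lengthen_fraction: float = 0.10
    shorten_fraction: float = 0.02
    switch_fraction: float = 0.03
    st_specific_fraction: float = 0.03
    inducible_fraction: float = 0.016
    usage_shift: float = 0.2
    jitter_sd: float = 5.0
    ip_tract_rate: float = 0.02
    no_utr3_fraction: float = 0.1
    region_site_rate: float = 0.05  # NULL APA genes with one non-UTR site
    seed: int = 1

    def validate(self) -> None:
        ev = (
            self.lengthen_fraction
            + self.shorten_fraction
            + self.switch_fraction
            + self.st_specific_fraction
            + self.inducible_fraction
        )
        if ev > self.apa_fraction + 1e-12:
            raise ValueError(
                f"planted event fractions sum to {ev:.3f} > apa_fraction {self.apa_fraction}"
            )
        if not 0 <= self.apa_fraction <= 1:
            raise ValueError("apa_fraction must be in [0, 1]")
        if abs(sum(self.pacs_per_apa_gene.values()) - 1.0) > 1e-9:
            raise ValueError("pacs_per_apa_gene probabilities must sum to 1")
        if any(k < 2 or k > len(_OFFSETS_UTR) for k in self.pacs_per_apa_gene):
            raise ValueError("pacs_per_apa_gene supports 2..5 PACs")
        for name in ("n_genes", "n_reps_per_condition"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")


@dataclass
class GroundTruth:
    """Planted truth: per-site positions/usage, per-gene labels, artifacts."""

    sites: pd.DataFrame
    genes: pd.DataFrame
    artifacts: pd.DataFrame


@dataclass
class SimResult:
    genome_fasta: str
    gff3: str
    sample_sheet: str
    tag_beds: dict
    truth: GroundTruth


# ---------------------------------------------------------------------------
# gene architecture


def _gene_layout(gene_id, chrom, strand, o, has_utr3):
    """Interval layout of one locus; all coordinates 0-based half-open."""
    if has_utr3:
        L = UTR5_LEN + CDS1_LEN + INTRON_LEN + CDS2_LEN + UTR3_LEN
    else:
        L = UTR5_LEN + CDS1_LEN + INTRON_LEN + CDS2_LEN
    if strand == "+":
        utr5 = (o, o + UTR5_LEN)
        cds1 = (o + UTR5_LEN, o + UTR5_LEN + CDS1_LEN)
        intron = (cds1[1], cds1[1] + INTRON_LEN)
        cds2 = (intron[1], intron[1] + CDS2_LEN)
        utr3 = (cds2[1], cds2[1] + UTR3_LEN) if has_utr3 else None
        exon1 = (o, cds1[1])
        exon2 = (cds2[0], utr3[1] if has_utr3 else cds2[1])
        anchor = utr3[0] if has_utr3 else o + L
    else:
        # transcription right -> left; 3' end at low coordinates
        utr3 = (o, o + UTR3_LEN) if has_utr3 else None
        cds2_s = o + UTR3_LEN if has_utr3 else o
        cds2 = (cds2_s, cds2_s + CDS2_LEN)
        intron = (cds2[1], cds2[1] + INTRON_LEN)
        cds1 = (intron[1], intron[1] + CDS1_LEN)
        utr5 = (cds1[1], cds1[1] + UTR5_LEN)
        exon1 = (o, cds2[1])
        exon2 = (cds1[0], utr5[1])
        anchor = utr3[1] - 1 if has_utr3 else o - 1
    return {
        "gene_id": gene_id,
        "chrom": chrom,
        "strand": strand,
        "start": o,
        "end": o + L,
        "utr5": utr5,
        "cds1": cds1,
        "intron": intron,
        "cds2": cds2,
        "utr3": utr3,
        "exons": sorted([exon1, exon2]),
        "anchor": anchor,
        "has_utr3": has_utr3,
    }


def _site_pos(layout, offset):
    """Genome coordinate of a cleavage site ``offset`` nt past the 3' UTR start."""
    if layout["strand"] == "+":
        return layout["anchor"] + offset
    return layout["anchor"] - offset


def _site_region(layout, offset):
    if layout["has_utr3"]:
        return "UTR3" if offset < UTR3_LEN else "EXTENDED_UTR3"
    return "EXTENDED_UTR3"


def _midpoint(iv):
    return (iv[0] + iv[1]) // 2


# ---------------------------------------------------------------------------
# usage-share construction per event label


def _base_shares(rng, k):
    w = rng.uniform(0.5, 1.5, size=k)
    return w / w.sum()


def _shares_for_label(rng, label, k, usage_shift):
    """(share_ck, share_st) arrays over the gene's k (or k+1) sites."""
    if label in ("NULL",):
        w = _base_shares(rng, k)
        return w, w.copy()
    if label in ("LENGTHEN", "SHORTEN"):
        donor = 0 if label == "LENGTHEN" else k - 1
        receiver = k - 1 if label == "LENGTHEN" else 0
        w = _base_shares(rng, k)
        w[donor] = 0.45 + rng.uniform(0, 0.1)
        others = [i for i in range(k) if i != donor]
        w[others] = w[others] / w[others].sum() * (1 - w[donor])
        st = w.copy()
        st[donor] -= usage_shift
        st[receiver] += usage_shift
        return w, st
    if label == "SWITCH":
        # proximal PAC up 4-fold, distal PAC down 4-fold, total conserved
        a = 0.2 if k == 2 else 0.15
        b = 4 * a
        ck = np.full(k, (1 - a - b) / max(k - 2, 1))
        ck[0], ck[-1] = a, b
        st = ck.copy()
        st[0], st[-1] = b, a
        return ck, st
    if label == "SPECIFIC":
        # k base sites plus one distal ST-only site (k + 1 shares)
        w = _base_shares(rng, k)
        s = 0.15
        ck = np.append(w, 0.0)
        st = np.append(w * (1 - s), s)
        return ck, st
    if label == "INDUCIBLE":
        ck = np.zeros(k)
        ck[0] = 1.0
        st = np.full(k, 0.6 / (k - 1))
        st[0] = 0.4
        return ck, st
    raise ValueError(f"unknown label {label!r}")


# ---------------------------------------------------------------------------
# simulate


def _rnb(rng, mean, disp, size=None):
    """Negative binomial draw(s) with mean/dispersion parameterization."""
    if mean <= 0:
        return np.zeros(size or 1, dtype=int) if size else 0
    if disp <= 1e-12:
        return rng.poisson(mean, size=size)
    n = 1.0 / disp
    p = 1.0 / (1.0 + disp * mean)
    return rng.negative_binomial(n, p, size=size)


def simulate(config: SimConfig, outdir: str | os.PathLike) -> SimResult:
    """Write genome FASTA, GFF3, per-sample tag BEDs, sample sheet and truth.

    All outputs are deterministic functions of ``config`` (including its
    seed): rerunning with the same config reproduces every file byte for
    byte.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    outdir = str(outdir)
    os.makedirs(outdir, exist_ok=True)

    genes = _plan_genes(rng, config)
    chrom_lens = _chrom_lengths(config.n_genes)
    sites = _plan_sites(rng, config, genes)
    artifacts = _plan_artifacts(rng, config, genes)
    genome_path = _write_genome(rng, outdir, chrom_lens, artifacts)
    gff_path = _write_gff3(outdir, genes)
    sheet_path, beds = _write_tags(rng, config, outdir, genes, sites, artifacts, chrom_lens)

    sites_df = pd.DataFrame(sites)
    genes_df = pd.DataFrame(
        [
            {
                "gene_id": g["gene_id"],
                "label": g["label"],
                "n_true_pacs": g["n_sites"],
                "chrom": g["chrom"],
                "strand": g["strand"],
                "has_utr3": g["has_utr3"],
                "gene_mean": g["gene_mean"],
            }
            for g in genes
        ]
    )
    artifacts_df = pd.DataFrame(
        artifacts, columns=["chrom", "strand", "pos", "mean_per_sample"]
    )
    sites_df.to_csv(os.path.join(outdir, "truth_sites.tsv"), sep="\t", index=False)
    genes_df.to_csv(os.path.join(outdir, "truth_genes.tsv"), sep="\t", index=False)
    artifacts_df.to_csv(os.path.join(outdir, "truth_artifacts.tsv"), sep="\t", index=False)
    return SimResult(
        genome_fasta=genome_path,
        gff3=gff_path,
        sample_sheet=sheet_path,
        tag_beds=beds,
        truth=GroundTruth(sites=sites_df, genes=genes_df, artifacts=artifacts_df),
    )


def _chrom_lengths(n_genes):
    n_chroms = int(np.ceil(n_genes / GENES_PER_CHROM))
    lens = {}
    for c in range(n_chroms):
        n_on = min(GENES_PER_CHROM, n_genes - c * GENES_PER_CHROM)
        locus = UTR5_LEN + CDS1_LEN + INTRON_LEN + CDS2_LEN + UTR3_LEN
        lens[f"chr{c + 1}"] = LEFT_MARGIN + n_on * (locus + SPACER) + LEFT_MARGIN
    return lens


def _plan_genes(rng, config):
    n = config.n_genes
    labels = np.array(["NULL"] * n, dtype=object)
    order = rng.permutation(n)
    n_apa = int(round(config.apa_fraction * n))
    apa_idx = order[:n_apa]
    cursor = 0
    for label, frac in (
        ("LENGTHEN", config.lengthen_fraction),
        ("SHORTEN", config.shorten_fraction),
        ("SWITCH", config.switch_fraction),
        ("SPECIFIC", config.st_specific_fraction),
        ("INDUCIBLE", config.inducible_fraction),
    ):
        m = int(round(frac * n))
        labels[apa_idx[cursor : cursor + m]] = label
        cursor += m
    is_apa = np.zeros(n, dtype=bool)
    is_apa[apa_idx] = True

    ks = np.array(sorted(config.pacs_per_apa_gene), dtype=int)
    kp = np.array([config.pacs_per_apa_gene[k] for k in ks], dtype=float)
    no_utr = rng.random(n) < config.no_utr3_fraction
    region_site = rng.random(n) < config.region_site_rate

    genes = []
    for i in range(n):
        chrom_i = i // GENES_PER_CHROM
        on_chrom = i % GENES_PER_CHROM
        locus = UTR5_LEN + CDS1_LEN + INTRON_LEN + CDS2_LEN + UTR3_LEN
        o = LEFT_MARGIN + on_chrom * (locus + SPACER)
        strand = "+" if rng.random() < 0.5 else "-"
        gid = f"G{i + 1:05d}"
        layout = _gene_layout(gid, f"chr{chrom_i + 1}", strand, o, not no_utr[i])
        label = labels[i]
        if is_apa[i]:
            k = int(rng.choice(ks, p=kp))
        else:
            k = 1
        if label == "SPECIFIC":
            k = min(k, len(_OFFSETS_UTR) - 1)  # leave room for the ST-only site
        n_sites = k + 1 if label == "SPECIFIC" else k
        layout.update(
            label=label if is_apa[i] else "NULL",
            k=k,
            n_sites=n_sites,
            gene_mean=float(config.mean_expression * rng.uniform(0.65, 1.35)),
            region_site=bool(region_site[i] and is_apa[i] and label == "NULL" and not no_utr[i]),
        )
        genes.append(layout)
    return genes


def _plan_sites(rng, config, genes):
    sites = []
    region_cycle = ("cds1", "intron", "utr5")
    n_reloc = 0
    for g in genes:
        offsets = _OFFSETS_UTR if g["has_utr3"] else _OFFSETS_NOUTR
        share_ck, share_st = _shares_for_label(rng, g["label"], g["k"], config.usage_shift)
        for j in range(g["n_sites"]):
            d = offsets[j]
            pos = _site_pos(g, d)
            region = _site_region(g, d)
            site_label = "BASE"
            if g["label"] == "SPECIFIC" and j == g["n_sites"] - 1:
                site_label = "SPECIFIC_ST"
            elif g["label"] == "INDUCIBLE" and j > 0:
                site_label = "INDUCED"
            if g["region_site"] and j == 0:
                iv = g[region_cycle[n_reloc % len(region_cycle)]]
                pos = _midpoint(iv)
                region = {"cds1": "CDS", "intron": "INTRON", "utr5": "UTR5"}[
                    region_cycle[n_reloc % len(region_cycle)]
                ]
                d = -1
                n_reloc += 1
            sites.append(
                {
                    "gene_id": g["gene_id"],
                    "site_id": f"{g['gene_id']}.s{j + 1}",
                    "chrom": g["chrom"],
                    "strand": g["strand"],
                    "pos": int(pos),
                    "region": region,
                    "utr_offset": int(d),
                    "site_label": site_label,
                    "share_ck": float(share_ck[j]),
                    "share_st": float(share_st[j]),
                }
            )
    return sites


def _plan_artifacts(rng, config, genes):
    n_art = int(round(config.ip_tract_rate * len(genes)))
    chosen = rng.choice(len(genes), size=n_art, replace=False) if n_art else []
    artifacts = []
    for i in sorted(chosen):
        g = genes[i]
        pos = g["start"] + (g["end"] - g["start"]) + 650  # mid-spacer, intergenic
        artifacts.append((g["chrom"], g["strand"], int(pos), _ARTIFACT_MEAN))
    return artifacts


def _write_genome(rng, outdir, chrom_lens, artifacts):
    path = os.path.join(outdir, "genome.fa")
    bases = np.frombuffer(b"ACGT", dtype="S1")
    seqs = {}
    for chrom, L in chrom_lens.items():
        seqs[chrom] = rng.choice(bases, size=L).copy()
    for chrom, strand, pos, _ in artifacts:
        arr = seqs[chrom]
        if strand == "+":
            arr[pos + 1 : pos + 1 + _ARTIFACT_TRACT] = b"A"
        else:
            arr[max(0, pos - _ARTIFACT_TRACT) : pos] = b"T"
    with open(path, "w") as out:
        for chrom, arr in seqs.items():
            out.write(f">{chrom}\n")
            s = arr.tobytes().decode()
            for i in range(0, len(s), 60):
                out.write(s[i : i + 60] + "\n")
    return path


def _gff_line(chrom, ftype, start, end, strand, attrs):
    return f"{chrom}\tpatapa_sim\t{ftype}\t{start + 1}\t{end}\t.\t{strand}\t.\t{attrs}\n"


def _write_gff3(outdir, genes):
    path = os.path.join(outdir, "annotation.gff3")
    with open(path, "w") as out:
        out.write("##gff-version 3\n")
        for g in genes:
            gid = g["gene_id"]
            mid = f"{gid}.t1"
            out.write(_gff_line(g["chrom"], "gene", g["start"], g["end"], g["strand"], f"ID={gid}"))
            out.write(
                _gff_line(g["chrom"], "mRNA", g["start"], g["end"], g["strand"], f"ID={mid};Parent={gid}")
            )
            for s, e in g["exons"]:
                out.write(_gff_line(g["chrom"], "exon", s, e, g["strand"], f"Parent={mid}"))
            for s, e in (g["cds1"], g["cds2"]):
                out.write(_gff_line(g["chrom"], "CDS", s, e, g["strand"], f"Parent={mid}"))
            s, e = g["utr5"]
            out.write(_gff_line(g["chrom"], "five_prime_UTR", s, e, g["strand"], f"Parent={mid}"))
            if g["utr3"] is not None:
                s, e = g["utr3"]
                out.write(
                    _gff_line(g["chrom"], "three_prime_UTR", s, e, g["strand"], f"Parent={mid}")
                )
    return path


def _write_tags(rng, config, outdir, genes, sites, artifacts, chrom_lens):
    n_rep = config.n_reps_per_condition
    samples = [(f"CK_{r + 1}", "CK", r + 1) for r in range(n_rep)] + [
        (f"ST_{r + 1}", "ST", r + 1) for r in range(n_rep)
    ]
    site_pos = np.array([s["pos"] for s in sites] + [a[2] for a in artifacts], dtype=int)
    site_chrom = np.array([s["chrom"] for s in sites] + [a[0] for a in artifacts], dtype=object)
    site_strand = np.array([s["strand"] for s in sites] + [a[1] for a in artifacts], dtype=object)
    jitter_sd = np.array(
        [config.jitter_sd] * len(sites) + [_ARTIFACT_JITTER] * len(artifacts)
    )
    chrom_len_arr = np.array([chrom_lens[c] for c in site_chrom], dtype=int)

    # per-gene site index ranges and share matrices
    gene_slices = []
    start = 0
    for g in genes:
        gene_slices.append((start, start + g["n_sites"]))
        start += g["n_sites"]
    share_ck = np.array([s["share_ck"] for s in sites])
    share_st = np.array([s["share_st"] for s in sites])

    beds = {}
    rows = []
    for sample_id, condition, replicate in samples:
        counts = np.zeros(len(site_pos), dtype=int)
        shares = share_ck if condition == "CK" else share_st
        for g, (a, b) in zip(genes, gene_slices):
            total = int(_rnb(rng, g["gene_mean"], config.dispersion))
            if total > 0:
                counts[a:b] = rng.multinomial(total, shares[a:b] / shares[a:b].sum()) if shares[a:b].sum() > 0 else 0
        for j in range(len(artifacts)):
            counts[len(sites) + j] = int(_rnb(rng, artifacts[j][3], config.dispersion))
        pos = np.repeat(site_pos, counts)
        sd = np.repeat(jitter_sd, counts)
        maxp = np.repeat(chrom_len_arr, counts) - 1
        jit = np.rint(rng.normal(0.0, 1.0, size=len(pos)) * sd).astype(int)
        pos = np.clip(pos + jit, 0, maxp)
        df = pd.DataFrame(
            {
                "chrom": np.repeat(site_chrom, counts),
                "start": pos,
                "end": pos + 1,
                "name": ".",
                "score": 0,
                "strand": np.repeat(site_strand, counts),
            }
        ).sort_values(["chrom", "start"], kind="stable", ignore_index=True)
        bed = os.path.join(outdir, f"{sample_id}.bed")
        df.to_csv(bed, sep="\t", header=False, index=False)
        beds[sample_id] = bed
        rows.append((sample_id, f"{sample_id}.bed", condition, replicate))

    sheet = os.path.join(outdir, "samples.tsv")
    pd.DataFrame(rows, columns=["sample_id", "path", "condition", "replicate"]).to_csv(
        sheet, sep="\t", index=False
    )
    return sheet, beds


# ---------------------------------------------------------------------------
# truth comparison


def match_pacs(pacs, sites: pd.DataFrame, tolerance_nt: int = 24) -> dict:
    """PAC-level precision/recall: summit within tolerance of a true site."""
    true_by_key: dict[tuple, np.ndarray] = {
        key: grp["pos"].to_numpy()
        for key, grp in sites.groupby(["chrom", "strand"])
    }
    called_by_key: dict[tuple, list[int]] = {}
    for p in pacs:
        called_by_key.setdefault((p.chrom, p.strand), []).append(p.summit)
    n_called = len(pacs)
    tp_called = 0
    for key, summits in called_by_key.items():
        truth = true_by_key.get(key)
        if truth is None:
            continue
        truth = np.sort(truth)
        for s in summits:
            i = np.searchsorted(truth, s)
            near = [truth[j] for j in (i - 1, i) if 0 <= j < len(truth)]
            if near and min(abs(s - t) for t in near) <= tolerance_nt:
                tp_called += 1
    n_true = len(sites)
    tp_true = 0
    for key, grp_pos in true_by_key.items():
        called = np.sort(np.array(called_by_key.get(key, []), dtype=int))
        for t in grp_pos:
            if len(called) == 0:
                continue
            i = np.searchsorted(called, t)
            near = [called[j] for j in (i - 1, i) if 0 <= j < len(called)]
            if near and min(abs(int(t) - int(c)) for c in near) <= tolerance_nt:
                tp_true += 1
    return {
        "n_called": n_called,
        "n_true": n_true,
        "precision": tp_called / n_called if n_called else 0.0,
        "recall": tp_true / n_true if n_true else 0.0,
    }


def _set_confusion(called: set, planted: set) -> dict:
    tp = len(called & planted)
    return {
        "n_called": len(called),
        "n_planted": len(planted),
        "n_true_positive": tp,
        "n_false_positive": len(called - planted),
        "recall": tp / len(planted) if planted else 1.0,
        "precision": tp / len(called) if called else 1.0,
    }


def truth_compare(result, truth: GroundTruth, tolerance_nt: int = 24) -> dict:
    """Score a pipeline run against the planted truth.

    ``result`` is a pipeline RunResult (pacs, apa_table, utr_table,
    events).  Each gene carries one planted label, and event classes are
    not mutually exclusive in the calls themselves (a gene that moves
    usage between PACs at constant expression satisfies the switching
    definition literally, and every planted event shifts usage), so each
    confusion is scored over the genes whose label can discriminate it:
    3' UTR classes over genes planted LENGTHEN / SHORTEN / NULL,
    switching false calls over genes planted SWITCH / NULL, and
    specific-PAC precision against all planted ST-only sites (dedicated
    specific sites plus inducible genes' induced sites) with recall over
    the dedicated specific sites.
    """
    out: dict = {"pac": match_pacs(result.pacs, truth.sites, tolerance_nt)}

    genes = truth.genes
    true_apa = set(genes.loc[genes["n_true_pacs"] > 1, "gene_id"])
    apa = result.apa_table
    called_apa = set(apa.loc[apa["is_apa"], "gene_id"]) if len(apa) else set()
    out["apa_fraction_true"] = len(true_apa) / len(genes)
    out["apa_fraction_called"] = len(called_apa) / len(genes)

    label_of = genes.set_index("gene_id")["label"]
    ls_pool = set(genes.loc[genes["label"].isin(["LENGTHEN", "SHORTEN", "NULL"]), "gene_id"])
    utr = result.utr_table
    out["utr_classes"] = {}
    for cls in ("LENGTHEN", "SHORTEN"):
        planted = set(genes.loc[genes["label"] == cls, "gene_id"])
        called = (
            set(utr.loc[(utr["cls"] == cls) & utr["gene_id"].isin(ls_pool), "gene_id"])
            if len(utr)
            else set()
        )
        out["utr_classes"][cls] = _set_confusion(called, planted)

    planted_switch = set(genes.loc[genes["label"] == "SWITCH", "gene_id"])
    switch_pool = planted_switch | set(genes.loc[genes["label"] == "NULL", "gene_id"])
    called_switch = (
        set(result.events.switching["gene_id"]) if len(result.events.switching) else set()
    )
    out["switching"] = _set_confusion(called_switch & switch_pool, planted_switch)

    spec_sites = truth.sites[truth.sites["site_label"] == "SPECIFIC_ST"]
    st_only_sites = truth.sites[truth.sites["site_label"].isin(["SPECIFIC_ST", "INDUCED"])]
    called_spec = [
        p for p in result.pacs if p.pac_id in set(result.events.specific["pac_id"])
    ]
    out["specific"] = {
        "n_called": len(called_spec),
        "recall": match_pacs(called_spec, spec_sites, tolerance_nt)["recall"],
        "precision": match_pacs(called_spec, st_only_sites, tolerance_nt)["precision"],
    }

    planted_ind = set(genes.loc[genes["label"] == "INDUCIBLE", "gene_id"])
    called_ind = (
        set(result.events.inducible["gene_id"]) if len(result.events.inducible) else set()
    )
    out["inducible"] = _set_confusion(called_ind, planted_ind)

    out["label_of_called_switch_fp"] = sorted(
        label_of.get(g, "?") for g in called_switch - planted_switch
    )
    return out
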