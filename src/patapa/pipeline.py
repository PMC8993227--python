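"""End-to-end orchestration: tags -> PACs -> DE -> 3' UTR dynamics -> events.

``run_all`` executes the fixed stage order and writes every summary table
the report needs: PAC/gene totals and APA ratios (overall and per
condition), the PAC region distribution, DE-PAC / DE gene / DE-APA counts
with overlaps, 3' UTR class and quadrant counts, and APA event counts —
each as TSV plus one human-readable summary.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import pandas as pd
import yaml

from . import apa_events, de_stats, io_formats, pac_calling, utr_dynamics
from .pac_calling import CallingParams

logger = logging.getLogger(__name__)

_FORMAT_BY_EXT = {".bed": "bed", ".sam": "sam", ".bam": "bam"}


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    genome: str
    gff3: str
    samples: str
    outdir: str
    params: CallingParams = field(default_factory=CallingParams)
    ext_bp: int = 200
    fallback_bp: int = 218
    min_mapq: int = 10
    alpha: float = 0.05
    min_total: int = 10
    homolog_map: str | None = None
    other_lengthen_genes: str | None = None
    write_coverage: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        params = CallingParams(**raw.pop("params", {}))
        cfg = cls(params=params, **raw)
        for p in (cfg.genome, cfg.gff3, cfg.samples):
            if not os.path.exists(p):
                raise FileNotFoundError(p)
        return cfg

    def to_yaml(self, path: str) -> None:
        raw = {
            k: v for k, v in vars(self).items() if k != "params" and v is not None
        }
        raw["params"] = vars(self.params)
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=True)


@dataclass
class RunResult:
    pacs: list
    apa_table: pd.DataFrame
    pac_matrix: de_stats.PACMatrix
    de_pac: pd.DataFrame
    de_gene: pd.DataFrame
    utr_summary: dict
    utr_table: pd.DataFrame
    events: apa_events.APAEventSet
    report: dict


def _call_pacs(tags, genes, params, require_filtered=True):
    pacs = pac_calling.cluster_tags(tags, params, require_filtered=require_filtered)
    pacs = pac_calling.assign_pacs(pacs, genes)
    return pac_calling.filter_min_support(pacs, params)


def run_all(config: RunConfig) -> RunResult:
    """Run every stage and write the report into ``config.outdir``."""
    os.makedirs(config.outdir, exist_ok=True)
    config.to_yaml(os.path.join(config.outdir, "run_config.yaml"))
    _setup_logging(config.outdir)

    stage = "load_inputs"
    try:
        genome = io_formats.GenomeSeq.from_fasta(config.genome)
        genes = io_formats.read_annotation(config.gff3, config.ext_bp, config.fallback_bp)
        sheet = io_formats.read_sample_sheet(config.samples)
        tags_by_sample = {}
        for entry in sheet.entries:
            fmt = _FORMAT_BY_EXT.get(os.path.splitext(entry.path)[1].lower())
            if fmt is None:
                raise ValueError(f"cannot infer tag format of {entry.path}")
            tags_by_sample[entry.sample_id] = io_formats.read_tags(
                entry.path, fmt, entry.sample_id, config.min_mapq
            )

        stage = "internal_priming_filter"
        all_tags = [t for ts in tags_by_sample.values() for t in ts]
        kept, removed = pac_calling.filter_internal_priming(all_tags, genome, config.params)
        if config.write_coverage:
            cov_dir = os.path.join(config.outdir, "coverage")
            os.makedirs(cov_dir, exist_ok=True)
            for sid in sheet.sample_ids:
                io_formats.write_coverage(
                    [t for t in kept if t.sample_id == sid],
                    sid,
                    os.path.join(cov_dir, f"{sid}.bedgraph"),
                )

        stage = "pac_calling"
        pacs = _call_pacs(kept, genes, config.params)
        io_formats.write_pacs(
            pacs,
            os.path.join(config.outdir, "pacs.bed"),
            os.path.join(config.outdir, "pacs.tsv"),
            sheet.sample_ids,
        )
        apa_table = pac_calling.apa_gene_table(pacs)

        stage = "differential_expression"
        mat = de_stats.PACMatrix.from_pacs(pacs, sheet)
        de_pac = de_stats.nb_test(mat, alpha=config.alpha)
        gene_mat = de_stats.gene_expression(mat)
        de_gene = de_stats.nb_test(gene_mat, alpha=config.alpha)
        de_pac.to_csv(os.path.join(config.outdir, "de_pac.tsv"), sep="\t", index=False)
        de_gene.to_csv(os.path.join(config.outdir, "de_gene.tsv"), sep="\t", index=False)

        stage = "utr_dynamics"
        lengths = utr_dynamics.pac_utr_lengths(pacs, genes)
        dyn = utr_dynamics.compute_utr_dynamics(mat, lengths)
        utr_summary, utr_table = utr_dynamics.classify_genes(dyn, config.alpha, de_gene)
        utr_table.to_csv(os.path.join(config.outdir, "utr.tsv"), sep="\t", index=False)

        stage = "apa_events"
        events = apa_events.call_events(
            de_pac, mat, alpha=config.alpha, min_total=config.min_total
        )
        ev_dir = os.path.join(config.outdir, "events")
        os.makedirs(ev_dir, exist_ok=True)
        events.switching.to_csv(os.path.join(ev_dir, "switching.tsv"), sep="\t", index=False)
        events.specific.to_csv(os.path.join(ev_dir, "st_specific_pacs.tsv"), sep="\t", index=False)
        events.inducible.to_csv(os.path.join(ev_dir, "inducible_apa.tsv"), sep="\t", index=False)
        if config.homolog_map and config.other_lengthen_genes:
            hmap = pd.read_csv(config.homolog_map, sep="\t")
            other = set(pd.read_csv(config.other_lengthen_genes, sep="\t")["gene_id"])
            here = set(utr_table.loc[utr_table["cls"] == "LENGTHEN", "gene_id"])
            events.overlap = apa_events.homolog_overlap(here, other, hmap)

        stage = "report"
        report = _build_report(
            config, sheet, genes, kept, tags_by_sample, pacs, apa_table,
            de_pac, de_gene, utr_summary, utr_table, events,
        )
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001 - stage attribution is the contract
        raise StageError(stage, exc) from exc

    return RunResult(
        pacs=pacs,
        apa_table=apa_table,
        pac_matrix=mat,
        de_pac=de_pac,
        de_gene=de_gene,
        utr_summary=utr_summary,
        utr_table=utr_table,
        events=events,
        report=report,
    )


def _setup_logging(outdir: str) -> None:
    handler = logging.FileHandler(os.path.join(outdir, "run.log"), mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("patapa")
    root.addHandler(handler)
    root.setLevel(logging.INFO)


def _build_report(
    config, sheet, genes, kept_tags, tags_by_sample, pacs, apa_table,
    de_pac, de_gene, utr_summary, utr_table, events,
) -> dict:
    out = config.outdir

    region_counts = pd.Series([p.region for p in pacs]).value_counts().sort_index()
    region_df = region_counts.rename_axis("region").reset_index(name="n_pacs")
    # extension-recovered PACs pool with UTR3 for the headline ratio
    utr3_like = int(region_counts.get("UTR3", 0) + region_counts.get("EXTENDED_UTR3", 0))
    region_df.to_csv(os.path.join(out, "region_distribution.tsv"), sep="\t", index=False)

    apa_rows = [_apa_ratio_row("ALL", pacs)]
    for cond in sheet.conditions:
        cond_samples = set(sheet.samples_for(cond))
        cond_tags = [t for t in kept_tags if t.sample_id in cond_samples]
        cond_pacs = _call_pacs(cond_tags, genes, config.params)
        apa_rows.append(_apa_ratio_row(cond, cond_pacs))
    apa_df = pd.DataFrame(apa_rows)
    apa_df.to_csv(os.path.join(out, "apa_ratio_by_condition.tsv"), sep="\t", index=False)

    de_genes = set(de_gene.loc[de_gene["is_de"], "unit_id"])
    pac_per_gene = apa_table.set_index("gene_id")["n_pacs"]
    de_pac_genes = {
        g for g in de_pac.loc[de_pac["is_de"], "gene_id"] if isinstance(g, str) and g != "."
    }
    de_apa_genes = {g for g in de_pac_genes if pac_per_gene.get(g, 0) > 1}
    overlaps = de_stats.overlap_sets(de_genes, de_pac_genes, de_apa_genes)
    de_df = pd.DataFrame(
        [
            {"set": "DE_genes", "n": len(de_genes)},
            {"set": "DE_PAC_genes", "n": len(de_pac_genes)},
            {"set": "DE_APA_genes", "n": len(de_apa_genes)},
            {"set": "DE_genes_and_DE_PAC_genes", "n": overlaps["de_gene_vs_de_pac"]["n_intersection"]},
            {"set": "DE_genes_and_DE_APA_genes", "n": overlaps["de_gene_vs_de_apa"]["n_intersection"]},
        ]
    )
    de_df.to_csv(os.path.join(out, "de_overlap.tsv"), sep="\t", index=False)

    cls_rows = [
        {"class": k, "n": v} for k, v in utr_summary.items()
    ]
    pd.DataFrame(cls_rows).to_csv(os.path.join(out, "utr_classes.tsv"), sep="\t", index=False)

    ev_df = pd.DataFrame(
        [
            {"event": "switching_genes", "n": events.switching["gene_id"].nunique() if len(events.switching) else 0},
            {"event": "st_specific_pacs", "n": len(events.specific)},
            {"event": "st_specific_pac_genes", "n": events.specific["gene_id"].nunique() if len(events.specific) else 0},
            {"event": "inducible_apa_genes", "n": len(events.inducible)},
        ]
    )
    ev_df.to_csv(os.path.join(out, "event_counts.tsv"), sep="\t", index=False)

    report = {
        "n_tags_kept": len(kept_tags),
        "n_pacs": len(pacs),
        "n_genes_with_pacs": int(len(apa_table)),
        "apa_gene_fraction": float(apa_table["is_apa"].mean()) if len(apa_table) else 0.0,
        "utr3_pac_fraction": utr3_like / len(pacs) if pacs else 0.0,
        "region_distribution": {r.region: int(r.n_pacs) for r in region_df.itertuples()},
        "apa_ratio_by_condition": {r["subset"]: r["apa_fraction"] for r in apa_rows},
        "n_de_pacs": int(de_pac["is_de"].sum()),
        "n_de_genes": len(de_genes),
        "n_de_pac_genes": len(de_pac_genes),
        "n_de_apa_genes": len(de_apa_genes),
        "overlaps": overlaps,
        "utr_summary": utr_summary,
        "events": {r.event: int(r.n) for r in ev_df.itertuples()},
    }
    _write_summary_text(os.path.join(out, "summary.txt"), report)
    return report


def _apa_ratio_row(subset, pacs) -> dict:
    tab = pac_calling.apa_gene_table(pacs)
    return {
        "subset": subset,
        "n_pacs": len(pacs),
        "n_genes": int(len(tab)),
        "n_apa_genes": int(tab["is_apa"].sum()) if len(tab) else 0,
        "apa_fraction": float(tab["is_apa"].mean()) if len(tab) else 0.0,
    }


def _write_summary_text(path: str, report: dict) -> None:
    lines = [
        "patapa run summary",
        "==================",
        f"tags kept after internal-priming filter: {report['n_tags_kept']}",
        f"PACs called: {report['n_pacs']}",
        f"genes with >=1 PAC: {report['n_genes_with_pacs']}",
        f"APA gene fraction (>1 PAC): {report['apa_gene_fraction']:.3f}",
        f"PAC fraction in 3' UTR (incl. extension): {report['utr3_pac_fraction']:.3f}",
        "region distribution: "
        + ", ".join(f"{k}={v}" for k, v in report["region_distribution"].items()),
        f"DE PACs: {report['n_de_pacs']}; DE genes: {report['n_de_genes']}; "
        f"DE-PAC genes: {report['n_de_pac_genes']}; DE-APA genes: {report['n_de_apa_genes']}",
        "3' UTR classes: "
        + ", ".join(f"{k}={v}" for k, v in report["utr_summary"].items()),
        "events: " + ", ".join(f"{k}={v}" for k, v in report["events"].items()),
    ]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
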