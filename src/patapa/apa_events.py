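"""APA event calls: switching genes, condition-specific PACs, and
condition-inducible APA genes, plus homolog-based overlap of event gene
sets between two analyses (e.g. two species).

Definitions
-----------
switching gene
    a gene with at least one significantly upregulated PAC and at least
    one significantly downregulated PAC (padj < alpha, opposite log2fc
    signs) — the transcript output shifts between poly(A) sites.
condition-specific PAC
    zero tags in every sample of the other condition and at least
    ``min_total`` tags in the named condition (strict-zero rule;
    ``max_other`` relaxes it).
condition-inducible APA gene
    at most one expressed PAC in the control condition but two or more
    under treatment ("expressed" = pooled count >= min_total in that
    condition).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .de_stats import PACMatrix


@dataclass
class APAEventSet:
    switching: pd.DataFrame = field(default_factory=pd.DataFrame)
    specific: pd.DataFrame = field(default_factory=pd.DataFrame)
    inducible: pd.DataFrame = field(default_factory=pd.DataFrame)
    overlap: dict | None = None


def call_switching(de_pac: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Switching genes from a PAC-level DE table with gene_id metadata.

    Returns one row per (up PAC, down PAC) pair within a gene; a gene may
    contribute several pairs.
    """
    required = {"unit_id", "gene_id", "log2fc", "padj"}
    if not required.issubset(de_pac.columns):
        raise ValueError(f"call_switching needs columns {sorted(required)}")
    sig = de_pac[(de_pac["padj"] < alpha) & (de_pac["gene_id"].notna()) & (de_pac["gene_id"] != ".")]
    rows = []
    for gene_id, grp in sig.groupby("gene_id"):
        ups = grp[grp["log2fc"] > 0]
        downs = grp[grp["log2fc"] < 0]
        for u in ups.itertuples(index=False):
            for d in downs.itertuples(index=False):
                rows.append(
                    {
                        "gene_id": gene_id,
                        "up_pac": u.unit_id,
                        "down_pac": d.unit_id,
                        "up_log2fc": u.log2fc,
                        "down_log2fc": d.log2fc,
                    }
                )
    return pd.DataFrame(rows, columns=["gene_id", "up_pac", "down_pac", "up_log2fc", "down_log2fc"])


def call_specific_pacs(
    mat: PACMatrix,
    condition: str = "ST",
    min_total: int = 10,
    max_other: int = 0,
) -> pd.DataFrame:
    """PACs expressed only in ``condition``.

    A PAC qualifies when its pooled raw count in the other condition is
    <= ``max_other`` (default 0, i.e. literally never observed there)
    and its pooled count in ``condition`` is >= ``min_total``.
    """
    conds = mat.conditions
    if condition not in conds:
        raise ValueError(f"condition {condition!r} not in design {conds}")
    other = [c for c in conds if c != condition]
    if len(other) != 1:
        raise ValueError("call_specific_pacs requires a two-condition design")
    tot_cond = mat.counts[mat.samples_for(condition)].sum(axis=1)
    tot_other = mat.counts[mat.samples_for(other[0])].sum(axis=1)
    mask = (tot_other <= max_other) & (tot_cond >= min_total)
    out = pd.DataFrame(
        {
            "pac_id": mat.counts.index[mask],
            "condition": condition,
            "total_in_condition": tot_cond[mask].to_numpy(dtype=int),
            "total_in_other": tot_other[mask].to_numpy(dtype=int),
        }
    )
    if mat.meta is not None:
        out["gene_id"] = mat.meta.loc[out["pac_id"], "gene_id"].to_numpy()
    return out.reset_index(drop=True)


def expressed_pac_counts(mat: PACMatrix, min_total: int = 10) -> pd.DataFrame:
    """Per gene and condition, the number of expressed PACs.

    Expressed means a pooled raw count >= min_total in that condition;
    a PAC with zero tags is never expressed, so min_total 0 degrades to
    "any tag at all".
    """
    if mat.meta is None:
        raise ValueError("expressed_pac_counts requires PAC meta with gene_id")
    usable = (mat.meta["gene_id"] != ".") & (mat.meta["region"] != "INTERGENIC")
    gene_ids = mat.meta.loc[usable, "gene_id"]
    floor = max(min_total, 1)
    rows = {}
    for cond in mat.conditions:
        tot = mat.counts.loc[usable.index[usable], mat.samples_for(cond)].sum(axis=1)
        rows[cond] = (tot >= floor).groupby(gene_ids).sum()
    return pd.DataFrame(rows).fillna(0).astype(int)


def call_inducible_apa(
    mat: PACMatrix,
    min_total: int = 10,
    control: str = "CK",
    treatment: str = "ST",
) -> pd.DataFrame:
    """Genes using <= 1 PAC under control but >= 2 under treatment."""
    tab = expressed_pac_counts(mat, min_total=min_total)
    mask = (tab[control] <= 1) & (tab[treatment] >= 2)
    out = tab[mask].reset_index().rename(
        columns={"gene_id": "gene_id", control: f"n_expressed_{control}", treatment: f"n_expressed_{treatment}"}
    )
    return out


def homolog_overlap(
    set_a: set[str],
    set_b: set[str],
    homolog_map: pd.DataFrame,
) -> dict:
    """Overlap of two gene sets through a many-to-many homolog pairing.

    ``homolog_map`` has columns gene_a, gene_b.  Reports genes in A with
    at least one homolog in B's set (and vice versa), and the number of
    homolog pairs with both members present.  Genes absent from the map
    count as non-overlapping.
    """
    if not {"gene_a", "gene_b"}.issubset(homolog_map.columns):
        raise ValueError("homolog_map needs columns gene_a, gene_b")
    pairs = homolog_map[["gene_a", "gene_b"]].drop_duplicates()
    both = pairs[pairs["gene_a"].isin(set_a) & pairs["gene_b"].isin(set_b)]
    a_hit = set(both["gene_a"])
    b_hit = set(both["gene_b"])
    return {
        "n_a": len(set_a),
        "n_b": len(set_b),
        "n_a_with_homolog_in_b": len(a_hit),
        "n_b_with_homolog_in_a": len(b_hit),
        "n_shared_pairs": len(both),
    }


def call_events(
    de_pac: pd.DataFrame,
    mat: PACMatrix,
    alpha: float = 0.05,
    min_total: int = 10,
    condition: str = "ST",
) -> APAEventSet:
    """All event classes in one pass (convenience wrapper for the pipeline)."""
    return APAEventSet(
        switching=call_switching(de_pac, alpha=alpha),
        specific=call_specific_pacs(mat, condition=condition, min_total=min_total),
        inducible=call_inducible_apa(mat, min_total=min_total),
    )
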