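"""Usage-weighted 3' UTR length dynamics between conditions.

For every gene with at least two PACs in its 3' UTR (annotated UTR plus
the downstream rescue extension), the module computes usage-weighted 3'
UTR lengths per condition, a Pearson direction statistic r (r > 0 means
the 3' UTR lengthens under treatment, r < 0 means it shortens), and a
chi-square test of the condition-by-PAC usage table.  Genes are classed
LENGTHEN / SHORTEN / UNCHANGED after BH adjustment of the chi-square
p-values across all eligible genes.

The weighted-length and direction statistics are this package's explicit
operationalization: 3' UTR length is measured from the stop-codon-adjacent
3' UTR start to the PAC summit, and r correlates per-sample weighted
lengths with a 0/1 condition indicator across samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .de_stats import PACMatrix, bh_adjust

UTR_REGIONS = ("UTR3", "EXTENDED_UTR3")
_MC_REPS = 2000
_MC_SEED = 715  # internal seed for the Monte-Carlo chi-square fallback


def weighted_utr_length(lengths, usage) -> float:
    """Usage-weighted mean 3' UTR length, sum_i usage_i * length_i (nt).

    ``usage`` must be non-negative and sum to 1 (within 1e-9).
    """
    lengths = np.asarray(lengths, dtype=float)
    usage = np.asarray(usage, dtype=float)
    if (usage < 0).any() or abs(usage.sum() - 1.0) > 1e-9:
        raise ValueError("usage shares must be non-negative and sum to 1")
    return float(usage @ lengths)


def direction_statistic(
    counts: pd.DataFrame,
    lengths: np.ndarray,
    design: pd.DataFrame,
    ref: str = "CK",
    alt: str = "ST",
) -> tuple[float, bool]:
    """Pearson r between the condition indicator and per-sample weighted length.

    Samples with zero total count for the gene are dropped.  Returns
    (r, degenerate); degenerate is True when either side has zero
    variance (r is then 0 by convention).
    """
    wul = []
    indicator = []
    for s in counts.columns:
        total = counts[s].sum()
        if total == 0:
            continue
        wul.append(float((counts[s] / total) @ lengths))
        indicator.append(0.0 if design.loc[s, "condition"] == ref else 1.0)
    wul = np.asarray(wul)
    indicator = np.asarray(indicator)
    if len(wul) < 2 or np.ptp(wul) == 0 or np.ptp(indicator) == 0:
        return 0.0, True
    r = float(stats.pearsonr(indicator, wul).statistic)
    return r, False


def chi_square_shift(
    gene_counts_ck,
    gene_counts_st,
    mc_reps: int = _MC_REPS,
    seed: int = _MC_SEED,
) -> tuple[float, float]:
    """Pearson chi-square on the 2 x k condition-by-PAC usage table.

    Columns (PACs) with zero totals are required absent; k must be >= 2.
    When any expected cell is below 5 the asymptotic p-value is replaced
    by a Monte-Carlo one (tables resampled under independence with the
    observed row totals and pooled column proportions; fixed internal
    seed for determinism).
    """
    table = np.asarray([gene_counts_ck, gene_counts_st], dtype=float)
    if table.shape[1] < 2:
        raise ValueError("chi_square_shift needs at least two PACs")
    if (table.sum(axis=0) == 0).any():
        raise ValueError("every PAC column must have a positive pooled total")
    stat, p, _, expected = stats.chi2_contingency(table, correction=False)
    if (expected < 5).any():
        p = _mc_pvalue(table, float(stat), mc_reps, seed)
    return float(stat), float(p)


def _mc_pvalue(table: np.ndarray, observed: float, reps: int, seed: int) -> float:
    rng = np.random.default_rng(seed)
    row_tot = table.sum(axis=1).astype(int)
    col_p = table.sum(axis=0) / table.sum()
    sims = np.stack(
        [rng.multinomial(n, col_p, size=reps) for n in row_tot], axis=1
    ).astype(float)  # (reps, 2, k)
    exp = (
        sims.sum(axis=2, keepdims=True)
        * sims.sum(axis=1, keepdims=True)
        / sims.sum(axis=(1, 2), keepdims=True)
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        stats_sim = np.nansum(np.square(sims - exp) / exp, axis=(1, 2))
    return float((1 + np.sum(stats_sim >= observed - 1e-12)) / (1 + reps))


@dataclass
class UTRDynamics:
    """Per-gene 3' UTR dynamics record (one row of the results table)."""

    gene_id: str
    n_utr_pacs: int
    wul_ck: float
    wul_st: float
    r: float
    r_degenerate: bool
    chi2_stat: float
    chi2_p: float


def compute_utr_dynamics(
    mat: PACMatrix,
    utr_lengths: pd.Series,
    ref: str = "CK",
    alt: str = "ST",
) -> pd.DataFrame:
    """Per-gene weighted-length, direction and chi-square statistics.

    ``mat`` is the PAC-level matrix with gene_id/region meta;
    ``utr_lengths`` maps pac_id -> 3' UTR length (nt, summit-anchored).
    Only genes with >= 2 PACs in UTR3/EXTENDED_UTR3 are eligible; a gene
    with zero counts in one condition is flagged and excluded.
    """
    if mat.meta is None:
        raise ValueError("compute_utr_dynamics requires PAC meta")
    meta = mat.meta
    in_utr = meta["region"].isin(UTR_REGIONS) & (meta["gene_id"] != ".")
    ck_cols = mat.samples_for(ref)
    st_cols = mat.samples_for(alt)
    records: list[UTRDynamics] = []
    for gene_id, pac_ids in meta.index[in_utr].groupby(meta.loc[in_utr, "gene_id"]).items():
        if len(pac_ids) < 2:
            continue
        counts = mat.counts.loc[pac_ids]
        lengths = utr_lengths.loc[pac_ids].to_numpy(dtype=float)
        tot_ck = counts[ck_cols].sum(axis=1).to_numpy(dtype=float)
        tot_st = counts[st_cols].sum(axis=1).to_numpy(dtype=float)
        if tot_ck.sum() == 0 or tot_st.sum() == 0:
            continue  # weighted length undefined in one condition
        keep = (tot_ck + tot_st) > 0
        if keep.sum() < 2:
            continue
        tot_ck, tot_st, lengths = tot_ck[keep], tot_st[keep], lengths[keep]
        counts = counts.loc[np.asarray(pac_ids)[keep]]
        wul_ck = weighted_utr_length(lengths, tot_ck / tot_ck.sum())
        wul_st = weighted_utr_length(lengths, tot_st / tot_st.sum())
        r, degen = direction_statistic(counts, lengths, mat.design, ref, alt)
        stat, p = chi_square_shift(tot_ck, tot_st)
        records.append(
            UTRDynamics(gene_id, int(keep.sum()), wul_ck, wul_st, r, degen, stat, p)
        )
    return pd.DataFrame([vars(rec) for rec in records])


def classify_genes(
    dynamics: pd.DataFrame,
    alpha: float = 0.05,
    gene_de: pd.DataFrame | None = None,
) -> tuple[dict, pd.DataFrame]:
    """Class labels and summary counts after BH adjustment across genes.

    LENGTHEN iff r > 0 and chi2_padj < alpha; SHORTEN iff r < 0 and
    chi2_padj < alpha; UNCHANGED otherwise.  When a gene-level DE table
    is supplied its log2fc is joined so length-by-expression quadrant
    counts (e.g. lengthen-and-up) can be reported.
    """
    table = dynamics.copy()
    if table.empty:
        summary = {"n_lengthen": 0, "n_shorten": 0, "n_unchanged": 0, "n_eligible": 0}
        return summary, table.assign(chi2_padj=[], cls=[])
    table["chi2_padj"] = bh_adjust(table["chi2_p"])
    sig = table["chi2_padj"] < alpha
    table["cls"] = np.select(
        [sig & (table["r"] > 0), sig & (table["r"] < 0)],
        ["LENGTHEN", "SHORTEN"],
        default="UNCHANGED",
    )
    if gene_de is not None:
        fc = gene_de.set_index("unit_id")["log2fc"]
        table["log2fc"] = table["gene_id"].map(fc)
    summary = {
        "n_lengthen": int((table["cls"] == "LENGTHEN").sum()),
        "n_shorten": int((table["cls"] == "SHORTEN").sum()),
        "n_unchanged": int((table["cls"] == "UNCHANGED").sum()),
        "n_eligible": int(len(table)),
    }
    if "log2fc" in table.columns:
        for cls in ("LENGTHEN", "SHORTEN"):
            sub = table[table["cls"] == cls]
            summary[f"n_{cls.lower()}_up"] = int((sub["log2fc"] > 0).sum())
            summary[f"n_{cls.lower()}_down"] = int((sub["log2fc"] < 0).sum())
    return summary, table


def pac_utr_lengths(pacs, genes) -> pd.Series:
    """3' UTR length (nt) of each UTR3/EXTENDED_UTR3 PAC, summit-anchored."""
    by_id = {g.gene_id: g for g in genes}
    out = {}
    for p in pacs:
        if p.region in UTR_REGIONS and p.gene_id in by_id:
            out[p.pac_id] = by_id[p.gene_id].utr3_length_to(p.summit)
    return pd.Series(out, name="utr3_length", dtype=float)
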