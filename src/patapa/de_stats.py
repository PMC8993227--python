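"""Differential expression of PACs and genes between two conditions.

Implements the two load-bearing ideas of the standard count-based DE
workflow: median-of-ratios normalization and a negative-binomial two-group
test with Benjamini-Hochberg adjustment.  Log2 fold changes are not
shrunk and no dispersion trend is fitted, so exact numerical parity with
full-featured DE engines is out of scope by design.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

DISPERSION_FLOOR = 1e-8
_PSEUDO_MEAN = 0.5  # pseudo-mean stabilising log-fold-changes at zero counts
_DISPERSION_PRIOR_DF = 10.0  # weight of the across-unit prior in the squeeze


@dataclass
class PACMatrix:
    """Unit-by-sample count matrix with its two-condition design.

    ``counts`` rows are PACs (or genes), columns are samples; ``design``
    is indexed by sample_id with columns condition and replicate.
    ``meta`` optionally carries per-unit gene_id and region labels.
    """

    counts: pd.DataFrame
    design: pd.DataFrame
    meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if list(self.counts.columns) != list(self.design.index):
            self.design = self.design.loc[self.counts.columns]
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def conditions(self) -> list[str]:
        return sorted(self.design["condition"].unique())

    def samples_for(self, condition: str) -> list[str]:
        return list(self.design.index[self.design["condition"] == condition])

    @classmethod
    def from_pacs(cls, pacs: Sequence, sample_sheet) -> "PACMatrix":
        from .io_formats import pacs_to_frame

        df = pacs_to_frame(pacs, sample_sheet.sample_ids)
        counts = df.set_index("pac_id")[sample_sheet.sample_ids].astype(int)
        meta = df.set_index("pac_id")[["gene_id", "region"]]
        return cls(counts=counts, design=sample_sheet.design_frame(), meta=meta)


def normalize_median_of_ratios(
    mat: PACMatrix,
) -> tuple[pd.Series, pd.DataFrame]:
    """Median-of-ratios size factors and the normalized count matrix.

    The reference per unit is the geometric mean across samples over
    units observed in every sample; each sample's size factor is the
    median of its counts over those references.  If no unit is positive
    in all samples, the geometric means fall back to positive entries
    only (computed over each unit's nonzero samples).
    """
    counts = mat.counts.to_numpy(dtype=float)
    if counts.sum() == 0:
        raise ValueError("cannot normalize an all-zero count matrix")
    with np.errstate(divide="ignore"):
        logc = np.log(counts)
    all_pos = np.all(counts > 0, axis=1)
    if all_pos.any():
        ref = np.exp(logc[all_pos].mean(axis=1))
        use = counts[all_pos]
    else:
        npos = (counts > 0).sum(axis=1)
        any_pos = npos > 0
        ref = np.exp(np.where(logc[any_pos] > -np.inf, logc[any_pos], 0.0).sum(axis=1) / npos[any_pos])
        use = counts[any_pos]
    ratios = use / ref[:, None]
    sf = np.array([np.median(col[col > 0]) for col in ratios.T])
    size_factors = pd.Series(sf, index=mat.counts.columns, name="size_factor")
    normalized = mat.counts / size_factors
    return size_factors, normalized


def bh_adjust(pvalues: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (step-up FDR)."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def _pooled_dispersion(norm: np.ndarray, groups: list[np.ndarray]) -> np.ndarray:
    """Per-unit NB dispersion: pooled method of moments, squeezed across units.

    Within each condition the moment estimate is a = (var - mean)/mean^2;
    estimates are pooled across conditions by residual df.  With few
    replicates the per-unit estimate is extremely noisy (4 df at 3 + 3),
    so it is squeezed toward the median positive estimate across units
    with a prior weight of ``_DISPERSION_PRIOR_DF`` pseudo-df — the
    moderation strategy count-based DE packages rely on.  The result is
    floored at ``DISPERSION_FLOOR``.
    """
    num = np.zeros(norm.shape[0])
    den = np.zeros(norm.shape[0])
    for cols in groups:
        x = norm[:, cols]
        n = x.shape[1]
        if n < 2:
            continue
        m = x.mean(axis=1)
        v = x.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            a = np.where(m > 0, (v - m) / np.square(m), 0.0)
        num += (n - 1) * a
        den += n - 1
    disp = np.where(den > 0, num / np.maximum(den, 1), 0.0)
    positive = disp[disp > 0]
    prior = float(np.median(positive)) if positive.size else 0.0
    disp = (disp * den + prior * _DISPERSION_PRIOR_DF) / (den + _DISPERSION_PRIOR_DF)
    return np.maximum(disp, DISPERSION_FLOOR)


def nb_test(mat: PACMatrix, alpha: float = 0.05) -> pd.DataFrame:
    """Two-group NB Wald-type test of log2 fold change (ST vs CK) per unit.

    Group means of normalized counts are the NB mean estimates; the Wald
    statistic uses the delta-method variance of the log ratio,
    (1/mu + a)/n per group with squeezed dispersion a, referred to a
    moderated t distribution whose df combine the residual df with the
    dispersion prior's pseudo-df.  Units whose dispersion sits at the
    floor are tested
    instead with the exact conditional Poisson (binomial) test on raw
    counts with size-factor offsets.  P-values are BH-adjusted over all
    tested units.
    """
    conditions = mat.conditions
    if len(conditions) != 2:
        raise ValueError("nb_test requires exactly two conditions")
    ref, alt = conditions
    if set(conditions) == {"CK", "ST"}:
        ref, alt = "CK", "ST"
    cols = list(mat.counts.columns)
    idx_ref = np.array([cols.index(s) for s in mat.samples_for(ref)])
    idx_alt = np.array([cols.index(s) for s in mat.samples_for(alt)])
    if len(idx_ref) < 2 or len(idx_alt) < 2:
        raise ValueError("need >= 2 replicates per condition")

    size_factors, norm_df = normalize_median_of_ratios(mat)
    raw = mat.counts.to_numpy(dtype=float)
    nonzero = raw.sum(axis=1) > 0
    units = mat.counts.index[nonzero]
    norm = norm_df.to_numpy(dtype=float)[nonzero]
    raw = raw[nonzero]

    disp = _pooled_dispersion(norm, [idx_ref, idx_alt])
    m_ref = norm[:, idx_ref].mean(axis=1)
    m_alt = norm[:, idx_alt].mean(axis=1)
    n_ref, n_alt = len(idx_ref), len(idx_alt)

    log2fc = np.log2((m_alt + _PSEUDO_MEAN) / (m_ref + _PSEUDO_MEAN))
    beta = np.log((m_alt + _PSEUDO_MEAN) / (m_ref + _PSEUDO_MEAN))
    se2 = (1.0 / (m_ref + _PSEUDO_MEAN) + disp) / n_ref + (
        1.0 / (m_alt + _PSEUDO_MEAN) + disp
    ) / n_alt
    wald = beta / np.sqrt(se2)
    # moderated-t reference: residual df plus the dispersion prior's
    # pseudo-df, reflecting the information actually behind the SE
    df_mod = (n_ref - 1) + (n_alt - 1) + _DISPERSION_PRIOR_DF
    pvals = 2.0 * stats.t.sf(np.abs(wald), df=df_mod)

    # at-floor dispersion: exact conditional Poisson (binomial) test
    at_floor = disp <= DISPERSION_FLOOR
    if at_floor.any():
        sf = size_factors.to_numpy()
        p0 = sf[idx_alt].sum() / (sf[idx_ref].sum() + sf[idx_alt].sum())
        for i in np.where(at_floor)[0]:
            k = int(raw[i, idx_alt].sum())
            n = int(raw[i].sum())
            pvals[i] = stats.binomtest(k, n, p0).pvalue

    padj = bh_adjust(pvals)
    res = pd.DataFrame(
        {
            "unit_id": units,
            "base_mean": norm.mean(axis=1),
            "log2fc": log2fc,
            "pvalue": pvals,
            "padj": padj,
            "is_de": padj < alpha,
        }
    ).reset_index(drop=True)
    if mat.meta is not None:
        res = res.merge(
            mat.meta.reset_index().rename(columns={mat.meta.index.name or "index": "unit_id"}),
            on="unit_id",
            how="left",
        )
    return res


def gene_expression(mat: PACMatrix) -> PACMatrix:
    """Collapse a PAC matrix to gene level by summing each gene's PAC counts.

    Gene expression is the total tag count over the gene's PACs;
    intergenic PACs are excluded and AMB PACs contribute to their
    assigned gene when one is set.
    """
    if mat.meta is None or "gene_id" not in mat.meta.columns:
        raise ValueError("gene_expression requires PAC meta with gene_id")
    meta = mat.meta
    usable = (meta["gene_id"] != ".") & (meta["region"] != "INTERGENIC")
    counts = mat.counts.loc[usable.index[usable]]
    gene_counts = counts.groupby(meta.loc[usable, "gene_id"]).sum()
    gene_counts.index.name = "gene_id"
    return PACMatrix(counts=gene_counts, design=mat.design.copy())


def overlap_sets(
    de_genes: set[str],
    de_pac_genes: set[str],
    de_apa_genes: set[str],
) -> dict:
    """Venn-style overlaps between DE genes, DE-PAC genes and DE-APA genes.

    Fractions are of DE genes overlapping each of the other two sets,
    matching the figure-style summary the numbers feed.
    """

    def _pair(a: set[str], b: set[str]) -> dict:
        inter = a & b
        return {
            "n_a": len(a),
            "n_b": len(b),
            "n_intersection": len(inter),
            "n_a_only": len(a - b),
            "n_b_only": len(b - a),
        }

    frac_pac = len(de_genes & de_pac_genes) / len(de_genes) if de_genes else 0.0
    frac_apa = len(de_genes & de_apa_genes) / len(de_genes) if de_genes else 0.0
    return {
        "de_gene_vs_de_pac": _pair(de_genes, de_pac_genes),
        "de_gene_vs_de_apa": _pair(de_genes, de_apa_genes),
        "fraction_de_genes_with_de_pac": frac_pac,
        "fraction_de_genes_with_de_apa": frac_apa,
    }
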