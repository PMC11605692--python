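"""Allele-specific expression from phased RNA allelic counts.

Gene-level phased counts are the sufficient statistic under known phase, so
per-SNP counts are summed per haplotype and the major-haplotype total is
tested against Beta-Binomial(n, 0.5, rho) (exactly binomial at rho = 0).
Genes pass as ASE at major allele frequency > 0.65 with BH-adjusted
p < 0.05 and TPM >= 1.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

MAF_THRESHOLD = 0.65   # strictly greater than
PADJ_THRESHOLD = 0.05  # strictly less than
TPM_THRESHOLD = 1.0    # >=


def aggregate_gene_counts(snvs: pd.DataFrame) -> pd.DataFrame:
    """Sum phased per-SNP reads to gene-level (H1, H2) plus SNP count."""
    if (snvs[["hap1_reads", "hap2_reads"]] < 0).to_numpy().any():
        raise ValueError("negative allelic read count")
    agg = (snvs.groupby("gene_id", observed=True)
           .agg(hap1=("hap1_reads", "sum"), hap2=("hap2_reads", "sum"),
                n_snps=("pos", "size"))
           .reset_index())
    total = agg["hap1"] + agg["hap2"]
    if (total < 1).any():
        raise ValueError("gene with zero total phased reads")
    agg["major_haplotype"] = np.where(agg["hap1"] >= agg["hap2"], 1, 2)
    agg["maf"] = np.maximum(agg["hap1"], agg["hap2"]) / total
    return agg


def ase_test(h1: int, h2: int, rho: float = 0.0) -> float:
    """Two-sided deviation of (h1, h2) from a balanced allelic ratio.

    Tail-doubled p-value of k = max(h1, h2) under Beta-Binomial(n, 0.5, rho),
    capped at 1; rho = 0 reduces exactly to the binomial test.
    """
    if h1 < 0 or h2 < 0 or h1 + h2 < 1:
        raise ValueError("counts must be >= 0 with at least one read")
    if not 0.0 <= rho < 1.0:
        raise ValueError("dispersion rho must be in [0, 1)")
    n = h1 + h2
    k = max(h1, h2)
    if rho == 0.0:
        upper = stats.binom.sf(k - 1, n, 0.5)
    else:
        a = b = (1.0 - rho) / (2.0 * rho)
        upper = stats.betabinom.sf(k - 1, n, a, b)
    return float(min(1.0, 2.0 * upper))


def estimate_dispersion(agg: pd.DataFrame, maf_cap: float = 0.65) -> float:
    """Method-of-moments rho from putative null genes (aggregate maf <= cap).

    Solves E[(k - n/2)^2] = (n/4)(1 + (n-1) rho) pooled over genes, floored
    at 0.
    """
    null = agg[agg["maf"] <= maf_cap]
    if null.empty:
        return 0.0
    n = (null["hap1"] + null["hap2"]).to_numpy(dtype=float)
    k = null["hap1"].to_numpy(dtype=float)
    chi = (k - n / 2.0) ** 2 / (n / 4.0)
    den = float((n - 1).sum())
    if den <= 0:
        return 0.0
    return max(0.0, float((chi.sum() - len(null)) / den))


def classify_cohort(snvs: pd.DataFrame, tpm: pd.DataFrame,
                    rho: float | None = None) -> pd.DataFrame:
    """Gene-level ASE classification for one sample.

    Genes with TPM < 1 or no phased SNP are 'not_testable'.  BH adjustment
    runs across all tested genes; classification is ASE iff maf > 0.65 and
    adjusted p < 0.05, else BAE.  With rho None the dispersion is estimated
    from the sample's balanced genes.
    """
    agg = aggregate_gene_counts(snvs)
    merged = tpm.merge(agg, on="gene_id", how="left")
    testable = merged["n_snps"].notna() & (merged["tpm"] >= TPM_THRESHOLD)
    if rho is None:
        rho = estimate_dispersion(agg)
    pvals = np.full(len(merged), np.nan)
    rows_t = np.flatnonzero(np.asarray(testable))
    for i in rows_t:
        pvals[i] = ase_test(int(merged.iloc[i]["hap1"]), int(merged.iloc[i]["hap2"]), rho)
    padj = np.full(len(merged), np.nan)
    if len(rows_t):
        padj[rows_t] = multipletests(pvals[rows_t], method="fdr_bh")[1]
    out = merged.copy()
    out["p_value"] = pvals
    out["p_adj"] = padj
    classification = np.where(
        ~np.asarray(testable), "not_testable",
        np.where((out["maf"] > MAF_THRESHOLD) & (out["p_adj"] < PADJ_THRESHOLD), "ASE", "BAE"))
    out["classification"] = classification
    out["n_snps"] = out["n_snps"].fillna(0).astype(int)
    out["major_haplotype"] = out["major_haplotype"].fillna(0).astype(int)
    cols = ["gene_id", "n_snps", "hap1", "hap2", "major_haplotype", "maf",
            "p_value", "p_adj", "tpm", "classification"]
    return out[cols]


def methylation_phase_relation(gene_result: pd.Series | dict,
                               promoter_admr: pd.Series | dict | None) -> str:
    """'cis' when the hypermethylated promoter haplotype IS the major
    expressed one, 'trans' when it is the other; 'unknown' when the gene is
    not testable or has no promoter aDMR."""
    if promoter_admr is None:
        return "unknown"
    if gene_result.get("classification", "not_testable") == "not_testable":
        return "unknown"
    hyper = 1 if promoter_admr["mean_meth_h1"] >= promoter_admr["mean_meth_h2"] else 2
    return "cis" if hyper == int(gene_result["major_haplotype"]) else "trans"
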