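"""Allelically differentially methylated region (aDMR) detection.

Smoothing, a beta-binomial Wald test per CpG, run-based segmentation into
candidate regions, and copy-number-context classification.  The per-CpG
test uses smoothed haplotype frequencies with a method-of-moments
dispersion pooled per chromosome; region deltas are computed from RAW
frequencies so the downstream |delta| >= 0.15 filter keeps its meaning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import covering_index


@dataclass(frozen=True)
class AdmrParams:
    """Segmentation and test defaults (DSS-callDMR-style)."""

    p_threshold: float = 1e-5
    min_len: int = 50
    min_cpgs: int = 3
    merge_bp: int = 100
    pct_sig: float = 0.5
    window_bp: int = 500
    delta_min: float = 0.15


def smooth_haplotype_frequencies(sites: pd.DataFrame, window_bp: int = 500) -> pd.DataFrame:
    """Coverage-weighted mean frequency over CpGs within +-window_bp/2.

    ``sites`` is the wide per-site table from ``pivot_haplotypes`` (chrom,
    pos, k1, n1, k2, n2).  Adds columns f1, f2 (raw), f1s, f2s (smoothed),
    plus the window aggregates w{1,2} = sum of in-window coverage and
    q{1,2} = sum of n_i*(n_i - 1), which the Wald test needs for the
    variance of the pooled estimator.  A site with no in-window neighbours
    returns its raw frequency.
    """
    out = sites.reset_index(drop=True).copy()
    out["f1"] = out["k1"] / out["n1"]
    out["f2"] = out["k2"] / out["n2"]
    half = window_bp / 2.0
    for hap in (1, 2):
        smoothed = np.empty(len(out))
        w_tot = np.empty(len(out))
        q_tot = np.empty(len(out))
        for _, grp in out.groupby("chrom", sort=False, observed=True):
            pos = grp["pos"].to_numpy(dtype=np.float64)
            k = grp[f"k{hap}"].to_numpy(dtype=np.float64)
            n = grp[f"n{hap}"].to_numpy(dtype=np.float64)
            ck = np.concatenate([[0.0], np.cumsum(k)])
            cn = np.concatenate([[0.0], np.cumsum(n)])
            cq = np.concatenate([[0.0], np.cumsum(n * (n - 1))])
            lo = np.searchsorted(pos, pos - half, side="left")
            hi = np.searchsorted(pos, pos + half, side="right")
            wk = ck[hi] - ck[lo]
            wn = cn[hi] - cn[lo]
            raw = np.divide(k, n, out=np.zeros_like(k), where=n > 0)
            smoothed[grp.index] = np.where(wn > 0, wk / np.maximum(wn, 1), raw)
            w_tot[grp.index] = wn
            q_tot[grp.index] = cq[hi] - cq[lo]
        out[f"f{hap}s"] = smoothed
        out[f"w{hap}"] = w_tot
        out[f"q{hap}"] = q_tot
    return out


def estimate_dispersion(smoothed: pd.DataFrame, chi_cap: float = 9.0) -> dict[str, float]:
    """Method-of-moments beta-binomial dispersion rho, pooled per chromosome.

    Uses the chi-square inflation of raw counts around the smoothed means:
    E[(k - n p)^2 / (n p (1-p))] = 1 + (n-1) rho.  Per-site chi values are
    winsorized at ``chi_cap`` so sites straddling methylation-domain
    boundaries (raw frequency far from the window mean) do not dominate the
    pooled estimate.  Floored at 0.
    """
    rho = {}
    for chrom, grp in smoothed.groupby("chrom", sort=False, observed=True):
        num = 0.0
        den = 0.0
        m = 0
        for hap in (1, 2):
            p = grp[f"f{hap}s"].to_numpy()
            k = grp[f"k{hap}"].to_numpy(dtype=np.float64)
            n = grp[f"n{hap}"].to_numpy(dtype=np.float64)
            ok = (p > 0) & (p < 1) & (n >= 2)
            if not ok.any():
                continue
            chi = (k[ok] - n[ok] * p[ok]) ** 2 / (n[ok] * p[ok] * (1 - p[ok]))
            num += float(np.minimum(chi, chi_cap).sum())
            den += float((n[ok] - 1).sum())
            m += int(ok.sum())
        rho[chrom] = max(0.0, (num - m) / den) if den > 0 else 0.0
    return rho


def _bb_variance(p: np.ndarray, w: np.ndarray, q: np.ndarray, rho: float) -> np.ndarray:
    """Variance of the window-pooled frequency estimate under beta-binomial
    dispersion: p(1-p) * (W + rho*Q) / W^2 with W = sum n_i, Q = sum n_i(n_i-1).

    For an isolated site (window of one) this is the textbook
    p(1-p)(1 + (n-1)rho)/n.
    """
    w = np.maximum(w, 1.0)
    return p * (1 - p) * (w + rho * q) / w ** 2


def test_per_cpg(sites: pd.DataFrame, window_bp: int = 500,
                 rho: dict[str, float] | float | None = None) -> pd.DataFrame:
    """Wald test of smoothed haplotype-1 vs haplotype-2 frequency per CpG.

    Returns a frame with chrom, pos, raw and smoothed frequencies, coverage,
    wald_stat and two-sided normal p_value.  Sites where both haplotypes have
    degenerate (0/1) equal smoothed frequency get p_value 1; degenerate but
    unequal frequencies are treated as complete separation (p_value 0).
    """
    smoothed = smooth_haplotype_frequencies(sites, window_bp)
    if rho is None:
        rho = estimate_dispersion(smoothed)
    frames = []
    for chrom, grp in smoothed.groupby("chrom", sort=False, observed=True):
        r = rho if isinstance(rho, (int, float)) else rho.get(chrom, 0.0)
        p1 = grp["f1s"].to_numpy()
        p2 = grp["f2s"].to_numpy()
        v = (_bb_variance(p1, grp["w1"].to_numpy(dtype=np.float64),
                          grp["q1"].to_numpy(dtype=np.float64), r)
             + _bb_variance(p2, grp["w2"].to_numpy(dtype=np.float64),
                            grp["q2"].to_numpy(dtype=np.float64), r))
        d = p1 - p2
        with np.errstate(divide="ignore", invalid="ignore"):
            wald = np.where(v > 0, d / np.sqrt(v), np.where(d == 0, 0.0, np.sign(d) * np.inf))
        pval = 2 * stats.norm.sf(np.abs(wald))
        pval = np.where((v <= 0) & (d == 0), 1.0, pval)
        res = grp[["chrom", "pos", "f1", "f2", "f1s", "f2s", "n1", "n2"]].copy()
        res["wald_stat"] = wald
        res["p_value"] = np.clip(pval, 0.0, 1.0)
        frames.append(res)
    return pd.concat(frames, ignore_index=True)


def call_admrs(results: pd.DataFrame, params: AdmrParams = AdmrParams()) -> pd.DataFrame:
    """Segment per-CpG test results into aDMRs.

    Candidate regions are maximal runs of significant CpGs (p < p_threshold),
    merging runs whose significant CpGs are <= merge_bp apart.  A region is
    kept when it has >= min_cpgs CpGs, spans >= min_len bp, has a fraction of
    significant CpGs >= pct_sig, and |mean raw f1 - mean raw f2| >= delta_min.
    """
    rows = []
    for chrom, grp in results.sort_values(["chrom", "pos"]).groupby("chrom", sort=False, observed=True):
        pos = grp["pos"].to_numpy()
        pval = grp["p_value"].to_numpy()
        sig = pval < params.p_threshold
        sig_idx = np.flatnonzero(sig)
        if len(sig_idx) == 0:
            continue
        gaps = np.diff(pos[sig_idx])
        breaks = np.flatnonzero(gaps > params.merge_bp)
        group_bounds = np.split(sig_idx, breaks + 1)
        for member in group_bounds:
            i0, i1 = member[0], member[-1]
            region = grp.iloc[i0:i1 + 1]
            n_cpgs = len(region)
            n_sig = int(sig[i0:i1 + 1].sum())
            start = int(pos[i0])
            end = int(pos[i1]) + 2
            if n_cpgs < params.min_cpgs or (end - start) < params.min_len:
                continue
            if n_sig / n_cpgs < params.pct_sig:
                continue
            m1 = float(region["f1"].mean())
            m2 = float(region["f2"].mean())
            diff = m1 - m2
            if abs(diff) < params.delta_min:
                continue
            rows.append({
                "chrom": chrom, "start": start, "end": end, "n_cpgs": n_cpgs,
                "mean_meth_h1": m1, "mean_meth_h2": m2, "diff_methyl": diff,
                "area_stat": float(region["wald_stat"].sum()),
                "min_p": float(region["p_value"].min()),
            })
    admrs = pd.DataFrame(rows, columns=["chrom", "start", "end", "n_cpgs", "mean_meth_h1",
                                        "mean_meth_h2", "diff_methyl", "area_stat", "min_p"])
    if len(admrs):
        admrs.insert(0, "name", [f"admr_{i:06d}" for i in range(len(admrs))])
    else:
        admrs.insert(0, "name", pd.Series(dtype=str))
    return admrs


def classify_cn_context(admrs: pd.DataFrame, segments: pd.DataFrame) -> pd.Series:
    """CN context at each aDMR midpoint: LOH / HetDip / HetCNV / unknown."""
    if admrs.empty:
        return pd.Series(dtype=object, name="cn_context")
    points = pd.DataFrame({
        "chrom": admrs["chrom"].to_numpy(),
        "pos": ((admrs["start"] + admrs["end"]) // 2).to_numpy(),
    })
    if segments is None or segments.empty:
        return pd.Series(["unknown"] * len(admrs), index=admrs.index, name="cn_context")
    idx = covering_index(points, segments.reset_index(drop=True))
    major = segments["major_cn"].to_numpy()
    minor = segments["minor_cn"].to_numpy()
    out = []
    for i in idx:
        if i < 0:
            out.append("unknown")
        elif minor[i] == 0:
            out.append("LOH")
        elif major[i] == 1 and minor[i] == 1:
            out.append("HetDip")
        else:
            out.append("HetCNV")
    return pd.Series(out, index=admrs.index, name="cn_context")


def detect_admrs(calls: pd.DataFrame, params: AdmrParams = AdmrParams()) -> pd.DataFrame:
    """Convenience: strand-merged calls -> called aDMR table."""
    from .methylation import pivot_haplotypes

    sites, _ = pivot_haplotypes(calls)
    if sites.empty:
        return call_admrs(pd.DataFrame(columns=["chrom", "pos", "f1", "f2", "f1s", "f2s",
                                                "n1", "n2", "wald_stat", "p_value"]), params)
    tested = test_per_cpg(sites, params.window_bp)
    return call_admrs(tested, params)
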