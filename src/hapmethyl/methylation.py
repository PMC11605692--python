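"""Parsing, validation and aggregation of per-CpG haplotype methylation calls."""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
import pandas as pd

UNPHASED = 0
CPG_WIDTH = 2


class ConsensusResult(NamedTuple):
    frequencies: pd.DataFrame
    n_dropped_zero_depth: int


def validate_calls(calls: pd.DataFrame, name: str = "calls") -> None:
    """Schema and count sanity; raises ValueError naming the offending site."""
    need = {"chrom", "start", "strand", "haplotype", "n_methylated", "n_total"}
    missing = need - set(calls.columns)
    if missing:
        raise ValueError(f"{name}: missing columns {sorted(missing)}")
    meth = np.asarray(calls["n_methylated"])
    total = np.asarray(calls["n_total"])
    bad = (meth < 0) | (total < 0) | (meth > total)
    if bad.any():
        row = calls.iloc[int(np.flatnonzero(bad)[0])]
        raise ValueError(
            f"{name}: n_methylated > n_total (or negative counts) at "
            f"{row['chrom']}:{row['start']}")
    if (np.asarray(calls["start"]) < 0).any():
        raise ValueError(f"{name}: negative position")
    bad_strand = ~calls["strand"].isin(["+", "-"])
    if bad_strand.any():
        row = calls.iloc[int(np.flatnonzero(np.asarray(bad_strand))[0])]
        raise ValueError(f"{name}: invalid strand {row['strand']!r} at {row['chrom']}:{row['start']}")


def merge_strands_to_consensus(calls: pd.DataFrame, minus_offset: int = 1) -> pd.DataFrame:
    """Sum methylated/total reads over both strands of each CG dyad.

    Minus-strand records sit at the G of the dyad and are normalized to the
    plus-strand C position (``pos - minus_offset``) before a group-by sum.
    The output carries one record per (chrom, pos, haplotype) with strand
    '+'; already-consensus input passes through unchanged (idempotent).
    """
    validate_calls(calls)
    df = calls.copy()
    neg = df["strand"] == "-"
    norm = df["start"].to_numpy(dtype=np.int64, copy=True)
    norm[np.asarray(neg)] -= minus_offset
    if (norm < 0).any():
        i = int(np.flatnonzero(norm < 0)[0])
        row = df.iloc[i]
        raise ValueError(
            f"minus-strand record at {row['chrom']}:{row['start']} cannot be "
            f"normalized (position would become negative)")
    df["start"] = norm
    merged = (df.groupby(["chrom", "start", "haplotype"], sort=True, observed=True)
              [["n_methylated", "n_total"]].sum().reset_index())
    merged["end"] = merged["start"] + CPG_WIDTH
    merged["strand"] = "+"
    return merged[["chrom", "start", "end", "strand", "haplotype", "n_methylated", "n_total"]]


def consensus_frequency(calls: pd.DataFrame) -> ConsensusResult:
    """Per-record methylation frequency; zero-depth records dropped and counted."""
    validate_calls(calls)
    depth = calls["n_total"].to_numpy()
    keep = depth > 0
    n_dropped = int((~keep).sum())
    kept = calls[keep]
    freq = pd.DataFrame({
        "chrom": kept["chrom"].to_numpy(),
        "pos": kept["start"].to_numpy(),
        "haplotype": kept["haplotype"].to_numpy(),
        "frequency": kept["n_methylated"].to_numpy() / kept["n_total"].to_numpy(),
        "depth": kept["n_total"].to_numpy(),
    })
    return ConsensusResult(freq, n_dropped)


def phased_fraction(calls: pd.DataFrame) -> float:
    """Fraction of covered CpG sites carrying a haplotype-1 or -2 call."""
    validate_calls(calls)
    covered = calls[calls["n_total"] > 0]
    if covered.empty:
        return float("nan")
    sites = covered.groupby(["chrom", "start"], observed=True)["haplotype"] \
        .apply(lambda h: bool(h.isin([1, 2]).any()))
    return float(sites.sum() / len(sites))


def pivot_haplotypes(calls: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Wide per-site table with both haplotypes; single-haplotype sites split off.

    Input must be strand-merged.  Returns (both, flagged) where ``both`` has
    columns chrom, pos, k1, n1, k2, n2 (methylated/total per haplotype) and
    ``flagged`` holds sites observed on only one haplotype.
    """
    validate_calls(calls)
    phased = calls[calls["haplotype"].isin([1, 2]) & (calls["n_total"] > 0)]
    dup = phased.duplicated(subset=["chrom", "start", "haplotype"])
    if dup.any():
        row = phased[dup].iloc[0]
        raise ValueError(f"duplicate position within a haplotype at {row['chrom']}:{row['start']}")
    wide = phased.pivot_table(index=["chrom", "start"], columns="haplotype",
                              values=["n_methylated", "n_total"], aggfunc="first")
    k1 = wide.get(("n_methylated", 1))
    k2 = wide.get(("n_methylated", 2))
    n1 = wide.get(("n_total", 1))
    n2 = wide.get(("n_total", 2))
    out = pd.DataFrame({
        "k1": k1 if k1 is not None else np.nan,
        "n1": n1 if n1 is not None else np.nan,
        "k2": k2 if k2 is not None else np.nan,
        "n2": n2 if n2 is not None else np.nan,
    }, index=wide.index).reset_index().rename(columns={"start": "pos"})
    complete = out["n1"].notna() & out["n2"].notna()
    both = out[complete].reset_index(drop=True)
    for col in ("k1", "n1", "k2", "n2"):
        both[col] = both[col].astype(np.int64)
    flagged = out[~complete].reset_index(drop=True)
    return both.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True), flagged
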