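"""Homologous-recombination-deficiency scoring.

Genomic scar scores (LOH / TAI / LST), the microhomology deletion fraction,
the published logistic model combining six features, and HR-gene promoter
methylation calls.

The logistic model is fixed: intercept -3.364 with positive coefficients
(1.611, 0.091, 1.153, 0.847, 0.667, 2.398) on the standardized features
(SBS3, SBS8, SV3, SV5, HRD index, microhomology deletion fraction), in that
order.  Features are ln(x+1)-transformed and z-normalized over the cohort
before scoring.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .intervals import covering_index

INTERCEPT = -3.364
COEFFICIENTS = np.array([1.611, 0.091, 1.153, 0.847, 0.667, 2.398])
FEATURE_ORDER = ("sbs3", "sbs8", "sv3", "sv5", "hrd_index", "mh_del_fraction")
HRD_HIGH_THRESHOLD = 0.7

LOH_MIN_LEN = 15_000_000
LST_MIN_SEGMENT = 10_000_000
LST_SMOOTH_LEN = 3_000_000
MH_MIN_LEN = 1
DEL_MIN_LEN = 3  # strictly greater than


@dataclass(frozen=True)
class ScarScores:
    loh: int
    tai: int
    lst: int

    def __post_init__(self):
        if min(self.loh, self.tai, self.lst) < 0:
            raise ValueError("scar scores must be >= 0")


def hrd_index(scores: ScarScores) -> int:
    """Arithmetic sum LOH + TAI + LST."""
    return scores.loh + scores.tai + scores.lst


# ---------------------------------------------------------------------------
# microhomology
# ---------------------------------------------------------------------------

def microhomology_length(deleted_seq: str, left_flank: str, right_flank: str) -> int:
    """Longest homology between the deleted sequence and either breakpoint.

    max(prefix of deleted matching the start of the right flank, suffix of
    deleted matching the end of the left flank), capped at the deletion length.
    """
    n = len(deleted_seq)
    pref = 0
    for i in range(min(n, len(right_flank))):
        if deleted_seq[i] != right_flank[i]:
            break
        pref += 1
    suf = 0
    for i in range(1, min(n, len(left_flank)) + 1):
        if deleted_seq[-i] != left_flank[-i]:
            break
        suf += 1
    return min(max(pref, suf), n)


def microhomology_deletion_fraction(deletions: pd.DataFrame, mh_min: int = MH_MIN_LEN,
                                    denominator: str = "all") -> float:
    """Fraction of deletions that are > 3 bp with breakpoint microhomology.

    ``denominator`` is 'all' (every deletion) or 'gt3' (only deletions > 3 bp).
    If no deletion exceeds 3 bp the fraction is undefined; 0 is returned with
    a warning.
    """
    if denominator not in ("all", "gt3"):
        raise ValueError("denominator must be 'all' or 'gt3'")
    if deletions.empty:
        warnings.warn("no deletions supplied; microhomology fraction set to 0")
        return 0.0
    lengths = (deletions["end"] - deletions["start"]).to_numpy()
    gt3 = lengths > DEL_MIN_LEN
    if not gt3.any():
        warnings.warn("no deletion longer than 3 bp; microhomology fraction set to 0")
        return 0.0
    mh = np.array([
        microhomology_length(r["deleted_seq"], r["left_flank"], r["right_flank"])
        for _, r in deletions.iterrows()
    ])
    numer = int((gt3 & (mh >= mh_min)).sum())
    denom = int(gt3.sum()) if denominator == "gt3" else len(deletions)
    return numer / denom


# ---------------------------------------------------------------------------
# scar scores
# ---------------------------------------------------------------------------

def _merge_equal_states(segs: pd.DataFrame) -> pd.DataFrame:
    """Merge adjacent segments with identical (major, minor) per chromosome."""
    rows = []
    for chrom, grp in segs.sort_values(["chrom", "start"]).groupby("chrom", sort=False, observed=True):
        cur = None
        for _, seg in grp.iterrows():
            if (cur is not None and cur["end"] == seg["start"]
                    and cur["major_cn"] == seg["major_cn"] and cur["minor_cn"] == seg["minor_cn"]):
                cur["end"] = seg["end"]
            else:
                if cur is not None:
                    rows.append(cur)
                cur = {"chrom": chrom, "start": int(seg["start"]), "end": int(seg["end"]),
                       "major_cn": int(seg["major_cn"]), "minor_cn": int(seg["minor_cn"])}
        if cur is not None:
            rows.append(cur)
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "major_cn", "minor_cn"])


def _absorb_small(segs: list[dict], min_len: int) -> list[dict]:
    """Iteratively absorb segments shorter than min_len into their longer
    neighbour (coordinates extend; state is the neighbour's), then re-merge."""
    segs = [dict(s) for s in segs]
    changed = True
    while changed and len(segs) > 1:
        changed = False
        lengths = [s["end"] - s["start"] for s in segs]
        i = int(np.argmin(lengths))
        if lengths[i] < min_len:
            if i == 0:
                segs[1]["start"] = segs[0]["start"]
            elif i == len(segs) - 1:
                segs[-2]["end"] = segs[-1]["end"]
            else:
                left_len = segs[i - 1]["end"] - segs[i - 1]["start"]
                right_len = segs[i + 1]["end"] - segs[i + 1]["start"]
                if left_len >= right_len:
                    segs[i - 1]["end"] = segs[i]["end"]
                else:
                    segs[i + 1]["start"] = segs[i]["start"]
            del segs[i]
            changed = True
        # merge adjacent equal states
        j = 0
        while j < len(segs) - 1:
            a, b = segs[j], segs[j + 1]
            if a["end"] == b["start"] and a["major_cn"] == b["major_cn"] and a["minor_cn"] == b["minor_cn"]:
                a["end"] = b["end"]
                del segs[j + 1]
                changed = True
            else:
                j += 1
    return segs


def scar_scores(segments: pd.DataFrame, karyotype: pd.DataFrame,
                loh_min_len: int = LOH_MIN_LEN,
                lst_min_segment: int = LST_MIN_SEGMENT,
                lst_smooth_len: int = LST_SMOOTH_LEN,
                tai_min_len: int = 0) -> ScarScores:
    """LOH, TAI and LST counts from allele-specific CN segments.

    LOH: segments with minor_cn = 0 longer than loh_min_len that do not span
    a whole chromosome.  TAI: allelic-imbalance segments (major != minor)
    reaching a chromosome end without crossing the centromere and not
    spanning the whole chromosome.  LST: per arm, breakpoints between
    adjacent differing segments both >= lst_min_segment after absorbing
    segments < lst_smooth_len.  Adjacent equal-state segments are merged
    first, so subdividing a segment never changes the scores.
    """
    karyo = karyotype.set_index("chrom")
    merged = _merge_equal_states(segments)
    loh = tai = lst = 0
    for chrom, grp in merged.groupby("chrom", sort=False, observed=True):
        if chrom not in karyo.index:
            raise ValueError(f"chromosome {chrom} missing from karyotype")
        chrom_len = int(karyo.loc[chrom, "length"])
        cen = int(karyo.loc[chrom, "centromere"])
        grp = grp.sort_values("start")
        for _, seg in grp.iterrows():
            length = seg["end"] - seg["start"]
            whole = seg["start"] == 0 and seg["end"] == chrom_len
            if seg["minor_cn"] == 0 and length > loh_min_len and not whole:
                loh += 1
            imbalanced = seg["major_cn"] != seg["minor_cn"]
            reaches_end = seg["start"] == 0 or seg["end"] == chrom_len
            crosses_cen = seg["start"] < cen < seg["end"]
            if imbalanced and reaches_end and not crosses_cen and not whole and length > tai_min_len:
                tai += 1
        # LST per arm: split segments at the centromere
        for arm_lo, arm_hi in ((0, cen), (cen, chrom_len)):
            arm_segs = []
            for _, seg in grp.iterrows():
                s = max(int(seg["start"]), arm_lo)
                e = min(int(seg["end"]), arm_hi)
                if e > s:
                    arm_segs.append({"chrom": chrom, "start": s, "end": e,
                                     "major_cn": int(seg["major_cn"]), "minor_cn": int(seg["minor_cn"])})
            arm_segs = _absorb_small(arm_segs, lst_smooth_len)
            for a, b in zip(arm_segs[:-1], arm_segs[1:]):
                if (a["major_cn"], a["minor_cn"]) == (b["major_cn"], b["minor_cn"]):
                    continue
                if (a["end"] - a["start"]) >= lst_min_segment and (b["end"] - b["start"]) >= lst_min_segment:
                    lst += 1
    return ScarScores(loh=loh, tai=tai, lst=lst)


# ---------------------------------------------------------------------------
# feature standardization and logistic scoring
# ---------------------------------------------------------------------------

def standardize_features(cohort: pd.DataFrame, *, external_stats: pd.DataFrame | None = None,
                         ddof: int = 1) -> pd.DataFrame:
    """ln(x+1) transform then z-normalize each feature over the cohort.

    ``cohort`` has one row per sample and the six feature columns in
    ``FEATURE_ORDER``.  With ``external_stats`` (columns mean, sd indexed by
    feature, on the ln(x+1) scale) the cohort is standardized against those
    instead, enabling single-sample scoring.  Zero-variance features map to
    z = 0 with a warning.
    """
    missing = set(FEATURE_ORDER) - set(cohort.columns)
    if missing:
        raise ValueError(f"cohort feature table missing columns {sorted(missing)}")
    if external_stats is None and len(cohort) < 2:
        raise ValueError("within-cohort standardization needs >= 2 samples; "
                         "supply external_stats for single-sample scoring")
    logged = np.log1p(cohort[list(FEATURE_ORDER)].astype(float))
    if external_stats is not None:
        mean = external_stats["mean"].reindex(list(FEATURE_ORDER))
        sd = external_stats["sd"].reindex(list(FEATURE_ORDER))
    else:
        mean = logged.mean(axis=0)
        sd = logged.std(axis=0, ddof=ddof)
    z = (logged - mean) / sd
    degenerate = ~(sd > 0)
    if degenerate.any():
        warnings.warn(f"zero-variance feature(s) {list(sd.index[degenerate])}; z set to 0")
        z.loc[:, np.asarray(degenerate)] = 0.0
    z.index = cohort.index
    return z


def hrdetect_score(z: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Logistic score from standardized features, in FEATURE_ORDER."""
    if isinstance(z, pd.DataFrame):
        z = z[list(FEATURE_ORDER)].to_numpy(dtype=float)
    z = np.atleast_2d(np.asarray(z, dtype=float))
    if z.shape[1] != 6:
        raise ValueError("expected 6 standardized features")
    eta = INTERCEPT + z @ COEFFICIENTS
    return 1.0 / (1.0 + np.exp(-eta))


def classify_hrd_high(score: float | np.ndarray, threshold: float = HRD_HIGH_THRESHOLD) -> np.ndarray:
    """'high' iff score >= threshold (default 0.7)."""
    return np.where(np.asarray(score) >= threshold, "high", "not_high")


# ---------------------------------------------------------------------------
# HR-gene promoter methylation
# ---------------------------------------------------------------------------

def promoter_methylation_fraction(promoter: pd.Series | dict,
                                  tumor_freqs: pd.DataFrame,
                                  normal_stats: pd.DataFrame,
                                  cn_segments: pd.DataFrame | None = None) -> dict:
    """Fraction of promoter CpGs methylated above the matched-normal level.

    A CpG counts as methylated when its tumor frequency exceeds the normal
    mean by more than one normal SD.  ``normal_stats`` has columns chrom,
    pos, mean, sd.  LOH status comes from the CN segment covering the
    promoter midpoint.
    """
    chrom, start, end = promoter["chrom"], promoter["start"], promoter["end"]
    tum = tumor_freqs[(tumor_freqs["chrom"] == chrom)
                      & (tumor_freqs["pos"] >= start) & (tumor_freqs["pos"] < end)]
    norm = normal_stats[(normal_stats["chrom"] == chrom)
                        & (normal_stats["pos"] >= start) & (normal_stats["pos"] < end)]
    joined = tum.merge(norm[["chrom", "pos", "mean", "sd"]], on=["chrom", "pos"], how="inner")
    if joined.empty:
        raise ValueError(f"no evaluable CpG in promoter {chrom}:{start}-{end}")
    methylated = joined["frequency"] > joined["mean"] + joined["sd"]
    loh_status = "unknown"
    if cn_segments is not None and len(cn_segments):
        mid = (int(start) + int(end)) // 2
        idx = covering_index(pd.DataFrame({"chrom": [chrom], "pos": [mid]}),
                             cn_segments.reset_index(drop=True))
        if idx[0] >= 0:
            loh_status = "LOH" if cn_segments.iloc[idx[0]]["minor_cn"] == 0 else "HET"
    return {
        "gene": promoter.get("gene_id", ""),
        "fraction_methylated_sites": float(methylated.mean()),
        "n_evaluable": int(len(joined)),
        "loh_status": loh_status,
    }
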