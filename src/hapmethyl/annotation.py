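"""Strand-aware promoter construction, reciprocal-overlap annotation,
recurrence tallies, and average-methylation classification."""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
import pandas as pd

from .intervals import check_intervals, reciprocal_pairs

PROMOTER_UPSTREAM = 1500
PROMOTER_DOWNSTREAM = 500
POLYA_FLANK = 500
REGULATORY_CATEGORIES = ("CGI", "TF_site", "promoter", "enhancer", "polyA_flank")
METHYLATED_THRESHOLD = 0.25  # strictly greater than


class AnnotationSummary(NamedTuple):
    fraction_regulatory: float
    category_fractions: dict[str, float]
    n_admrs: int


def build_promoters(transcripts: pd.DataFrame,
                    upstream: int = PROMOTER_UPSTREAM,
                    downstream: int = PROMOTER_DOWNSTREAM) -> pd.DataFrame:
    """Promoter windows around each TSS: upstream bp before and downstream bp
    after in the direction of transcription, clipped at 0."""
    tss = transcripts["tss"].to_numpy(dtype=np.int64)
    plus = (transcripts["strand"] == "+").to_numpy()
    start = np.where(plus, tss - upstream, tss - downstream)
    end = np.where(plus, tss + downstream, tss + upstream)
    out = pd.DataFrame({
        "chrom": transcripts["chrom"].to_numpy(),
        "start": np.maximum(start, 0),
        "end": end,
        "gene_id": transcripts["gene_id"].to_numpy(),
        "transcript_id": transcripts["transcript_id"].to_numpy(),
        "strand": transcripts["strand"].to_numpy(),
    })
    check_intervals(out, "promoters")
    return out


def build_polya_flanks(polya_sites: pd.DataFrame, flank: int = POLYA_FLANK) -> pd.DataFrame:
    """[site-flank, site+flank) windows, clipped at 0; overlaps not merged."""
    pos = polya_sites["pos"].to_numpy(dtype=np.int64)
    out = pd.DataFrame({
        "chrom": polya_sites["chrom"].to_numpy(),
        "start": np.maximum(pos - flank, 0),
        "end": pos + flank,
    })
    check_intervals(out, "polyA flanks")
    return out


def intersect_reciprocal50(a: pd.DataFrame, b: pd.DataFrame, fraction: float = 0.5) -> pd.DataFrame:
    """bedtools ``intersect -e -f 0.5 -F 0.5`` semantics: a pair is reported
    when the overlap covers >= fraction of EITHER interval."""
    check_intervals(a, "a")
    check_intervals(b, "b")
    return reciprocal_pairs(a, b, fraction)


def annotate_admrs(admrs: pd.DataFrame, feature_sets: dict[str, pd.DataFrame],
                   fraction: float = 0.5) -> tuple[pd.DataFrame, AnnotationSummary]:
    """Assign category labels to aDMRs under the reciprocal-overlap rule.

    ``feature_sets`` maps category name -> interval frame.  An aDMR may carry
    several categories; the summary reports the fraction carrying at least
    one regulatory category.
    """
    names = admrs["name"] if "name" in admrs.columns else pd.Series(
        [f"admr_{i:06d}" for i in range(len(admrs))], index=admrs.index)
    rows = []
    hit_any = np.zeros(len(admrs), dtype=bool)
    per_cat_hits = {}
    for category, features in feature_sets.items():
        hit = np.zeros(len(admrs), dtype=bool)
        if features is not None and len(features) and len(admrs):
            pairs = intersect_reciprocal50(admrs, features, fraction)
            for _, pr in pairs.iterrows():
                a_idx = int(pr["a_idx"])
                feat = features.iloc[int(pr["b_idx"])]
                feat_id = feat.get("feature_id",
                                   feat.get("transcript_id", f"{category}_{int(pr['b_idx'])}"))
                rows.append({"admr_id": names.iloc[a_idx], "category": category,
                             "feature_id": feat_id})
                hit[a_idx] = True
        per_cat_hits[category] = hit
        if category in REGULATORY_CATEGORIES:
            hit_any |= hit
    hit_anything = (np.logical_or.reduce(list(per_cat_hits.values()))
                    if per_cat_hits else np.zeros(len(admrs), dtype=bool))
    for i in np.flatnonzero(~hit_anything):
        rows.append({"admr_id": names.iloc[i], "category": "none", "feature_id": ""})
    annotated = pd.DataFrame(rows, columns=["admr_id", "category", "feature_id"])
    n = len(admrs)
    summary = AnnotationSummary(
        fraction_regulatory=float(hit_any.sum() / n) if n else float("nan"),
        category_fractions={c: float(h.sum() / n) if n else float("nan")
                            for c, h in per_cat_hits.items()},
        n_admrs=n,
    )
    return annotated, summary


def recurrent_promoter_admrs(per_sample_admrs: dict[str, pd.DataFrame],
                             promoters: pd.DataFrame,
                             min_samples: int = 2,
                             fraction: float = 0.5) -> pd.DataFrame:
    """Per transcript, the number of distinct samples whose aDMRs hit its
    promoter under the reciprocal-overlap rule; recurrent = count >= min_samples."""
    counts = np.zeros(len(promoters), dtype=np.int64)
    for _, admrs in per_sample_admrs.items():
        if admrs is None or admrs.empty:
            continue
        pairs = intersect_reciprocal50(admrs, promoters, fraction)
        hit = np.unique(pairs["b_idx"].to_numpy()) if len(pairs) else []
        counts[hit] += 1
    out = pd.DataFrame({
        "gene_id": promoters["gene_id"].to_numpy(),
        "transcript_id": promoters["transcript_id"].to_numpy(),
        "n_samples": counts,
    })
    out["recurrent"] = out["n_samples"] >= min_samples
    return out


def average_region_methylation(regions: pd.DataFrame, frequencies: pd.DataFrame,
                               threshold: float = METHYLATED_THRESHOLD,
                               depth_weighted: bool = False) -> pd.DataFrame:
    """Mean methylation frequency over CpGs inside each region.

    Unweighted by default (a depth-weighted variant sits behind the flag).
    Regions with no CpGs are 'undefined' and carry NaN; otherwise classified
    'methylated' iff mean is strictly greater than the threshold.
    """
    freq_by_chrom = {c: g.sort_values("pos") for c, g in frequencies.groupby("chrom", observed=True)}
    means, classes = [], []
    for _, region in regions.iterrows():
        grp = freq_by_chrom.get(region["chrom"])
        mean = np.nan
        if grp is not None:
            pos = grp["pos"].to_numpy()
            i0, i1 = np.searchsorted(pos, [region["start"], region["end"]])
            inside = grp.iloc[i0:i1]
            if len(inside):
                if depth_weighted and "depth" in inside.columns and inside["depth"].sum() > 0:
                    mean = float(np.average(inside["frequency"], weights=inside["depth"]))
                else:
                    mean = float(inside["frequency"].mean())
        means.append(mean)
        classes.append("undefined" if np.isnan(mean)
                       else ("methylated" if mean > threshold else "unmethylated"))
    out = regions.copy()
    out["mean_methylation"] = means
    out["classification"] = classes
    return out
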