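"""Tumor-specific aDMR filtering: the three-stage exclusion cascade.

Stage 1 flags aDMRs overlapping any aDMR called in the matched normal;
stage 2 flags aDMRs partially methylated in more than 1% of a normal WGBS
panel; stage 3 flags aDMRs within 10 kb of known imprinted regions.  Flags
commute, so the surviving set is order-independent; removal happens only at
cascade end.

Boundary conventions follow the wording asymmetry of the rules: the partial
band [0.35, 0.65] is endpoint-inclusive, while the ">60% of CpGs partial"
and ">1% of panel samples" cuts are strict.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
import pandas as pd

from .intervals import overlaps_any, within_distance

PARTIAL_LO = 0.35
PARTIAL_HI = 0.65
MIN_CPGS_EVALUABLE = 5
MIN_DEPTH = 5
PARTIAL_CPG_FRACTION = 0.60   # strict >
PANEL_SAMPLE_FRACTION = 0.01  # strict >
IMPRINTED_WINDOW_BP = 10_000

FLAGS = ("matched_normal", "panel_partial", "imprinted")


class FilterReport(NamedTuple):
    n_input: int
    n_removed_matched_normal: int
    n_removed_panel_partial: int
    n_removed_imprinted: int
    n_removed_total: int
    n_retained: int


def exclude_matched_normal(tumor_admrs: pd.DataFrame, normal_admrs: pd.DataFrame) -> pd.Series:
    """Flag tumor aDMRs intersecting (>= 1 bp) any matched-normal aDMR."""
    if tumor_admrs.empty or normal_admrs is None or normal_admrs.empty:
        return pd.Series(np.zeros(len(tumor_admrs), dtype=bool),
                         index=tumor_admrs.index, name="flag_matched_normal")
    flags = overlaps_any(tumor_admrs, normal_admrs)
    return pd.Series(flags, index=tumor_admrs.index, name="flag_matched_normal")


def partial_methylation_profile(admrs: pd.DataFrame, panel: pd.DataFrame,
                                min_depth: int = MIN_DEPTH,
                                min_cpgs: int = MIN_CPGS_EVALUABLE,
                                band: tuple[float, float] = (PARTIAL_LO, PARTIAL_HI),
                                cpg_fraction: float = PARTIAL_CPG_FRACTION) -> pd.DataFrame:
    """Per-aDMR tally of evaluable and partially methylated panel samples.

    A panel sample is evaluable for an aDMR when >= min_cpgs CpGs inside it
    have depth >= min_depth; it counts as partial when the fraction of those
    CpGs with frequency in [band] is strictly greater than cpg_fraction.
    """
    profiles = []
    if panel is None or panel.empty:
        for name in admrs.get("name", pd.Series(range(len(admrs)))):
            profiles.append({"admr_id": name, "n_evaluable": 0, "n_partial": 0})
        return pd.DataFrame(profiles, columns=["admr_id", "n_evaluable", "n_partial"])
    lo, hi = band
    panel_by_chrom = {c: g.sort_values("pos") for c, g in panel.groupby("chrom", observed=True)}
    names = admrs["name"] if "name" in admrs.columns else pd.Series(range(len(admrs)), index=admrs.index)
    for (_, admr), name in zip(admrs.iterrows(), names):
        grp = panel_by_chrom.get(admr["chrom"])
        n_eval = 0
        n_part = 0
        if grp is not None:
            pos = grp["pos"].to_numpy()
            i0, i1 = np.searchsorted(pos, [admr["start"], admr["end"]])
            inside = grp.iloc[i0:i1]
            inside = inside[inside["depth"] >= min_depth]
            for _, sample in inside.groupby("sample_id", observed=True):
                if len(sample) < min_cpgs:
                    continue
                n_eval += 1
                frac = ((sample["frequency"] >= lo) & (sample["frequency"] <= hi)).mean()
                if frac > cpg_fraction:
                    n_part += 1
        profiles.append({"admr_id": name, "n_evaluable": n_eval, "n_partial": n_part})
    return pd.DataFrame(profiles, columns=["admr_id", "n_evaluable", "n_partial"])


def exclude_panel_partial(admrs: pd.DataFrame, profiles: pd.DataFrame, panel_size: int,
                          sample_fraction: float = PANEL_SAMPLE_FRACTION) -> pd.Series:
    """Flag aDMRs partial in strictly more than sample_fraction of the panel."""
    if admrs.empty:
        return pd.Series(dtype=bool, name="flag_panel_partial")
    prof = profiles.set_index("admr_id")
    names = admrs["name"] if "name" in admrs.columns else pd.Series(range(len(admrs)), index=admrs.index)
    n_partial = prof.reindex(names)["n_partial"].fillna(0).to_numpy()
    flags = n_partial > sample_fraction * panel_size
    return pd.Series(flags, index=admrs.index, name="flag_panel_partial")


def exclude_imprinted(admrs: pd.DataFrame, imprinted_regions: pd.DataFrame,
                      window_bp: int = IMPRINTED_WINDOW_BP) -> pd.Series:
    """Flag aDMRs within window_bp of any known imprinted interval."""
    if admrs.empty or imprinted_regions is None or imprinted_regions.empty:
        return pd.Series(np.zeros(len(admrs), dtype=bool),
                         index=admrs.index, name="flag_imprinted")
    flags = within_distance(admrs, imprinted_regions, window_bp)
    return pd.Series(flags, index=admrs.index, name="flag_imprinted")


def tumor_specific_admrs(tumor_admrs: pd.DataFrame, normal_admrs: pd.DataFrame,
                         panel: pd.DataFrame, imprinted_regions: pd.DataFrame,
                         panel_size: int | None = None) -> tuple[pd.DataFrame, FilterReport]:
    """Run the full cascade; returns (flag-annotated survivors, report).

    An aDMR failing several filters is removed once but counted under every
    flag it carries.  ``panel_size`` defaults to the number of distinct
    samples present in ``panel``.
    """
    if panel_size is None:
        panel_size = 0 if panel is None or panel.empty else int(panel["sample_id"].nunique())
    flagged = tumor_admrs.copy()
    flagged["flag_matched_normal"] = exclude_matched_normal(tumor_admrs, normal_admrs)
    profiles = partial_methylation_profile(tumor_admrs, panel)
    flagged["flag_panel_partial"] = exclude_panel_partial(tumor_admrs, profiles, panel_size)
    flagged["flag_imprinted"] = exclude_imprinted(tumor_admrs, imprinted_regions)
    any_flag = flagged[[f"flag_{f}" for f in FLAGS]].any(axis=1) if len(flagged) else pd.Series(dtype=bool)
    report = FilterReport(
        n_input=len(flagged),
        n_removed_matched_normal=int(flagged.get("flag_matched_normal", pd.Series(dtype=bool)).sum()),
        n_removed_panel_partial=int(flagged.get("flag_panel_partial", pd.Series(dtype=bool)).sum()),
        n_removed_imprinted=int(flagged.get("flag_imprinted", pd.Series(dtype=bool)).sum()),
        n_removed_total=int(any_flag.sum()) if len(flagged) else 0,
        n_retained=int((~any_flag).sum()) if len(flagged) else 0,
    )
    kept = flagged[~any_flag] if len(flagged) else flagged
    return kept.reset_index(drop=True), report
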