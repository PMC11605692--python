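"""Interval arithmetic on 0-based half-open genomic intervals.

All functions take pandas DataFrames with at least ``chrom``, ``start`` and
``end`` columns (integers, 0-based half-open).  Query results refer to the
positional (iloc) index of the input frames so callers can join back onto
arbitrary indexes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

REQUIRED_COLS = ("chrom", "start", "end")


def check_intervals(df: pd.DataFrame, name: str = "intervals", *, allow_zero_length: bool = False) -> None:
    """Validate an interval frame; raises ValueError naming the first bad row."""
    for col in REQUIRED_COLS:
        if col not in df.columns:
            raise ValueError(f"{name}: missing required column {col!r}")
    start = np.asarray(df["start"], dtype=np.int64)
    end = np.asarray(df["end"], dtype=np.int64)
    bad = start < 0
    if bad.any():
        i = int(np.flatnonzero(bad)[0])
        raise ValueError(f"{name}: negative start at row {i} ({df.iloc[i]['chrom']}:{start[i]}-{end[i]})")
    bad = (end < start) if allow_zero_length else (end <= start)
    if bad.any():
        i = int(np.flatnonzero(bad)[0])
        raise ValueError(f"{name}: empty or inverted interval at row {i} ({df.iloc[i]['chrom']}:{start[i]}-{end[i]})")


def _per_chrom(df: pd.DataFrame):
    for chrom, grp in df.groupby("chrom", sort=False, observed=True):
        yield chrom, grp


def overlap_pairs(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """All pairs (i, j) with a.iloc[i] and b.iloc[j] intersecting by >= 1 bp.

    Returns a frame with columns ``a_idx``, ``b_idx``, ``overlap`` (bp).
    """
    check_intervals(a, "a")
    check_intervals(b, "b")
    out_a, out_b, out_ov = [], [], []
    b_by_chrom = {c: g for c, g in _per_chrom(b)}
    a_pos = {c: g.index for c, g in _per_chrom(a)}
    a_iloc = pd.Series(np.arange(len(a)), index=a.index)
    b_iloc = pd.Series(np.arange(len(b)), index=b.index)
    for chrom, ga in _per_chrom(a):
        gb = b_by_chrom.get(chrom)
        if gb is None:
            continue
        order = np.argsort(np.asarray(gb["start"]), kind="stable")
        bs = np.asarray(gb["start"])[order]
        be = np.asarray(gb["end"])[order]
        bi = np.asarray(b_iloc[gb.index])[order]
        for ai, (s, e) in zip(np.asarray(a_iloc[ga.index]), zip(np.asarray(ga["start"]), np.asarray(ga["end"]))):
            hi = np.searchsorted(bs, e, side="left")  # b.start < a.end
            if hi == 0:
                continue
            mask = be[:hi] > s
            if not mask.any():
                continue
            sel = np.flatnonzero(mask)
            ov = np.minimum(e, be[sel]) - np.maximum(s, bs[sel])
            out_a.extend([ai] * len(sel))
            out_b.extend(bi[sel])
            out_ov.extend(ov)
    return pd.DataFrame({"a_idx": np.array(out_a, dtype=np.int64),
                         "b_idx": np.array(out_b, dtype=np.int64),
                         "overlap": np.array(out_ov, dtype=np.int64)})


def overlaps_any(query: pd.DataFrame, subject: pd.DataFrame) -> np.ndarray:
    """Boolean array over query rows: does the row intersect any subject interval?"""
    flags = np.zeros(len(query), dtype=bool)
    if len(query) and len(subject):
        pairs = overlap_pairs(query, subject)
        flags[pairs["a_idx"].unique()] = True
    return flags


def reciprocal_pairs(a: pd.DataFrame, b: pd.DataFrame, fraction: float = 0.5) -> pd.DataFrame:
    """Pairs overlapping by >= fraction of EITHER interval's length.

    Mirrors ``bedtools intersect -e -f F -F F``: a pair is reported when
    overlap >= fraction*len(a) OR overlap >= fraction*len(b).
    Zero-length intervals are rejected (fraction-of-length is undefined).
    """
    pairs = overlap_pairs(a, b)
    if pairs.empty:
        return pairs
    len_a = (np.asarray(a["end"]) - np.asarray(a["start"]))[pairs["a_idx"]]
    len_b = (np.asarray(b["end"]) - np.asarray(b["start"]))[pairs["b_idx"]]
    keep = (pairs["overlap"] >= fraction * len_a) | (pairs["overlap"] >= fraction * len_b)
    return pairs[np.asarray(keep)].reset_index(drop=True)


def within_distance(query: pd.DataFrame, subject: pd.DataFrame, max_gap: int) -> np.ndarray:
    """Boolean array over query rows: gap to the nearest subject interval <= max_gap.

    The gap between two intersecting or adjacent intervals is 0.
    """
    check_intervals(query, "query")
    check_intervals(subject, "subject")
    flags = np.zeros(len(query), dtype=bool)
    if not len(subject):
        return flags
    subj = {c: (np.sort(np.asarray(g["start"])), np.asarray(g["end"])[np.argsort(np.asarray(g["start"]), kind="stable")])
            for c, g in _per_chrom(subject)}
    q_iloc = pd.Series(np.arange(len(query)), index=query.index)
    for chrom, gq in _per_chrom(query):
        if chrom not in subj:
            continue
        bs, be = subj[chrom]
        for qi, s, e in zip(np.asarray(q_iloc[gq.index]), np.asarray(gq["start"]), np.asarray(gq["end"])):
            gap = np.maximum(np.maximum(bs - e, s - be), 0)
            if gap.min() <= max_gap:
                flags[qi] = True
    return flags


def covering_index(points: pd.DataFrame, segments: pd.DataFrame) -> np.ndarray:
    """For each (chrom, pos) point, the iloc of a segment with start <= pos < end, else -1."""
    if "pos" not in points.columns:
        raise ValueError("points frame needs a 'pos' column")
    check_intervals(segments, "segments")
    out = np.full(len(points), -1, dtype=np.int64)
    seg = {c: g for c, g in _per_chrom(segments)}
    s_iloc = pd.Series(np.arange(len(segments)), index=segments.index)
    p_iloc = pd.Series(np.arange(len(points)), index=points.index)
    for chrom, gp in points.groupby("chrom", sort=False, observed=True):
        gs = seg.get(chrom)
        if gs is None:
            continue
        order = np.argsort(np.asarray(gs["start"]), kind="stable")
        ss = np.asarray(gs["start"])[order]
        se = np.asarray(gs["end"])[order]
        si = np.asarray(s_iloc[gs.index])[order]
        pos = np.asarray(gp["pos"], dtype=np.int64)
        k = np.searchsorted(ss, pos, side="right") - 1
        ok = (k >= 0) & (pos < se[np.clip(k, 0, None)])
        out[np.asarray(p_iloc[gp.index])[ok]] = si[k[ok]]
    return out
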