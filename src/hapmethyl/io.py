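"""Readers and writers for the plain-text dialects used throughout.

All coordinates are 0-based half-open; every writer documents this in a
``#`` header line.  Haplotypes are encoded 1/2 for phased calls and 0 for
unphased.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

COORD_HEADER = "# coordinates: 0-based, half-open"

CALL_COLUMNS = ["chrom", "start", "end", "strand", "haplotype", "n_methylated", "n_total"]
FREQ_COLUMNS = ["sample_id", "chrom", "pos", "frequency", "depth"]
ADMR_COLUMNS = ["chrom", "start", "end", "name", "score", "strand",
                "n_cpgs", "mean_meth_h1", "mean_meth_h2", "diff_methyl", "min_p", "cn_context"]
CN_COLUMNS = ["chrom", "start", "end", "major_cn", "minor_cn"]
DELETION_COLUMNS = ["id", "chrom", "start", "end", "deleted_seq", "left_flank", "right_flank"]
TRANSCRIPT_COLUMNS = ["gene_id", "transcript_id", "chrom", "strand", "tss", "gene_start", "gene_end"]


def _write_tsv(df: pd.DataFrame, path: str, header_note: str = COORD_HEADER) -> None:
    with open(path, "w") as fh:
        fh.write(header_note + "\n")
        df.to_csv(fh, sep="\t", index=False)


def _read_tsv(path: str, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kw)


def write_calls(calls: pd.DataFrame, path: str) -> None:
    _write_tsv(calls[CALL_COLUMNS], path)


def read_calls(path: str) -> pd.DataFrame:
    df = _read_tsv(path, dtype={"chrom": str})
    missing = set(CALL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df[CALL_COLUMNS]


def write_panel_frequencies(freqs: pd.DataFrame, path: str) -> None:
    _write_tsv(freqs[FREQ_COLUMNS], path)


def read_panel_frequencies(path: str) -> pd.DataFrame:
    df = _read_tsv(path, dtype={"chrom": str, "sample_id": str})
    missing = set(FREQ_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df[FREQ_COLUMNS]


def read_nanopolish_frequency(path: str, sample_id: str = "sample") -> pd.DataFrame:
    """Read a nanopolish-style methylation frequency TSV.

    Requires columns chromosome, start, end, methylated_frequency at minimum;
    extra columns are ignored.  ``called_sites`` is used as depth when present.
    """
    df = _read_tsv(path, dtype={"chromosome": str})
    need = {"chromosome", "start", "end", "methylated_frequency"}
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    depth = df["called_sites"] if "called_sites" in df.columns else pd.Series(np.zeros(len(df), dtype=int))
    return pd.DataFrame({
        "sample_id": sample_id,
        "chrom": df["chromosome"],
        "pos": df["start"].astype(np.int64),
        "frequency": df["methylated_frequency"].astype(float),
        "depth": depth.astype(np.int64),
    })


def write_bed(df: pd.DataFrame, path: str, extra_cols: list[str] | None = None) -> None:
    cols = ["chrom", "start", "end"] + (extra_cols or [])
    _write_tsv(df[cols], path)


def read_bed(path: str) -> pd.DataFrame:
    df = _read_tsv(path, dtype={"chrom": str})
    if not {"chrom", "start", "end"}.issubset(df.columns):
        # headerless three-column BED
        df = pd.read_csv(path, sep="\t", comment="#", header=None,
                         names=["chrom", "start", "end"], usecols=[0, 1, 2], dtype={0: str})
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    return df


def write_admrs(admrs: pd.DataFrame, path: str) -> None:
    """aDMRs as BED6+ (score = round(1000*|diff_methyl|), strand '.')."""
    out = admrs.copy()
    if "name" not in out.columns:
        out["name"] = [f"admr_{i:06d}" for i in range(len(out))]
    out["score"] = np.round(1000 * out["diff_methyl"].abs()).astype(int)
    out["strand"] = "."
    if "cn_context" not in out.columns:
        out["cn_context"] = "unknown"
    _write_tsv(out[ADMR_COLUMNS], path)


def read_admrs(path: str) -> pd.DataFrame:
    return _read_tsv(path, dtype={"chrom": str})


def write_cn_segments(segments: pd.DataFrame, path: str) -> None:
    _write_tsv(segments[CN_COLUMNS], path)


def read_cn_segments(path: str) -> pd.DataFrame:
    df = _read_tsv(path, dtype={"chrom": str})
    missing = set(CN_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_deletions(deletions: pd.DataFrame, path: str) -> None:
    _write_tsv(deletions[DELETION_COLUMNS], path)


def read_deletions(path: str) -> pd.DataFrame:
    df = _read_tsv(path, dtype={"chrom": str, "id": str})
    missing = set(DELETION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_transcripts(transcripts: pd.DataFrame, path: str) -> None:
    _write_tsv(transcripts[TRANSCRIPT_COLUMNS], path)


def read_transcripts(path: str) -> pd.DataFrame:
    df = _read_tsv(path, dtype={"chrom": str})
    missing = set(TRANSCRIPT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_manifest(directory: str, entries: dict[str, str]) -> None:
    """Manifest for a fixture-bundle directory: filename -> description."""
    with open(os.path.join(directory, "MANIFEST.tsv"), "w") as fh:
        fh.write("# fixture bundle manifest; coordinates 0-based half-open\n")
        fh.write("file\tdescription\n")
        for name, desc in entries.items():
            fh.write(f"{name}\t{desc}\n")
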