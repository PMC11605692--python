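"""Ground-truth-annotated synthetic inputs for every pipeline stage.

Simulates phased tumor/normal methylomes with planted allelic regions, a
normal WGBS frequency panel, phased allelic RNA counts, allele-specific
copy-number segments, and deletion records with flanking sequence.  All
draws derive from ``SimConfig.seed``; identical configs give bit-identical
outputs.  Coordinates are 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CHROM_PREFIX = "chr"
CPG_WIDTH = 2  # a CG dyad occupies [pos, pos+2)

ADMR_CLASSES = ("tumor_specific", "imprinted", "random_asm", "cnv_driven")


class PackingError(ValueError):
    """Raised when the requested planted regions cannot fit in the genome."""


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    n_chromosomes: int = 2
    chrom_length_bp: int = 1_000_000
    n_cpgs_per_chrom: int = 2000
    mean_coverage_per_haplotype: float = 13.0
    n_planted_tumor_admrs: int = 6
    n_planted_imprinted_regions: int = 2
    n_planted_random_asm: int = 2
    n_planted_cnv_driven: int = 0
    admr_delta: float = 0.5
    admr_width_cpgs: int = 20
    panel_size: int = 20
    panel_partial_fraction_at_imprinted: float = 0.9
    panel_mean_depth: float = 30.0
    panel_low_depth_fraction: float = 0.0
    n_ase_genes: int = 20
    n_null_genes: int = 100
    ase_maf: float = 0.8
    reads_per_ase_gene: int = 100
    ase_trans_fraction: float = 0.8
    loh_fraction_of_genome: float = 0.2
    n_cn_segments_per_chrom: int = 32
    n_deletions: int = 200
    mh_deletion_fraction_true: float = 0.4
    min_deletion_length: int = 1

    def __post_init__(self):
        fractions = {
            "admr_delta": self.admr_delta,
            "panel_partial_fraction_at_imprinted": self.panel_partial_fraction_at_imprinted,
            "panel_low_depth_fraction": self.panel_low_depth_fraction,
            "ase_maf": self.ase_maf,
            "ase_trans_fraction": self.ase_trans_fraction,
            "loh_fraction_of_genome": self.loh_fraction_of_genome,
            "mh_deletion_fraction_true": self.mh_deletion_fraction_true,
        }
        for name, value in fractions.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        counts = {
            "n_chromosomes": self.n_chromosomes, "chrom_length_bp": self.chrom_length_bp,
            "n_cpgs_per_chrom": self.n_cpgs_per_chrom,
            "n_planted_tumor_admrs": self.n_planted_tumor_admrs,
            "n_planted_imprinted_regions": self.n_planted_imprinted_regions,
            "n_planted_random_asm": self.n_planted_random_asm,
            "n_planted_cnv_driven": self.n_planted_cnv_driven,
            "admr_width_cpgs": self.admr_width_cpgs, "panel_size": self.panel_size,
            "n_ase_genes": self.n_ase_genes, "n_null_genes": self.n_null_genes,
            "reads_per_ase_gene": self.reads_per_ase_gene,
            "n_deletions": self.n_deletions, "min_deletion_length": self.min_deletion_length,
        }
        for name, value in counts.items():
            if value < 0:
                raise ValueError(f"{name} must be >= 0, got {value}")
        if self.mean_coverage_per_haplotype < 0 or self.panel_mean_depth < 0:
            raise ValueError("coverage parameters must be >= 0")


@dataclass
class TruthSet:
    """Ground truth for planted features; each feature appears exactly once."""

    planted_admrs: pd.DataFrame = field(default_factory=pd.DataFrame)
    planted_ase_genes: pd.DataFrame = field(default_factory=pd.DataFrame)
    planted_mh_deletions: list = field(default_factory=list)
    loh_segments: pd.DataFrame = field(default_factory=pd.DataFrame)


def chrom_names(config: SimConfig) -> list[str]:
    return [f"{CHROM_PREFIX}{i + 1}" for i in range(config.n_chromosomes)]


# ---------------------------------------------------------------------------
# genome layout (shared between tumor, normal and the WGBS panel)
# ---------------------------------------------------------------------------

def _rng(config: SimConfig, *stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, *stream])


def genome_layout(config: SimConfig) -> dict:
    """CpG positions, background frequencies and planted regions.

    Deterministic in the seed and independent of sample role, so tumor,
    matched normal and panel all see the same genome.
    """
    rng = _rng(config, 101)
    layout = {"chroms": {}, "regions": None}
    for chrom in chrom_names(config):
        n = config.n_cpgs_per_chrom
        max_slots = (config.chrom_length_bp - CPG_WIDTH) // CPG_WIDTH
        if n > max_slots:
            raise PackingError(f"{chrom}: {n} CpGs do not fit in {config.chrom_length_bp} bp")
        pos = np.sort(rng.choice(max_slots, size=n, replace=False)) * CPG_WIDTH
        # genome-wide bimodal background: mostly-unmethylated and
        # mostly-methylated domains.  The mixture component persists over
        # blocks of CpGs (methylation is locally coherent in real genomes);
        # per-site values jitter around the block base.
        freq = np.empty(n)
        i = 0
        while i < n:
            width = int(rng.geometric(1.0 / 10.0))
            base = rng.beta(10.0, 0.5) if rng.random() < 0.5 else rng.beta(0.5, 10.0)
            j = min(i + width, n)
            freq[i:j] = np.clip(base + rng.normal(0.0, 0.03, size=j - i), 0.001, 0.999)
            i = j
        layout["chroms"][chrom] = {"pos": pos, "bg_freq": freq}
    layout["regions"] = _plant_regions(config, layout, rng)
    return layout


def _plant_regions(config: SimConfig, layout: dict, rng: np.random.Generator) -> pd.DataFrame:
    classes = (["tumor_specific"] * config.n_planted_tumor_admrs
               + ["imprinted"] * config.n_planted_imprinted_regions
               + ["random_asm"] * config.n_planted_random_asm
               + ["cnv_driven"] * config.n_planted_cnv_driven)
    chroms = chrom_names(config)
    width = config.admr_width_cpgs
    gap = max(5, width // 2)  # CpG-index gap so neighbouring plants stay separable
    taken: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    rows = []
    for k, cls in enumerate(classes):
        placed = False
        for _ in range(2000):
            chrom = chroms[int(rng.integers(len(chroms)))]
            n = config.n_cpgs_per_chrom
            if n < width:
                continue
            i0 = int(rng.integers(n - width + 1))
            lo, hi = i0 - gap, i0 + width + gap
            if any(not (hi <= a or lo >= b) for a, b in taken[chrom]):
                continue  # rejection-resample on overlap
            taken[chrom].append((lo, hi))
            pos = layout["chroms"][chrom]["pos"]
            # planted regions sit on a coherent regional base (CGI-like,
            # mostly unmethylated) so the allelic shift is region-consistent
            base = float(rng.beta(0.5, 10.0))
            info = layout["chroms"][chrom]
            info["bg_freq"][i0:i0 + width] = np.clip(
                base + rng.normal(0.0, 0.02, size=width), 0.001, 0.999)
            rows.append({
                "region_id": f"plant_{k:04d}",
                "chrom": chrom,
                "start": int(pos[i0]),
                "end": int(pos[i0 + width - 1]) + CPG_WIDTH,
                "cls": cls,
                "cpg_lo": i0,
                "cpg_hi": i0 + width,
                "hyper_haplotype": int(rng.integers(1, 3)),
            })
            placed = True
            break
        if not placed:
            raise PackingError(
                f"could not place {len(classes)} regions of {width} CpGs "
                f"on {len(chroms)} chromosome(s) of {config.n_cpgs_per_chrom} CpGs")
    cols = ["region_id", "chrom", "start", "end", "cls", "cpg_lo", "cpg_hi", "hyper_haplotype"]
    return pd.DataFrame(rows, columns=cols)


def _shift_away_from_boundary(freq: np.ndarray, delta: float) -> np.ndarray:
    """Shift frequencies by +-delta, choosing the sign that stays in [0, 1]."""
    up = freq + delta
    down = freq - delta
    return np.clip(np.where(up <= 1.0, up, down), 0.0, 1.0)


def _haplotype_frequencies(config: SimConfig, layout: dict, role: str) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-chromosome (haplotype-1, haplotype-2) true site frequencies for a role."""
    if role not in ("tumor", "normal"):
        raise ValueError(f"role must be 'tumor' or 'normal', got {role!r}")
    out = {}
    for chrom, info in layout["chroms"].items():
        f1 = info["bg_freq"].copy()
        f2 = info["bg_freq"].copy()
        out[chrom] = (f1, f2)
    regions = layout["regions"]
    for _, reg in regions.iterrows():
        # somatic classes only exist in the tumor role
        if reg["cls"] in ("tumor_specific", "cnv_driven") and role != "tumor":
            continue
        f1, f2 = out[reg["chrom"]]
        sl = slice(reg["cpg_lo"], reg["cpg_hi"])
        hyper = reg["hyper_haplotype"]
        if reg["cls"] == "imprinted":
            # one haplotype near-fully methylated in both roles
            (f1 if hyper == 1 else f2)[sl] = 0.95
            (f2 if hyper == 1 else f1)[sl] = 0.05
        else:
            target = f1 if hyper == 1 else f2
            target[sl] = _shift_away_from_boundary(target[sl], config.admr_delta)
    return out


# ---------------------------------------------------------------------------
# phased methylome
# ---------------------------------------------------------------------------

def simulate_phased_methylome(config: SimConfig, role: str = "tumor") -> tuple[pd.DataFrame, TruthSet]:
    """Per-CpG, per-strand, per-haplotype methylation calls plus ground truth.

    Both strands of every CpG are emitted; the minus-strand record sits at
    pos+1 (the G of the dyad).  Read totals are Poisson with mean
    ``mean_coverage_per_haplotype / 2`` per strand; methylated counts are
    binomial at the site's true haplotype frequency.
    """
    layout = genome_layout(config)
    freqs = _haplotype_frequencies(config, layout, role)
    rng = _rng(config, 111, 1 if role == "tumor" else 2)
    lam = config.mean_coverage_per_haplotype / 2.0
    frames = []
    for chrom in chrom_names(config):
        pos = layout["chroms"][chrom]["pos"]
        n = len(pos)
        f1, f2 = freqs[chrom]
        for hap, f in ((1, f1), (2, f2)):
            for strand, offset in (("+", 0), ("-", 1)):
                total = rng.poisson(lam, size=n)
                meth = rng.binomial(total, f)
                frames.append(pd.DataFrame({
                    "chrom": chrom,
                    "start": pos + offset,
                    "end": pos + offset + 1,
                    "strand": strand,
                    "haplotype": hap,
                    "n_methylated": meth,
                    "n_total": total,
                }))
    calls = (pd.concat(frames, ignore_index=True)
             .sort_values(["chrom", "start", "haplotype", "strand"], kind="stable")
             .reset_index(drop=True))
    truth = TruthSet(planted_admrs=layout["regions"].copy())
    return calls, truth


# ---------------------------------------------------------------------------
# normal WGBS panel
# ---------------------------------------------------------------------------

def simulate_normal_wgbs_panel(config: SimConfig, truth: TruthSet) -> pd.DataFrame:
    """Unphased methylation-frequency panel over the same CpG layout.

    At planted imprinted regions a ``panel_partial_fraction_at_imprinted``
    share of samples shows partial methylation (frequency in [0.35, 0.65]);
    everywhere else samples follow the bimodal background (full/empty).
    Returns a long frame (sample_id, chrom, pos, frequency, depth).
    """
    layout = genome_layout(config)
    rng = _rng(config, 121)
    imprinted = truth.planted_admrs
    imprinted = imprinted[imprinted["cls"] == "imprinted"] if len(imprinted) else imprinted
    frames = []
    for s in range(config.panel_size):
        sample_id = f"panel_{s:03d}"
        for chrom in chrom_names(config):
            info = layout["chroms"][chrom]
            pos, bg = info["pos"], info["bg_freq"]
            n = len(pos)
            depth = rng.poisson(config.panel_mean_depth, size=n)
            if config.panel_low_depth_fraction > 0:
                low = rng.random(n) < config.panel_low_depth_fraction
                depth[low] = rng.poisson(2.0, size=int(low.sum()))
            true_f = bg.copy()
            forced = np.full(n, np.nan)  # partial sites: emit the frequency directly
            if len(imprinted):
                for _, reg in imprinted[imprinted["chrom"] == chrom].iterrows():
                    sl = slice(reg["cpg_lo"], reg["cpg_hi"])
                    width = reg["cpg_hi"] - reg["cpg_lo"]
                    if rng.random() < config.panel_partial_fraction_at_imprinted:
                        forced[sl] = rng.uniform(0.38, 0.62, size=width)
                    else:
                        # whole region reads as fully or barely methylated
                        true_f[sl] = 0.97 if rng.random() < 0.5 else 0.03
            meth = rng.binomial(depth, true_f)
            with np.errstate(invalid="ignore"):
                freq = np.where(depth > 0, meth / np.maximum(depth, 1), 0.0)
            freq = np.where(np.isnan(forced), freq, forced)
            frames.append(pd.DataFrame({
                "sample_id": sample_id, "chrom": chrom, "pos": pos,
                "frequency": freq, "depth": depth,
            }))
    if not frames:
        return pd.DataFrame(columns=["sample_id", "chrom", "pos", "frequency", "depth"])
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# allelic expression
# ---------------------------------------------------------------------------

def simulate_allelic_expression(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Phased per-SNP allelic RNA counts, a TPM table, and ASE ground truth.

    Null genes draw haplotype-1 reads Binomial(n, 0.5); planted ASE genes use
    ``ase_maf`` on a randomly chosen major haplotype.  Each gene carries
    1-10 phased SNPs; TPM values straddle the 1-TPM threshold by design.
    For planted ASE genes a hypermethylated promoter haplotype is chosen,
    in trans with the major expressed allele for ``ase_trans_fraction``
    of genes (methylation-silenced alleles).
    """
    rng = _rng(config, 131)
    chroms = chrom_names(config)
    snv_rows, tpm_rows, truth_rows = [], [], []
    n_total = config.n_ase_genes + config.n_null_genes
    for g in range(n_total):
        gene_id = f"GENE{g:05d}"
        is_ase = g < config.n_ase_genes and config.ase_maf != 0.5
        maf = config.ase_maf if is_ase else 0.5
        major = int(rng.integers(1, 3))
        n_snps = int(rng.integers(1, 11))
        chrom = chroms[int(rng.integers(len(chroms)))]
        base = int(rng.integers(0, config.chrom_length_bp - 1000))
        for s in range(n_snps):
            n_reads = max(1, int(rng.poisson(config.reads_per_ase_gene / n_snps)))
            major_reads = int(rng.binomial(n_reads, maf))
            h1 = major_reads if major == 1 else n_reads - major_reads
            snv_rows.append({
                "gene_id": gene_id, "chrom": chrom, "pos": base + 10 * s,
                "hap1_reads": h1, "hap2_reads": n_reads - h1,
            })
        if is_ase:
            tpm = float(np.round(rng.uniform(1.5, 60.0), 3))
        else:
            # a fifth of null genes fall below the 1-TPM floor
            tpm = float(np.round(rng.uniform(0.1, 0.99), 3)) if rng.random() < 0.2 \
                else float(np.round(rng.uniform(1.0, 60.0), 3))
        tpm_rows.append({"gene_id": gene_id, "tpm": tpm})
        if is_ase:
            trans = bool(rng.random() < config.ase_trans_fraction)
            hyper = (2 if major == 1 else 1) if trans else major
            truth_rows.append({
                "gene_id": gene_id, "true_maf": maf, "major_haplotype": major,
                "hypermeth_haplotype": hyper, "silenced_in_trans": trans,
            })
    snvs = pd.DataFrame(snv_rows, columns=["gene_id", "chrom", "pos", "hap1_reads", "hap2_reads"])
    tpm = pd.DataFrame(tpm_rows, columns=["gene_id", "tpm"])
    truth = pd.DataFrame(truth_rows, columns=["gene_id", "true_maf", "major_haplotype",
                                              "hypermeth_haplotype", "silenced_in_trans"])
    return snvs, tpm, truth


# ---------------------------------------------------------------------------
# copy-number segments
# ---------------------------------------------------------------------------

def toy_karyotype(config: SimConfig) -> pd.DataFrame:
    """Arm bounds for the synthetic genome: centromere at 40% of each chromosome."""
    return pd.DataFrame({
        "chrom": chrom_names(config),
        "length": config.chrom_length_bp,
        "centromere": int(0.4 * config.chrom_length_bp),
    })


def simulate_cn_segments(config: SimConfig) -> pd.DataFrame:
    """Allele-specific CN segments tiling each chromosome without gaps.

    ``loh_fraction_of_genome`` of total length (within one segment's
    granularity) gets minor_cn = 0; the rest splits between balanced (1,1)
    and imbalanced heterozygous states.
    """
    rng = _rng(config, 141)
    rows = []
    for chrom in chrom_names(config):
        n_seg = config.n_cn_segments_per_chrom
        cuts = np.sort(rng.choice(config.chrom_length_bp - 1, size=n_seg - 1, replace=False)) + 1
        bounds = np.concatenate([[0], cuts, [config.chrom_length_bp]])
        for s, e in zip(bounds[:-1], bounds[1:]):
            rows.append({"chrom": chrom, "start": int(s), "end": int(e)})
    segs = pd.DataFrame(rows)
    lengths = (segs["end"] - segs["start"]).to_numpy()
    genome = float(lengths.sum())
    target = config.loh_fraction_of_genome * genome
    order = rng.permutation(len(segs))
    is_loh = np.zeros(len(segs), dtype=bool)
    acc = 0.0
    for i in order:
        if acc + lengths[i] <= target + 0.02 * genome and acc < target:
            is_loh[i] = True
            acc += lengths[i]
    major = np.ones(len(segs), dtype=np.int64)
    minor = np.ones(len(segs), dtype=np.int64)
    states = np.array([[1, 1], [2, 1], [2, 2], [3, 1]])
    picks = rng.choice(len(states), size=len(segs), p=[0.6, 0.2, 0.1, 0.1])
    major[:] = states[picks, 0]
    minor[:] = states[picks, 1]
    major[is_loh] = rng.integers(1, 4, size=int(is_loh.sum()))
    minor[is_loh] = 0
    segs["major_cn"] = major
    segs["minor_cn"] = minor
    karyo = toy_karyotype(config).set_index("chrom")
    cen = karyo.loc[segs["chrom"], "centromere"].to_numpy()
    mid = (segs["start"] + segs["end"]) // 2
    segs["arm"] = np.where(mid < cen, "p", "q")
    return segs


# ---------------------------------------------------------------------------
# deletions with flanking sequence
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))
FLANK_LEN = 12


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BASES, size=n))


def _other_base(rng: np.random.Generator, base: str) -> str:
    choices = [b for b in "ACGT" if b != base]
    return choices[int(rng.integers(3))]


def simulate_deletions_with_flanks(config: SimConfig) -> tuple[pd.DataFrame, TruthSet]:
    """Deletion records; a controlled fraction of the >3 bp ones carry planted
    microhomology of exactly 1-5 bp between deleted sequence and right flank.

    The remainder (and all <=3 bp deletions) are rejection-checked to be
    homology-free on both sides.
    """
    rng = _rng(config, 151)
    chroms = chrom_names(config)
    rows, mh_ids, mh_lens = [], [], []
    for i in range(config.n_deletions):
        del_id = f"del_{i:05d}"
        length = int(rng.integers(config.min_deletion_length, 61))
        deleted = _random_seq(rng, length)
        plant = length > 3 and rng.random() < config.mh_deletion_fraction_true
        if plant:
            k = int(min(rng.integers(1, 6), length))
            right = deleted[:k] + _random_seq(rng, FLANK_LEN - k)
            if k < length and right[k] == deleted[k]:  # keep homology exactly k
                right = right[:k] + _other_base(rng, deleted[k]) + right[k + 1:]
            left = _random_seq(rng, FLANK_LEN)
            while left[-1] == deleted[-1]:
                left = left[:-1] + _other_base(rng, deleted[-1])
            mh_ids.append(del_id)
            mh_lens.append(k)
        else:
            left = _random_seq(rng, FLANK_LEN)
            right = _random_seq(rng, FLANK_LEN)
            # reject accidental homology at either breakpoint
            while right[0] == deleted[0]:
                right = _other_base(rng, deleted[0]) + right[1:]
            while left[-1] == deleted[-1]:
                left = left[:-1] + _other_base(rng, deleted[-1])
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(FLANK_LEN, config.chrom_length_bp - length - FLANK_LEN))
        rows.append({
            "id": del_id, "chrom": chrom, "start": start, "end": start + length,
            "deleted_seq": deleted, "left_flank": left, "right_flank": right,
        })
    deletions = pd.DataFrame(rows, columns=["id", "chrom", "start", "end",
                                            "deleted_seq", "left_flank", "right_flank"])
    truth = TruthSet(planted_mh_deletions=list(zip(mh_ids, mh_lens)))
    return deletions, truth


# ---------------------------------------------------------------------------
# annotation tracks and HRD cohort helpers (artifact plumbing for the demo)
# ---------------------------------------------------------------------------

def simulate_feature_tracks(config: SimConfig, truth: TruthSet,
                            promoter_fraction: float = 0.6,
                            n_random_features: int = 30,
                            ) -> tuple[dict[str, pd.DataFrame], pd.DataFrame, pd.DataFrame]:
    """Feature BED tracks and a transcript table over the synthetic genome.

    Places promoters over ``promoter_fraction`` of planted aDMRs (so the
    annotation summary has a known expectation) plus random CGI/enhancer/TF/
    polyA features elsewhere.
    """
    rng = _rng(config, 161)
    chroms = chrom_names(config)
    regions = truth.planted_admrs
    tx_rows = []
    for i, (_, reg) in enumerate(regions.iterrows()):
        if rng.random() >= promoter_fraction:
            continue
        strand = "+" if rng.random() < 0.5 else "-"
        mid = (reg["start"] + reg["end"]) // 2
        # choose the TSS so the promoter window covers the planted region
        tss = mid + 400 if strand == "+" else mid - 400
        tx_rows.append({
            "gene_id": f"G{i:04d}", "transcript_id": f"T{i:04d}",
            "chrom": reg["chrom"], "strand": strand, "tss": int(max(tss, 1600)),
            "gene_start": int(max(tss - (0 if strand == "+" else 20000), 0)),
            "gene_end": int(tss + (20000 if strand == "+" else 0)),
        })
    for j in range(n_random_features):
        strand = "+" if rng.random() < 0.5 else "-"
        tss = int(rng.integers(2000, config.chrom_length_bp - 25000))
        tx_rows.append({
            "gene_id": f"GR{j:04d}", "transcript_id": f"TR{j:04d}",
            "chrom": chroms[int(rng.integers(len(chroms)))], "strand": strand,
            "tss": tss,
            "gene_start": tss if strand == "+" else tss - 20000,
            "gene_end": tss + 20000 if strand == "+" else tss,
        })
    transcripts = pd.DataFrame(tx_rows, columns=["gene_id", "transcript_id", "chrom",
                                                 "strand", "tss", "gene_start", "gene_end"])

    def random_track(width_lo, width_hi, n):
        starts = rng.integers(0, config.chrom_length_bp - width_hi, size=n)
        widths = rng.integers(width_lo, width_hi, size=n)
        return pd.DataFrame({
            "chrom": rng.choice(chroms, size=n),
            "start": starts, "end": starts + widths,
        }).astype({"start": np.int64, "end": np.int64})

    tracks = {
        "CGI": random_track(300, 2000, n_random_features),
        "enhancer": random_track(200, 1500, n_random_features),
        "TF_site": random_track(10, 50, n_random_features),
    }
    polya = pd.DataFrame({
        "chrom": rng.choice(chroms, size=n_random_features),
        "pos": rng.integers(1000, config.chrom_length_bp - 1000, size=n_random_features),
    })
    return tracks, transcripts, polya


def simulate_signature_exposures(config: SimConfig, hrd_like: bool,
                                 stream: int = 0) -> dict[str, float]:
    """SBS / SV signature exposures for one sample (inputs, not fitted here)."""
    rng = _rng(config, 171, stream)
    if hrd_like:
        return {"sbs3": float(rng.gamma(9, 400)), "sbs8": float(rng.gamma(4, 150)),
                "sv3": float(rng.gamma(6, 30)), "sv5": float(rng.gamma(4, 20))}
    return {"sbs3": float(rng.gamma(1.2, 40)), "sbs8": float(rng.gamma(1.5, 40)),
            "sv3": float(rng.gamma(1.1, 5)), "sv5": float(rng.gamma(1.5, 8))}
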