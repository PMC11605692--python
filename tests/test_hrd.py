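import math

import numpy as np
import pandas as pd
import pytest

from hapmethyl.hrd import (COEFFICIENTS, FEATURE_ORDER, INTERCEPT, ScarScores,
                           classify_hrd_high, hrd_index, hrdetect_score,
                           microhomology_deletion_fraction, microhomology_length,
                           promoter_methylation_fraction, scar_scores,
                           standardize_features)


# -- microhomology -----------------------------------------------------------

def test_mh_right_flank_prefix():
    assert microhomology_length("ACGT", "GGGGGGGGGG", "ACTTGGGGGG") == 2


def test_mh_none():
    assert microhomology_length("TTTT", "GGGGGGGGGG", "CCCCCCCCCC") == 0


def test_mh_left_flank_suffix():
    # deleted ends with 'CGT'; left flank ends with 'CGT'
    assert microhomology_length("AACGT", "GGGGGGGCGT", "TTTTTTTTTT") == 3


def test_mh_capped_at_deletion_length():
    assert microhomology_length("AC", "GGGGGGGGAC", "ACGGGGGGGG") == 2


def test_mh_matches_bruteforce(rng):
    bases = np.array(list("ACGT"))
    for _ in range(200):
        d = "".join(rng.choice(bases, size=int(rng.integers(1, 30))))
        lf = "".join(rng.choice(bases, size=12))
        rf = "".join(rng.choice(bases, size=12))
        # brute-force all-k scan
        best = 0
        for k in range(1, len(d) + 1):
            if k <= len(rf) and d[:k] == rf[:k]:
                best = max(best, k)
            if k <= len(lf) and d[-k:] == lf[-k:]:
                best = max(best, k)
        assert microhomology_length(d, lf, rf) == best


def del_frame(specs):
    """specs: list of (length, deleted, left, right)."""
    rows = []
    for i, (length, d, lf, rf) in enumerate(specs):
        rows.append({"id": f"d{i}", "chrom": "chr1", "start": 1000 * i,
                     "end": 1000 * i + length, "deleted_seq": d,
                     "left_flank": lf, "right_flank": rf})
    return pd.DataFrame(rows)


def test_mh_fraction_arithmetic():
    with_mh = [(5, "ACGTA", "G" * 10, "ACGTA" + "G" * 5)] * 4
    without = [(5, "TTTTT", "G" * 10, "C" * 10)] * 6
    dels = del_frame(with_mh + without)
    assert microhomology_deletion_fraction(dels) == pytest.approx(0.4)


def test_mh_fraction_all_short_warns():
    dels = del_frame([(2, "AC", "G" * 10, "C" * 10)] * 5)
    with pytest.warns(UserWarning):
        assert microhomology_deletion_fraction(dels) == 0.0


def test_mh_fraction_denominator_modes():
    with_mh = [(5, "ACGTA", "G" * 10, "ACGTA" + "G" * 5)] * 2
    short = [(2, "TT", "G" * 10, "C" * 10)] * 2
    clean = [(10, "T" * 10, "G" * 10, "C" * 10)] * 1
    dels = del_frame(with_mh + short + clean)
    assert microhomology_deletion_fraction(dels, denominator="all") == pytest.approx(2 / 5)
    assert microhomology_deletion_fraction(dels, denominator="gt3") == pytest.approx(2 / 3)


# -- scar scores -------------------------------------------------------------

def karyo(n=2, length=100_000_000, cen=40_000_000):
    return pd.DataFrame({"chrom": [f"chr{i+1}" for i in range(n)],
                         "length": length, "centromere": cen})


def seg(chrom, start, end, major, minor):
    return {"chrom": chrom, "start": start, "end": end, "major_cn": major, "minor_cn": minor}


def test_scar_all_balanced_zero():
    segs = pd.DataFrame([seg("chr1", 0, 100_000_000, 1, 1),
                         seg("chr2", 0, 100_000_000, 1, 1)])
    s = scar_scores(segs, karyo())
    assert (s.loh, s.tai, s.lst) == (0, 0, 0)


def test_scar_interstitial_loh():
    segs = pd.DataFrame([seg("chr1", 10_000_000, 30_000_000, 2, 0),
                         seg("chr1", 0, 10_000_000, 1, 1),
                         seg("chr1", 30_000_000, 100_000_000, 1, 1),
                         seg("chr2", 0, 100_000_000, 1, 1)])
    assert scar_scores(segs, karyo()).loh == 1


def test_scar_whole_chromosome_loh_not_counted():
    segs = pd.DataFrame([seg("chr1", 0, 100_000_000, 2, 0),
                         seg("chr2", 0, 100_000_000, 1, 1)])
    assert scar_scores(segs, karyo()).loh == 0


def test_scar_tai_telomeric_imbalance():
    segs = pd.DataFrame([seg("chr1", 0, 20_000_000, 2, 1),      # reaches p end, no cen
                         seg("chr1", 20_000_000, 100_000_000, 1, 1),
                         seg("chr2", 0, 100_000_000, 1, 1)])
    s = scar_scores(segs, karyo())
    assert s.tai == 1


def test_scar_tai_crossing_centromere_excluded():
    segs = pd.DataFrame([seg("chr1", 0, 50_000_000, 2, 1),  # spans the 40 Mb centromere
                         seg("chr1", 50_000_000, 100_000_000, 1, 1),
                         seg("chr2", 0, 100_000_000, 1, 1)])
    assert scar_scores(segs, karyo()).tai == 0


def test_scar_subdivision_invariance():
    whole = pd.DataFrame([seg("chr1", 0, 20_000_000, 2, 1),
                          seg("chr1", 20_000_000, 100_000_000, 1, 1),
                          seg("chr2", 0, 100_000_000, 1, 1)])
    split = pd.DataFrame([seg("chr1", 0, 7_000_000, 2, 1),
                          seg("chr1", 7_000_000, 20_000_000, 2, 1),
                          seg("chr1", 20_000_000, 60_000_000, 1, 1),
                          seg("chr1", 60_000_000, 100_000_000, 1, 1),
                          seg("chr2", 0, 100_000_000, 1, 1)])
    assert scar_scores(whole, karyo()) == scar_scores(split, karyo())


def oracle_scar(segs, kary, loh_min=15_000_000, lst_min=10_000_000, smooth=3_000_000):
    """Independent straight-loop re-implementation of the three rules."""
    kary = kary.set_index("chrom")
    # merge equal adjacent
    merged = []
    for chrom in segs["chrom"].unique():
        grp = segs[segs["chrom"] == chrom].sort_values("start").to_dict("records")
        cur = None
        for s in grp:
            if cur and cur["end"] == s["start"] and (cur["major_cn"], cur["minor_cn"]) == (s["major_cn"], s["minor_cn"]):
                cur = dict(cur, end=s["end"])
            else:
                if cur:
                    merged.append(cur)
                cur = dict(s)
        merged.append(cur)
    loh = tai = lst = 0
    for s in merged:
        L = kary.loc[s["chrom"], "length"]
        cen = kary.loc[s["chrom"], "centromere"]
        whole = s["start"] == 0 and s["end"] == L
        if s["minor_cn"] == 0 and s["end"] - s["start"] > loh_min and not whole:
            loh += 1
        if (s["major_cn"] != s["minor_cn"] and (s["start"] == 0 or s["end"] == L)
                and not (s["start"] < cen < s["end"]) and not whole):
            tai += 1
    for chrom in segs["chrom"].unique():
        L = kary.loc[chrom, "length"]
        cen = kary.loc[chrom, "centromere"]
        for lo, hi in ((0, cen), (cen, L)):
            arm = []
            for s in sorted((x for x in merged if x["chrom"] == chrom), key=lambda x: x["start"]):
                a, b = max(s["start"], lo), min(s["end"], hi)
                if b > a:
                    arm.append({"start": a, "end": b, "st": (s["major_cn"], s["minor_cn"])})
            # absorb smallest-first
            while len(arm) > 1:
                i = min(range(len(arm)), key=lambda j: arm[j]["end"] - arm[j]["start"])
                if arm[i]["end"] - arm[i]["start"] >= smooth:
                    break
                if i == 0:
                    arm[1]["start"] = arm[0]["start"]
                elif i == len(arm) - 1:
                    arm[-2]["end"] = arm[-1]["end"]
                else:
                    llen = arm[i - 1]["end"] - arm[i - 1]["start"]
                    rlen = arm[i + 1]["end"] - arm[i + 1]["start"]
                    if llen >= rlen:
                        arm[i - 1]["end"] = arm[i]["end"]
                    else:
                        arm[i + 1]["start"] = arm[i]["start"]
                del arm[i]
                j = 0
                while j < len(arm) - 1:
                    if arm[j]["end"] == arm[j + 1]["start"] and arm[j]["st"] == arm[j + 1]["st"]:
                        arm[j]["end"] = arm[j + 1]["end"]
                        del arm[j + 1]
                    else:
                        j += 1
            for a, b in zip(arm[:-1], arm[1:]):
                if a["st"] != b["st"] and (a["end"] - a["start"]) >= lst_min \
                        and (b["end"] - b["start"]) >= lst_min:
                    lst += 1
    return loh, tai, lst


@pytest.mark.parametrize("seed", range(5))
def test_scar_matches_independent_oracle(seed):
    rng = np.random.default_rng(seed)
    rows = []
    for chrom in ("chr1", "chr2"):
        cuts = np.sort(rng.choice(np.arange(1, 100), size=9, replace=False)) * 1_000_000
        bounds = np.concatenate([[0], cuts, [100_000_000]])
        states = [(1, 1), (2, 1), (2, 0), (3, 1), (2, 2), (1, 0)]
        for a, b in zip(bounds[:-1], bounds[1:]):
            major, minor = states[int(rng.integers(len(states)))]
            rows.append(seg(chrom, int(a), int(b), major, minor))
    segs = pd.DataFrame(rows)
    got = scar_scores(segs, karyo())
    assert (got.loh, got.tai, got.lst) == oracle_scar(segs, karyo())


def test_hrd_index_sum():
    assert hrd_index(ScarScores(0, 0, 0)) == 0
    assert hrd_index(ScarScores(5, 7, 11)) == 23


def test_hrd_index_random_sums(rng):
    for _ in range(100):
        a, b, c = (int(x) for x in rng.integers(0, 40, 3))
        assert hrd_index(ScarScores(a, b, c)) == a + b + c


# -- standardization and scoring ---------------------------------------------

def cohort_frame(matrix):
    return pd.DataFrame(matrix, columns=list(FEATURE_ORDER))


def test_standardize_mean_zero_sd_one(rng):
    cohort = cohort_frame(rng.gamma(2, 10, size=(20, 6)))
    z = standardize_features(cohort)
    np.testing.assert_allclose(z.mean(axis=0), 0, atol=1e-10)
    np.testing.assert_allclose(z.std(axis=0, ddof=1), 1, atol=1e-10)


def test_standardize_zero_variance_path():
    cohort = cohort_frame([[1, 2, 3, 4, 5, 6], [1, 5, 3, 9, 5, 2]])
    with pytest.warns(UserWarning, match="zero-variance"):
        z = standardize_features(cohort)
    assert (z["sbs3"] == 0).all()
    assert (z["sv3"] == 0).all()


def test_standardize_hand_computed_fixture():
    raw = [3.0, 10.0, 0.0, 7.0, 1.0]
    cohort = cohort_frame([[v] * 6 for v in raw])
    z = standardize_features(cohort)
    logged = np.log(np.array(raw) + 1)
    expect = (logged - logged.mean()) / logged.std(ddof=1)
    for col in FEATURE_ORDER:
        np.testing.assert_allclose(z[col], expect, atol=1e-10)


def test_standardize_single_sample_needs_external_stats():
    cohort = cohort_frame([[1, 2, 3, 4, 5, 6]])
    with pytest.raises(ValueError, match="external_stats"):
        standardize_features(cohort)
    stats_df = pd.DataFrame({"mean": 0.0, "sd": 1.0}, index=list(FEATURE_ORDER))
    z = standardize_features(cohort, external_stats=stats_df)
    np.testing.assert_allclose(z.iloc[0], np.log1p([1, 2, 3, 4, 5, 6]))


def test_hrdetect_score_at_zero():
    score = hrdetect_score(np.zeros(6))
    assert score[0] == pytest.approx(1 / (1 + math.exp(3.364)), abs=1e-15)


def test_hrdetect_monotone_limit():
    z = np.zeros(6)
    z[5] = 50.0
    assert hrdetect_score(z)[0] > 1 - 1e-10


def test_hrdetect_strictly_increasing_each_feature(rng):
    for _ in range(50):
        z = rng.normal(size=6)
        base = hrdetect_score(z)[0]
        for i in range(6):
            z2 = z.copy()
            z2[i] += 0.1
            assert hrdetect_score(z2)[0] > base


def test_hrdetect_feature_order_matches_coefficients():
    # bumping the mh fraction (coef 2.398) moves the score more than SBS8 (0.091)
    z = np.zeros(6)
    z_mh = z.copy(); z_mh[5] = 1.0
    z_sbs8 = z.copy(); z_sbs8[1] = 1.0
    assert hrdetect_score(z_mh)[0] > hrdetect_score(z_sbs8)[0]


@pytest.mark.parametrize("score,expect", [(0.70, "high"), (0.6999, "not_high"), (0.999, "high")])
def test_classify_hrd_high(score, expect):
    assert classify_hrd_high(score) == expect


# -- promoter methylation ----------------------------------------------------

def promoter_fixture(n, n_exceed):
    promoter = {"chrom": "chr1", "start": 1000, "end": 1000 + 10 * n, "gene_id": "BRCA1"}
    pos = [1000 + 10 * i for i in range(n)]
    tumor = pd.DataFrame({"chrom": "chr1", "pos": pos,
                          "frequency": [0.9 if i < n_exceed else 0.1 for i in range(n)]})
    normal = pd.DataFrame({"chrom": "chr1", "pos": pos, "mean": 0.2, "sd": 0.1})
    return promoter, tumor, normal


def test_promoter_fraction_full_separation():
    promoter, tumor, normal = promoter_fixture(10, 10)
    out = promoter_methylation_fraction(promoter, tumor, normal)
    assert out["fraction_methylated_sites"] == 1.0


def test_promoter_fraction_none():
    promoter, tumor, normal = promoter_fixture(10, 0)
    out = promoter_methylation_fraction(promoter, tumor, normal)
    assert out["fraction_methylated_sites"] == 0.0


def test_promoter_fraction_thirteen_of_twenty():
    promoter, tumor, normal = promoter_fixture(20, 13)
    out = promoter_methylation_fraction(promoter, tumor, normal)
    assert out["fraction_methylated_sites"] == pytest.approx(0.65)


def test_promoter_loh_status():
    promoter, tumor, normal = promoter_fixture(10, 5)
    segs = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [10_000],
                         "major_cn": [2], "minor_cn": [0]})
    out = promoter_methylation_fraction(promoter, tumor, normal, segs)
    assert out["loh_status"] == "LOH"
    segs_het = segs.assign(minor_cn=1)
    out2 = promoter_methylation_fraction(promoter, tumor, normal, segs_het)
    assert out2["loh_status"] == "HET"
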