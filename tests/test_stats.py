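from itertools import combinations

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from epimut.stats import (benjamini_hochberg, enrichment_test, mann_whitney_u,
                          region_rates, sample_random_regions,
                          subsample_stability)

from conftest import bed_frame, make_cohort


def enumeration_oracle(x, y, alternative):
    """Independent brute-force U permutation distribution (midranks)."""
    pooled = np.concatenate([x, y])
    m = len(x)
    ranks = scipy.stats.rankdata(pooled)
    u_obs = ranks[:m].sum() - m * (m + 1) / 2
    center = m * len(y) / 2
    us = [ranks[list(c)].sum() - m * (m + 1) / 2
          for c in combinations(range(len(pooled)), m)]
    us = np.array(us)
    eps = 1e-9
    if alternative == "greater":
        p = np.mean(us >= u_obs - eps)
    elif alternative == "less":
        p = np.mean(us <= u_obs + eps)
    else:
        p = np.mean(np.abs(us - center) >= abs(u_obs - center) - eps)
    return u_obs, p


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

def test_complete_ties_give_central_u_and_p_one():
    u, p = mann_whitney_u([5, 5, 5], [5, 5, 5, 5])
    assert u == 6.0 and p == 1.0


def test_separated_samples_one_sided():
    # all 3 smallest in x: P(U <= 0) = 1 / C(6,3) = 0.05
    u, p = mann_whitney_u([1, 2, 3], [4, 5, 6], alternative="less")
    assert u == 0.0 and p == pytest.approx(0.05)


@pytest.mark.parametrize("alternative", ["two_sided", "greater", "less"])
def test_exact_path_matches_enumeration(rng, alternative):
    for _ in range(60):
        m, n = rng.integers(1, 7, size=2)
        x = rng.integers(0, 6, size=m).astype(float)
        y = rng.integers(0, 6, size=n).astype(float)
        u, p = mann_whitney_u(x, y, alternative=alternative)
        u0, p0 = enumeration_oracle(x, y, alternative)
        assert u == pytest.approx(u0) and p == pytest.approx(p0, abs=1e-12)


def test_swap_symmetry_small_and_large(rng):
    """U_x + U_y = mn and the two-sided p is invariant under swapping."""
    for m, n in [(5, 6), (30, 25)]:
        x = rng.integers(0, 10, size=m).astype(float)
        y = rng.integers(0, 10, size=n).astype(float)
        ux, px = mann_whitney_u(x, y)
        uy, py = mann_whitney_u(y, x)
        assert ux + uy == pytest.approx(m * n)
        assert px == pytest.approx(py)


def test_empty_sample_is_an_error():
    with pytest.raises(ValueError):
        mann_whitney_u([], [1.0])


from hypothesis import given, settings
from hypothesis import strategies as st

small_vec = st.lists(st.integers(min_value=0, max_value=8), min_size=1,
                     max_size=6)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(x=small_vec, y=small_vec)
def test_exact_p_matches_enumeration_property(x, y):
    """Exact-path p equals the brute-force permutation p for any small input."""
    u, p = mann_whitney_u(x, y)
    u0, p0 = enumeration_oracle(np.array(x, float), np.array(y, float),
                                "two_sided")
    assert u == pytest.approx(u0) and p == pytest.approx(p0, abs=1e-12)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(x=small_vec, y=small_vec)
def test_swap_maps_u_to_complement(x, y):
    ux, px = mann_whitney_u(x, y)
    uy, py = mann_whitney_u(y, x)
    assert ux + uy == pytest.approx(len(x) * len(y))
    assert px == pytest.approx(py)


def test_bh_qvalues_monotone_in_p(rng):
    p = rng.random(50)
    q = benjamini_hochberg(p)
    order = np.argsort(p)
    assert np.all(np.diff(q[order]) >= -1e-12)
    assert np.all(q >= p - 1e-12)


# ---------------------------------------------------------------------------
# region rates and random regions
# ---------------------------------------------------------------------------

def test_region_rate_simple_and_zero():
    coh = make_cohort([150, 160])
    rates = region_rates(coh, bed_frame([("chr1", 100, 200)]))
    assert rates[0] == pytest.approx(0.02)
    rates = region_rates(make_cohort([]), bed_frame([("chr1", 100, 200)]))
    assert rates[0] == 0.0


def test_region_rates_match_bruteforce(rng):
    regions = bed_frame([("chr1", int(s), int(s + l)) for s, l in
                         zip(rng.integers(0, 50_000, 20),
                             rng.integers(50, 2000, 20))])
    positions = rng.integers(0, 55_000, 500)
    coh = make_cohort(positions)
    rates = region_rates(coh, regions)
    for i, r in enumerate(regions.itertuples(index=False)):
        expected = sum(1 for p in positions if r.start <= p < r.end)
        assert rates[i] == pytest.approx(expected / (r.end - r.start))


def test_random_regions_contract_and_determinism(rng):
    genome = {"chr1": "".join(rng.choice(list("ACGT"), 100_000))}
    regions = bed_frame([("chr1", 100, 600), ("chr1", 5000, 5100)])
    a = sample_random_regions(regions, genome, seed=9)
    b = sample_random_regions(regions, genome, seed=9)
    pd.testing.assert_frame_equal(a, b)
    assert list(a["end"] - a["start"]) == [500, 100]
    assert (a["chrom"] == "chr1").all()
    c = sample_random_regions(regions, genome, seed=10)
    assert not a.equals(c)


def test_random_regions_uniform_starts(rng):
    """Chi-square uniformity of start positions over 20 genome bins."""
    genome = {"chr1": "".join(rng.choice(list("ACGT"), 100_000))}
    one = bed_frame([("chr1", 0, 100)] * 10_000)
    out = sample_random_regions(one, genome, seed=3)
    hist, _ = np.histogram(out["start"], bins=20, range=(0, 100_000 - 99))
    p = scipy.stats.chisquare(hist).pvalue
    assert p > 0.001


def test_random_regions_avoid_n_runs_and_source_overlap(rng):
    seq = list("".join(rng.choice(list("ACGT"), 20_000)))
    seq[8_000:12_000] = "N" * 4000
    genome = {"chr1": "".join(seq)}
    regions = bed_frame([("chr1", 0, 1000)] * 200)
    out = sample_random_regions(regions, genome, seed=1, exclude_overlap=True)
    for r in out.itertuples(index=False):
        assert "N" * 500 not in genome["chr1"][r.start:r.end]
        assert not (r.start < 1000 and r.end > 0 and r.start < 1000)


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------

def test_enrichment_zero_everywhere_is_na_fold_p_one():
    regions = bed_frame([("chr1", 1000 * i, 1000 * i + 200) for i in range(1, 6)])
    res = enrichment_test(make_cohort([]), regions, null_kind="flank",
                          flank_bp=300)
    assert np.isnan(res.fold) and res.p_value == 1.0


def test_enrichment_flank_null_detects_planted_signal(rng):
    regions = bed_frame([("chr1", 10_000 * i, 10_000 * i + 500)
                         for i in range(1, 40)])
    inside = [int(rng.integers(r.start, r.end)) for r in
              regions.itertuples(index=False) for _ in range(6)]
    outside = list(rng.integers(5000, 395_000, size=300))
    res = enrichment_test(make_cohort(inside + outside), regions,
                          null_kind="flank", flank_bp=2000)
    assert res.fold > 2 and res.p_value < 1e-4


def test_paired_flank_uses_signed_rank():
    regions = bed_frame([("chr1", 10_000 * i, 10_000 * i + 500)
                         for i in range(1, 12)])
    rng = np.random.default_rng(5)
    inside = [int(rng.integers(r.start, r.end)) for r in
              regions.itertuples(index=False) for _ in range(4)]
    res = enrichment_test(make_cohort(inside), regions,
                          null_kind="paired_flank", flank_bp=2000)
    assert res.p_value < 0.01 and res.null_kind == "paired_flank"


def test_subsample_stability_single_draw_composition(small_dataset):
    """n_draws=1 equals one subsample + one enrichment_test on the same seed."""
    from epimut.io import subsample_cohort
    regions = small_dataset.features["mirnas"]
    cohort = small_dataset.cohort
    df, summary = subsample_stability(cohort, regions, n_samples=10, n_draws=1,
                                      seed=7, null_kind="flank", flank_bp=2000)
    s = int(df.loc[0, "seed"])
    sub = subsample_cohort(cohort, 10, seed=s)
    res = enrichment_test(sub, regions, null_kind="flank", flank_bp=2000, seed=s)
    assert df.loc[0, "fold"] == pytest.approx(res.fold, nan_ok=True)
    assert df.loc[0, "p"] == pytest.approx(res.p_value)


def test_subsample_stability_planted_enrichment_is_stable(small_dataset):
    regions = small_dataset.features["mirnas"]
    df, summary = subsample_stability(small_dataset.cohort, regions,
                                      n_samples=10, n_draws=20, seed=3,
                                      null_kind="random",
                                      genome=small_dataset.genome, n_random=3)
    assert summary["frac_significant"] >= 0.8
    assert 1.5 < summary["median_fold"] < 5.0
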