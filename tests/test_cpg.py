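import numpy as np
import pandas as pd
import pytest

from epimut.cpg import (cpg_cytosine_positions, cpg_oe_window,
                        methylation_around_mutations, methylation_ct_ratio,
                        mutation_occurrence, occurrence_vs_metric,
                        sliding_metrics)
from epimut.io import MUTATION_COLUMNS, MutationCohort, cohort_from_frame

from conftest import make_cohort


def window_oracle(seq, convention="inflated"):
    """Independent character-by-character recount of the window metrics."""
    n = len(seq)
    n_c = sum(1 for ch in seq if ch == "C")
    n_g = sum(1 for ch in seq if ch == "G")
    n_cpg = sum(1 for a, b in zip(seq, seq[1:]) if a == "C" and b == "G")
    if n_c == 0 or n_g == 0:
        oe = np.nan
    else:
        factor = n * n / (n - 1) if convention == "inflated" else n
        oe = n_cpg / (n_c * n_g) * factor
    return n_cpg, n_c, n_g, oe


def test_cg_repeat_window_value():
    """The printed formula on a pure-CpG 400bp window gives 2.00501."""
    oe = cpg_oe_window("CG" * 200)
    assert oe == pytest.approx(200 / (200 * 200) * 400 * 400 / 399, abs=1e-12)
    assert round(oe, 5) == 2.00501
    # classic convention drops the N/(N-1) inflation
    assert cpg_oe_window("CG" * 200, oe_convention="classic") == pytest.approx(2.0)


def test_no_c_is_na():
    assert np.isnan(cpg_oe_window("AT" * 200))


def test_sliding_single_window_and_short_sequence():
    track = sliding_metrics("ACGT" * 100, N=400)
    assert len(track) == 1
    assert len(sliding_metrics("ACGT", N=400)) == 0


def test_homopolymer_track():
    track = sliding_metrics("A" * 500, N=400)
    assert (track["GC"] == 0).all() and (track["CG"] == 0).all()
    assert track["OE"].isna().all()


def test_sliding_equals_recount_oracle(rng):
    seq = "".join(rng.choice(list("ACGTN"), 5000, p=[.3, .2, .2, .25, .05]))
    track = sliding_metrics(seq, N=400)
    for i in rng.choice(len(track), 60, replace=False):
        row = track.iloc[i]
        n_cpg, n_c, n_g, oe = window_oracle(seq[int(row["start"]):int(row["start"]) + 400])
        assert row["n_cpg"] == n_cpg and row["n_c"] == n_c and row["n_g"] == n_g
        if np.isnan(oe):
            assert np.isnan(row["OE"])
        else:
            assert row["OE"] == pytest.approx(oe, abs=1e-12)


_COMP = str.maketrans("ACGTN", "TGCAN")


def test_oe_reverse_complement_invariance(rng):
    """n_CpG and n_C*n_G are reverse-complement invariant, hence so is OE."""
    for _ in range(40):
        seq = "".join(rng.choice(list("ACGT"), 400))
        rc = seq.translate(_COMP)[::-1]
        a, b = cpg_oe_window(seq), cpg_oe_window(rc)
        if np.isnan(a):
            assert np.isnan(b)
        else:
            assert a == pytest.approx(b, abs=1e-12)


# ---------------------------------------------------------------------------
# mutation occurrence
# ---------------------------------------------------------------------------

def test_occurrence_isolated_and_paired():
    occ = mutation_occurrence(make_cohort([1000]), window_bp=400)
    assert list(occ["occurrence"]) == [1]
    occ = mutation_occurrence(make_cohort([("S1", 1000), ("S2", 1010)]),
                              window_bp=400)
    assert list(occ["occurrence"]) == [2, 2]


def test_occurrence_matches_quadratic_oracle(rng):
    positions = [(f"S{i % 4}", int(p)) for i, p in
                 enumerate(rng.integers(0, 20_000, 300))]
    coh = make_cohort(positions)
    occ = mutation_occurrence(coh, window_bp=400)
    events = [p for _s, p in positions]
    for row in occ.itertuples(index=False):
        expected = sum(1 for p in events if abs(p - row.pos) <= 200)
        assert row.occurrence == expected


def test_monotone_toy_gives_rho_minus_one():
    """Sites whose occurrence ranks exactly opposite their window OE."""
    # window per site: c CG pairs + (30-c) isolated C + (30-c) isolated G,
    # padded with A: n_C = n_G = 30 everywhere, OE proportional to c
    blocks, rows = [], []
    n_sites = 6
    for i in range(n_sites):
        c = 24 - 4 * i                      # decreasing CpG count
        win = "CG" * c + "CA" * (30 - c) + "GA" * (30 - c)
        win = win + "A" * (400 - len(win))
        blocks.append(win + "A" * 600)      # 1kb block; windows never overlap
        pos = i * 1000 + 200                # centre of the 400bp window
        for s in range(i + 1):              # occurrence = i+1, same position
            rows.append((f"S{s}", "chr1", pos, "A", "C", "ref_GA"))
    genome = {"chr1": "".join(blocks)}
    coh = cohort_from_frame(pd.DataFrame(rows, columns=MUTATION_COLUMNS))
    bins, rho, p = occurrence_vs_metric(coh, genome, metric="OE")
    assert rho == pytest.approx(-1.0)
    assert len(bins) == n_sites


def test_constant_metric_is_na(caplog):
    genome = {"chr1": "A" * 5000}
    coh = make_cohort([1000, 1010, 2000, 2010, 3000], ref="A", alt="C")
    bins, rho, p = occurrence_vs_metric(coh, genome, metric="CG")
    assert np.isnan(rho) and np.isnan(p)


# ---------------------------------------------------------------------------
# methylation around mutations
# ---------------------------------------------------------------------------

def _meth(records):
    return pd.DataFrame(records, columns=["chrom", "pos", "level", "coverage"])


def test_no_nearby_records_excluded_and_unit_levels():
    coh = make_cohort([1000, 9000])
    meth = _meth([("chr1", 950, 1.0, 10), ("chr1", 1100, 1.0, 10)])
    per_site, bins = methylation_around_mutations(coh, meth)
    by_pos = per_site.set_index("pos")["mean_methylation"]
    assert by_pos[1000] == 1.0
    assert np.isnan(by_pos[9000])
    assert (bins["mean_methylation"] == 1.0).all()


def test_methylation_window_mean_matches_direct_oracle(rng):
    coh = make_cohort(sorted(rng.integers(1000, 50_000, 40)))
    records = [("chr1", int(p), float(l), 10) for p, l in
               zip(rng.integers(0, 52_000, 800), rng.random(800))]
    meth = _meth(records)
    per_site, _bins = methylation_around_mutations(coh, meth, window_bp=1000)
    for row in per_site.itertuples(index=False):
        near = [l for _c, p, l, _cov in records if abs(p - row.pos) <= 500]
        if not near:
            assert np.isnan(row.mean_methylation)
        else:
            assert row.mean_methylation == pytest.approx(np.mean(near))


# ---------------------------------------------------------------------------
# C->T rate by methylation stratum
# ---------------------------------------------------------------------------

def test_ct_ratio_na_without_ct_events():
    genome = {"chr1": "AACGTTACGTT"}  # CpGs at 2-3 and 7-8
    meth = _meth([("chr1", 2, 0.9, 10), ("chr1", 3, 0.9, 10),
                  ("chr1", 7, 0.1, 10), ("chr1", 8, 0.1, 10)])
    coh = make_cohort([0], ref="A", alt="G")
    res = methylation_ct_ratio(coh, meth, genome)
    assert np.isnan(res.ratio)
    assert res.n_sites_methylated == 2 and res.n_sites_unmethylated == 2


def test_ct_ratio_counts_both_strands():
    genome = {"chr1": "AACGTTACGTT"}
    meth = _meth([("chr1", 2, 0.9, 10), ("chr1", 3, 0.9, 10),
                  ("chr1", 7, 0.1, 10), ("chr1", 8, 0.1, 10)])
    rows = [("S1", "chr1", 2, "C", "T", "ref_CT"),   # plus-strand C->T, meth
            ("S2", "chr1", 3, "G", "A", "ref_GA"),   # minus-strand C->T, meth
            ("S1", "chr1", 7, "C", "T", "ref_CT"),   # unmethylated CpG
            ("S1", "chr1", 2, "C", "G", "ref_CT")]   # not a transition: ignored
    coh = MutationCohort(pd.DataFrame(rows, columns=MUTATION_COLUMNS))
    res = methylation_ct_ratio(coh, meth, genome)
    assert res.n_events_methylated == 2 and res.n_events_unmethylated == 1
    assert res.ratio == pytest.approx((2 / 2) / (1 / 2))


def test_cpg_cytosine_positions_cover_both_bases():
    pos = cpg_cytosine_positions({"c": "ACGCGT"})["c"]
    assert list(pos) == [1, 2, 3, 4]
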