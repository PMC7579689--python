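"""Rank-based enrichment testing of per-region mutation rates against nulls.

Three null models: each region's own flanks (unpaired Mann-Whitney on the
per-region rate vectors), length/chromosome-matched random regions, and a
paired flank comparison via the Wilcoxon signed-rank test. Fold changes come
from pooled counts (total events / total bp), not from the rank statistic, so
a significant U with fold near 1 is possible and meaningful.

The Mann-Whitney implementation uses exact enumeration of the permutation
distribution of U (midranks, ties included) when both samples have at most
8 observations, and the tie-corrected normal approximation with continuity
correction otherwise (delegated to scipy).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .intervals import count_in_intervals, position_index
from .io import MutationCohort, subsample_cohort

EXACT_MAX_N = 8


def region_rates(cohort: MutationCohort, regions: pd.DataFrame) -> np.ndarray:
    """Per-region mutation rate (events per bp, pooled over samples)."""
    if len(regions) == 0:
        raise ValueError("no regions")
    lengths = (regions["end"] - regions["start"]).to_numpy()
    if (lengths <= 0).any():
        raise ValueError("zero-length region")
    counts = count_in_intervals(position_index(cohort.df), regions)
    return counts / lengths


def sample_random_regions(regions: pd.DataFrame, genome: dict[str, str],
                          seed: int, exclude_overlap: bool = False,
                          max_retries: int = 1000) -> pd.DataFrame:
    """One random region per input region: same chromosome, same length,
    uniform start. Candidates containing an N-run at least half the region
    length are rejected, as are overlaps with the source set when
    ``exclude_overlap``; after ``max_retries`` rejections the offending
    region is reported. Deterministic given ``seed``."""
    rng = np.random.default_rng(seed)
    from .intervals import IntervalIndex
    src_ix = IntervalIndex(regions.reset_index(drop=True)) if exclude_overlap else None
    rows = []
    for r in regions.itertuples(index=False):
        seq = genome.get(r.chrom)
        if seq is None:
            raise ValueError(f"chromosome {r.chrom} absent from genome")
        length = r.end - r.start
        limit = len(seq) - length
        if limit < 0:
            raise ValueError(f"region {r.name} longer than {r.chrom}")
        n_run = "N" * max(1, (length + 1) // 2)
        for _ in range(max_retries):
            start = int(rng.integers(0, limit + 1))
            cand = seq[start:start + length]
            if n_run in cand:
                continue
            if src_ix is not None and src_ix.overlaps_any(r.chrom, start,
                                                          start + length):
                continue
            rows.append((r.chrom, start, start + length, f"rand_{r.name}",
                         0, "."))
            break
        else:
            raise RuntimeError(
                f"could not place a random match for region {r.name} "
                f"after {max_retries} tries")
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name",
                                     "score", "strand"])
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    return df


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

def mann_whitney_u(x, y, alternative: str = "two_sided") -> tuple[float, float]:
    """Mann-Whitney U statistic for ``x`` and its p-value.

    Average ranks for ties. Exact permutation p when both samples have <= 8
    observations (ties handled by enumerating subsets of the pooled midranks);
    otherwise scipy's tie-corrected normal approximation with continuity
    correction. ``alternative`` is two_sided / greater / less, stated for x.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    m, n = len(x), len(y)
    if m == 0 or n == 0:
        raise ValueError("empty sample")
    pooled = np.concatenate([x, y])
    ranks = scipy.stats.rankdata(pooled)
    u_x = float(ranks[:m].sum() - m * (m + 1) / 2)

    if np.ptp(pooled) == 0:
        return u_x, 1.0

    if m <= EXACT_MAX_N and n <= EXACT_MAX_N:
        return u_x, _exact_p(ranks, m, u_x, alternative)

    alt = {"two_sided": "two-sided", "greater": "greater", "less": "less"}[alternative]
    res = scipy.stats.mannwhitneyu(x, y, alternative=alt, method="asymptotic",
                                   use_continuity=True)
    p = float(res.pvalue)
    return u_x, min(max(p, np.nextafter(0, 1)), 1.0)


def _exact_p(ranks: np.ndarray, m: int, u_obs: float, alternative: str) -> float:
    """Permutation distribution of U over all C(m+n, m) group assignments."""
    total = len(ranks)
    n = total - m
    offset = m * (m + 1) / 2
    center = m * n / 2
    n_total = comb(total, m)
    n_ge = n_le = n_far = 0
    eps = 1e-9
    for subset in combinations(range(total), m):
        u = ranks[list(subset)].sum() - offset
        if u >= u_obs - eps:
            n_ge += 1
        if u <= u_obs + eps:
            n_le += 1
        if abs(u - center) >= abs(u_obs - center) - eps:
            n_far += 1
    if alternative == "greater":
        p = n_ge / n_total
    elif alternative == "less":
        p = n_le / n_total
    else:
        p = n_far / n_total
    return min(p, 1.0)


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH-adjusted q-values (monotone in p across the family)."""
    p = np.asarray(p_values, dtype=float)
    if len(p) == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# enrichment tests
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentResult:
    """Fold + rank-test outcome for one region set against a named null."""

    region_set_name: str
    n_regions: int
    fold: float                  # pooled body rate / pooled null rate; NaN if 0/0
    U: float
    p_value: float
    null_kind: str
    seed: int
    q_value: float | None = None

    def as_dict(self) -> dict:
        return {"region_set": self.region_set_name, "n_regions": self.n_regions,
                "null_kind": self.null_kind, "fold": self.fold, "U": self.U,
                "p": self.p_value, "q": self.q_value, "seed": self.seed}


def _flank_frame(regions: pd.DataFrame, flank_bp: int) -> pd.DataFrame:
    left = regions.assign(start=(regions["start"] - flank_bp).clip(lower=0),
                          end=regions["start"])
    right = regions.assign(start=regions["end"], end=regions["end"] + flank_bp)
    return left, right


def enrichment_test(cohort: MutationCohort, regions: pd.DataFrame,
                    null_kind: str = "flank", flank_bp: int = 5000,
                    seed: int = 0, n_random: int = 5,
                    genome: dict[str, str] | None = None,
                    region_set_name: str = "regions",
                    alternative: str = "two_sided") -> EnrichmentResult:
    """Test whether mutations concentrate in ``regions`` relative to a null.

    flank: per-region body rates vs per-region pooled flank rates (unpaired
    Mann-Whitney). random: vs rates of ``n_random`` chromosome/length-matched
    random sets (requires ``genome``). paired_flank: Wilcoxon signed-rank on
    per-region (body - flank) rate differences. Fold is always the ratio of
    pooled rates; NaN when the null rate is zero.
    """
    if len(regions) == 0:
        raise ValueError("no regions")
    positions = position_index(cohort.df)
    body_counts = count_in_intervals(positions, regions)
    body_bp = (regions["end"] - regions["start"]).to_numpy()
    body_rates = body_counts / body_bp

    if null_kind in ("flank", "paired_flank"):
        left, right = _flank_frame(regions, flank_bp)
        lc = count_in_intervals(positions, left)
        rc = count_in_intervals(positions, right)
        null_counts = lc + rc
        null_bp = ((left["end"] - left["start"]).to_numpy()
                   + (right["end"] - right["start"]).to_numpy())
        keep = null_bp > 0
        null_rates = null_counts[keep] / null_bp[keep]
    elif null_kind == "random":
        if genome is None:
            raise ValueError("random null requires a genome")
        rng_seeds = np.random.SeedSequence(seed).generate_state(n_random)
        null_rates_list, null_counts_acc, null_bp_acc = [], 0, 0
        for s in rng_seeds:
            rand = sample_random_regions(regions, genome, int(s % (2**31)))
            c = count_in_intervals(positions, rand)
            bp = (rand["end"] - rand["start"]).to_numpy()
            null_rates_list.append(c / bp)
            null_counts_acc += c.sum()
            null_bp_acc += bp.sum()
        null_rates = np.concatenate(null_rates_list)
        null_counts = None
    else:
        raise ValueError(f"unknown null_kind {null_kind!r}")

    if null_kind == "random":
        pooled_null_rate = null_counts_acc / null_bp_acc
    else:
        pooled_null_rate = null_counts.sum() / null_bp.sum()
    pooled_body_rate = body_counts.sum() / body_bp.sum()
    if pooled_null_rate > 0:
        fold = float(pooled_body_rate / pooled_null_rate)
    else:
        fold = np.nan

    if null_kind == "paired_flank":
        diffs = body_rates - (null_counts / np.maximum(null_bp, 1))
        if np.allclose(diffs, 0):
            u, p = 0.0, 1.0
        else:
            alt = {"two_sided": "two-sided", "greater": "greater",
                   "less": "less"}[alternative]
            res = scipy.stats.wilcoxon(diffs, alternative=alt)
            u, p = float(res.statistic), float(res.pvalue)
    else:
        u, p = mann_whitney_u(body_rates, null_rates, alternative=alternative)

    return EnrichmentResult(region_set_name=region_set_name,
                            n_regions=len(regions), fold=fold, U=u, p_value=p,
                            null_kind=null_kind, seed=seed)


def subsample_stability(cohort: MutationCohort, regions: pd.DataFrame,
                        n_samples: int = 10, n_draws: int = 50, seed: int = 0,
                        **test_kwargs) -> tuple[pd.DataFrame, dict]:
    """Re-test enrichment on repeated random sub-cohorts of ``n_samples``.

    Emulates down-sampling a large cohort to a small working set and asking
    whether the enrichment call is stable. Returns the per-draw (fold, p)
    table and a summary with median/IQR of fold and the fraction of draws
    significant at 0.05.
    """
    if len(cohort.sample_ids) < n_samples:
        raise ValueError("cohort smaller than the requested subsample")
    draw_seeds = np.random.SeedSequence(seed).generate_state(n_draws)
    rows = []
    for i, s in enumerate(draw_seeds):
        s = int(s % (2**31))
        sub = subsample_cohort(cohort, n_samples, seed=s)
        res = enrichment_test(sub, regions, seed=s, **test_kwargs)
        rows.append((i, s, res.fold, res.p_value))
    df = pd.DataFrame(rows, columns=["draw", "seed", "fold", "p"])
    folds = df["fold"].dropna()
    summary = {
        "median_fold": float(folds.median()) if len(folds) else np.nan,
        "fold_iqr": (float(folds.quantile(0.75) - folds.quantile(0.25))
                     if len(folds) else np.nan),
        "frac_significant": float((df["p"] < 0.05).mean()),
        "n_draws": n_draws,
    }
    return df, summary
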