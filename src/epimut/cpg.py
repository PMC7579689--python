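"""CpG density/depletion metrics and methylation coupling around mutations.

The central quantity is the observed/expected CpG ratio of a sliding window,

    OE = (n_CpG / (n_C * n_G)) * N^2 / (N - 1)

with N the window size. The N^2/(N-1) form is the one implemented by default
("inflated" convention); the textbook form uses a plain factor of N ("classic"),
selectable via ``oe_convention``. Low OE marks historical CpG erosion by
deamination of methylated cytosines, which is why mutation occurrence is
expected to anti-correlate with OE but not with raw CpG or GC content.

"Mutation occurrence" is operationally defined here as the number of mutation
events (across samples) within a fixed window centred on a mutated site,
inclusive of the site itself.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .io import MutationCohort

log = logging.getLogger(__name__)


def _seq_counts(seq: str) -> tuple[int, int, int]:
    """(n_CpG, n_C, n_G) with CpG counted as overlapping literal 'CG'."""
    return seq.count("CG"), seq.count("C"), seq.count("G")


def _oe_from_counts(n_cpg: int, n_c: int, n_g: int, n: int,
                    convention: str) -> float:
    if n_c == 0 or n_g == 0:
        return np.nan
    density = n_cpg / (n_c * n_g)
    if convention == "inflated":
        return density * n * n / (n - 1)
    if convention == "classic":
        return density * n
    raise ValueError(f"unknown OE convention {convention!r}")


def cpg_oe_window(seq: str, oe_convention: str = "inflated") -> float:
    """Observed/expected CpG ratio of a single window; NaN when C or G absent."""
    n = len(seq)
    if n < 2:
        raise ValueError("window must have length >= 2")
    n_cpg, n_c, n_g = _seq_counts(seq)
    return _oe_from_counts(n_cpg, n_c, n_g, n, oe_convention)


def sliding_metrics(seq: str, N: int = 400, step: int = 1,
                    oe_convention: str = "inflated") -> pd.DataFrame:
    """Sliding-window CpG metrics: one row per window start.

    Columns: start, n_cpg, n_c, n_g, CG (= n_cpg/(N-1)), GC (= (n_C+n_G)/N),
    OE. Computed from exact integer cumulative counts, so the incremental
    track equals a per-window recount identically. A sequence shorter than N
    yields an empty track with a warning.
    """
    if len(seq) < N:
        log.warning("sequence length %d < window %d; empty metric track",
                    len(seq), N)
        return pd.DataFrame(columns=["start", "n_cpg", "n_c", "n_g",
                                     "CG", "GC", "OE"])
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    is_c = (arr == ord("C")).astype(np.int64)
    is_g = (arr == ord("G")).astype(np.int64)
    is_cpg = np.zeros(len(arr), dtype=np.int64)
    is_cpg[:-1] = is_c[:-1] & (arr[1:] == ord("G"))
    cum_c = np.concatenate([[0], np.cumsum(is_c)])
    cum_g = np.concatenate([[0], np.cumsum(is_g)])
    cum_cpg = np.concatenate([[0], np.cumsum(is_cpg)])
    starts = np.arange(0, len(seq) - N + 1, step)
    n_c = cum_c[starts + N] - cum_c[starts]
    n_g = cum_g[starts + N] - cum_g[starts]
    # CpG dinucleotides fully inside the window: starts at [s, s+N-1)
    n_cpg = cum_cpg[starts + N - 1] - cum_cpg[starts]
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = (n_c * n_g).astype(float)
        oe_density = np.where(denom > 0, n_cpg / denom, np.nan)
    factor = N * N / (N - 1) if oe_convention == "inflated" else float(N)
    if oe_convention not in ("inflated", "classic"):
        raise ValueError(f"unknown OE convention {oe_convention!r}")
    return pd.DataFrame({
        "start": starts, "n_cpg": n_cpg, "n_c": n_c, "n_g": n_g,
        "CG": n_cpg / (N - 1), "GC": (n_c + n_g) / N,
        "OE": oe_density * factor,
    })


# ---------------------------------------------------------------------------
# mutation occurrence
# ---------------------------------------------------------------------------

def mutation_occurrence(cohort: MutationCohort, window_bp: int = 400,
                        ) -> pd.DataFrame:
    """Event count within +/- window_bp/2 of each distinct mutated site.

    Events are pooled across samples and include the site itself; the window
    is inclusive on both edges. Returns (chrom, pos, occurrence), one row per
    distinct mutated position.
    """
    if window_bp % 2 != 0:
        raise ValueError("window_bp must be even")
    half = window_bp // 2
    out = []
    for chrom, grp in cohort.df.groupby("chrom", sort=False):
        events = np.sort(grp["pos"].to_numpy())
        sites = np.unique(events)
        occ = (np.searchsorted(events, sites + half, side="right")
               - np.searchsorted(events, sites - half, side="left"))
        out.append(pd.DataFrame({"chrom": chrom, "pos": sites,
                                 "occurrence": occ}))
    if not out:
        return pd.DataFrame(columns=["chrom", "pos", "occurrence"])
    return pd.concat(out, ignore_index=True)


def _site_metrics(sites: pd.DataFrame, genome: dict[str, str], window_bp: int,
                  oe_convention: str) -> pd.DataFrame:
    """CG/GC/OE of the window_bp window centred on each site.

    Windows truncated by a chromosome end are dropped rather than padded.
    """
    half = window_bp // 2
    rows = []
    for row in sites.itertuples(index=False):
        seq = genome.get(row.chrom)
        if seq is None:
            continue
        s = row.pos - half
        e = s + window_bp
        if s < 0 or e > len(seq):
            continue
        win = seq[s:e]
        n_cpg, n_c, n_g = _seq_counts(win)
        rows.append((row.chrom, row.pos, row.occurrence,
                     n_cpg / (window_bp - 1), (n_c + n_g) / window_bp,
                     _oe_from_counts(n_cpg, n_c, n_g, window_bp, oe_convention)))
    return pd.DataFrame(rows, columns=["chrom", "pos", "occurrence",
                                       "CG", "GC", "OE"])


def occurrence_vs_metric(cohort: MutationCohort, genome: dict[str, str],
                         metric: str = "OE", window_bp: int = 400,
                         oe_convention: str = "inflated",
                         ) -> tuple[pd.DataFrame, float, float]:
    """Correlate mutation occurrence with a local sequence metric.

    Per distinct mutated site, the metric (CG, GC or OE) is computed on the
    window centred on it; sites with undefined metric are dropped. Returns
    (bins, rho, p): ``bins`` holds mean metric and site count per occurrence
    value; rho/p are the Spearman rank correlation over sites. With fewer
    than 3 distinct occurrence values, or a constant metric, the correlation
    is NaN (noted in the log).
    """
    if metric not in ("CG", "GC", "OE"):
        raise ValueError("metric must be CG, GC or OE")
    sites = mutation_occurrence(cohort, window_bp=window_bp)
    per_site = _site_metrics(sites, genome, window_bp, oe_convention)
    per_site = per_site.dropna(subset=[metric])
    bins = (per_site.groupby("occurrence")[metric]
            .agg(mean_metric="mean", n_windows="size").reset_index())
    reps = _cluster_representatives(per_site, window_bp)
    vals = reps[metric].to_numpy()
    occ = reps["occurrence"].to_numpy()
    if len(np.unique(occ)) < 3 or len(np.unique(vals)) < 2:
        log.info("occurrence/%s correlation undefined: insufficient spread "
                 "(ties)", metric)
        return bins, np.nan, np.nan
    rho, p = scipy.stats.spearmanr(occ, vals)
    return bins, float(rho), float(p)


def _cluster_representatives(per_site: pd.DataFrame, window_bp: int,
                             ) -> pd.DataFrame:
    """One site per recurrence cluster (sites closer than window_bp linked).

    Sites inside one cluster share their occurrence count and nearly their
    whole metric window, so using all of them pseudo-replicates observations
    and inflates the correlation's variance; the representative (highest
    occurrence, leftmost on ties) keeps the test calibrated. Isolated sites
    are their own cluster, so sparse data is unaffected.
    """
    keep = []
    for _chrom, grp in per_site.groupby("chrom", sort=False):
        grp = grp.sort_values("pos")
        pos = grp["pos"].to_numpy()
        new_cluster = np.ones(len(grp), dtype=bool)
        new_cluster[1:] = np.diff(pos) > window_bp
        cluster_id = np.cumsum(new_cluster)
        g = grp.assign(_cluster=cluster_id)
        idx = (g.sort_values(["occurrence", "pos"], ascending=[False, True])
               .groupby("_cluster", sort=False).head(1).index)
        keep.append(grp.loc[grp.index.intersection(idx)])
    if not keep:
        return per_site
    return pd.concat(keep)


# ---------------------------------------------------------------------------
# methylation coupling
# ---------------------------------------------------------------------------

def methylation_around_mutations(cohort: MutationCohort, methylation: pd.DataFrame,
                                 window_bp: int = 1000,
                                 occurrence_window_bp: int = 400,
                                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean CpG methylation of windows centred on each mutated site.

    Per distinct mutated site, the mean level of methylation records within
    +/- window_bp/2 (NaN when no record is near). Sites are then binned by
    mutation occurrence; bins report the mean of per-site means and the site
    count (NaN sites excluded). Returns (per_site, bins).
    """
    half = window_bp // 2
    sites = mutation_occurrence(cohort, window_bp=occurrence_window_bp)
    meth_by_chrom = {c: g.sort_values("pos") for c, g in
                     methylation.groupby("chrom", sort=False)}
    means = np.full(len(sites), np.nan)
    for i, row in enumerate(sites.itertuples(index=False)):
        grp = meth_by_chrom.get(row.chrom)
        if grp is None:
            continue
        pos = grp["pos"].to_numpy()
        lo = np.searchsorted(pos, row.pos - half, side="left")
        hi = np.searchsorted(pos, row.pos + half, side="right")
        if hi > lo:
            means[i] = grp["level"].to_numpy()[lo:hi].mean()
    per_site = sites.assign(mean_methylation=means)
    ok = per_site.dropna(subset=["mean_methylation"])
    bins = (ok.groupby("occurrence")["mean_methylation"]
            .agg(mean_methylation="mean", n_windows="size").reset_index())
    return per_site, bins


@dataclass(frozen=True)
class CTRateRatio:
    """C->T rate at methylated vs unmethylated CpG cytosines."""

    n_sites_methylated: int
    n_sites_unmethylated: int
    n_events_methylated: int
    n_events_unmethylated: int
    rate_methylated: float
    rate_unmethylated: float
    ratio: float


def cpg_cytosine_positions(genome: dict[str, str]) -> dict[str, np.ndarray]:
    """Positions of both cytosines of every CpG: the C (plus strand) and the
    G (whose minus-strand complement is the C of the palindromic CpG)."""
    out = {}
    for chrom, seq in genome.items():
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        cg = np.flatnonzero((arr[:-1] == ord("C")) & (arr[1:] == ord("G")))
        out[chrom] = np.union1d(cg, cg + 1)
    return out


def methylation_ct_ratio(cohort: MutationCohort, methylation: pd.DataFrame,
                         genome: dict[str, str],
                         level_threshold: float = 0.5) -> CTRateRatio:
    """Ratio of the C->T mutation rate at methylated vs unmethylated CpGs.

    CpG context is decided from the reference genome, not the methylation
    file. A site counts as a C->T event when the plus-strand C mutates C->T,
    or the paired G mutates G->A (the C->T on the minus strand). Sites
    without a methylation record are excluded; strata are split at
    ``level_threshold``. The ratio is NaN when either stratum is empty or
    the unmethylated stratum has no events.
    """
    cpg_pos = cpg_cytosine_positions(genome)
    stats = {True: [0, 0], False: [0, 0]}  # methylated -> [n_sites, n_events]
    df = cohort.df
    for chrom, seq in genome.items():
        pos = cpg_pos.get(chrom)
        if pos is None or len(pos) == 0:
            continue
        meth = methylation[methylation["chrom"] == chrom]
        levels = pd.Series(meth["level"].to_numpy(), index=meth["pos"].to_numpy())
        levels = levels[~levels.index.duplicated()]
        known = levels.reindex(pos)
        known = known.dropna()
        site_pos = known.index.to_numpy()
        site_meth = known.to_numpy() >= level_threshold
        sub = df[df["chrom"] == chrom]
        ct = sub[((sub["ref"] == "C") & (sub["alt"] == "T"))
                 | ((sub["ref"] == "G") & (sub["alt"] == "A"))]
        event_counts = pd.Series(0, index=site_pos)
        hits = ct[ct["pos"].isin(set(site_pos.tolist()))]
        for p, grp in hits.groupby("pos"):
            # G->A only counts as minus-strand C->T at the G of the CpG
            base = seq[p]
            valid = grp[(grp["ref"] == base)
                        & (((base == "C") & (grp["alt"] == "T"))
                           | ((base == "G") & (grp["alt"] == "A")))]
            event_counts.loc[p] = len(valid)
        for is_meth in (True, False):
            mask = site_meth == is_meth
            stats[is_meth][0] += int(mask.sum())
            stats[is_meth][1] += int(event_counts.to_numpy()[mask].sum())
    n_m, e_m = stats[True]
    n_u, e_u = stats[False]
    rate_m = e_m / n_m if n_m else np.nan
    rate_u = e_u / n_u if n_u else np.nan
    if not n_m or not n_u or not e_u:
        ratio = np.nan
    else:
        ratio = rate_m / rate_u
    return CTRateRatio(n_sites_methylated=n_m, n_sites_unmethylated=n_u,
                       n_events_methylated=e_m, n_events_unmethylated=e_u,
                       rate_methylated=rate_m, rate_unmethylated=rate_u,
                       ratio=ratio)
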