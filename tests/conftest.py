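import numpy as np
import pandas as pd
import pytest

from epimut.io import MUTATION_COLUMNS, classify_substitution, cohort_from_frame
from epimut.simulate import SimConfig, simulate_dataset

#: desk-scale configuration reused by the unit tests (seconds, not minutes)
SMALL_CONFIG = SimConfig(
    seed=11, n_chroms=1, chrom_len=300_000, n_genes=30, n_mirnas=60,
    n_peaks={"CTCF": 60, "H3K27me3": 40, "DNase": 60},
    peak_len={"CTCF": (150, 400), "H3K27me3": (500, 2000), "DNase": (150, 600)},
    n_ncrnas=10, n_pseudogenes=5, cpg_island_count=8, n_samples=12,
    n_hypermutators=1)


@pytest.fixture(scope="session")
def small_dataset():
    return simulate_dataset(SMALL_CONFIG)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_cohort(positions, chrom="chr1", sample="S1", ref="C", alt="A",
                samples=None):
    """Cohort with one SNV per position; positions may be (sample, pos) pairs."""
    rows = []
    for item in positions:
        if isinstance(item, tuple):
            s, p = item
        else:
            s, p = sample, item
        rows.append((s, chrom, int(p), ref, alt,
                     classify_substitution(ref, alt)))
    df = pd.DataFrame(rows, columns=MUTATION_COLUMNS)
    return cohort_from_frame(df, samples=samples)


def bed_frame(intervals, strand="+"):
    """BED-like frame from (chrom, start, end[, strand]) tuples."""
    rows = []
    for i, iv in enumerate(intervals):
        if len(iv) == 4:
            c, s, e, st = iv
        else:
            c, s, e = iv
            st = strand
        rows.append((c, int(s), int(e), f"f{i}", 0, st))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score",
                                     "strand"])
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    return df
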