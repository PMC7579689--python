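"""Genomic-element annotation of mutations and gene-level cohort stratification.

Every mutation gets exactly one of ten categories; when a position lies in
several element types the highest-priority one wins (most specific element
first, mirroring common peak-annotation tools). Promoter and transcription
termination site (TTS) windows are computed strand-aware from the gene span.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
import pandas as pd

from .intervals import IntervalIndex
from .io import MutationCohort, cohort_from_frame

CATEGORIES = ("miRNA", "exonic", "5'UTR", "3'UTR", "promoter", "TTS",
              "ncRNA", "pseudogene", "intronic", "intergenic")

DEFAULT_PRIORITY = list(CATEGORIES)  # intergenic last = fallback

MIRNA_CLASSES = ("intron_miRNA", "CDS_miRNA", "intergenic_miRNA")

_EMPTY = pd.DataFrame(columns=["chrom", "start", "end", "name", "score", "strand"])


def _ensure_frame(df: pd.DataFrame | None) -> pd.DataFrame:
    return _EMPTY.copy() if df is None or len(df) == 0 else df.reset_index(drop=True)


@dataclass
class AnnotationModel:
    """Gene models plus small-RNA/pseudogene sets and window conventions.

    ``genes`` holds gene spans; ``cds``/``utr5``/``utr3`` hold sub-elements
    whose ``name`` column refers back to the gene. Introns are derived as
    gene span minus all exonic sub-elements. ``promoter_window`` is
    (upstream_bp, downstream_bp) around the TSS on the gene's strand, default
    TSS-1000..TSS+100; ``tts_window`` likewise around the TES, default
    TES-100..TES+1000.
    """

    genes: pd.DataFrame = None
    cds: pd.DataFrame = None
    utr5: pd.DataFrame = None
    utr3: pd.DataFrame = None
    mirnas: pd.DataFrame = None
    ncrnas: pd.DataFrame = None
    pseudogenes: pd.DataFrame = None
    promoter_window: tuple[int, int] = (1000, 100)
    tts_window: tuple[int, int] = (100, 1000)
    priority: list[str] = field(default_factory=lambda: list(DEFAULT_PRIORITY))

    def __post_init__(self):
        for name in ("genes", "cds", "utr5", "utr3", "mirnas", "ncrnas",
                     "pseudogenes"):
            setattr(self, name, _ensure_frame(getattr(self, name)))
        if sorted(self.priority) != sorted(CATEGORIES):
            raise ValueError("priority must cover exactly the 10 categories")
        if min(self.promoter_window) < 0 or min(self.tts_window) < 0:
            raise ValueError("windows must be non-negative")

    @cached_property
    def exons(self) -> pd.DataFrame:
        """All exonic sub-elements (CDS + both UTRs)."""
        return pd.concat([self.cds, self.utr5, self.utr3], ignore_index=True)

    @cached_property
    def introns(self) -> pd.DataFrame:
        """Per-gene complement of exons within the gene span."""
        rows = []
        exons_by_gene: dict[str, list[tuple[int, int]]] = {}
        for row in self.exons.itertuples(index=False):
            exons_by_gene.setdefault(row.name, []).append((row.start, row.end))
        for g in self.genes.itertuples(index=False):
            merged = _merge([iv for iv in exons_by_gene.get(g.name, [])
                             if iv[0] < g.end and iv[1] > g.start])
            cursor = g.start
            for s, e in merged:
                if cursor < s:
                    rows.append((g.chrom, cursor, min(s, g.end), g.name, 0, g.strand))
                cursor = max(cursor, e)
            if cursor < g.end:
                rows.append((g.chrom, cursor, g.end, g.name, 0, g.strand))
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "name",
                                           "score", "strand"])

    @cached_property
    def promoters(self) -> pd.DataFrame:
        return _strand_windows(self.genes, self.promoter_window, anchor="tss")

    @cached_property
    def tts_regions(self) -> pd.DataFrame:
        return _strand_windows(self.genes, self.tts_window, anchor="tes")

    @cached_property
    def _indexes(self) -> dict[str, IntervalIndex]:
        frames = {
            "miRNA": self.mirnas,
            "exonic": self.cds,
            "5'UTR": self.utr5,
            "3'UTR": self.utr3,
            "promoter": self.promoters,
            "TTS": self.tts_regions,
            "ncRNA": self.ncrnas,
            "pseudogene": self.pseudogenes,
            "intronic": self.introns,
        }
        return {cat: IntervalIndex(df) for cat, df in frames.items()}


def _merge(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[list[int]] = []
    for s, e in sorted(ivs):
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def _strand_windows(genes: pd.DataFrame, window: tuple[int, int],
                    anchor: str) -> pd.DataFrame:
    """Half-open windows around TSS/TES; strandless genes treated as '+'."""
    up, down = window
    rows = []
    for g in genes.itertuples(index=False):
        minus = g.strand == "-"
        if anchor == "tss":
            a = g.end if minus else g.start
        else:
            a = g.start if minus else g.end
        if minus:
            s, e = a - down, a + up
        else:
            s, e = a - up, a + down
        s = max(0, s)
        if s < e:
            rows.append((g.chrom, s, e, g.name, 0, g.strand))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name",
                                       "score", "strand"])


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def annotate_positions(chroms: np.ndarray, positions: np.ndarray,
                       model: AnnotationModel) -> np.ndarray:
    """Category per (chrom, pos), resolved by the model's priority order."""
    chroms = np.asarray(chroms, dtype=object)
    positions = np.asarray(positions)
    cats = np.full(len(positions), "intergenic", dtype=object)
    unassigned = np.ones(len(positions), dtype=bool)
    for cat in model.priority:
        if cat == "intergenic" or not unassigned.any():
            continue
        hit = model._indexes[cat].covers(chroms[unassigned], positions[unassigned])
        idx = np.flatnonzero(unassigned)[hit]
        cats[idx] = cat
        unassigned[idx] = False
    return cats


def annotate_mutation(mutation, model: AnnotationModel) -> str:
    """Single-position convenience wrapper around :func:`annotate_positions`."""
    return annotate_positions(np.array([mutation.chrom]),
                              np.array([mutation.pos]), model)[0]


def count_by_category(cohort: MutationCohort, model: AnnotationModel) -> pd.Series:
    """Mutation counts over the 10 categories; sums to ``len(cohort)``."""
    cats = annotate_positions(cohort.df["chrom"].to_numpy(),
                              cohort.df["pos"].to_numpy(), model)
    counts = pd.Series(cats).value_counts()
    return counts.reindex(CATEGORIES, fill_value=0).astype(np.int64)


# ---------------------------------------------------------------------------
# miRNA host context
# ---------------------------------------------------------------------------

def classify_mirnas(mirnas: pd.DataFrame, model: AnnotationModel) -> pd.Series:
    """Host-context class per miRNA: CDS > intron > intergenic.

    Any >=1 bp overlap with a coding exon makes a miRNA a CDS_miRNA; failing
    that, intron overlap makes it an intron_miRNA; the rest are intergenic.
    The three classes partition the input set.
    """
    cds_ix = IntervalIndex(model.cds)
    intron_ix = IntervalIndex(model.introns)
    out = []
    for m in mirnas.itertuples(index=False):
        if cds_ix.overlaps_any(m.chrom, m.start, m.end):
            out.append("CDS_miRNA")
        elif intron_ix.overlaps_any(m.chrom, m.start, m.end):
            out.append("intron_miRNA")
        else:
            out.append("intergenic_miRNA")
    return pd.Series(out, index=mirnas.index, name="mirna_class")


# ---------------------------------------------------------------------------
# gene-level stratification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneMutationTable:
    """Per-gene count of samples carrying >= 1 mutation in the gene span."""

    counts: pd.Series
    cohort_size: int

    def fractions(self) -> pd.Series:
        return self.counts / self.cohort_size


def gene_mutation_frequency(cohort: MutationCohort,
                            genes: pd.DataFrame) -> GeneMutationTable:
    if len(cohort.sample_ids) == 0:
        raise ValueError("empty cohort")
    ix = IntervalIndex(genes)
    names = genes["name"]
    hits: dict[str, set[str]] = {n: set() for n in names}
    for row in cohort.df.itertuples(index=False):
        for j in ix.stab(row.chrom, row.pos):
            hits[names.loc[j]].add(row.sample_id)
    counts = pd.Series({n: len(s) for n, s in hits.items()}, name="n_samples")
    return GeneMutationTable(counts.sort_values(ascending=False),
                             cohort_size=len(cohort.sample_ids))


def top_genes(table: GeneMutationTable, min_fraction: float = 0.10) -> set[str]:
    """Genes mutated in more than ``min_fraction`` of samples (ties included)."""
    frac = table.fractions()
    return set(frac.index[frac > min_fraction])


def split_by_genes(cohort: MutationCohort, gene_set: set[str],
                   genes: pd.DataFrame) -> tuple[MutationCohort, MutationCohort]:
    """Partition mutations into (overlapping a listed gene, everything else)."""
    sel = genes[genes["name"].isin(gene_set)]
    ix = IntervalIndex(sel.reset_index(drop=True))
    mask = ix.covers(cohort.df["chrom"].to_numpy(), cohort.df["pos"].to_numpy())
    df_in = cohort.df[mask]
    df_out = cohort.df[~mask]
    return (cohort_from_frame(df_in, provenance=cohort.provenance + "|in_genes")
            if len(df_in) else _empty_like(cohort, "in_genes"),
            cohort_from_frame(df_out, provenance=cohort.provenance + "|out_genes")
            if len(df_out) else _empty_like(cohort, "out_genes"))


def _empty_like(cohort: MutationCohort, tag: str) -> MutationCohort:
    return MutationCohort(cohort.df.iloc[0:0].reset_index(drop=True),
                          provenance=cohort.provenance + "|" + tag)
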