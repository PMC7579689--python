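"""Synthetic cohort generator with planted enrichment structure.

The generator emits a complete toy dataset — genome, gene/miRNA/peak
annotation, per-CpG methylation and a per-sample somatic mutation cohort —
whose statistical structure matches the assumptions of the downstream
analysis, with every planted parameter recorded for recovery tests:

* background sequence is i.i.d. at the configured GC content, then CpG-eroded
  (a fraction of non-island CpGs have their C deaminated to T) so that the
  background observed/expected CpG ratio sits well below the planted CpG
  islands', as in real mammalian genomes;
* per-base SNV probability is mu0 times the product of the fold enrichments
  of every feature class covering the base, times a C->T channel boost at
  methylated CpG cytosines (applied on either strand: the minus-strand C->T
  is emitted as G->A at the G of the CpG);
* a configurable number of hypermutator samples mutate at a fixed multiple
  of mu0; indels are added in proportion to the SNV count.

Every artifact is a pure function of (config, seed).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as gio
from .annotation import AnnotationModel, _strand_windows
from .cpg import cpg_cytosine_positions, sliding_metrics
from .intervals import IntervalIndex, count_in_intervals, position_index

log = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimConfig:
    """Planted world for the synthetic cohort.

    Defaults state a desk-scale version of a colorectal-cancer-like setting:
    a 2 Mb genome, 40 tumour samples at a base rate of 5e-5 SNVs per bp per
    sample, ~8% indels, 2 hypermutators at 20x the base rate, a 10-fold C->T
    boost at methylated CpGs, and per-feature-class fold enrichments (miRNA
    3x, CTCF 2x, H3K27me3 1.5x, promoters depleted at 0.5x). Fold composition
    across overlapping classes is multiplicative.
    """

    seed: int = 0
    n_chroms: int = 2
    chrom_len: int = 1_000_000
    gc_background: float = 0.41
    cpg_depletion: float = 0.8          # P(C->T erosion) at non-island CpGs
    n_genes: int = 120
    n_mirnas: int = 300
    mirna_len: tuple[int, int] = (80, 150)
    # context proportions follow the observed intron/CDS/intergenic split of
    # annotated human miRNAs (~55% / 6.6% / 38.4%)
    mirna_context_fractions: tuple[float, float, float] = (0.55, 0.066, 0.384)
    n_peaks: dict = field(default_factory=lambda: {
        "CTCF": 400, "H3K27me3": 300, "H3K4me3": 300, "H3K27ac": 300,
        "DNase": 400})
    peak_len: dict = field(default_factory=lambda: {
        "CTCF": (150, 400), "H3K27me3": (500, 2000), "H3K4me3": (500, 2000),
        "H3K27ac": (500, 2000), "DNase": (150, 600)})
    n_ncrnas: int = 50
    n_pseudogenes: int = 30
    cpg_island_count: int = 30
    cpg_island_len: int = 600
    island_meth_beta: tuple[float, float] = (1.5, 10.0)   # hypomethylated
    background_meth_beta: tuple[float, float] = (10.0, 2.0)  # ~0.83 mean
    background_low_fraction: float = 0.12  # bimodality outside islands
    tumour_shift: float = 0.7
    mu0: float = 5e-5
    fold_enrichment: dict = field(default_factory=lambda: {
        "miRNA": 3.0, "CTCF": 2.0, "H3K27me3": 1.5, "promoter": 0.5,
        "H3K4me3": 1.0, "H3K27ac": 1.0, "DNase": 1.0})
    meth_ct_multiplier: float = 10.0
    meth_threshold: float = 0.5
    indel_fraction: float = 0.08
    n_samples: int = 40
    n_hypermutators: int = 2
    hypermutator_multiplier: float = 20.0
    oe_coupling_beta: float = 0.0       # optional planted rate ~ exp(-beta*OE)

    def __post_init__(self):
        if self.mu0 < 0 or any(f <= 0 for f in self.fold_enrichment.values()):
            raise ValueError("rates must be >= 0 and folds > 0")
        if self.n_hypermutators > self.n_samples:
            raise ValueError("more hypermutators than samples")

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chroms)]


@dataclass
class GroundTruth:
    """Realized quantities of one simulation, for recovery tests."""

    hypermutator_ids: list[str]
    per_sample_counts: dict[str, int]
    per_class_counts: dict[str, int]
    true_folds: dict[str, float]
    n_snvs: int
    n_indels: int

    def to_frame(self) -> pd.DataFrame:
        rows = [("hypermutators", ",".join(self.hypermutator_ids)),
                ("n_snvs", self.n_snvs), ("n_indels", self.n_indels)]
        rows += [(f"count_{k}", v) for k, v in sorted(self.per_class_counts.items())]
        rows += [(f"fold_{k}", v) for k, v in sorted(self.true_folds.items())]
        rows += [(f"sample_{k}", v) for k, v in sorted(self.per_sample_counts.items())]
        return pd.DataFrame(rows, columns=["key", "value"])


@dataclass
class SimulatedDataset:
    config: SimConfig
    genome: dict[str, str]
    islands: pd.DataFrame
    features: dict[str, pd.DataFrame]   # genes, cds, utr5, utr3, mirnas, ncrnas,
                                        # pseudogenes, peak classes
    methylation: pd.DataFrame
    cohort: gio.MutationCohort
    ground_truth: GroundTruth

    def annotation_model(self) -> AnnotationModel:
        f = self.features
        return AnnotationModel(genes=f["genes"], cds=f["cds"], utr5=f["utr5"],
                               utr3=f["utr3"], mirnas=f["mirnas"],
                               ncrnas=f["ncrnas"], pseudogenes=f["pseudogenes"])

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        gio.write_fasta(self.genome, out / "genome.fa")
        gio.write_bed(self.islands, out / "cpg_islands.bed")
        for name, df in self.features.items():
            gio.write_bed(df, out / f"{name}.bed")
        gio.write_bedgraph_methylation(self.methylation, out / "methylation.bedgraph")
        gio.write_mutations(self.cohort, out / "mutations.maf.tsv")
        self.ground_truth.to_frame().to_csv(out / "ground_truth.tsv", sep="\t",
                                            index=False)
        with open(out / "config.json", "w") as fh:
            json.dump(asdict(self.config), fh, indent=2, default=list)


# ---------------------------------------------------------------------------
# placement helpers
# ---------------------------------------------------------------------------

class _Placer:
    """Rejection-samples non-overlapping intervals within one feature class."""

    def __init__(self, chrom_lens: dict[str, int], rng: np.random.Generator,
                 margin: int = 5000):
        self.chrom_lens = chrom_lens
        self.rng = rng
        self.margin = margin
        self.placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_lens}
        chroms = list(chrom_lens)
        w = np.array([chrom_lens[c] for c in chroms], dtype=float)
        self._chroms, self._w = chroms, w / w.sum()

    def _overlaps(self, chrom: str, start: int, end: int) -> bool:
        return any(s < end and e > start for s, e in self.placed[chrom])

    def place(self, length: int, chrom: str | None = None,
              within: tuple[str, int, int] | None = None,
              max_tries: int = 200) -> tuple[str, int, int]:
        for _ in range(max_tries):
            if within is not None:
                c, lo, hi = within
                if hi - lo < length:
                    break
                start = int(self.rng.integers(lo, hi - length + 1))
            else:
                c = chrom or self._chroms[
                    int(self.rng.choice(len(self._chroms), p=self._w))]
                lo = self.margin
                hi = self.chrom_lens[c] - self.margin - length
                if hi < lo:
                    raise ValueError("chromosome too short for placement")
                start = int(self.rng.integers(lo, hi + 1))
            end = start + length
            if not self._overlaps(c, start, end):
                self.placed[c].append((start, end))
                return c, start, end
        raise RuntimeError(f"could not place interval of length {length}")


def _bed_frame(rows) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score",
                                     "strand"])
    if len(df):
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
    return df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

def generate_genome(config: SimConfig, rng: np.random.Generator,
                    ) -> tuple[dict[str, str], pd.DataFrame]:
    """Background sequence + planted CpG islands; returns (genome, island BED).

    Non-island CpGs are eroded (C->T with probability ``cpg_depletion``) so
    the background observed/expected CpG ratio lands near
    (1 - cpg_depletion), below the islands'.
    """
    # CpG erosion converts C->T, so draw at a compensated GC content such
    # that the realized post-erosion GC matches the configured value:
    # gc' satisfies gc' - depletion * (gc'/2)^2 = gc_background.
    gc = config.gc_background
    for _ in range(20):
        gc = config.gc_background + config.cpg_depletion * (gc / 2) ** 2
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    genome_codes: dict[str, np.ndarray] = {}
    for chrom in config.chrom_names():
        codes = _BASES[rng.choice(4, size=config.chrom_len, p=p)]
        genome_codes[chrom] = codes

    # islands: CpG-rich stretches left unteroded
    total_island = config.cpg_island_count * config.cpg_island_len
    if total_island > 0.5 * config.n_chroms * config.chrom_len:
        raise ValueError("island demands exceed chromosome space")
    placer = _Placer({c: config.chrom_len for c in config.chrom_names()}, rng,
                     margin=1000)
    island_rows = []
    for i in range(config.cpg_island_count):
        chrom, start, end = placer.place(config.cpg_island_len)
        island_rows.append((chrom, start, end, f"island_{i}", 0, "."))
        genome_codes[chrom][start:end] = _island_sequence(
            config.cpg_island_len, rng)
    islands = _bed_frame(island_rows)

    island_mask: dict[str, np.ndarray] = {
        c: np.zeros(config.chrom_len, dtype=bool) for c in config.chrom_names()}
    for r in islands.itertuples(index=False):
        island_mask[r.chrom][r.start:r.end] = True

    genome: dict[str, str] = {}
    for chrom, codes in genome_codes.items():
        cg = np.flatnonzero((codes[:-1] == ord("C")) & (codes[1:] == ord("G")))
        cg = cg[~island_mask[chrom][cg]]
        erode = cg[rng.random(len(cg)) < config.cpg_depletion]
        codes[erode] = ord("T")
        genome[chrom] = codes.tobytes().decode("ascii")
    return genome, islands


def _island_sequence(length: int, rng: np.random.Generator) -> np.ndarray:
    """CpG-rich sequence: emit 'CG' with prob 0.12, else a GC-0.55 base."""
    out = np.empty(length, dtype=np.uint8)
    i = 0
    p = np.array([0.225, 0.275, 0.275, 0.225])
    singles = _BASES[rng.choice(4, size=length, p=p)]
    emit_cg = rng.random(length) < 0.12
    j = 0
    while i < length:
        if emit_cg[j] and i + 1 < length:
            out[i], out[i + 1] = ord("C"), ord("G")
            i += 2
        else:
            out[i] = singles[j]
            i += 1
        j += 1
    return out


# ---------------------------------------------------------------------------
# features
# ---------------------------------------------------------------------------

def generate_features(config: SimConfig, genome: dict[str, str],
                      rng: np.random.Generator) -> dict[str, pd.DataFrame]:
    """Genes with sub-elements, context-labelled miRNAs, ncRNAs, pseudogenes
    and one peak set per class; non-overlapping within each class."""
    chrom_lens = {c: len(s) for c, s in genome.items()}
    gene_placer = _Placer(chrom_lens, rng)
    gene_rows, cds_rows, utr5_rows, utr3_rows = [], [], [], []
    intron_spans: list[tuple[str, int, int, str]] = []
    cds_spans: list[tuple[str, int, int]] = []
    for gi in range(config.n_genes):
        utr_a, utr_b = 200, 300
        exon_len = 250
        intron_lens = rng.integers(400, 1200, size=2)
        length = utr_a + 3 * exon_len + int(intron_lens.sum()) + utr_b
        chrom, start, end = gene_placer.place(length)
        strand = "+" if rng.random() < 0.5 else "-"
        name = f"gene_{gi}"
        gene_rows.append((chrom, start, end, name, 0, strand))
        # layout on genomic coordinates; 5'UTR is at the left end on '+'
        cursor = start
        blocks = [("utrA", utr_a)]
        for k in range(3):
            blocks.append(("cds", exon_len))
            if k < 2:
                blocks.append(("intron", int(intron_lens[k])))
        blocks.append(("utrB", utr_b))
        for kind, ln in blocks:
            s, e = cursor, cursor + ln
            cursor = e
            if kind == "cds":
                cds_rows.append((chrom, s, e, name, 0, strand))
                cds_spans.append((chrom, s, e))
            elif kind == "intron":
                intron_spans.append((chrom, s, e, name))
            elif kind == "utrA":
                (utr5_rows if strand == "+" else utr3_rows).append(
                    (chrom, s, e, name, 0, strand))
            else:
                (utr3_rows if strand == "+" else utr5_rows).append(
                    (chrom, s, e, name, 0, strand))

    genes = _bed_frame(gene_rows)
    gene_ix = IntervalIndex(genes)

    # miRNAs with host-context labels
    f_intron, f_cds, _ = config.mirna_context_fractions
    n_intron = round(config.n_mirnas * f_intron)
    n_cds = round(config.n_mirnas * f_cds)
    n_inter = config.n_mirnas - n_intron - n_cds
    mirna_placer = _Placer(chrom_lens, rng)
    mirna_rows, contexts = [], []
    mi = 0
    for _ in range(n_intron):
        ln = int(rng.integers(*config.mirna_len))
        for _ in range(200):
            c, s, e, _g = intron_spans[int(rng.integers(len(intron_spans)))]
            if e - s >= ln + 2:
                try:
                    chrom, start, end = mirna_placer.place(
                        ln, within=(c, s + 1, e - 1))
                except RuntimeError:
                    continue
                mirna_rows.append((chrom, start, end, f"mir_{mi}", 0, "+"))
                contexts.append("intron_miRNA")
                mi += 1
                break
        else:
            raise RuntimeError("could not place intronic miRNA")
    for _ in range(n_cds):
        ln = int(rng.integers(*config.mirna_len))
        for _ in range(200):
            c, s, e = cds_spans[int(rng.integers(len(cds_spans)))]
            if e - s >= ln:
                try:
                    chrom, start, end = mirna_placer.place(ln, within=(c, s, e))
                except RuntimeError:
                    continue
                mirna_rows.append((chrom, start, end, f"mir_{mi}", 0, "+"))
                contexts.append("CDS_miRNA")
                mi += 1
                break
        else:
            raise RuntimeError("could not place CDS miRNA")
    for _ in range(n_inter):
        ln = int(rng.integers(*config.mirna_len))
        for _ in range(500):
            chrom, start, end = mirna_placer.place(ln)
            if not gene_ix.overlaps_any(chrom, start, end):
                mirna_rows.append((chrom, start, end, f"mir_{mi}", 0, "+"))
                contexts.append("intergenic_miRNA")
                mi += 1
                break
            mirna_placer.placed[chrom].remove((start, end))
        else:
            raise RuntimeError("could not place intergenic miRNA")
    mirnas = pd.DataFrame(mirna_rows, columns=["chrom", "start", "end", "name",
                                               "score", "strand"])
    mirnas["context"] = contexts
    order = np.lexsort((mirnas["start"].to_numpy(),
                        mirnas["chrom"].to_numpy().astype(str)))
    mirnas = mirnas.iloc[order].reset_index(drop=True)
    mirnas["start"] = mirnas["start"].astype(np.int64)
    mirnas["end"] = mirnas["end"].astype(np.int64)

    def _intergenic_set(n: int, lo: int, hi: int, prefix: str) -> pd.DataFrame:
        placer = _Placer(chrom_lens, rng)
        rows = []
        for i in range(n):
            ln = int(rng.integers(lo, hi))
            for _ in range(500):
                chrom, start, end = placer.place(ln)
                if not gene_ix.overlaps_any(chrom, start, end):
                    rows.append((chrom, start, end, f"{prefix}_{i}", 0, "."))
                    break
                placer.placed[chrom].remove((start, end))
            else:
                raise RuntimeError(f"could not place {prefix} feature")
        return _bed_frame(rows)

    features = {
        "genes": genes,
        "cds": _bed_frame(cds_rows),
        "utr5": _bed_frame(utr5_rows),
        "utr3": _bed_frame(utr3_rows),
        "mirnas": mirnas,
        "ncrnas": _intergenic_set(config.n_ncrnas, 500, 2000, "ncrna"),
        "pseudogenes": _intergenic_set(config.n_pseudogenes, 1000, 3000, "pseudo"),
    }
    for cls, n in config.n_peaks.items():
        placer = _Placer(chrom_lens, rng)
        lo, hi = config.peak_len[cls]
        rows = []
        for i in range(n):
            ln = int(rng.integers(lo, hi))
            chrom, start, end = placer.place(ln)
            rows.append((chrom, start, end, f"{cls}_{i}", 0, "."))
        features[cls] = _bed_frame(rows)
    return features


# ---------------------------------------------------------------------------
# methylation
# ---------------------------------------------------------------------------

def generate_methylation(config: SimConfig, genome: dict[str, str],
                         islands: pd.DataFrame, rng: np.random.Generator,
                         condition: str = "normal") -> pd.DataFrame:
    """One record per CpG cytosine (both strands, shared level per CpG).

    Island CpGs are hypomethylated; background CpGs are drawn from a bimodal
    mixture with mean near 0.8. ``condition='tumour'`` multiplies all levels
    by ``tumour_shift``, emulating global tumour hypomethylation.
    """
    island_ix = IntervalIndex(islands)
    frames = []
    for chrom, seq in genome.items():
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        cg = np.flatnonzero((arr[:-1] == ord("C")) & (arr[1:] == ord("G")))
        if len(cg) == 0:
            continue
        in_island = island_ix.covers(np.full(len(cg), chrom, dtype=object), cg)
        levels = np.empty(len(cg))
        a_i, b_i = config.island_meth_beta
        a_b, b_b = config.background_meth_beta
        levels[in_island] = rng.beta(a_i, b_i, size=int(in_island.sum()))
        n_bg = int((~in_island).sum())
        bg = rng.beta(a_b, b_b, size=n_bg)
        low = rng.random(n_bg) < config.background_low_fraction
        bg[low] = rng.beta(a_i, b_i, size=int(low.sum()))
        levels[~in_island] = bg
        if condition == "tumour":
            levels = levels * config.tumour_shift
        coverage = rng.poisson(30, size=len(cg)) + 1
        both_pos = np.concatenate([cg, cg + 1])
        both_lvl = np.concatenate([levels, levels])
        both_cov = np.concatenate([coverage, coverage])
        order = np.argsort(both_pos, kind="mergesort")
        frames.append(pd.DataFrame({
            "chrom": chrom, "pos": both_pos[order],
            "level": both_lvl[order], "coverage": both_cov[order]}))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# mutations
# ---------------------------------------------------------------------------

def generate_mutations(config: SimConfig, genome: dict[str, str],
                       features: dict[str, pd.DataFrame],
                       methylation: pd.DataFrame, rng: np.random.Generator,
                       ) -> tuple[gio.MutationCohort, GroundTruth]:
    """Draw the per-sample cohort under the planted rate model."""
    chroms = list(genome)
    expected = (config.mu0 * sum(len(genome[c]) for c in chroms)
                * (config.n_samples
                   + config.n_hypermutators * (config.hypermutator_multiplier - 1)))
    if expected > 1e7:
        raise ValueError(f"expected mutation count {expected:.2g} > 1e7; "
                         "shrink the configuration")

    fold_regions = {
        "miRNA": features["mirnas"],
        "promoter": _strand_windows(features["genes"], (1000, 100), "tss"),
    }
    for cls in config.n_peaks:
        fold_regions[cls] = features[cls]

    mult_boost = (2.0 + config.meth_ct_multiplier) / 3.0
    p_transition = config.meth_ct_multiplier / (config.meth_ct_multiplier + 2.0)

    rate: dict[str, np.ndarray] = {}
    boosted: dict[str, np.ndarray] = {}
    for chrom in chroms:
        L = len(genome[chrom])
        mult = np.ones(L)
        for cls, regions in fold_regions.items():
            fold = config.fold_enrichment.get(cls, 1.0)
            if fold == 1.0:
                continue
            for r in regions[regions["chrom"] == chrom].itertuples(index=False):
                mult[max(r.start, 0):min(r.end, L)] *= fold
        meth = methylation[methylation["chrom"] == chrom]
        hot = meth.loc[meth["level"] >= config.meth_threshold, "pos"].to_numpy()
        boosted[chrom] = hot
        r = config.mu0 * mult
        r[hot] *= mult_boost
        if config.oe_coupling_beta:
            r *= _oe_rate_factor(genome[chrom], config.oe_coupling_beta)
        rate[chrom] = r

    cum = {c: np.cumsum(rate[c]) for c in chroms}
    totals = np.array([cum[c][-1] for c in chroms])

    sample_ids = [f"S{i + 1:03d}" for i in range(config.n_samples)]
    hyper_ids = sorted(rng.choice(sample_ids, size=config.n_hypermutators,
                                  replace=False).tolist())
    rows = []
    n_snvs = n_indels = 0
    for sid in sample_ids:
        factor = (config.hypermutator_multiplier if sid in hyper_ids else 1.0)
        for ci, chrom in enumerate(chroms):
            seq = genome[chrom]
            n_ev = int(rng.poisson(totals[ci] * factor))
            if n_ev == 0:
                continue
            u = rng.random(n_ev) * totals[ci]
            pos = np.unique(np.searchsorted(cum[chrom], u, side="right"))
            hot = boosted[chrom]
            is_hot = np.isin(pos, hot)
            for p, hotp in zip(pos, is_hot):
                ref = seq[p]
                if ref == "N":
                    continue
                alt = _draw_alt(ref, bool(hotp), p_transition, rng)
                rows.append((sid, chrom, int(p), ref, alt,
                             gio.classify_substitution(ref, alt)))
                n_snvs += 1
            n_ind = int(rng.poisson(config.indel_fraction * len(pos)))
            if n_ind:
                u2 = rng.random(n_ind) * totals[ci]
                ipos = np.searchsorted(cum[chrom], u2, side="right")
                for p in np.unique(ipos):
                    if rng.random() < 0.5:
                        ref, alt = seq[p], "-"
                    else:
                        ref, alt = "-", "ACGT"[int(rng.integers(4))]
                    rows.append((sid, chrom, int(p), ref, alt, "indel"))
                    n_indels += 1

    if rows:
        df = pd.DataFrame(rows, columns=gio.MUTATION_COLUMNS)
        cohort = gio.cohort_from_frame(df, provenance="simulated",
                                       samples=sample_ids)
    else:
        cohort = gio.empty_cohort(provenance="simulated")
        cohort = gio.MutationCohort(cohort.df, provenance="simulated",
                                    samples=frozenset(sample_ids))

    positions = position_index(cohort.df)
    per_class = {cls: int(count_in_intervals(positions, regions).sum())
                 for cls, regions in fold_regions.items()}
    gt = GroundTruth(
        hypermutator_ids=hyper_ids,
        per_sample_counts=cohort.per_sample_counts().to_dict(),
        per_class_counts=per_class,
        true_folds=dict(config.fold_enrichment),
        n_snvs=n_snvs, n_indels=n_indels)
    return cohort, gt


def _draw_alt(ref: str, hot: bool, p_transition: float,
              rng: np.random.Generator) -> str:
    others = [b for b in "ACGT" if b != ref]
    if hot and ref in "CG":
        transition = "T" if ref == "C" else "A"
        if rng.random() < p_transition:
            return transition
        rest = [b for b in others if b != transition]
        return rest[int(rng.integers(2))]
    return others[int(rng.integers(3))]


def _oe_rate_factor(seq: str, beta: float, N: int = 400) -> np.ndarray:
    """Per-base multiplier exp(-beta * (OE - mean OE)); 1 where OE undefined."""
    track = sliding_metrics(seq, N=N)
    oe = track["OE"].to_numpy()
    factor = np.ones(len(seq))
    center = np.nanmean(oe)
    vals = np.where(np.isnan(oe), 0.0, np.exp(-beta * (oe - center)))
    vals[np.isnan(oe)] = 1.0
    factor[N // 2:N // 2 + len(oe)] = vals
    return factor


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def simulate_dataset(config: SimConfig | None = None) -> SimulatedDataset:
    """Generate the full dataset from one seeded stream (pure in config)."""
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed)
    genome, islands = generate_genome(config, rng)
    features = generate_features(config, genome, rng)
    methylation = generate_methylation(config, genome, islands, rng)
    cohort, gt = generate_mutations(config, genome, features, methylation, rng)
    return SimulatedDataset(config=config, genome=genome, islands=islands,
                            features=features, methylation=methylation,
                            cohort=cohort, ground_truth=gt)
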