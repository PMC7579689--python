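"""Readers/writers for the formats the pipeline touches, plus cohort-level filters.

Internal convention: all coordinates are 0-based half-open. MAF-style and VCF
input is 1-based inclusive and converted at this boundary, nowhere else.

Mutation cohorts are held as a pandas DataFrame with columns
``sample_id, chrom, pos, ref, alt, var_class`` wrapped in :class:`MutationCohort`;
feature sets are BED-like DataFrames with columns
``chrom, start, end, name, score, strand``.
"""

from __future__ import annotations

import io as _stdio
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

VAR_CLASSES = ("ref_CT", "ref_GA", "indel")
#: extra class emitted only under the literal legend reading (see classify_substitution)
VAR_CLASS_OTHER = "other"

_FASTA_ALPHABET = frozenset("ACGTN")

MUTATION_COLUMNS = ["sample_id", "chrom", "pos", "ref", "alt", "var_class"]
BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


class FormatError(ValueError):
    """Malformed input file; message names the file and, where known, the line."""


class SomaticMutation(NamedTuple):
    """One per-sample somatic variant call.

    ``pos`` is the 0-based position of the first reference base. For indels
    exactly one of ``ref``/``alt`` is ``"-"``.
    """

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    var_class: str


@dataclass(frozen=True)
class MutationCohort:
    """An ordered collection of somatic mutation calls across samples.

    ``df`` is sorted by (chrom, pos, sample_id); ``n_rejected`` counts input
    records dropped at parse time (e.g. ref == alt).
    """

    df: pd.DataFrame
    provenance: str = ""
    n_rejected: int = 0
    #: full sample roster; defaults to the samples observed in ``df`` but may
    #: include mutation-free samples (they matter for per-sample frequencies)
    samples: frozenset[str] | None = None

    def __post_init__(self):
        missing = [c for c in MUTATION_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"cohort frame missing columns {missing}")
        if self.samples is not None:
            observed = set(self.df["sample_id"].unique())
            if not observed <= self.samples:
                raise ValueError("df contains sample_ids outside the roster")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def sample_ids(self) -> frozenset[str]:
        if self.samples is not None:
            return self.samples
        return frozenset(self.df["sample_id"].unique())

    def per_sample_counts(self) -> pd.Series:
        """Mutation count per sample over the full roster (zeros included)."""
        counts = self.df.groupby("sample_id").size()
        return counts.reindex(sorted(self.sample_ids), fill_value=0)

    def iter_mutations(self) -> Iterable[SomaticMutation]:
        for row in self.df.itertuples(index=False):
            yield SomaticMutation(row.sample_id, row.chrom, int(row.pos), row.ref,
                                  row.alt, row.var_class)

    def restrict_samples(self, samples: Iterable[str]) -> "MutationCohort":
        keep = frozenset(samples)
        sub = self.df[self.df["sample_id"].isin(keep)].reset_index(drop=True)
        return replace(self, df=sub, samples=keep)

    def snvs(self) -> "MutationCohort":
        sub = self.df[self.df["var_class"] != "indel"].reset_index(drop=True)
        return replace(self, df=sub)


def cohort_from_frame(df: pd.DataFrame, provenance: str = "",
                      n_rejected: int = 0,
                      samples: Iterable[str] | None = None) -> MutationCohort:
    """Sort and wrap a raw mutation frame into a :class:`MutationCohort`."""
    out = (df[MUTATION_COLUMNS]
           .sort_values(["chrom", "pos", "sample_id"], kind="mergesort")
           .reset_index(drop=True))
    return MutationCohort(out, provenance=provenance, n_rejected=n_rejected,
                          samples=frozenset(samples) if samples is not None else None)


def empty_cohort(provenance: str = "") -> MutationCohort:
    df = pd.DataFrame({c: pd.Series(dtype=(np.int64 if c == "pos" else object))
                       for c in MUTATION_COLUMNS})
    return MutationCohort(df, provenance=provenance)


# ---------------------------------------------------------------------------
# substitution classes
# ---------------------------------------------------------------------------

def classify_substitution(ref: str, alt: str, mode: str = "partition") -> str:
    """Assign a variant to one of the strata ref_CT / ref_GA / indel.

    The default ``partition`` mode splits SNVs by the reference allele:
    pyrimidine reference (C or T) -> ``ref_CT``, purine reference (G or A) ->
    ``ref_GA``; any length-changing variant is ``indel``. Together with "all"
    (the union) these strata partition every cohort. The alternative
    ``literal`` mode additionally requires the alternate allele to cross the
    pyrimidine/purine divide (C/T->G/A or G/A->C/T) and labels the remaining
    SNVs ``other``; it does not partition and exists for comparison only.

    Multi-nucleotide substitutions of equal length are classified by their
    first reference base.
    """
    if ref == alt:
        raise ValueError(f"invalid variant: ref == alt == {ref!r}")
    if ref == "-" or alt == "-" or len(ref) != len(alt):
        return "indel"
    if mode == "partition":
        return "ref_CT" if ref[0] in "CT" else "ref_GA"
    if mode == "literal":
        if ref[0] in "CT" and alt[0] in "GA":
            return "ref_CT"
        if ref[0] in "GA" and alt[0] in "CT":
            return "ref_GA"
        return VAR_CLASS_OTHER
    raise ValueError(f"unknown classification mode {mode!r}")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into ``{chrom: uppercase sequence}``.

    Sequences are uppercased and must use the alphabet {A,C,G,T,N}.
    Chromosome names are taken verbatim from the first whitespace-delimited
    header token.
    """
    path = Path(path)
    with open(path) as fh:
        first = None
        for lineno, line in enumerate(fh, 1):
            if line.strip():
                first = (lineno, line)
                break
        if first is None:
            raise FormatError(f"{path}: empty FASTA file")
        if not first[1].startswith(">"):
            raise FormatError(
                f"{path}: line {first[0]}: expected FASTA header starting with '>'")
    genome: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        bad = set(seq) - _FASTA_ALPHABET
        if bad:
            raise FormatError(
                f"{path}: record {rec.id}: invalid characters {sorted(bad)}")
        genome[rec.id] = seq
    return genome


def write_fasta(genome: dict[str, str], path, width: int = 60) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in genome.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# mutations: minimal MAF dialect and VCF
# ---------------------------------------------------------------------------

def read_mutations(path, dialect: str = "maf_min", sample_id: str | None = None,
                   class_mode: str = "partition") -> MutationCohort:
    """Read somatic mutation calls into a :class:`MutationCohort`.

    ``maf_min`` is a header line plus tab-separated columns
    ``sample, chrom, pos (1-based), ref, alt``; lines starting with '#' are
    comments. ``vcf`` reads VCF v4.x; the sample is taken from genotype
    columns carrying a non-reference call, or from ``sample_id`` for
    site-only files. Multi-allelic rows are split one record per alternate
    allele. Records with ref == alt are rejected (counted, not fatal);
    positions are converted to 0-based.
    """
    if dialect == "maf_min":
        return _read_maf_min(path, class_mode)
    if dialect == "vcf":
        return _read_vcf(path, sample_id, class_mode)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_maf_min(path, class_mode: str) -> MutationCohort:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", header=0, dtype=str)
    if df.shape[1] < 5:
        raise FormatError(f"{path}: expected >= 5 tab-separated columns")
    df = df.iloc[:, :5]
    df.columns = ["sample_id", "chrom", "pos", "ref", "alt"]
    df["pos"] = df["pos"].astype(np.int64) - 1
    if (df["pos"] < 0).any():
        raise FormatError(f"{path}: 1-based position < 1")
    bad = df["ref"] == df["alt"]
    n_rejected = int(bad.sum())
    if n_rejected:
        log.warning("%s: rejected %d records with ref == alt", path, n_rejected)
        df = df[~bad]
    df = df.copy()
    df["var_class"] = [classify_substitution(r, a, class_mode)
                       for r, a in zip(df["ref"], df["alt"])]
    return cohort_from_frame(df, provenance=f"maf_min:{path}", n_rejected=n_rejected)


def _read_vcf(path, sample_id: str | None, class_mode: str) -> MutationCohort:
    import pysam

    rows = []
    n_rejected = 0
    with pysam.VariantFile(str(path)) as vf:
        file_samples = list(vf.header.samples)
        for rec in vf:
            ref = rec.ref.upper()
            for alt in (rec.alts or ()):
                alt = alt.upper()
                if alt == ref:
                    n_rejected += 1
                    continue
                ref_n, alt_n, pos = _normalize_vcf_allele(ref, alt, rec.pos - 1)
                if file_samples and sample_id is None:
                    carriers = [s for s in file_samples
                                if _carries_alt(rec.samples[s], ref, alt)]
                else:
                    carriers = [sample_id if sample_id is not None else str(path)]
                for s in carriers:
                    rows.append((s, rec.chrom, pos, ref_n, alt_n,
                                 classify_substitution(ref_n, alt_n, class_mode)))
    if n_rejected:
        log.warning("%s: rejected %d records with ref == alt", path, n_rejected)
    if not rows:
        return empty_cohort(provenance=f"vcf:{path}")
    df = pd.DataFrame(rows, columns=MUTATION_COLUMNS)
    return cohort_from_frame(df, provenance=f"vcf:{path}", n_rejected=n_rejected)


def _carries_alt(sample_rec, ref: str, alt: str) -> bool:
    alleles = sample_rec.alleles if sample_rec.alleles else ()
    return any(a is not None and a.upper() == alt for a in alleles)


def _normalize_vcf_allele(ref: str, alt: str, pos0: int) -> tuple[str, str, int]:
    """Convert VCF padded indel notation to the '-' dialect used internally."""
    if len(ref) == len(alt):
        return ref, alt, pos0
    # VCF anchors indels on a shared leading base
    if len(ref) > len(alt) and ref.startswith(alt):
        return ref[len(alt):], "-", pos0 + len(alt)
    if len(alt) > len(ref) and alt.startswith(ref):
        return "-", alt[len(ref):], pos0 + len(ref)
    return ref, alt, pos0  # complex substitution; keep as-is


def write_mutations(cohort: MutationCohort, path) -> None:
    """Write the minimal MAF dialect (1-based positions, '#' metadata header)."""
    df = cohort.df.copy()
    df["pos"] = df["pos"] + 1
    with open(path, "w") as fh:
        fh.write("# epimut minimal MAF dialect; pos is 1-based\n")
        fh.write("sample\tchrom\tpos\tref\talt\n")
        df[["sample_id", "chrom", "pos", "ref", "alt"]].to_csv(
            fh, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# cohort filters
# ---------------------------------------------------------------------------

def filter_hypermutators(cohort: MutationCohort, method: str = "iqr",
                         k: float = 3.0, threshold: int | None = None,
                         ) -> tuple[MutationCohort, list[str]]:
    """Drop samples with outlying total mutation burden.

    ``iqr`` removes samples whose count exceeds Q3 + k*IQR of the per-sample
    counts (Tukey fence, default k=3); ``absolute`` removes samples whose
    count exceeds ``threshold``. Returns the filtered cohort and the removed
    sample ids (sorted).
    """
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    counts = cohort.per_sample_counts()
    if method == "iqr":
        q1, q3 = np.percentile(counts.to_numpy(), [25, 75])
        cutoff = q3 + k * (q3 - q1)
    elif method == "absolute":
        if threshold is None or threshold <= 0:
            raise ValueError("absolute method needs a positive threshold")
        cutoff = threshold
    else:
        raise ValueError(f"unknown method {method!r}")
    removed = sorted(counts.index[counts > cutoff])
    keep = sorted(set(counts.index) - set(removed))
    if not keep:
        raise ValueError(
            f"hypermutator filter removed all samples (cutoff {cutoff:.1f}); "
            "raise k or the threshold")
    log.info("hypermutator filter (%s, cutoff %.1f): removed %d samples",
             method, cutoff, len(removed))
    return cohort.restrict_samples(keep), removed


def subsample_cohort(cohort: MutationCohort, n_samples: int, seed: int,
                     ) -> MutationCohort:
    """Uniform sample of ``n_samples`` samples without replacement.

    Deterministic given ``seed``; the cohort is restricted to the chosen
    samples' mutations.
    """
    samples = sorted(cohort.sample_ids)
    if n_samples > len(samples):
        raise ValueError(f"n_samples={n_samples} > {len(samples)} available")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(samples, size=n_samples, replace=False)
    return cohort.restrict_samples(chosen)


# ---------------------------------------------------------------------------
# BED / bedGraph
# ---------------------------------------------------------------------------

def read_bed(path) -> pd.DataFrame:
    """Read BED3/BED6 into a frame with columns chrom,start,end,name,score,strand.

    Intervals are 0-based half-open, preserved exactly. BED3 input is padded
    with name='.', score=0, strand='.'; the original column count is kept in
    ``df.attrs['bed_columns']`` so writes can round-trip byte-identically.
    """
    path = Path(path)
    rows = []
    ncols = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}: line {lineno}: fewer than 3 columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as e:
                raise FormatError(f"{path}: line {lineno}: {e}") from None
            if start >= end:
                raise FormatError(
                    f"{path}: line {lineno}: start {start} >= end {end}")
            name = parts[3] if len(parts) > 3 else "."
            score = parts[4] if len(parts) > 4 else "0"
            strand = parts[5] if len(parts) > 5 else "."
            if strand not in "+-.":
                raise FormatError(f"{path}: line {lineno}: bad strand {strand!r}")
            rows.append((parts[0], start, end, name, score, strand))
            ncols = max(ncols or 0, min(len(parts), 6))
    df = pd.DataFrame(rows, columns=BED_COLUMNS)
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    df.attrs["bed_columns"] = ncols or 6
    return df


def write_bed(features: pd.DataFrame, path, columns: int | None = None) -> None:
    """Write a feature frame as BED; column count from ``attrs`` unless given."""
    ncols = columns or features.attrs.get("bed_columns", 6)
    cols = BED_COLUMNS[:ncols]
    features[cols].to_csv(path, sep="\t", header=False, index=False)


def read_bedgraph_methylation(path, percent: bool = False) -> pd.DataFrame:
    """Read per-CpG methylation from bedGraph into (chrom, pos, level, coverage).

    ``pos`` is the interval start (the CpG cytosine). The value column must
    lie in [0,1], or in [0,100] with ``percent=True`` (auto-scaled). An
    optional 5th column is read as coverage (default 1).
    """
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(f"{path}: line {lineno}: fewer than 4 columns")
            start, end = int(parts[1]), int(parts[2])
            if start >= end:
                raise FormatError(f"{path}: line {lineno}: start >= end")
            level = float(parts[3])
            if percent:
                level /= 100.0
            if not 0.0 <= level <= 1.0:
                raise FormatError(
                    f"{path}: line {lineno}: methylation level {parts[3]} outside "
                    "[0,1]; pass percent=True for 0-100 scaled files")
            coverage = int(parts[4]) if len(parts) > 4 else 1
            rows.append((parts[0], start, level, coverage))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "level", "coverage"])
    df["pos"] = df["pos"].astype(np.int64)
    df["coverage"] = df["coverage"].astype(np.int64)
    return df


def write_bedgraph_methylation(meth: pd.DataFrame, path) -> None:
    out = pd.DataFrame({
        "chrom": meth["chrom"],
        "start": meth["pos"],
        "end": meth["pos"] + 1,
        "level": meth["level"].map(lambda v: format(v, ".6g")),
        "coverage": meth["coverage"],
    })
    out.to_csv(path, sep="\t", header=False, index=False)
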