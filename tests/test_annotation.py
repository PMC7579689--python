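import numpy as np
import pandas as pd
import pytest

from epimut.annotation import (AnnotationModel, CATEGORIES, annotate_mutation,
                               annotate_positions, classify_mirnas,
                               count_by_category, gene_mutation_frequency,
                               split_by_genes, top_genes)
from epimut.io import SomaticMutation

from conftest import bed_frame, make_cohort


@pytest.fixture()
def toy_model():
    genes = bed_frame([("chr1", 1000, 5000, "+")])
    genes.loc[0, "name"] = "geneA"
    cds = bed_frame([("chr1", 1000, 1200, "+")])
    cds.loc[0, "name"] = "geneA"
    return AnnotationModel(genes=genes, cds=cds)


def _mut(chrom, pos):
    return SomaticMutation("S1", chrom, pos, "C", "A", "ref_CT")


def test_exon_wins_inside_cds(toy_model):
    assert annotate_mutation(_mut("chr1", 1100), toy_model) == "exonic"


def test_promoter_window_upstream_of_tss(toy_model):
    # TSS at 1000, default window TSS-1000..TSS+100 contains 500
    assert annotate_mutation(_mut("chr1", 500), toy_model) == "promoter"


def test_unknown_chromosome_is_intergenic(toy_model):
    assert annotate_mutation(_mut("chrZ", 999_999), toy_model) == "intergenic"


def test_intron_is_gene_minus_exons(toy_model):
    # 1200..5000 has no exon: intron (TTS window 4900..6000 outranks at the end)
    assert annotate_mutation(_mut("chr1", 3000), toy_model) == "intronic"
    assert annotate_mutation(_mut("chr1", 4950), toy_model) == "TTS"


def test_minus_strand_promoter():
    genes = bed_frame([("chr1", 1000, 5000, "-")])
    genes.loc[0, "name"] = "geneB"
    model = AnnotationModel(genes=genes)
    # TSS at the right end for '-' genes: window 4900..6000
    assert annotate_mutation(_mut("chr1", 5500), model) == "promoter"
    assert annotate_mutation(_mut("chr1", 500), model) == "TTS"


def test_count_by_category_empty_and_planted(toy_model):
    empty = make_cohort([])
    counts = count_by_category(empty, toy_model)
    assert counts.sum() == 0 and set(counts.index) == set(CATEGORIES)
    planted = make_cohort([50_000 + i for i in range(100)])  # far intergenic
    counts = count_by_category(planted, toy_model)
    assert counts["intergenic"] == 100 and counts.sum() == 100


def _oracle_category(chrom, pos, model):
    """Brute-force re-annotation: scan every interval list per category."""
    def _in(df):
        for r in df.itertuples(index=False):
            if r.chrom == chrom and r.start <= pos < r.end:
                return True
        return False
    membership = {
        "miRNA": _in(model.mirnas), "exonic": _in(model.cds),
        "5'UTR": _in(model.utr5), "3'UTR": _in(model.utr3),
        "promoter": _in(model.promoters), "TTS": _in(model.tts_regions),
        "ncRNA": _in(model.ncrnas), "pseudogene": _in(model.pseudogenes),
        "intronic": _in(model.introns),
    }
    for cat in model.priority:
        if membership.get(cat):
            return cat
    return "intergenic"


def test_annotation_matches_bruteforce_oracle(small_dataset):
    """Vectorized priority annotation equals exhaustive per-mutation scanning."""
    model = small_dataset.annotation_model()
    df = small_dataset.cohort.df.sample(300, random_state=0)
    got = annotate_positions(df["chrom"].to_numpy(), df["pos"].to_numpy(), model)
    expected = [_oracle_category(c, p, model)
                for c, p in zip(df["chrom"], df["pos"])]
    assert list(got) == expected


def test_annotation_conservation_and_order_independence(small_dataset):
    model = small_dataset.annotation_model()
    cohort = small_dataset.cohort
    counts = count_by_category(cohort, model)
    assert counts.sum() == len(cohort)
    shuffled = make_cohort([])  # rebuild with a different row order
    df = cohort.df.sample(frac=1.0, random_state=1).reset_index(drop=True)
    from epimut.io import MutationCohort
    counts2 = count_by_category(MutationCohort(df), model)
    pd.testing.assert_series_equal(counts, counts2)


# ---------------------------------------------------------------------------
# miRNA host context
# ---------------------------------------------------------------------------

def test_mirna_classes_and_precedence():
    genes = bed_frame([("chr1", 0, 10_000, "+")])
    genes.loc[0, "name"] = "g"
    cds = bed_frame([("chr1", 0, 1000, "+"), ("chr1", 5000, 6000, "+")])
    cds["name"] = "g"
    model = AnnotationModel(genes=genes, cds=cds)
    mirnas = bed_frame([
        ("chr1", 2000, 2100, "+"),   # wholly intronic
        ("chr1", 999, 1050, "+"),    # 1bp CDS overlap + 50bp intron: CDS wins
        ("chr1", 20_000, 20_100, "+"),
    ])
    got = classify_mirnas(mirnas, model)
    assert list(got) == ["intron_miRNA", "CDS_miRNA", "intergenic_miRNA"]


def test_mirna_partition_matches_overlap_oracle(small_dataset):
    model = small_dataset.annotation_model()
    mirnas = small_dataset.features["mirnas"]
    got = classify_mirnas(mirnas, model)
    assert len(got) == len(mirnas)  # partition: every miRNA classified

    def overlaps(df, m):
        return any(r.chrom == m.chrom and r.start < m.end and r.end > m.start
                   for r in df.itertuples(index=False))
    for m, cls in zip(mirnas.itertuples(index=False), got):
        if overlaps(model.cds, m):
            assert cls == "CDS_miRNA"
        elif overlaps(model.introns, m):
            assert cls == "intron_miRNA"
        else:
            assert cls == "intergenic_miRNA"


# ---------------------------------------------------------------------------
# gene-level stratification
# ---------------------------------------------------------------------------

def test_gene_fraction_counts_samples_once():
    genes = bed_frame([("chr1", 100, 200, "+")])
    genes.loc[0, "name"] = "g"
    # 3 of 10 samples hit the gene; one of them twice
    muts = [("S1", 150), ("S1", 160), ("S2", 150), ("S3", 199)]
    muts += [(f"S{i}", 5000) for i in range(4, 11)]
    coh = make_cohort(muts)
    table = gene_mutation_frequency(coh, genes)
    assert table.fractions()["g"] == pytest.approx(0.3)
    assert top_genes(table, min_fraction=1.0) == set()
    assert top_genes(table, min_fraction=0.25) == {"g"}


def test_top_genes_planted_two_above_threshold():
    genes = bed_frame([("chr1", 0, 100, "+"), ("chr1", 1000, 1100, "+"),
                       ("chr1", 2000, 2100, "+")])
    genes["name"] = ["hot1", "hot2", "cold"]
    muts = [(f"S{i}", 50) for i in range(3)]        # hot1: 3/20 = 15%
    muts += [(f"S{i}", 1050) for i in range(5)]     # hot2: 5/20 = 25%
    muts += [("S0", 2050)]                          # cold: 1/20 = 5%
    muts += [(f"S{i}", 9000) for i in range(20)]    # all 20 samples exist
    coh = make_cohort(muts)
    table = gene_mutation_frequency(coh, genes)
    assert top_genes(table, min_fraction=0.10) == {"hot1", "hot2"}


def test_split_by_genes_partition(small_dataset):
    genes = small_dataset.features["genes"]
    cohort = small_dataset.cohort
    names = set(genes["name"].iloc[:10])
    inside, outside = split_by_genes(cohort, names, genes)
    assert len(inside) + len(outside) == len(cohort)
    # oracle: membership by exhaustive span scan
    spans = [(r.chrom, r.start, r.end) for r in
             genes[genes["name"].isin(names)].itertuples(index=False)]
    for row in inside.df.itertuples(index=False):
        assert any(c == row.chrom and s <= row.pos < e for c, s, e in spans)
    for row in outside.df.sample(200, random_state=0).itertuples(index=False):
        assert not any(c == row.chrom and s <= row.pos < e for c, s, e in spans)


def test_split_by_genes_degenerate_sets():
    genes = bed_frame([("chr1", 0, 100, "+")])
    genes.loc[0, "name"] = "g"
    coh = make_cohort([10, 20, 5000])
    inside, outside = split_by_genes(coh, set(), genes)
    assert len(inside) == 0 and len(outside) == 3
    inside, outside = split_by_genes(coh, {"g"}, genes)
    assert len(inside) == 2 and len(outside) == 1
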