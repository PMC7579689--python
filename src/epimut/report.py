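"""Consolidated analysis report: one run over a dataset, all tables out.

This is the orchestration layer: it strings together hypermutator filtering,
category annotation, composite profiles, enrichment tests (with a single
Benjamini-Hochberg family across all region sets tested in the run),
CpG/methylation metrics and oscillation scores, and writes everything as TSV
with '#' metadata headers. Outputs are written atomically (temp file +
rename) and are a pure function of (inputs, seed).
"""

from __future__ import annotations

import logging
import os
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

from . import cpg
from .annotation import AnnotationModel, count_by_category
from .io import MutationCohort, filter_hypermutators
from .profile import MetageneProfile, ProfileSpec, oscillation_score, peak_profile, scaled_profile
from .stats import benjamini_hochberg, enrichment_test, sample_random_regions

log = logging.getLogger(__name__)

#: conventional flank widths per peak class
PEAK_FLANKS = {"CTCF": 300, "H3K27me3": 4000, "H3K4me3": 4000,
               "H3K27ac": 4000, "DNase": 5000}


def _atomic_write(path: Path, write_fn) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=path.name + ".")
    try:
        with os.fdopen(fd, "w") as fh:
            write_fn(fh)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _write_tsv(path: Path, df: pd.DataFrame, header_lines: list[str]) -> None:
    def _fn(fh):
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")
    _atomic_write(path, _fn)


def run_report(cohort: MutationCohort, genome: dict[str, str],
               model: AnnotationModel, peaks: dict[str, pd.DataFrame],
               methylation: pd.DataFrame | None, outdir, seed: int = 0,
               filter_hyper: bool = True, null_kind: str = "random",
               n_random: int = 5, spec: ProfileSpec | None = None,
               ) -> dict[str, pd.DataFrame]:
    """Run the full analysis and write one TSV per table under ``outdir``.

    ``peaks`` maps peak-class name (e.g. CTCF, H3K27me3, DNase) to a BED-like
    frame. Returns the tables in memory as well. The enrichment family
    (miRNA + promoters + every peak class + a random-region control) shares
    one BH correction.
    """
    outdir = Path(outdir)
    spec = spec or ProfileSpec()
    tables: dict[str, pd.DataFrame] = {}
    meta = [f"seed {seed}", f"null {null_kind}",
            f"n_samples_in {len(cohort.sample_ids)}"]

    if filter_hyper:
        cohort, removed = filter_hypermutators(cohort)
        meta.append(f"hypermutators_removed {','.join(removed) or '-'}")
    meta.append(f"n_samples_used {len(cohort.sample_ids)}")

    cats = count_by_category(cohort, model)
    tables["category_counts"] = cats.rename_axis("category").reset_index(name="count")
    _write_tsv(outdir / "category_counts.tsv", tables["category_counts"], meta)

    region_sets: dict[str, pd.DataFrame] = {"miRNA": model.mirnas,
                                            "promoter": model.promoters}
    region_sets.update(peaks)
    results = []
    for name, regions in region_sets.items():
        flank = PEAK_FLANKS.get(name, 5000)
        res = enrichment_test(cohort, regions, null_kind=null_kind,
                              flank_bp=flank, seed=seed, n_random=n_random,
                              genome=genome, region_set_name=name)
        results.append(res)
    # matched random control: a shuffled copy of the miRNA set
    control = sample_random_regions(model.mirnas, genome, seed=seed + 1)
    res = enrichment_test(cohort, control, null_kind=null_kind, flank_bp=5000,
                          seed=seed, n_random=n_random, genome=genome,
                          region_set_name="random_control")
    results.append(res)
    q = benjamini_hochberg([r.p_value for r in results])
    for r, qv in zip(results, q):
        r.q_value = float(qv)
    tables["enrichment"] = pd.DataFrame([r.as_dict() for r in results])
    _write_tsv(outdir / "enrichment.tsv", tables["enrichment"], meta)

    profiles: dict[str, MetageneProfile] = {}
    if len(model.genes):
        profiles["genes"] = scaled_profile(cohort, model.genes, spec)
    if len(model.mirnas):
        profiles["mirnas"] = scaled_profile(cohort, model.mirnas, spec)
    osc_rows = []
    for name, pk in peaks.items():
        prof = peak_profile(cohort, pk, PEAK_FLANKS.get(name, 4000), spec)
        profiles[name] = prof
        n_ext, amp = oscillation_score(prof)
        osc_rows.append((name, n_ext, amp))
    for name, prof in profiles.items():
        _write_tsv(outdir / f"profile_{name}.tsv", prof.to_frame(), meta)
    tables["oscillation"] = pd.DataFrame(
        osc_rows, columns=["region_set", "n_extrema", "amplitude"])
    _write_tsv(outdir / "oscillation.tsv", tables["oscillation"], meta)

    corr_rows = []
    for metric in ("CG", "GC", "OE"):
        _bins, rho, p = cpg.occurrence_vs_metric(cohort.snvs(), genome,
                                                 metric=metric)
        corr_rows.append((metric, rho, p))
    tables["occurrence_metric"] = pd.DataFrame(
        corr_rows, columns=["metric", "spearman_rho", "p"])
    _write_tsv(outdir / "occurrence_metric.tsv", tables["occurrence_metric"], meta)

    if methylation is not None and len(methylation):
        _per_site, bins = cpg.methylation_around_mutations(cohort, methylation)
        tables["methylation_bins"] = bins
        _write_tsv(outdir / "methylation_bins.tsv", bins, meta)
        ct = cpg.methylation_ct_ratio(cohort, methylation, genome)
        tables["methylation_ct"] = pd.DataFrame([{
            "n_sites_methylated": ct.n_sites_methylated,
            "n_sites_unmethylated": ct.n_sites_unmethylated,
            "rate_methylated": ct.rate_methylated,
            "rate_unmethylated": ct.rate_unmethylated,
            "ct_rate_ratio": ct.ratio}])
        _write_tsv(outdir / "methylation_ct.tsv", tables["methylation_ct"], meta)

    _atomic_write(outdir / "summary.txt",
                  lambda fh: fh.write(_summary_text(tables, meta)))
    return tables


def _summary_text(tables: dict[str, pd.DataFrame], meta: list[str]) -> str:
    lines = ["analysis summary", *("  " + m for m in meta), ""]
    enr = tables.get("enrichment")
    if enr is not None:
        lines.append("enrichment (fold vs null, BH-corrected q):")
        for r in enr.itertuples(index=False):
            flag = "*" if (r.q is not None and not np.isnan(r.q) and r.q < 0.05) else " "
            lines.append(f"  {flag} {r.region_set:<16} fold={r.fold:6.2f}  "
                         f"p={r.p:.3g}  q={r.q:.3g}")
        lines.append("")
    corr = tables.get("occurrence_metric")
    if corr is not None:
        lines.append("occurrence vs sequence metric (Spearman):")
        for r in corr.itertuples(index=False):
            lines.append(f"    {r.metric:<3} rho={r.spearman_rho:+.3f}  "
                         f"p={r.p:.3g}")
        lines.append("")
    ct = tables.get("methylation_ct")
    if ct is not None:
        lines.append(f"C->T rate ratio methylated/unmethylated CpG: "
                     f"{ct['ct_rate_ratio'].iloc[0]:.2f}")
    return "\n".join(lines) + "\n"


def run_on_simulation(config=None, outdir=None, seed: int | None = None,
                      **report_kwargs):
    """Simulate a dataset and run the full report on it; returns (dataset, tables).

    Convenience entry point used by the examples and the acceptance script.
    """
    from .simulate import SimConfig, simulate_dataset

    config = config or SimConfig()
    if seed is not None:
        from dataclasses import replace
        config = replace(config, seed=seed)
    ds = simulate_dataset(config)
    peaks = {cls: ds.features[cls] for cls in config.n_peaks}
    if outdir is None:
        import tempfile as _tf
        outdir = _tf.mkdtemp(prefix="epimut_report_")
    tables = run_report(ds.cohort, ds.genome, ds.annotation_model(), peaks,
                        ds.methylation, outdir, seed=config.seed,
                        **report_kwargs)
    return ds, tables
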