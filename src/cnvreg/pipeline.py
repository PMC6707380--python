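"""End-to-end orchestration: consensus -> merge -> CNVRs -> summaries.

``run_pipeline`` ties the stages together on files, mirroring the
call-set narrative of a discovery run (candidate calls in, consensus
retained, within-genome merged, CNVRs built and length-filtered), then
runs trio validation, annotation overlap, and enrichment where the
corresponding inputs were provided. Every threshold and flag in force
is recorded in the run report so a run is auditable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import io as cio
from .annotate import breed_specific, compare_external, overlap_features
from .calls import filter_supported_calls
from .enrich import qtl_enrichment
from .intervals import Thresholds
from .regions import build_cnvrs, filter_min_length, merge_within_sample
from .stats import chromosome_summary, size_and_frequency_stats
from .trios import derive_trios, trio_report

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Inputs, thresholds, and flags for one pipeline run."""

    primary_calls: Path
    support_calls: Path
    genome: Path
    pedigree: Path
    outdir: Path
    genes: Optional[Path] = None
    qtl: Optional[Path] = None
    external: Optional[Path] = None
    trios: Optional[Path] = None
    thresholds: Thresholds = field(default_factory=Thresholds)
    alpha: float = 0.05
    match_type: bool = False
    clique_merge: bool = False
    loose_trio_matching: bool = False

    def __post_init__(self) -> None:
        for name in ("primary_calls", "support_calls", "genome", "pedigree",
                     "genes", "qtl", "external", "trios"):
            p = getattr(self, name)
            if p is not None:
                p = Path(p)
                setattr(self, name, p)
                if not p.exists():
                    raise FileNotFoundError(f"{name}: {p} does not exist")
        self.outdir = Path(self.outdir)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; write stage outputs and return the run report."""
    out = config.outdir
    out.mkdir(parents=True, exist_ok=True)
    th = config.thresholds
    report: dict = {
        "thresholds": {
            "support_fraction": th.support_fraction,
            "reciprocal_fraction": th.reciprocal_fraction,
            "min_cnvr_length": th.min_cnvr_length,
            "min_feature_overlap": th.min_feature_overlap,
        },
        "flags": {
            "match_type": config.match_type,
            "clique_merge": config.clique_merge,
            "loose_trio_matching": config.loose_trio_matching,
            "support_comparison": "inclusive (fraction >= support_fraction)",
        },
        "alpha": config.alpha,
        "stages": {},
    }

    def _stage(name):
        report["stages"][name] = {}
        return report["stages"][name]

    try:
        genome = cio.read_genome(config.genome)
        samples = cio.read_pedigree(config.pedigree)
        sample_ids = {s.sample for s in samples}
        primary = cio.read_calls(config.primary_calls)
        support = cio.read_calls(config.support_calls)
    except Exception as e:
        raise RuntimeError(f"stage 'read inputs' failed: {e}") from e

    st = _stage("consensus")
    st["primary_calls_in"] = len(primary)
    st["support_calls_in"] = len(support)
    retained = filter_supported_calls(
        primary, support, th, match_type=config.match_type,
        known_samples=sample_ids,
    )
    st["calls_retained"] = len(retained)
    cio.write_calls(retained, out / "retained.tsv")

    st = _stage("build")
    by_sample: dict[str, list] = {}
    for c in retained:
        by_sample.setdefault(c.sample, []).append(c)
    merged = []
    for calls in by_sample.values():
        merged.extend(merge_within_sample(calls))
    st["calls_after_within_sample_merge"] = len(merged)
    cnvrs = build_cnvrs(merged, th, clique=config.clique_merge)
    st["cnvrs_before_length_filter"] = len(cnvrs)
    cnvrs = filter_min_length(cnvrs, th)
    st["cnvrs_final"] = len(cnvrs)
    cio.write_cnvrs_bed(cnvrs, out / "cnvrs.bed")

    st = _stage("summarize")
    if cnvrs:
        chrom_table, chrom_summary = chromosome_summary(cnvrs, genome)
        chrom_table.to_csv(out / "chromosome_summary.tsv", sep="\t", index=False)
        sizes = size_and_frequency_stats(cnvrs)
        assert sum(sizes["type_counts"].values()) == sizes["n_cnvr"]
        st.update({"genome": chrom_summary, "sizes": sizes})
        with open(out / "summary.json", "w") as fh:
            json.dump({"genome": chrom_summary, "sizes": sizes}, fh, indent=2,
                      default=str)

    st = _stage("trio_validation")
    trios = (cio.read_trios(config.trios) if config.trios
             else derive_trios(samples))
    st["n_trios"] = len(trios)
    if trios:
        table, summary = trio_report(
            cnvrs, trios,
            raw_calls=retained if config.loose_trio_matching else None,
        )
        table.to_csv(out / "trio_rates.tsv", sep="\t", index=False)
        st["summary"] = summary

    if config.genes:
        st = _stage("gene_overlap")
        genes = _read_track(config.genes, "gene")
        pairs, rollup = overlap_features(cnvrs, genes, th, genome=genome)
        pairs.to_csv(out / "cnvr_gene_overlap.tsv", sep="\t", index=False)
        st.update(rollup)

    if config.qtl:
        st = _stage("qtl_enrichment")
        qtl_feats = _read_track(config.qtl, "QTL")
        pairs, rollup = overlap_features(cnvrs, qtl_feats, th, genome=genome)
        pairs.to_csv(out / "cnvr_qtl_overlap.tsv", sep="\t", index=False)
        st.update(rollup)
        qtl_df = pd.DataFrame(
            [{"feature_id": f.feature_id, "label": f.label} for f in qtl_feats]
        )
        overlapped = set(pairs["feature_id"]) if len(pairs) else set()
        enr = qtl_enrichment(overlapped, qtl_df, alpha=config.alpha)
        enr.to_csv(out / "enrichment.tsv", sep="\t", index=False)
        st["n_traits_tested"] = int(len(enr))
        st["n_traits_significant"] = int(enr["significant"].sum()) if len(enr) else 0

    st = _stage("breed_specific")
    try:
        bs_table, bs_summary = breed_specific(cnvrs, samples)
        bs_table.to_csv(out / "breed_specific.tsv", sep="\t", index=False)
        st.update(bs_summary)
    except ValueError as e:
        raise RuntimeError(f"stage 'breed_specific' failed: {e}") from e

    if config.external:
        st = _stage("external_comparison")
        ext = _read_track(config.external, "external_cnvr")
        n, pct = compare_external(cnvrs, ext)
        st["n_overlapped"] = n
        st["ratio_pct"] = pct
        pd.DataFrame(
            [{"name": config.external.name, "n_overlapped": n, "ratio_pct": pct}]
        ).to_csv(out / "external_comparison.tsv", sep="\t", index=False)

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    return report


def _read_track(path: Path, default_class: str):
    if path.suffix in (".gff", ".gff3"):
        return cio.read_features_gff3(path)
    return cio.read_features_bed(path, default_class=default_class)
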