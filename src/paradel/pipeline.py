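"""End-to-end analysis: calling -> features -> enrichment -> regression.

Glues the stage modules together for one or more cohorts of ASCAT-style
segment tables sharing a gene set and genome annotation. Used by the CLI and
by programmatic callers (including the synthetic-cohort studies).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from . import calling, enrichment, features, regression
from .annotation import GenomeLayout, classify_passengers

logger = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    merge_bookended: bool = True
    hyper_threshold: int = 100
    recurrent: int = 3
    cap_mb: float = 10.0
    min_recurrent_hds: int = 3
    big_family_min: int = 4
    min_stratum_samples: int = 600
    with_loh: bool = True
    fisher_estimator: str = "sample"


@dataclass
class AnalysisResult:
    cohorts: dict
    combined_counts: pd.DataFrame          # gene_id, n_full_hd summed over cohorts
    passenger_table: pd.DataFrame          # passenger universe with annotations
    paralogy_enrichment: dict              # cohort/combined -> [EnrichmentResult]
    property_tests: dict | None
    essential_tests: dict
    loh_tests: dict
    length_correlations: dict
    feature_table: pd.DataFrame | None
    passenger_fits: dict | None
    paralog_fits: dict | None
    exclusion: dict | None
    segment_stats: dict
    gene_classes: pd.Series


def passenger_universe(genes: pd.DataFrame, annotations: pd.DataFrame,
                       counts: pd.DataFrame, gene_classes: pd.Series) -> pd.DataFrame:
    keep = genes.loc[gene_classes == "passenger", ["gene_id", "length"]]
    tbl = keep.merge(counts, on="gene_id", how="left").merge(
        annotations, on="gene_id", how="left")
    tbl = tbl.rename(columns={"length": "gene_length"})
    tbl["n_full_hd"] = tbl["n_full_hd"].fillna(0).astype(int)
    return tbl


def run_analysis(genes: pd.DataFrame, annotations: pd.DataFrame,
                 layout: GenomeLayout, fragile_sites: pd.DataFrame | None,
                 cohorts: dict, config: AnalysisConfig | None = None,
                 with_regression: bool = True,
                 with_exclusion: bool = True) -> AnalysisResult:
    """Run the whole analysis on {cohort_name: segment table/path}.

    Stages: per-cohort gene HD/LOH calling with sample QC; cohort combination
    by summing full-gene HD counts; paralogy enrichment per cohort and
    combined; paralog-property and essentiality tests; LOH MWU comparisons;
    gene-length correlations; covariate table and the two logistic models;
    the context-exclusion re-analysis.
    """
    cfg = config or AnalysisConfig()
    gene_classes = classify_passengers(
        genes, annotations.loc[annotations["is_driver"].fillna(False).astype(bool), "gene_id"])

    results = {}
    for name, segs in cohorts.items():
        results[name] = calling.build_gene_hd_table(
            genes, segs, layout, cohort=name, merge_bookended=cfg.merge_bookended,
            hyper_threshold=cfg.hyper_threshold, with_loh=cfg.with_loh)

    combined = calling.combine_cohorts(list(results.values()))
    passengers = passenger_universe(genes, annotations, combined, gene_classes)

    def _paralogy(tbl, label):
        try:
            return enrichment.hd_group_enrichment(tbl, "is_paralog",
                                                  recurrent=cfg.recurrent)
        except enrichment.StatsError:
            logger.warning("no genes with %d+ HDs in %s; reporting 0 vs 1+ only",
                           cfg.recurrent, label)
            return enrichment.hd_group_enrichment(tbl, "is_paralog",
                                                  recurrent=cfg.recurrent,
                                                  ever_only=True)

    paralogy = {}
    for name, res in results.items():
        per = passenger_universe(genes, annotations, res.gene_table, gene_classes)
        paralogy[name] = _paralogy(per, name)
    paralogy["combined"] = _paralogy(passengers, "combined")

    par_pass = passengers[passengers["is_paralog"].fillna(False).astype(bool)].copy()
    par_pass["big_family"] = par_pass["family_size"] >= cfg.big_family_min
    par_pass["wgd"] = par_pass["is_wgd"]
    par_pass["seq_identity"] = par_pass["max_seq_identity"]
    property_tests = None
    if len(par_pass):
        try:
            property_tests = enrichment.paralog_property_tests(
                par_pass, recurrent=cfg.recurrent)
        except enrichment.StatsError as exc:
            logger.warning("paralog property tests skipped: %s", exc)

    essential_tests = {}
    for col in [c for c in annotations.columns if c.startswith("essential_")]:
        try:
            essential_tests[col] = enrichment.hd_group_enrichment(
                par_pass, col, recurrent=cfg.recurrent)
        except enrichment.StatsError as exc:
            logger.warning("essentiality test %s skipped: %s", col, exc)

    loh_tests = {}
    length_corr = {}
    for name, res in results.items():
        per = passenger_universe(genes, annotations, res.gene_table, gene_classes)
        if cfg.with_loh and "loh_all" in res.gene_table.columns:
            loh_tests[name] = enrichment.loh_comparison(per, flag_col="is_paralog")
        try:
            length_corr[name] = {
                mode: enrichment.length_hd_correlation(per, mode=mode)
                for mode in ("full", "partial")}
        except enrichment.StatsError as exc:
            logger.warning("length correlation skipped for %s: %s", name, exc)

    feature_table = passenger_fits = paralog_fits = None
    if with_regression:
        feature_table = features.build_feature_table(
            genes, annotations, combined, layout, fragile_sites,
            universe=passengers["gene_id"], cap_mb=cfg.cap_mb,
            min_recurrent_hds=cfg.min_recurrent_hds,
            big_family_min=cfg.big_family_min, on_constant="drop")
        passenger_fits = regression.run_passenger_model(
            feature_table, recurrent=cfg.recurrent, on_error="skip")
        if feature_table["paralog"].astype(bool).sum() > 0:
            paralog_fits = regression.run_paralog_model(
                feature_table, recurrent=cfg.recurrent, on_error="skip")

    exclusion = None
    if with_exclusion:
        exclusion = exclusion_reanalysis(
            genes, annotations, results, fragile_sites, gene_classes, cfg)

    seg_stats = {name: res.segment_stats for name, res in results.items()}
    return AnalysisResult(
        cohorts=results, combined_counts=combined, passenger_table=passengers,
        paralogy_enrichment=paralogy, property_tests=property_tests,
        essential_tests=essential_tests, loh_tests=loh_tests,
        length_correlations=length_corr, feature_table=feature_table,
        passenger_fits=passenger_fits, paralog_fits=paralog_fits,
        exclusion=exclusion, segment_stats=seg_stats, gene_classes=gene_classes)


def exclusion_reanalysis(genes, annotations, cohort_results: dict,
                         fragile_sites, gene_classes, cfg: AnalysisConfig) -> dict:
    """Repeat the paralogy enrichment after dropping context-driven segments.

    Excluded segments at least partially delete a TSG, at least partially
    overlap a fragile site, or are telomere- or centromere-bound. Removing
    segments can only lower per-gene HD counts, so the 0-HD fraction never
    decreases.
    """
    tsg_ids = set(annotations.loc[annotations["is_tsg"].fillna(False).astype(bool), "gene_id"])
    tsg_spans = genes[genes["gene_id"].isin(tsg_ids)][["chrom", "start", "end"]]
    kept_counts = []
    n_excluded = 0
    n_total = 0
    for name, res in cohort_results.items():
        ctx = features.classify_segment_context(res.hd_segments, tsg_spans, fragile_sites)
        kept = ctx[~ctx["excluded"]]
        n_excluded += int(ctx["excluded"].sum())
        n_total += len(ctx)
        genes_auto = genes[genes["autosomal"]]
        calls = calling.call_gene_hds(genes_auto, kept)
        full = calls[calls["call"] == "full"]
        cnt = full.groupby("gene_id").size()
        tbl = genes_auto[["gene_id"]].copy()
        tbl["n_full_hd"] = tbl["gene_id"].map(cnt).fillna(0).astype(int)
        kept_counts.append(tbl)
    combined = kept_counts[0]
    for t in kept_counts[1:]:
        combined = combined.merge(t, on="gene_id", suffixes=("", "_b"))
        combined["n_full_hd"] = combined["n_full_hd"] + combined.pop("n_full_hd_b")
    passengers = passenger_universe(genes, annotations, combined, gene_classes)
    enr = enrichment.hd_group_enrichment(passengers, "is_paralog", recurrent=cfg.recurrent)
    return dict(enrichment=enr, combined_counts=combined,
                n_segments_excluded=n_excluded, n_segments_total=n_total,
                passenger_table=passengers)
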