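"""Genomic-context classification of HD segments and regression covariates.

Distance covariates follow the inverted-capped convention: distances between
closest edges are capped at ``cap_mb`` (default 10 Mb) and the feature is
``cap - distance``, so 10 means adjacent/overlapping and 0 means farther than
the cap (or no qualifying region on the chromosome).
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .annotation import GenomeLayout, normalize_chrom

logger = logging.getLogger(__name__)

MB = 1_000_000.0


class FeatureError(ValueError):
    pass


def recurrently_deleted_tsgs(annotations: pd.DataFrame, combined_counts: pd.DataFrame,
                             min_hds: int = 3) -> set:
    """TSGs with at least ``min_hds`` full HDs in the combined cohort table."""
    tsg = annotations.loc[annotations["is_tsg"].fillna(False).astype(bool), "gene_id"]
    counts = combined_counts.set_index("gene_id")["n_full_hd"]
    hit = counts.reindex(tsg).fillna(0) >= min_hds
    return set(hit.index[hit])


def _edge_distances(gene_start, gene_end, region_start, region_end):
    """Min edge-to-edge distance (bp) from each gene to any region (same chrom
    arrays); 0 when overlapping. Regions must be sorted by start."""
    n = len(gene_start)
    if len(region_start) == 0:
        return np.full(n, np.inf)
    rs = np.asarray(region_start, dtype=float)
    re = np.asarray(region_end, dtype=float)
    order = np.argsort(rs, kind="stable")
    rs, re = rs[order], re[order]
    out = np.full(n, np.inf)
    for k in range(len(rs)):  # regions per chromosome are few; loop over regions
        d = np.maximum(0.0, np.maximum(rs[k] - gene_end, gene_start - re[k]))
        out = np.minimum(out, d)
    return out


def inverted_distance(genes: pd.DataFrame, regions: pd.DataFrame,
                      cap_mb: float = 10.0, exclude_self: pd.Series | None = None) -> pd.Series:
    """Inverted capped distance (Mb) from each gene to the nearest region.

    ``max(0, cap - min_distance)``, same chromosome only. When
    ``exclude_self`` marks a gene that is itself one of the regions, its own
    interval is ignored for that gene (diagnostic use only).
    """
    out = np.zeros(len(genes))
    cap_bp = cap_mb * MB
    if regions is None or len(regions) == 0:
        return pd.Series(out, index=genes.index, name="inv_dist")
    regions = regions.copy()
    regions["chrom"] = regions["chrom"].map(normalize_chrom)
    reg_by_chrom = {c: g for c, g in regions.groupby("chrom")}
    for chrom, grp in genes.groupby("chrom", sort=False):
        reg = reg_by_chrom.get(normalize_chrom(chrom))
        if reg is None:
            continue
        gs = grp["start"].to_numpy(dtype=float)
        ge = grp["end"].to_numpy(dtype=float)
        pos = genes.index.get_indexer(grp.index)
        if exclude_self is not None and exclude_self.loc[grp.index].any():
            d = np.empty(len(grp))
            for j, (idx, s, e) in enumerate(zip(grp.index, gs, ge)):
                r = reg
                if exclude_self.loc[idx]:
                    r = reg[~((reg["start"] == s) & (reg["end"] == e))]
                d[j] = _edge_distances(np.array([s]), np.array([e]),
                                       r["start"].to_numpy(), r["end"].to_numpy())[0]
        else:
            d = _edge_distances(gs, ge, reg["start"].to_numpy(), reg["end"].to_numpy())
        out[pos] = np.maximum(0.0, cap_bp - d) / MB
    return pd.Series(out, index=genes.index, name="inv_dist")


def telomere_regions(layout: GenomeLayout) -> pd.DataFrame:
    """1-bp anchor regions at the observed (or assembly) chromosome ends."""
    rows = []
    for chrom, length in layout.chrom_lengths.items():
        if layout.observed is not None and chrom in layout.observed.table.index:
            b = layout.observed.for_chrom(chrom)
            lo, hi = int(b["tel_min"]), int(b["tel_max"])
        else:
            lo, hi = 1, length
        rows.append((chrom, lo, lo))
        rows.append((chrom, hi, hi))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def centromere_regions(layout: GenomeLayout) -> pd.DataFrame:
    rows = [(c, s, e) for c, (s, e) in layout.centromeres.items()]
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def overlaps_any(intervals: pd.DataFrame, regions: pd.DataFrame | None) -> np.ndarray:
    """Boolean per interval row: does it partially overlap any region?"""
    flag = np.zeros(len(intervals), dtype=bool)
    if regions is None or len(regions) == 0:
        return flag
    regions = regions.copy()
    regions["chrom"] = regions["chrom"].map(normalize_chrom)
    reg_by_chrom = {c: g.sort_values("start") for c, g in regions.groupby("chrom")}
    for chrom, grp in intervals.groupby("chrom", sort=False):
        reg = reg_by_chrom.get(normalize_chrom(chrom))
        if reg is None:
            continue
        rs = reg["start"].to_numpy()
        re_cummax = np.maximum.accumulate(reg["end"].to_numpy())
        # overlap iff some region with start <= seg.end has cummax(end) >= seg.start
        idx = np.searchsorted(rs, grp["end"].to_numpy(), side="right") - 1
        hit = (idx >= 0) & (re_cummax[np.clip(idx, 0, None)] >= grp["start"].to_numpy())
        flag[intervals.index.get_indexer(grp.index)] = hit
    return flag


def classify_segment_context(hd_segments: pd.DataFrame, tsg_spans: pd.DataFrame,
                             fragile_sites: pd.DataFrame) -> pd.DataFrame:
    """Per-segment context flags used for the segment-exclusion analysis.

    A segment is excluded iff it at least partially overlaps a TSG coding
    span, at least partially overlaps a fragile site, or is telomere- or
    centromere-bound (flags from ``detect_bound_segments``).
    """
    if not {"telomere_bound", "centromere_bound"}.issubset(hd_segments.columns):
        raise FeatureError("hd_segments must carry bound flags (run detect_bound_segments)")
    out = hd_segments.copy()
    out["overlaps_tsg"] = overlaps_any(out, tsg_spans)
    out["overlaps_fragile"] = overlaps_any(out, fragile_sites)
    out["excluded"] = (out["overlaps_tsg"] | out["overlaps_fragile"]
                       | out["telomere_bound"] | out["centromere_bound"])
    return out


def zscore(x: pd.Series) -> pd.Series:
    """Z-score with ddof=0; constant columns are rejected explicitly."""
    sd = float(np.std(x.to_numpy(dtype=float)))
    if not np.isfinite(sd) or sd == 0:
        raise FeatureError(f"cannot z-score constant column {x.name!r}")
    return (x - float(np.mean(x))) / sd


CONTINUOUS_COVARIATES = ["gene_length", "dist_tsg", "dist_fragile",
                         "dist_centromere", "dist_telomere", "seq_identity"]


def build_feature_table(genes: pd.DataFrame, annotations: pd.DataFrame,
                        combined_counts: pd.DataFrame, layout: GenomeLayout,
                        fragile_sites: pd.DataFrame | None,
                        universe: pd.Series | None = None,
                        cap_mb: float = 10.0, min_recurrent_hds: int = 3,
                        big_family_min: int = 4,
                        on_constant: str = "error") -> pd.DataFrame:
    """Assemble the per-gene covariate table for the logistic models.

    One row per universe gene (default: all genes in ``combined_counts``),
    carrying the raw covariates and z-scored copies (``z_`` prefix) computed
    over that universe; booleans are left unscaled. Inversion/capping happens
    before z-scoring. ``on_constant`` controls what happens to constant
    continuous columns: "error" (default) or "drop" (logged; used when e.g. no
    TSG is recurrently deleted so dist_tsg is identically zero).
    """
    ann = annotations.set_index("gene_id")
    counts = combined_counts.set_index("gene_id")["n_full_hd"]
    g = genes.set_index("gene_id")
    ids = counts.index if universe is None else pd.Index(universe)
    ids = ids.intersection(g.index)
    gg = g.loc[ids]

    tsg_ids = recurrently_deleted_tsgs(annotations, combined_counts, min_recurrent_hds)
    tsg_spans = (g.loc[g.index.intersection(tsg_ids)]
                 .reset_index()[["chrom", "start", "end"]])

    gm = gg.reset_index()
    tbl = pd.DataFrame({"gene_id": ids.to_numpy()})
    tbl["n_hds"] = counts.reindex(ids).to_numpy()
    tbl["paralog"] = ann["is_paralog"].reindex(ids).to_numpy()
    tbl["gene_length"] = gg["length"].to_numpy()
    tbl["dist_tsg"] = inverted_distance(gm, tsg_spans, cap_mb).to_numpy()
    tbl["dist_fragile"] = inverted_distance(gm, fragile_sites, cap_mb).to_numpy()
    tbl["dist_centromere"] = inverted_distance(gm, centromere_regions(layout), cap_mb).to_numpy()
    tbl["dist_telomere"] = inverted_distance(gm, telomere_regions(layout), cap_mb).to_numpy()
    fam = ann["family_size"].reindex(ids)
    tbl["family_size"] = fam.to_numpy()
    tbl["big_family"] = (fam >= big_family_min).fillna(False).to_numpy()
    tbl["wgd"] = ann["is_wgd"].reindex(ids).to_numpy()
    tbl["seq_identity"] = ann["max_seq_identity"].reindex(ids).to_numpy(dtype=float)

    n_missing = int(pd.isna(tbl["paralog"]).sum())
    if n_missing:
        logger.info("dropping %d universe genes with missing paralog annotation", n_missing)
        tbl = tbl[~pd.isna(tbl["paralog"])].reset_index(drop=True)
    tbl["paralog"] = tbl["paralog"].astype(bool)

    for col in CONTINUOUS_COVARIATES:
        if col == "seq_identity" and tbl[col].isna().any():
            continue  # singleton universe: identity undefined, not z-scored
        try:
            tbl["z_" + col] = zscore(tbl[col])
        except FeatureError:
            if on_constant == "drop":
                logger.warning("dropping constant covariate %r", col)
                tbl = tbl.drop(columns=[col])
            else:
                raise
    return tbl


def dist_sd_mb(feature_table: pd.DataFrame, col: str = "dist_tsg") -> float:
    """One standard deviation of an inverted-distance covariate, in Mb, so
    z-scored effect sizes stay interpretable."""
    return float(np.std(feature_table[col].to_numpy(dtype=float)))
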