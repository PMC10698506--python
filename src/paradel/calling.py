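"""Allele-specific copy-number segment parsing and gene-level HD/LOH calling.

A homozygous deletion (HD) is a segment where both the major and the minor
allele copy number are zero; a gene is called fully deleted in a sample when
its whole coding span lies inside one (optionally merged) HD segment of that
sample. LOH segments have exactly one allele at copy number zero.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import AUTOSOMES, GenomeLayout, normalize_chrom

logger = logging.getLogger(__name__)

SEGMENT_COLUMNS = ["sample", "chrom", "start", "end", "n_major", "n_minor"]

# Accepted ASCAT-style header aliases (extra columns are ignored).
_ALIASES = {
    "sample": "sample", "sampleid": "sample", "sample_id": "sample",
    "chr": "chrom", "chrom": "chrom", "chromosome": "chrom",
    "start": "start", "startpos": "start",
    "end": "end", "endpos": "end",
    "nmajor": "n_major", "n_major": "n_major", "major_cn": "n_major",
    "nminor": "n_minor", "n_minor": "n_minor", "minor_cn": "n_minor",
}


class SegmentError(ValueError):
    """Raised on malformed or inconsistent segment input."""


def read_segments(source, autosomes_only: bool = True) -> pd.DataFrame:
    """Read an ASCAT-style allele-specific segment table (TSV or DataFrame).

    Column names are matched case-insensitively against the common ASCAT
    dialects (sample/chr/startpos/endpos/nMajor/nMinor). Invariants checked:
    start <= end, 0 <= n_minor <= n_major.
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        df = pd.read_csv(source, sep="\t", comment="#")
    rename = {}
    for col in df.columns:
        key = str(col).strip().lower()
        if key in _ALIASES:
            rename[col] = _ALIASES[key]
    df = df.rename(columns=rename)
    missing = set(SEGMENT_COLUMNS) - set(df.columns)
    if missing:
        raise SegmentError(f"segment table missing columns: {sorted(missing)}")
    df = df[SEGMENT_COLUMNS].copy()
    df["chrom"] = df["chrom"].map(normalize_chrom)
    for col in ("start", "end", "n_major", "n_minor"):
        df[col] = pd.to_numeric(df[col], errors="raise").astype(np.int64)
    if (df["start"] > df["end"]).any():
        bad = df[df["start"] > df["end"]].iloc[0]
        raise SegmentError(f"segment with start > end: {bad['sample']} {bad['chrom']}:{bad['start']}")
    if (df["n_minor"] < 0).any() or (df["n_minor"] > df["n_major"]).any():
        raise SegmentError("copy numbers must satisfy 0 <= n_minor <= n_major")
    if autosomes_only:
        df = df[df["chrom"].isin(AUTOSOMES)].reset_index(drop=True)
    return df


def _check_no_overlap(df: pd.DataFrame, what: str) -> None:
    """df must be sorted by (sample, chrom, start); raises naming the locus."""
    prev_end = df.groupby(["sample", "chrom"], sort=False)["end"].shift()
    bad = df["start"] <= prev_end
    if bad.any():
        row = df[bad].iloc[0]
        raise SegmentError(
            f"overlapping {what} segments in sample {row['sample']} at "
            f"{row['chrom']}:{row['start']}")


def identify_hd_segments(segments: pd.DataFrame, merge_bookended: bool = True) -> pd.DataFrame:
    """Extract HD segments (major = minor = 0), optionally merging book-ended runs.

    Book-ended means gap-free (next start = previous end + 1); segments
    separated by >= 1 bp are never merged. Overlapping HD records within one
    sample raise. Returns sample, chrom, start, end, length, n_merged.
    """
    hd = segments[(segments["n_major"] == 0) & (segments["n_minor"] == 0)]
    hd = hd.sort_values(["sample", "chrom", "start"], kind="stable").reset_index(drop=True)
    if hd.empty:
        return pd.DataFrame(columns=["sample", "chrom", "start", "end", "length", "n_merged"])
    _check_no_overlap(hd, "HD")
    if merge_bookended:
        grp_change = (
            (hd["sample"] != hd["sample"].shift())
            | (hd["chrom"] != hd["chrom"].shift())
            | (hd["start"] > hd["end"].shift() + 1)
        )
        seg_id = grp_change.cumsum()
        hd = hd.groupby(seg_id).agg(
            sample=("sample", "first"), chrom=("chrom", "first"),
            start=("start", "min"), end=("end", "max"), n_merged=("start", "size"),
        ).reset_index(drop=True)
    else:
        hd = hd[["sample", "chrom", "start", "end"]].copy()
        hd["n_merged"] = 1
    hd["length"] = hd["end"] - hd["start"] + 1
    return hd[["sample", "chrom", "start", "end", "length", "n_merged"]]


def identify_loh_segments(segments: pd.DataFrame, layout: GenomeLayout) -> pd.DataFrame:
    """Extract LOH segments (minor = 0, major >= 1) with subtype and focal flag.

    Subtype is copy_loss (total copy 1), copy_neutral (total copy 2) or other
    (total >= 3). A segment is focal iff its length is less than half the
    length of the arm containing its midpoint; centromere-spanning segments
    are assigned to the midpoint arm and flagged.
    """
    loh = segments[(segments["n_minor"] == 0) & (segments["n_major"] >= 1)].copy()
    loh = loh.reset_index(drop=True)
    if loh.empty:
        loh["subtype"] = pd.Series(dtype=object)
        loh["focal"] = pd.Series(dtype=bool)
        loh["spans_centromere"] = pd.Series(dtype=bool)
        loh["length"] = pd.Series(dtype=np.int64)
        return loh
    total = loh["n_major"]
    loh["subtype"] = np.select([total == 1, total == 2], ["copy_loss", "copy_neutral"], "other")
    loh["length"] = loh["end"] - loh["start"] + 1
    mid = 0.5 * (loh["start"] + loh["end"])
    arm_len = np.empty(len(loh))
    spans = np.zeros(len(loh), dtype=bool)
    for chrom, grp in loh.groupby("chrom", sort=False):
        p, q = layout.arm_lengths(chrom)
        cs, ce = layout.centromeres[normalize_chrom(chrom)]
        idx = grp.index.to_numpy()
        arm_len[idx] = np.where(mid.loc[idx] < layout.centromere_mid(chrom), p, q)
        spans[idx] = (grp["start"] < cs) & (grp["end"] > ce)
    if spans.any():
        logger.warning("%d LOH segments span a centromere; assigned to midpoint arm",
                       int(spans.sum()))
    loh["focal"] = loh["length"] < 0.5 * arm_len
    loh["spans_centromere"] = spans
    return loh


def _gene_chrom_index(genes: pd.DataFrame) -> dict:
    """Per-chromosome arrays of gene spans sorted by start, for interval queries."""
    out = {}
    for chrom, grp in genes.groupby("chrom", sort=False):
        order = np.argsort(grp["start"].to_numpy(), kind="stable")
        out[chrom] = dict(
            row=grp.index.to_numpy()[order],
            start=grp["start"].to_numpy()[order],
            end=grp["end"].to_numpy()[order],
            max_len=int(grp["length"].max()),
        )
    return out


def map_genes_to_segments(genes: pd.DataFrame, segments: pd.DataFrame,
                          mode: str = "full") -> pd.DataFrame:
    """Pair segments with genes they fully contain (``mode='full'``) or merely
    overlap (``mode='overlap'``). Returns seg_idx (positional row in
    ``segments``) and gene_idx (index label in ``genes``).
    """
    if mode not in ("full", "overlap"):
        raise ValueError("mode must be 'full' or 'overlap'")
    index = _gene_chrom_index(genes)
    seg_out, gene_out = [], []
    segs = segments.reset_index(drop=True)
    for chrom, grp in segs.groupby("chrom", sort=False):
        gi = index.get(chrom)
        if gi is None:
            continue
        s = grp["start"].to_numpy()
        e = grp["end"].to_numpy()
        seg_pos = grp.index.to_numpy()
        if mode == "full":
            lo = np.searchsorted(gi["start"], s, side="left")
            hi = np.searchsorted(gi["start"], e, side="right")
        else:
            # overlap: gene start <= e and gene end >= s; bound candidate
            # starts below by the longest gene on the chromosome
            lo = np.searchsorted(gi["start"], s - gi["max_len"], side="left")
            hi = np.searchsorted(gi["start"], e, side="right")
        counts = np.maximum(hi - lo, 0)
        if counts.sum() == 0:
            continue
        rep = np.repeat(np.arange(len(grp)), counts)
        offs = np.arange(counts.sum()) - np.repeat(np.cumsum(counts) - counts, counts)
        cand = lo[rep] + offs
        if mode == "full":
            keep = gi["end"][cand] <= e[rep]
        else:
            keep = gi["end"][cand] >= s[rep]
        seg_out.append(seg_pos[rep[keep]])
        gene_out.append(gi["row"][cand[keep]])
    if not seg_out:
        return pd.DataFrame({"seg_idx": np.array([], dtype=int),
                             "gene_idx": np.array([], dtype=int)})
    return pd.DataFrame({"seg_idx": np.concatenate(seg_out),
                         "gene_idx": np.concatenate(gene_out)})


def call_gene_hds(genes: pd.DataFrame, hd_segments: pd.DataFrame) -> pd.DataFrame:
    """Per (sample, gene) HD call: 'full' if the coding span is fully within an
    HD segment of the sample, else 'partial' if any overlap. Genes untouched in
    a sample do not appear. One row per sample-gene pair."""
    ov = map_genes_to_segments(genes, hd_segments, mode="overlap")
    if ov.empty:
        return pd.DataFrame(columns=["sample", "gene_id", "call"])
    full = map_genes_to_segments(genes, hd_segments, mode="full")
    segs = hd_segments.reset_index(drop=True)
    pairs = pd.DataFrame({
        "sample": segs["sample"].to_numpy()[ov["seg_idx"]],
        "gene_id": genes["gene_id"].loc[ov["gene_idx"]].to_numpy(),
    })
    pairs["call"] = "partial"
    if not full.empty:
        fkeys = set(zip(segs["sample"].to_numpy()[full["seg_idx"]],
                        genes["gene_id"].loc[full["gene_idx"]].to_numpy()))
        mask = [
            (s, g) in fkeys for s, g in zip(pairs["sample"], pairs["gene_id"])
        ]
        pairs.loc[mask, "call"] = "full"
    # collapse duplicates; full dominates partial
    pairs["rank"] = (pairs["call"] == "full").astype(int)
    pairs = (pairs.sort_values("rank", ascending=False)
             .drop_duplicates(["sample", "gene_id"])
             .drop(columns="rank").reset_index(drop=True))
    return pairs


def filter_hyper_deleted(full_counts_per_sample: pd.Series, threshold: int = 100):
    """Retain samples with at most ``threshold`` full gene HDs ('over 100' is
    strict, so a sample with exactly 100 is kept). Returns (retained, dropped)."""
    dropped = full_counts_per_sample.index[full_counts_per_sample > threshold]
    retained = full_counts_per_sample.index.difference(dropped)
    if len(dropped):
        logger.info("dropped %d hyper-deleted samples (> %d full gene HDs)",
                    len(dropped), threshold)
    return list(retained), list(dropped)


def detect_bound_segments(hd_segments: pd.DataFrame, layout: GenomeLayout) -> pd.DataFrame:
    """Flag telomere- and centromere-bound HD segments.

    Telomere-bound: starts at the first or ends at the last observed
    coordinate of its chromosome. Centromere-bound: ends at the maximum
    observed coordinate before, or starts at the minimum observed coordinate
    after, the centromere assembly gap. Requires layout.observed (cohort-wide
    bounds). A whole-arm segment can carry both flags.
    """
    if layout.observed is None:
        raise ValueError("layout has no observed bounds; call with_observed_bounds first")
    out = hd_segments.copy()
    tel = np.zeros(len(out), dtype=bool)
    cen = np.zeros(len(out), dtype=bool)
    for chrom, grp in out.groupby("chrom", sort=False):
        b = layout.observed.for_chrom(chrom)
        idx = grp.index.to_numpy()
        tel[out.index.get_indexer(idx)] = (
            (grp["start"] == b["tel_min"]) | (grp["end"] == b["tel_max"])
        )
        cen[out.index.get_indexer(idx)] = (
            (grp["end"] == b["cen_left_max"]) | (grp["start"] == b["cen_right_min"])
        )
    out["telomere_bound"] = tel
    out["centromere_bound"] = cen
    return out


def genes_per_segment_stats(hd_segments: pd.DataFrame, genes: pd.DataFrame) -> dict:
    """Per-segment full-gene counts plus summaries.

    The median genes-lost is taken over gene-deleting segments only; the
    intragenic tally counts segments that overlap a gene without fully
    deleting any. Length summaries cover all HD segments.
    """
    segs = hd_segments.reset_index(drop=True)
    full = map_genes_to_segments(genes, segs, mode="full")
    ov = map_genes_to_segments(genes, segs, mode="overlap")
    n_full = np.zeros(len(segs), dtype=np.int64)
    if not full.empty:
        cnt = full.groupby("seg_idx").size()
        n_full[cnt.index.to_numpy()] = cnt.to_numpy()
    n_overlap = np.zeros(len(segs), dtype=np.int64)
    if not ov.empty:
        cnt = ov.groupby("seg_idx").size()
        n_overlap[cnt.index.to_numpy()] = cnt.to_numpy()
    per_segment = segs.assign(n_full_genes=n_full, n_overlap_genes=n_overlap)
    deleting = n_full > 0
    return dict(
        per_segment=per_segment,
        median_genes_per_deleting_segment=float(np.median(n_full[deleting])) if deleting.any() else np.nan,
        n_gene_deleting_segments=int(deleting.sum()),
        n_intragenic_segments=int(((n_full == 0) & (n_overlap > 0)).sum()),
        mean_length=float(segs["length"].mean()) if len(segs) else np.nan,
        mean_length_gene_deleting=float(segs.loc[deleting, "length"].mean()) if deleting.any() else np.nan,
    )


def hd_groups(n_hds: pd.Series, recurrent: int = 3) -> pd.DataFrame:
    """Group membership per gene: never (0), ever (1+) and recurrent (3+ by
    default). The recurrent group is a subset of the ever group."""
    return pd.DataFrame({
        "group_0": n_hds == 0,
        "group_1plus": n_hds >= 1,
        "group_recurrent": n_hds >= recurrent,
    }, index=n_hds.index)


@dataclass
class CohortHDResult:
    """Gene-level HD/LOH counts for one cohort plus per-segment detail and QC."""

    cohort: str
    gene_table: pd.DataFrame        # gene_id, n_full_hd, n_partial_hd, loh_* counts
    hd_segments: pd.DataFrame       # with bound flags and per-segment gene counts
    full_calls: pd.DataFrame        # (sample, gene_id) pairs, full HDs, retained samples
    samples: list
    dropped_samples: list
    segment_stats: dict


def build_gene_hd_table(genes: pd.DataFrame, segments: pd.DataFrame,
                        layout: GenomeLayout, cohort: str = "cohort",
                        merge_bookended: bool = True, hyper_threshold: int = 100,
                        with_loh: bool = True) -> CohortHDResult:
    """Run the per-cohort calling stage: HD segments, sample QC, gene counts.

    Hyper-deleted samples (more than ``hyper_threshold`` fully deleted genes)
    are dropped and all reported counts are recomputed on the retained set.
    Observed data boundaries for bound-segment detection are derived from the
    full (pre-QC) cohort, as they describe the assay coverage, not the tumors.
    """
    segments = read_segments(segments)
    layout = layout.with_observed_bounds(segments)
    all_samples = list(pd.unique(segments["sample"]))
    genes_auto = genes[genes["autosomal"]]

    hd = identify_hd_segments(segments, merge_bookended=merge_bookended)
    calls = call_gene_hds(genes_auto, hd)
    full_calls = calls[calls["call"] == "full"]
    per_sample = full_calls.groupby("sample").size().reindex(all_samples, fill_value=0)
    retained, dropped = filter_hyper_deleted(per_sample, hyper_threshold)
    retained_set = set(retained)

    hd = hd[hd["sample"].isin(retained_set)].reset_index(drop=True)
    hd = detect_bound_segments(hd, layout)
    stats = genes_per_segment_stats(hd, genes_auto)
    hd = stats["per_segment"]
    calls = calls[calls["sample"].isin(retained_set)]
    full_calls = calls[calls["call"] == "full"][["sample", "gene_id"]].reset_index(drop=True)

    tbl = genes_auto[["gene_id"]].copy()
    n_full = full_calls.groupby("gene_id").size()
    n_partial = calls.groupby("gene_id").size()  # any overlap (full or partial)
    tbl["n_full_hd"] = tbl["gene_id"].map(n_full).fillna(0).astype(np.int64)
    tbl["n_partial_hd"] = tbl["gene_id"].map(n_partial).fillna(0).astype(np.int64)

    if with_loh:
        loh = identify_loh_segments(segments[segments["sample"].isin(retained_set)], layout)
        classes = {
            "loh_all": loh,
            "loh_focal": loh[loh["focal"]],
            "loh_copy_loss": loh[loh["subtype"] == "copy_loss"],
            "loh_copy_neutral": loh[loh["subtype"] == "copy_neutral"],
        }
        for name, sub in classes.items():
            pairs = map_genes_to_segments(genes_auto, sub, mode="full")
            if pairs.empty:
                tbl[name] = 0
                continue
            sub_r = sub.reset_index(drop=True)
            uniq = pd.DataFrame({
                "sample": sub_r["sample"].to_numpy()[pairs["seg_idx"]],
                "gene_id": genes_auto["gene_id"].loc[pairs["gene_idx"]].to_numpy(),
            }).drop_duplicates()
            cnt = uniq.groupby("gene_id").size()
            tbl[name] = tbl["gene_id"].map(cnt).fillna(0).astype(np.int64)
    return CohortHDResult(
        cohort=cohort, gene_table=tbl.reset_index(drop=True), hd_segments=hd,
        full_calls=full_calls, samples=retained, dropped_samples=dropped,
        segment_stats={k: v for k, v in stats.items() if k != "per_segment"},
    )


def combine_cohorts(results) -> pd.DataFrame:
    """Combine cohorts into one dataset by summing per-gene full HD counts."""
    tables = [r.gene_table[["gene_id", "n_full_hd"]] for r in results]
    out = tables[0].copy()
    for t in tables[1:]:
        out = out.merge(t, on="gene_id", how="outer", suffixes=("", "_b"))
        out["n_full_hd"] = out["n_full_hd"].fillna(0) + out.pop("n_full_hd_b").fillna(0)
    out["n_full_hd"] = out["n_full_hd"].astype(np.int64)
    return out
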