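"""Static genome annotation: gene models, driver/TSG lists, region sets, essentiality.

All coordinates are internally 1-based inclusive (the convention of ASCAT-style
segment tables, which are the primary input). BED files are converted at the
boundary when read or written.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

AUTOSOMES = tuple(str(i) for i in range(1, 23))

GENE_COLUMNS = ["gene_id", "symbol", "chrom", "start", "end"]


def normalize_chrom(chrom) -> str:
    """Strip a 'chr' prefix so 'chr3' and '3' compare equal."""
    s = str(chrom)
    return s[3:] if s.lower().startswith("chr") else s


class AnnotationError(ValueError):
    """Raised on malformed annotation input."""


@dataclass(frozen=True)
class ObservedBounds:
    """Per-chromosome data boundaries observed in a segment cohort.

    ``tel_min``/``tel_max`` are the first/last covered coordinates of the
    chromosome; ``cen_left_max``/``cen_right_min`` are the maximum observed
    coordinate before, and minimum after, the centromere assembly gap
    (NaN-free only where data exist on that side).
    """

    table: pd.DataFrame  # index chrom; tel_min, tel_max, cen_left_max, cen_right_min

    def for_chrom(self, chrom: str) -> pd.Series:
        c = normalize_chrom(chrom)
        if c not in self.table.index:
            raise KeyError(f"chromosome {c!r} has no observed bounds")
        return self.table.loc[c]


@dataclass(frozen=True)
class GenomeLayout:
    """Chromosome lengths, centromere gaps and (optionally) observed data bounds."""

    chrom_lengths: dict
    centromeres: dict  # chrom -> (start, end), 1-based inclusive
    observed: ObservedBounds | None = None

    def __post_init__(self):
        for chrom, (cs, ce) in self.centromeres.items():
            if chrom not in self.chrom_lengths:
                raise AnnotationError(f"centromere on unknown chromosome {chrom!r}")
            length = self.chrom_lengths[chrom]
            if not (1 <= cs <= ce <= length):
                raise AnnotationError(
                    f"centromere [{cs}, {ce}] outside [1, {length}] on {chrom}"
                )

    @property
    def chromosomes(self) -> list:
        return list(self.chrom_lengths)

    def centromere_mid(self, chrom: str) -> float:
        cs, ce = self.centromeres[normalize_chrom(chrom)]
        return 0.5 * (cs + ce)

    def arm_lengths(self, chrom: str) -> tuple:
        """(p, q) arm lengths in bp, split at the centromere midpoint."""
        c = normalize_chrom(chrom)
        mid = self.centromere_mid(c)
        p = mid - 1.0
        q = self.chrom_lengths[c] - mid
        if p <= 0 or q <= 0:
            raise AnnotationError(f"non-positive arm length on {c}")
        return p, q

    def arm_of(self, chrom: str, pos: float) -> str:
        return "p" if pos < self.centromere_mid(chrom) else "q"

    def with_observed_bounds(self, segments: pd.DataFrame) -> "GenomeLayout":
        """Derive observed data boundaries from a full cohort's segment table.

        The bounds are the first/last covered coordinate of each chromosome and
        the closest covered coordinates on either side of the centromere gap;
        they define telomere- and centromere-bound segment detection.
        """
        rows = {}
        seg = segments.copy()
        seg["chrom"] = seg["chrom"].map(normalize_chrom)
        for chrom, grp in seg.groupby("chrom", sort=False):
            if chrom not in self.chrom_lengths:
                raise AnnotationError(f"segments on unknown chromosome {chrom!r}")
            cs, ce = self.centromeres[chrom]
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            left_ends = ends[starts < cs]
            right_starts = starts[ends > ce]
            rows[chrom] = dict(
                tel_min=int(starts.min()),
                tel_max=int(ends.max()),
                cen_left_max=int(left_ends.max()) if left_ends.size else np.nan,
                cen_right_min=int(right_starts.min()) if right_starts.size else np.nan,
            )
        table = pd.DataFrame.from_dict(rows, orient="index")
        return replace(self, observed=ObservedBounds(table))


def read_gene_models(source) -> pd.DataFrame:
    """Read a tabular gene-model file (or DataFrame) into the canonical frame.

    Expected columns: gene_id, symbol (optional), chrom, start, end with
    1-based inclusive coding-span coordinates (first exon start to last exon
    end of the longest transcript). Returns one row per gene with ``length``
    and ``autosomal`` derived. Malformed rows and duplicate ids raise.
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        df = pd.read_csv(source, sep="\t", comment="#")
    missing = {"gene_id", "chrom", "start", "end"} - set(df.columns)
    if missing:
        raise AnnotationError(f"gene model table missing columns: {sorted(missing)}")
    if "symbol" not in df.columns:
        df["symbol"] = df["gene_id"]
    df["chrom"] = df["chrom"].map(normalize_chrom)
    for col in ("start", "end"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna() | (vals < 1)]
        if len(bad):
            raise AnnotationError(f"malformed {col} at rows {list(bad[:5])}")
        df[col] = vals.astype(np.int64)
    bad = df.index[df["start"] > df["end"]]
    if len(bad):
        raise AnnotationError(f"start > end at rows {list(bad[:5])}")
    dup = df["gene_id"][df["gene_id"].duplicated()]
    if len(dup):
        raise AnnotationError(f"duplicate gene ids: {sorted(set(dup))[:5]}")
    df["length"] = df["end"] - df["start"] + 1
    df["autosomal"] = df["chrom"].isin(AUTOSOMES)
    return df[GENE_COLUMNS + ["length", "autosomal"]].reset_index(drop=True)


def _merge_intervals(starts: np.ndarray, ends: np.ndarray):
    """Merge overlapping/book-ended sorted intervals; returns merged arrays."""
    if starts.size == 0:
        return starts, ends
    order = np.argsort(starts, kind="stable")
    starts, ends = starts[order], ends[order]
    merged_s = [starts[0]]
    merged_e = [ends[0]]
    for s, e in zip(starts[1:], ends[1:]):
        if s <= merged_e[-1] + 1:
            merged_e[-1] = max(merged_e[-1], e)
        else:
            merged_s.append(s)
            merged_e.append(e)
    return np.asarray(merged_s), np.asarray(merged_e)


def classify_passengers(genes: pd.DataFrame, driver_ids) -> pd.Series:
    """Partition genes into driver / overlap_excluded / passenger / non_autosomal.

    A non-driver autosomal gene is ``overlap_excluded`` iff its coding span
    intersects the coding span of any driver gene on the same chromosome.
    The partition is exhaustive and disjoint. Unmatched driver ids are logged.
    """
    driver_ids = set(driver_ids)
    if not driver_ids:
        logger.warning("empty driver list: all autosomal genes are passengers")
    unmatched = driver_ids - set(genes["gene_id"])
    if unmatched:
        logger.warning("%d driver ids not in gene models", len(unmatched))
    is_driver = genes["gene_id"].isin(driver_ids).to_numpy()
    cls = np.where(~genes["autosomal"].to_numpy(), "non_autosomal",
                   np.where(is_driver, "driver", "passenger")).astype(object)

    overlap = np.zeros(len(genes), dtype=bool)
    drv = genes[is_driver]
    for chrom, dgrp in drv.groupby("chrom"):
        ms, me = _merge_intervals(dgrp["start"].to_numpy(), dgrp["end"].to_numpy())
        mask = (genes["chrom"] == chrom).to_numpy() & ~is_driver
        if not mask.any():
            continue
        gs = genes.loc[mask, "start"].to_numpy()
        ge = genes.loc[mask, "end"].to_numpy()
        idx = np.searchsorted(ms, ge, side="right") - 1
        hit = (idx >= 0) & (me[np.clip(idx, 0, None)] >= gs)
        overlap[np.flatnonzero(mask)] = hit
    cls[overlap & (cls == "passenger")] = "overlap_excluded"
    return pd.Series(cls, index=genes.index, name="gene_class")


def derive_essential_set(scores: pd.DataFrame, threshold: float = -0.6,
                         fraction: float = 0.9) -> set:
    """Genes broadly essential in a gene x cell-line fitness-score matrix.

    A gene is essential iff the fraction of cell lines (with a non-missing
    score) scoring below ``threshold`` is at least ``fraction``. The defaults
    encode the CERES convention: score < -0.6 in >= 90% of lines. Genes with
    all scores missing are excluded and logged.
    """
    if scores.empty:
        raise AnnotationError("empty score matrix")
    if not 0 < fraction <= 1:
        raise AnnotationError("fraction must be in (0, 1]")
    vals = scores.to_numpy(dtype=float)
    n_obs = np.sum(~np.isnan(vals), axis=1)
    all_missing = n_obs == 0
    if all_missing.any():
        logger.warning("%d genes with all scores missing excluded",
                       int(all_missing.sum()))
    with np.errstate(invalid="ignore"):
        n_below = np.nansum(vals < threshold, axis=1)
    ok = ~all_missing & (n_below / np.where(n_obs == 0, 1, n_obs) >= fraction)
    return set(scores.index[ok])


def read_region_bed(path, name: str | None = None) -> pd.DataFrame:
    """Read a BED3(+name) file into a 1-based inclusive region frame."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1, 2], names=["chrom", "start", "end"])
    df["chrom"] = df["chrom"].map(normalize_chrom)
    if (df["start"] < 0).any() or (df["start"] >= df["end"]).any():
        raise AnnotationError("invalid BED coordinates (need 0-based half-open start < end)")
    df["start"] = df["start"].astype(np.int64) + 1  # to 1-based inclusive
    df["end"] = df["end"].astype(np.int64)
    df["name"] = name if name is not None else "region"
    return df


def write_region_bed(regions: pd.DataFrame, path) -> None:
    """Write a 1-based inclusive region frame back out as BED3."""
    out = regions.copy()
    out["start"] = out["start"].astype(np.int64) - 1
    out[["chrom", "start", "end"]].to_csv(path, sep="\t", header=False, index=False)


def validate_regions(regions: pd.DataFrame, layout: GenomeLayout) -> pd.DataFrame:
    bad = ~regions["chrom"].map(normalize_chrom).isin(layout.chrom_lengths)
    if bad.any():
        raise AnnotationError(
            f"regions on chromosomes absent from layout: {sorted(set(regions.loc[bad, 'chrom']))}")
    if (regions["start"] > regions["end"]).any():
        raise AnnotationError("region with start > end")
    return regions


def read_paralog_table(source) -> pd.DataFrame:
    """Read a paralog-annotation TSV (gene_id, family_size, max_seq_identity, wgd).

    ``is_paralog`` is derived as family_size >= 1; sequence identity is a
    fraction in [0, 1], defined (and >= 0.20, the reciprocal-identity cut-off
    used to call a paralog at all) only for paralogs.
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        df = pd.read_csv(source, sep="\t", comment="#")
    need = {"gene_id", "family_size", "max_seq_identity", "wgd"}
    missing = need - set(df.columns)
    if missing:
        raise AnnotationError(f"paralog table missing columns: {sorted(missing)}")
    df["family_size"] = df["family_size"].astype(np.int64)
    if (df["family_size"] < 0).any():
        raise AnnotationError("negative family_size")
    df["is_paralog"] = df["family_size"] >= 1
    ident = pd.to_numeric(df["max_seq_identity"], errors="coerce")
    bad = (~df["is_paralog"]) & ident.notna()
    if bad.any():
        raise AnnotationError(
            f"sequence identity given for singleton genes: {list(df.loc[bad, 'gene_id'][:5])}")
    bad = df["is_paralog"] & (ident.isna() | (ident < 0.20) | (ident > 1.0))
    if bad.any():
        raise AnnotationError(
            f"paralog genes need identity in [0.20, 1]: {list(df.loc[bad, 'gene_id'][:5])}")
    df["max_seq_identity"] = ident
    df["is_wgd"] = df["wgd"].astype(bool) & df["is_paralog"]
    return df[["gene_id", "is_paralog", "family_size", "max_seq_identity", "is_wgd"]]


def assemble_gene_annotation(genes: pd.DataFrame, paralogs: pd.DataFrame | None,
                             driver_ids=(), tsg_ids=(),
                             essential_sets: dict | None = None) -> pd.DataFrame:
    """Join paralogy, driver/TSG and essentiality annotation onto the gene set.

    Genes missing from the paralog table keep ``is_paralog`` as NA and are
    dropped from paralog-specific analyses downstream (count logged). TSG ids
    are forced to be a subset of the driver ids.
    """
    out = genes[["gene_id"]].copy()
    if paralogs is not None:
        out = out.merge(read_paralog_table(paralogs) if not
                        {"is_paralog"}.issubset(paralogs.columns) else paralogs,
                        on="gene_id", how="left")
        n_missing = int(out["is_paralog"].isna().sum())
        if n_missing:
            logger.info("%d genes lack paralog annotation", n_missing)
    else:
        out["is_paralog"] = pd.NA
        out["family_size"] = pd.NA
        out["max_seq_identity"] = np.nan
        out["is_wgd"] = pd.NA
    driver_ids = set(driver_ids)
    tsg_ids = set(tsg_ids) | (set(tsg_ids) & driver_ids)
    out["is_driver"] = out["gene_id"].isin(driver_ids | set(tsg_ids))
    out["is_tsg"] = out["gene_id"].isin(tsg_ids)
    for name, ids in (essential_sets or {}).items():
        out[f"essential_{name}"] = out["gene_id"].isin(set(ids))
    return out
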