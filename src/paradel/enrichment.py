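"""Enrichment and comparison statistics on gene-level HD tables.

Covers the Fisher exact tests on HD groups (0 vs 1+, 0 vs 3+), per-cancer-type
stratified tests with Holm-Bonferroni correction, Mann-Whitney U comparisons
(LOH counts, sequence identity), Spearman gene-length correlations and the
saturation subsampling curve. Odds ratios are the sample (unconditional)
estimate ad/bc; the conditional MLE is available as an option. All tests are
two-sided.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .calling import hd_groups

logger = logging.getLogger(__name__)


class StatsError(ValueError):
    pass


_EXACT_FISHER_N = 500


def fisher_two_sided_p(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p by the point-probability rule.

    Sums hypergeometric probabilities of all tables with the observed margins
    that are no more probable than the observed one. For tables with
    N <= 500 the hypergeometric weights C(r1, x) * C(r2, c1 - x) are compared
    in exact integer arithmetic, so probability ties are decided exactly
    rather than within a floating-point tolerance; larger tables use a
    log-gamma computation with a 1e-12 relative tie band.
    """
    import math

    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    lo, hi = max(0, c1 - r2), min(r1, c1)
    if n <= _EXACT_FISHER_N:
        weights = [math.comb(r1, x) * math.comb(r2, c1 - x)
                   for x in range(lo, hi + 1)]
        w_obs = weights[a - lo]
        num = sum(w for w in weights if w <= w_obs)
        return min(1.0, num / math.comb(n, c1))
    x = np.arange(lo, hi + 1)
    logpmf = (gammaln(r1 + 1) - gammaln(x + 1) - gammaln(r1 - x + 1)
              + gammaln(r2 + 1) - gammaln(c1 - x + 1) - gammaln(r2 - c1 + x + 1)
              - (gammaln(n + 1) - gammaln(c1 + 1) - gammaln(n - c1 + 1)))
    pmf = np.exp(logpmf)
    pexact = pmf[a - lo]
    return min(1.0, float(pmf[pmf <= pexact * (1 + 1e-12)].sum()))


@dataclass
class EnrichmentResult:
    """One 2x2 enrichment test: OR (ad/bc), two-sided Fisher p, group sizes."""

    comparison: str
    table: np.ndarray  # [[a, b], [c, d]]; rows = groups, cols = flag yes/no
    odds_ratio: float
    p_value: float
    stratum: str | None = None
    adjusted_p: float | None = None

    @property
    def group_sizes(self):
        return self.table.sum(axis=1)


def fisher_exact_or(table, comparison: str = "", stratum: str | None = None,
                    estimator: str = "sample") -> EnrichmentResult:
    """Two-sided Fisher exact test with the sample odds ratio (a*d)/(b*c).

    A zero margin raises; a single zero cell yields OR 0 or inf with a finite
    p-value. ``estimator='conditional'`` reports the conditional MLE instead.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise StatsError("need a non-negative 2x2 table")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise StatsError("zero margin: odds ratio undefined")
    a, b, c, d = t.ravel()
    if estimator == "sample":
        if b * c == 0:
            odds = np.inf if a * d > 0 else (0.0 if a * d == 0 else np.nan)
        else:
            odds = (a * d) / (b * c)
    elif estimator == "conditional":
        odds = float(sps.contingency.odds_ratio(t, kind="conditional").statistic)
    else:
        raise StatsError(f"unknown estimator {estimator!r}")
    p = fisher_two_sided_p(int(a), int(b), int(c), int(d))
    return EnrichmentResult(comparison=comparison, table=t,
                            odds_ratio=float(odds), p_value=p, stratum=stratum)


def _two_by_two(flag: np.ndarray, in_group: np.ndarray, baseline: np.ndarray):
    """Rows = (group, baseline), cols = (flag, ~flag)."""
    a = int(np.sum(in_group & flag))
    b = int(np.sum(in_group & ~flag))
    c = int(np.sum(baseline & flag))
    d = int(np.sum(baseline & ~flag))
    return np.array([[a, b], [c, d]])


def hd_group_enrichment(gene_table: pd.DataFrame, flag_col: str,
                        count_col: str = "n_full_hd", recurrent: int = 3,
                        stratum: str | None = None,
                        ever_only: bool = False) -> list:
    """Fisher tests of a boolean gene property across HD groups.

    Compares 0 vs 1+ and 0 vs ``recurrent``+ HD genes on the universe of
    genes where the flag is defined (NA rows dropped with a log line).
    ``ever_only`` restricts to the 0 vs 1+ comparison (used for small strata
    where the recurrent group may be empty).
    """
    tbl = gene_table[[count_col, flag_col]]
    defined = ~pd.isna(tbl[flag_col])
    if not defined.all():
        logger.info("%d genes lack %s; excluded from enrichment",
                    int((~defined).sum()), flag_col)
        tbl = tbl[defined]
    flag = tbl[flag_col].astype(bool).to_numpy()
    groups = hd_groups(tbl[count_col], recurrent=recurrent)
    zero = groups["group_0"].to_numpy()
    comparisons = [("1+", groups["group_1plus"].to_numpy())]
    if not ever_only:
        comparisons.append((f"{recurrent}+", groups["group_recurrent"].to_numpy()))
    results = []
    for name, mask in comparisons:
        if mask.sum() == 0 or zero.sum() == 0:
            raise StatsError(f"empty group in comparison 0 vs {name}")
        t = _two_by_two(flag, mask, zero)
        results.append(fisher_exact_or(t, comparison=f"0 vs {name} : {flag_col}",
                                       stratum=stratum))
    return results


def group_percentages(gene_table: pd.DataFrame, flag_col: str,
                      count_col: str = "n_full_hd", recurrent: int = 3) -> pd.DataFrame:
    """Bar-plot data: per HD group, percentage of genes carrying the flag."""
    tbl = gene_table[~pd.isna(gene_table[flag_col])]
    flag = tbl[flag_col].astype(bool)
    groups = hd_groups(tbl[count_col], recurrent=recurrent)
    rows = []
    for name, mask in (("0", groups["group_0"]), ("1+", groups["group_1plus"]),
                       (f"{recurrent}+", groups["group_recurrent"])):
        n = int(mask.sum())
        rows.append((name, n, 100.0 * flag[mask].mean() if n else np.nan))
    return pd.DataFrame(rows, columns=["group", "n_genes", f"pct_{flag_col}"])


def holm_adjust(p_values) -> np.ndarray:
    """Holm-Bonferroni step-down adjusted p-values."""
    return multipletests(np.asarray(p_values, dtype=float), method="holm")[1]


def stratified_enrichment(tables_by_stratum: dict, flag_col: str,
                          sample_sizes: dict, min_samples: int = 600,
                          count_col: str = "n_full_hd") -> list:
    """Per-stratum (e.g. cancer type) 0 vs 1+ Fisher tests, Holm-adjusted.

    Strata with fewer than ``min_samples`` samples are omitted.
    """
    results = []
    for name, tbl in tables_by_stratum.items():
        if sample_sizes.get(name, 0) < min_samples:
            continue
        res = hd_group_enrichment(tbl, flag_col, count_col=count_col, stratum=name,
                                  ever_only=True)[0]
        results.append(res)
    if results:
        adj = holm_adjust([r.p_value for r in results])
        for r, p in zip(results, adj):
            r.adjusted_p = float(p)
    return results


@dataclass
class MWUResult:
    comparison: str
    statistic: float
    p_value: float
    n_x: int
    n_y: int
    median_x: float
    median_y: float


def mwu_compare(x, y, comparison: str = "") -> MWUResult:
    """Two-sided Mann-Whitney U (exact for small untied samples, tie- and
    continuity-corrected normal approximation otherwise). All-tied inputs
    return p = 1 with a warning."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise StatsError("empty group in MWU comparison")
    if np.all(x == x[0]) and np.all(y == x[0]):
        logger.warning("MWU on all-tied values: p = 1")
        u = x.size * y.size / 2.0
        return MWUResult(comparison, u, 1.0, x.size, y.size, float(x[0]), float(x[0]))
    u, p = sps.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    return MWUResult(comparison, float(u), float(p), x.size, y.size,
                     float(np.median(x)), float(np.median(y)))


def loh_comparison(gene_table: pd.DataFrame, flag_col: str = "is_paralog",
                   classes=("loh_all", "loh_focal", "loh_copy_loss", "loh_copy_neutral")) -> list:
    """MWU comparisons of per-gene LOH sample counts, paralog vs singleton,
    for each LOH class."""
    tbl = gene_table[~pd.isna(gene_table[flag_col])]
    flag = tbl[flag_col].astype(bool).to_numpy()
    out = []
    for cls in classes:
        out.append(mwu_compare(tbl.loc[flag, cls], tbl.loc[~flag, cls],
                               comparison=f"{cls}: paralog vs singleton"))
    return out


def paralog_property_tests(paralog_table: pd.DataFrame, recurrent: int = 3,
                           count_col: str = "n_full_hd") -> dict:
    """Property tests on the paralog-passenger universe.

    Fisher tests for big-family and WGD membership across HD groups, and MWU
    tests of closest-paralog sequence identity for 0 vs 1+ and 0 vs 3+ genes.
    """
    out = {
        "big_family": hd_group_enrichment(paralog_table, "big_family",
                                          count_col=count_col, recurrent=recurrent),
        "wgd": hd_group_enrichment(paralog_table, "wgd",
                                   count_col=count_col, recurrent=recurrent),
    }
    groups = hd_groups(paralog_table[count_col], recurrent=recurrent)
    ident = paralog_table["seq_identity"] if "seq_identity" in paralog_table else \
        paralog_table["max_seq_identity"]
    zero = ident[groups["group_0"]].dropna()
    out["seq_identity"] = [
        mwu_compare(ident[groups["group_1plus"]].dropna(), zero,
                    comparison="seq identity: 1+ vs 0"),
        mwu_compare(ident[groups["group_recurrent"]].dropna(), zero,
                    comparison=f"seq identity: {recurrent}+ vs 0"),
    ]
    return out


def length_hd_correlation(gene_table: pd.DataFrame, mode: str = "full") -> tuple:
    """Spearman correlation of gene length with HD frequency.

    ``mode='full'`` uses full-gene HD counts, ``mode='partial'`` counts all
    (partial or full) gene HDs. Returns (rho, p)."""
    col = {"full": "n_full_hd", "partial": "n_partial_hd"}[mode]
    x = gene_table["gene_length"].to_numpy(dtype=float)
    y = gene_table[col].to_numpy(dtype=float)
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise StatsError("constant vector in correlation")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


@dataclass
class SaturationCurve:
    """Unique deleted-gene counts for subsampled cohort sizes."""

    grid: np.ndarray
    mean: np.ndarray
    min: np.ndarray
    max: np.ndarray
    n_replicates: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"n_samples": self.grid, "mean": self.mean,
                             "min": self.min, "max": self.max,
                             "R": self.n_replicates, "seed": self.seed})


def saturation_curve(full_calls: pd.DataFrame, samples, grid,
                     n_replicates: int = 100, seed: int = 0) -> SaturationCurve:
    """Subsampling saturation of unique full-gene HDs.

    ``full_calls`` holds (sample, gene_id) pairs; ``samples`` is the full
    retained sample list (samples without any HD included). Subsampling is
    without replacement, replicate r seeded as seed + r. The full-cohort
    point equals the observed unique count with zero spread.
    """
    samples = list(samples)
    n_total = len(samples)
    sample_pos = {s: i for i, s in enumerate(samples)}
    gene_codes, gene_uniques = pd.factorize(full_calls["gene_id"])
    incidence = np.zeros((n_total, len(gene_uniques)), dtype=bool)
    rows = full_calls["sample"].map(sample_pos)
    if rows.isna().any():
        raise StatsError("full_calls contain samples outside the cohort list")
    incidence[rows.to_numpy(dtype=int), gene_codes] = True
    grid = np.asarray(sorted(grid))
    if (grid > n_total).any():
        raise StatsError("grid size exceeds cohort size")
    means, mins, maxs = [], [], []
    for n in grid:
        vals = []
        for r in range(n_replicates):
            rng = np.random.default_rng(seed + r)
            if n == n_total:
                chosen = np.arange(n_total)
            else:
                chosen = rng.choice(n_total, size=int(n), replace=False)
            vals.append(0 if n == 0 else
                        int(incidence[chosen].any(axis=0).sum()))
        vals = np.asarray(vals)
        means.append(vals.mean())
        mins.append(vals.min())
        maxs.append(vals.max())
    return SaturationCurve(grid=grid, mean=np.asarray(means, dtype=float),
                           min=np.asarray(mins), max=np.asarray(maxs),
                           n_replicates=n_replicates, seed=seed)


def enrichment_frame(results) -> pd.DataFrame:
    """Flatten EnrichmentResults into a report table."""
    rows = []
    for r in results:
        a, b, c, d = r.table.ravel()
        rows.append(dict(comparison=r.comparison, stratum=r.stratum,
                         a=a, b=b, c=c, d=d, odds_ratio=r.odds_ratio,
                         p_value=r.p_value, adjusted_p=r.adjusted_p))
    return pd.DataFrame(rows)
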