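"""Logistic models for ever (1+) and recurrent (3+) gene homozygous deletion.

Model form for all passenger genes::

    1[n_HDs >= k] ~ Paralog + Gene length + Dist.to TSG + Dist.to fragile site
                    + Dist.to centromere + Dist.to telomere

and for paralog passengers only, with paralog-property terms added::

    ... ~ WGD + Big family + Sequence identity + Gene length + distances

Continuous covariates enter z-scored (so ORs are per one standard deviation),
booleans unscaled; an intercept is always included. The recurrent model
contrasts 0 vs 3+ HDs, excluding genes with 1-2 HDs from the universe.
Confidence intervals are Wald.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

PASSENGER_COVARIATES = ["paralog", "gene_length", "dist_tsg", "dist_fragile",
                        "dist_centromere", "dist_telomere"]
PARALOG_COVARIATES = ["wgd", "big_family", "seq_identity", "gene_length",
                      "dist_tsg", "dist_fragile", "dist_centromere", "dist_telomere"]
BOOLEAN_COVARIATES = {"paralog", "wgd", "big_family"}


class ModelError(ValueError):
    pass


class SeparationError(ModelError):
    """Perfect separation or non-convergence: no finite MLE to report."""


@dataclass(frozen=True)
class ModelSpec:
    """Outcome threshold and ordered covariates of one logistic model."""

    outcome_min: int                    # 1 for ever-HD, 3 for recurrent-HD
    covariates: tuple
    universe: str = "passengers"

    @property
    def outcome_label(self) -> str:
        return f"{self.outcome_min}+"


class GeneHDLogit:
    """Logistic regression of gene HD status on genomic/paralog covariates.

    Built from a feature table (see ``features.build_feature_table``); the
    design uses the z-scored copy of each continuous covariate when present.
    ``fit()`` returns a :class:`GeneHDLogitResults`.
    """

    def __init__(self, feature_table: pd.DataFrame, spec: ModelSpec,
                 count_col: str = "n_hds"):
        self.spec = spec
        tbl = feature_table
        counts = tbl[count_col]
        keep = (counts == 0) | (counts >= spec.outcome_min)
        tbl = tbl[keep]
        y = (tbl[count_col] >= spec.outcome_min).to_numpy(dtype=float)
        cols = {}
        for cov in spec.covariates:
            if cov in BOOLEAN_COVARIATES:
                if tbl[cov].isna().any():
                    raise ModelError(f"missing values in boolean covariate {cov!r}")
                cols[cov] = tbl[cov].astype(float).to_numpy()
            else:
                zcol = "z_" + cov
                if zcol not in tbl.columns:
                    raise ModelError(f"continuous covariate {cov!r} has no z-scored column")
                cols[cov] = tbl[zcol].to_numpy(dtype=float)
        X = pd.DataFrame(cols, index=tbl.index)
        if X.isna().to_numpy().any():
            raise ModelError("missing covariate values in model universe")
        const = X.columns[X.nunique() <= 1]
        if len(const):
            raise ModelError(f"constant covariates: {list(const)}")
        mat = np.column_stack([np.ones(len(X)), X.to_numpy()])
        if np.linalg.matrix_rank(mat) < mat.shape[1]:
            raise ModelError("perfectly collinear covariates")
        if y.sum() == 0 or y.sum() == len(y):
            raise ModelError("universe empty in one outcome group")
        self.endog = y
        self.exog = sm.add_constant(X, prepend=True)
        self.n_case = int(y.sum())
        self.n_control = int(len(y) - y.sum())

    def fit(self, maxiter: int = 100, tol: float = 1e-8) -> "GeneHDLogitResults":
        model = sm.Logit(self.endog, self.exog)
        try:
            res = model.fit(disp=0, maxiter=maxiter, tol=tol)
        except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError) as exc:
            raise SeparationError(f"logistic fit failed: {exc}") from exc
        if not res.mle_retvals.get("converged", False):
            raise SeparationError("logistic fit did not converge "
                                  f"(params norm {np.linalg.norm(res.params):.2g})")
        if np.max(np.abs(res.params)) > 20:
            raise SeparationError("diverging coefficients suggest separation")
        return GeneHDLogitResults(self, res)


class GeneHDLogitResults:
    """Estimates, Wald CIs and diagnostics for one fitted HD logistic model."""

    def __init__(self, model: GeneHDLogit, sm_results):
        self.model = model
        self.spec = model.spec
        self._res = sm_results

    @property
    def params(self) -> pd.Series:
        return self._res.params

    @property
    def llf(self) -> float:
        return float(self._res.llf)

    @property
    def pvalues(self) -> pd.Series:
        return self._res.pvalues

    def odds_ratios(self, alpha: float = 0.05) -> pd.DataFrame:
        """Forest-plot table: OR, Wald CI, p per covariate (intercept dropped).

        For z-scored covariates the OR is the change per one standard
        deviation of the raw variable; for booleans it is the usual contrast.
        """
        ci = self._res.conf_int(alpha=alpha)
        out = pd.DataFrame({
            "coef": self._res.params,
            "odds_ratio": np.exp(self._res.params),
            "ci_low": np.exp(ci[0]),
            "ci_high": np.exp(ci[1]),
            "p_value": self._res.pvalues,
        })
        out = out.drop(index="const")
        out.insert(0, "outcome", self.spec.outcome_label)
        out["n_0"] = self.model.n_control
        out[f"n_{self.spec.outcome_label}"] = self.model.n_case
        return out

    def summary(self):
        return self._res.summary(title=(
            f"HD logistic model ({self.spec.universe}, 0 vs {self.spec.outcome_label} HDs)"))


@dataclass
class LRTResult:
    statistic: float
    df: int
    p_value: float


def likelihood_ratio_test(full: GeneHDLogitResults, reduced: GeneHDLogitResults) -> LRTResult:
    """Chi-squared LRT of nested HD logistic models (same universe/outcome)."""
    fc = set(full.spec.covariates)
    rc = set(reduced.spec.covariates)
    if not rc.issubset(fc):
        raise ModelError("models are not nested")
    if full.spec.outcome_min != reduced.spec.outcome_min or \
            len(full.model.endog) != len(reduced.model.endog):
        raise ModelError("models fit on different universes/outcomes")
    df = len(fc) - len(rc)
    stat = max(0.0, 2.0 * (full.llf - reduced.llf))
    p = 1.0 if df == 0 else float(sps.chi2.sf(stat, df))
    return LRTResult(statistic=float(stat), df=df, p_value=p)


def _run(feature_table, covariates, universe, recurrent, count_col="n_hds",
         on_error: str = "raise"):
    out = {}
    for k, label in ((1, "1+"), (recurrent, f"{recurrent}+")):
        spec = ModelSpec(outcome_min=k, covariates=tuple(covariates), universe=universe)
        try:
            out[label] = GeneHDLogit(feature_table, spec, count_col=count_col).fit()
        except ModelError:
            if on_error != "skip":
                raise
            import logging
            logging.getLogger(__name__).warning(
                "%s model for outcome %s not identifiable on this universe "
                "(separation or degenerate design); omitted", universe, label)
    return out


def run_passenger_model(feature_table: pd.DataFrame, recurrent: int = 3,
                        covariates=None, count_col: str = "n_hds",
                        on_error: str = "raise") -> dict:
    """Fit the 1+ and 3+ HD models on the passenger universe.

    Returns {"1+": results, "3+": results}. Covariates default to the
    passenger model form; covariates whose columns were dropped as constant
    upstream (e.g. dist_tsg with no recurrently deleted TSG) are omitted.
    ``on_error='skip'`` drops an outcome whose fit separates (small cohorts)
    instead of raising, with a logged warning.
    """
    covs = list(covariates or PASSENGER_COVARIATES)
    covs = [c for c in covs if c in BOOLEAN_COVARIATES or "z_" + c in feature_table.columns]
    return _run(feature_table, covs, "passengers", recurrent, count_col, on_error)


def run_paralog_model(feature_table: pd.DataFrame, recurrent: int = 3,
                      covariates=None, count_col: str = "n_hds",
                      on_error: str = "raise") -> dict:
    """Fit the paralog-property models on the paralog-passenger universe.

    Continuous covariates are re-z-scored on this universe so the per-SD
    interpretation refers to the genes the model actually sees.
    """
    from .features import CONTINUOUS_COVARIATES, FeatureError, zscore
    tbl = feature_table[feature_table["paralog"].astype(bool)].copy()
    covs = list(covariates or PARALOG_COVARIATES)
    for col in CONTINUOUS_COVARIATES:
        if col in tbl.columns and tbl[col].notna().all():
            try:
                tbl["z_" + col] = zscore(tbl[col])
            except FeatureError:
                tbl = tbl.drop(columns=["z_" + col], errors="ignore")
    covs = [c for c in covs if c in BOOLEAN_COVARIATES or "z_" + c in tbl.columns]
    return _run(tbl, covs, "paralog passengers", recurrent, count_col, on_error)


def forest_table(results: dict) -> pd.DataFrame:
    """Stack per-outcome OR tables into one forest-plot-ready frame."""
    return pd.concat([r.odds_ratios().assign(covariate=r.odds_ratios().index)
                      for r in results.values()], ignore_index=True)


def fit_feature_table_file(path, model: str = "passenger", recurrent: int = 3,
                           count_col: str = "n_hds", on_error: str = "raise") -> dict:
    """Fit the models directly from a feature-table TSV (gene_id, covariates,
    HD counts), e.g. one produced by the pipeline's ``features`` stage or a
    compatible externally supplied table. Z-scored columns are recomputed on
    the file's universe if absent."""
    tbl = pd.read_csv(path, sep="\t", comment="#")
    from .features import CONTINUOUS_COVARIATES, zscore
    for col in CONTINUOUS_COVARIATES:
        if col in tbl.columns and "z_" + col not in tbl.columns:
            if tbl[col].notna().all():
                tbl["z_" + col] = zscore(tbl[col])
    if model == "passenger":
        return run_passenger_model(tbl, recurrent=recurrent, count_col=count_col,
                                   on_error=on_error)
    if model == "paralog":
        zc = "z_seq_identity"
        if zc not in tbl.columns and "seq_identity" in tbl.columns:
            sub = tbl[tbl["paralog"].astype(bool)]
            tbl.loc[sub.index, zc] = zscore(sub["seq_identity"])
        return run_paralog_model(tbl, recurrent=recurrent, count_col=count_col,
                                 on_error=on_error)
    raise ModelError(f"unknown model {model!r}")
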