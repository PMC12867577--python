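"""Assumption-checked group comparison of per-animal summary metrics.

Models: multi-way ANOVA (Type-II sums of squares by default, Type III with
sum-to-zero contrasts on request), ANCOVA with continuous covariates such as
body mass, and Poisson GLMs. Normality is checked with Shapiro–Wilk on the
model residuals and variance homogeneity with the median-centred Levene
test, both summarised as pass/fail at α = 0.05. Post-hoc pairwise contrasts
use Tukey's HSD or pairwise t-tests with Holm / Bonferroni /
Benjamini–Hochberg correction, reported with conventional asterisk codes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests

ALPHA = 0.05  # fixed for check-marks so reports stay comparable


class StatsError(ValueError):
    pass


@dataclass
class ModelSpec:
    response: str
    factors: list[str]
    covariates: list[str] = field(default_factory=list)
    family: str = "gaussian"        # or "poisson"
    interaction: bool = False
    ss_type: int = 2                # 2 (default) or 3 with sum contrasts

    def __post_init__(self) -> None:
        if not self.factors:
            raise StatsError("at least one factor is required")
        if self.family not in ("gaussian", "poisson"):
            raise StatsError("family must be 'gaussian' or 'poisson'")
        if self.ss_type not in (2, 3):
            raise StatsError("ss_type must be 2 or 3")

    def formula(self) -> str:
        contrast = ", Sum" if self.ss_type == 3 else ""
        terms = [f"C({f}{contrast})" for f in self.factors]
        joiner = " * " if self.interaction and len(terms) > 1 else " + "
        rhs = joiner.join(terms)
        for cov in self.covariates:
            rhs += f" + {cov}"
        return f"{self.response} ~ {rhs}"


@dataclass
class AssumptionReport:
    """Shapiro–Wilk (residual normality) and Levene (variance homogeneity)
    p-values with pass marks at α = 0.05; ``None`` marks a test that could
    not be computed (too few observations), which is distinct from failing."""

    shapiro_p: float | None
    levene_p: float | None

    @property
    def shapiro_passed(self) -> bool | None:
        return None if self.shapiro_p is None else bool(self.shapiro_p >= ALPHA)

    @property
    def levene_passed(self) -> bool | None:
        return None if self.levene_p is None else bool(self.levene_p >= ALPHA)


@dataclass
class StatResult:
    model_table: pd.DataFrame          # term, df, statistic, p
    spec: ModelSpec
    data: pd.DataFrame
    fit: object
    adjusted_means: pd.DataFrame | None = None
    posthoc_table: pd.DataFrame | None = None
    correction: str | None = None
    assumptions: AssumptionReport | None = None


def build_analysis_table(
    trace: pd.DataFrame | None,
    rmr_results: pd.DataFrame | None,
    metadata,
    metric: str,
) -> pd.DataFrame:
    """One row per animal: the requested summary metric plus factors and
    body mass from the metadata.

    Metrics: ``rmr``/``tee``/``aee`` (from the RMR results), ``ee_mean``/
    ``rer_mean`` (per-animal means of the energy trace).
    """
    if metric in ("rmr", "tee", "aee"):
        if rmr_results is None or metric not in rmr_results.columns:
            raise StatsError(f"metric {metric!r} unavailable (no RMR results)")
        values = rmr_results[["animal_id", metric]].copy()
    elif metric in ("ee_mean", "rer_mean"):
        if trace is None:
            raise StatsError(f"metric {metric!r} unavailable (no energy trace)")
        channel = metric.removesuffix("_mean")
        values = (trace.groupby("animal_id", observed=True)[channel]
                  .mean().reset_index().rename(columns={channel: metric}))
    else:
        raise StatsError(
            f"metric {metric!r} unavailable; known: rmr, tee, aee, ee_mean, rer_mean")
    cols = ["animal_id"] + metadata.factors
    if "body_mass" in metadata.data.columns:
        cols.append("body_mass")
    return values.merge(metadata.data[cols], on="animal_id", how="left")


def _groups(table: pd.DataFrame, spec: ModelSpec) -> list[np.ndarray]:
    key = table[spec.factors].astype(str).agg("/".join, axis=1)
    return [g[spec.response].to_numpy(dtype=float)
            for _, g in table.groupby(key, observed=True)]


def check_assumptions(table: pd.DataFrame, spec: ModelSpec) -> AssumptionReport:
    """Shapiro–Wilk on model residuals; median-centred Levene across the
    factor-level groups."""
    fit = smf.ols(spec.formula(), data=table).fit()
    resid = np.asarray(fit.resid)
    shapiro_p = (float(scipy.stats.shapiro(resid).pvalue)
                 if len(resid) >= 3 else None)
    groups = _groups(table, spec)
    if len(groups) >= 2 and all(len(g) >= 2 for g in groups):
        levene_p = float(scipy.stats.levene(*groups, center="median").pvalue)
    else:
        levene_p = None
    return AssumptionReport(shapiro_p=shapiro_p, levene_p=levene_p)


def _check_rank(fit) -> None:
    exog = fit.model.exog
    rank = np.linalg.matrix_rank(exog)
    if rank < exog.shape[1]:
        names = fit.model.exog_names
        # identify aliased columns via pivoted QR
        _, r = np.linalg.qr(exog)
        diag = np.abs(np.diag(r))
        aliased = [names[i] for i in range(len(diag))
                   if diag[i] < 1e-8 * diag.max()]
        raise StatsError(f"design matrix is rank deficient; aliased terms: "
                         f"{aliased or 'unidentified'}")


def fit_model(table: pd.DataFrame, spec: ModelSpec) -> StatResult:
    """Fit the requested model and return the per-term test table.

    Gaussian models use least squares with Type-II (or Type-III) sums of
    squares; Poisson models use maximum likelihood with per-term Wald tests.
    For ANCOVA, covariate-adjusted group means (predictions at the covariate
    mean) are attached.
    """
    table = table.dropna(subset=[spec.response]).reset_index(drop=True)
    for f in spec.factors:
        if table[f].nunique() < 2:
            raise StatsError(f"factor {f!r} has a single level")
    formula = spec.formula()
    if spec.family == "gaussian":
        fit = smf.ols(formula, data=table).fit()
        _check_rank(fit)
        anova = anova_lm(fit, typ=spec.ss_type)
        model_table = pd.DataFrame({
            "term": anova.index,
            "df": anova["df"].to_numpy(),
            "statistic": anova["F"].to_numpy(),
            "p": anova["PR(>F)"].to_numpy(),
        })
        if float(np.var(table[spec.response].to_numpy(dtype=float))) == 0.0:
            # degenerate constant response: no effect by definition
            not_resid = model_table["term"] != "Residual"
            model_table.loc[not_resid, "statistic"] = 0.0
            model_table.loc[not_resid, "p"] = 1.0
    else:
        fit = smf.glm(formula, data=table,
                      family=sm.families.Poisson()).fit()
        _check_rank(fit)
        wald = fit.wald_test_terms(scalar=True)
        wt = wald.table
        model_table = pd.DataFrame({
            "term": wt.index,
            "df": wt["df_constraint"].to_numpy(dtype=float),
            "statistic": wt["statistic"].to_numpy(dtype=float),
            "p": wt["pvalue"].to_numpy(dtype=float),
        })

    adjusted = None
    if spec.covariates and spec.family == "gaussian":
        levels = table[spec.factors].drop_duplicates().reset_index(drop=True)
        at = levels.copy()
        for cov in spec.covariates:
            at[cov] = table[cov].mean()
        adjusted = levels.copy()
        adjusted["adjusted_mean"] = fit.predict(at).to_numpy()

    assumptions = (check_assumptions(table, spec)
                   if spec.family == "gaussian" else None)
    return StatResult(model_table=model_table, spec=spec, data=table, fit=fit,
                      adjusted_means=adjusted, assumptions=assumptions)


def significance_stars(p_adj: float) -> str:
    """Conventional asterisk notation for an adjusted p-value."""
    if not 0 <= p_adj <= 1:
        raise StatsError(f"p-value {p_adj} outside [0, 1]")
    if p_adj < 0.001:
        return "***"
    if p_adj < 0.01:
        return "**"
    if p_adj < 0.05:
        return "*"
    return "ns"


def adjust_pvalues(raw: np.ndarray, correction: str) -> np.ndarray:
    methods = {"holm": "holm", "bonferroni": "bonferroni", "BH": "fdr_bh"}
    if correction not in methods:
        raise StatsError(f"unknown correction {correction!r}; "
                         f"known: {sorted(methods)}")
    return multipletests(raw, method=methods[correction])[1]


def posthoc(result: StatResult, method: str = "tukey",
            correction: str = "holm", factor: str | None = None) -> pd.DataFrame:
    """All pairwise level contrasts of one factor with multiplicity control.

    ``tukey`` uses the studentised-range family-wise procedure (its own
    correction); ``pairwise_t`` runs two-sample t-tests adjusted by the
    stated correction.
    """
    factor = factor or result.spec.factors[0]
    table = result.data
    levels = sorted(table[factor].astype(str).unique())
    if len(levels) < 2:
        empty = pd.DataFrame(columns=["pair", "estimate", "p_raw", "p_adj", "stars"])
        result.posthoc_table = empty
        result.correction = method if method == "tukey" else correction
        return empty

    if method == "tukey":
        tk = pairwise_tukeyhsd(table[result.spec.response].to_numpy(dtype=float),
                               table[factor].astype(str).to_numpy(), alpha=ALPHA)
        rows = []
        for (g1, g2), est, p in zip(
                itertools.combinations(tk.groupsunique, 2),
                tk.meandiffs, tk.pvalues):
            rows.append({"pair": f"{g1} vs {g2}", "estimate": float(est),
                         "p_raw": float(p), "p_adj": float(p),
                         "stars": significance_stars(float(p))})
        out = pd.DataFrame(rows)
        result.correction = "tukey"
    elif method == "pairwise_t":
        rows = []
        for g1, g2 in itertools.combinations(levels, 2):
            x = table.loc[table[factor].astype(str) == g1,
                          result.spec.response].to_numpy(dtype=float)
            y = table.loc[table[factor].astype(str) == g2,
                          result.spec.response].to_numpy(dtype=float)
            t = scipy.stats.ttest_ind(x, y)
            rows.append({"pair": f"{g1} vs {g2}",
                         "estimate": float(np.mean(x) - np.mean(y)),
                         "p_raw": float(t.pvalue)})
        out = pd.DataFrame(rows)
        out["p_adj"] = adjust_pvalues(out["p_raw"].to_numpy(), correction)
        out["stars"] = out["p_adj"].map(significance_stars)
        result.correction = correction
    else:
        raise StatsError(f"unknown post-hoc method {method!r}")
    result.posthoc_table = out
    return out
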