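"""Determinants of engagement: screening, linear models, category summaries.

The analysis mirrors a conventional two-stage epidemiological workflow:

1. **Univariate screening** of each candidate covariate against the EI
   score. Continuous covariates use a correlation test, two-level
   categorical covariates a two-sample location test, covariates with three
   or more levels a one-way comparison. For every covariate both the
   parametric branch (Pearson / t / ANOVA) and the nonparametric branch
   (Spearman / Mann-Whitney / Kruskal-Wallis) are computed; the branch is
   *chosen* by Shapiro-Wilk normality checks at alpha = 0.05, and both
   p-values are reported so the choice is auditable. Covariates with
   p <= 0.25 enter the full model.
2. **Linear models** of EI on the screened covariates: an ordinary
   least-squares full model, then backward elimination removing the whole
   covariate (joint F-test for multi-level factors) with the largest
   p-value above 0.05 until everything remaining is significant.

Missing covariate values are handled by complete-case analysis per model;
the income "no_response" category is a real level, not missingness.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)

SCREEN_ALPHA = 0.25
RETAIN_ALPHA = 0.05
_SHAPIRO_ALPHA = 0.05


# --- variable specifications ------------------------------------------------

@dataclass(frozen=True)
class VariableSpec:
    """One analysis covariate: its type and (for factors) reference level."""

    name: str
    kind: str  # "continuous" | "categorical"
    reference: str | None = None

    def __post_init__(self):
        if self.kind not in ("continuous", "categorical"):
            raise ValueError(f"unknown variable kind: {self.kind!r}")


#: The fourteen candidate determinants considered in the analysis.
DEFAULT_VARIABLES: tuple[VariableSpec, ...] = (
    VariableSpec("mother_age_years", "continuous"),
    VariableSpec("education", "categorical", reference="no_university"),
    VariableSpec("employment", "categorical", reference="working_or_studying"),
    VariableSpec("income", "categorical", reference="no_response"),
    VariableSpec("marital", "categorical", reference="relationship"),
    VariableSpec("parity", "categorical", reference="multiparous"),
    VariableSpec("recruitment", "categorical", reference="family_or_friends"),
    VariableSpec("device", "categorical", reference="ios"),
    VariableSpec("system", "categorical", reference="app_only"),
    VariableSpec("country_of_birth", "categorical", reference="other"),
    VariableSpec("infant_birth_weight_g", "continuous"),
    VariableSpec("infant_sex", "categorical", reference="male"),
    VariableSpec("baseline_feeding", "categorical", reference="mixed_feeding"),
    VariableSpec("infant_age_at_T1_weeks", "continuous"),
)


# --- dichotomization --------------------------------------------------------

def _norm(label: str) -> str:
    return " ".join(str(label).strip().lower().split())


#: Raw questionnaire labels -> analysis categories. Already-dichotomized
#: labels map to themselves, so the transform is idempotent.
DEFAULT_DICHOTOMIZATION: Mapping[str, Mapping[str, str]] = {
    "education": {
        "degree": "degree", "higher degree": "degree",
        "high school education or less": "no_university",
        "trade certificate": "no_university", "diploma": "no_university",
        "no_university": "no_university",
    },
    "employment": {
        "full or part-time": "working_or_studying",
        "casual paid work": "working_or_studying",
        "full or part-time studying": "working_or_studying",
        "keeping house and/or raising children full-time": "not_in_labor_force",
        "unemployed or laid off": "not_in_labor_force",
        "working_or_studying": "working_or_studying",
        "not_in_labor_force": "not_in_labor_force",
    },
    "income": {
        "aus $1-$119 per week": "below_average",
        "aus $120-$299 per week": "below_average",
        "aus $300-$599 per week": "below_average",
        "aus $600-$799 per week": "below_average",
        "aus $800-$999 per week": "below_average",
        "aus $1000-$1499 per week": "average",
        "aus $1500-1999 per week": "above_average",
        "aus $1500-$1999 per week": "above_average",
        "aus $2000 or more per week": "higher_income",
        "no response": "no_response",
        "below_average": "below_average", "average": "average",
        "above_average": "above_average", "higher_income": "higher_income",
        "no_response": "no_response",
    },
    "marital": {
        "married": "relationship", "living in a defacto relationship": "relationship",
        "separated": "single", "divorced": "single", "widowed": "single",
        "never married": "single",
        "relationship": "relationship", "single": "single",
    },
    "recruitment": {
        "practitioner": "practitioner", "web-based": "web_based",
        "web_based": "web_based", "family or friends": "family_or_friends",
        "family_or_friends": "family_or_friends",
    },
    "device": {"ios": "ios", "android": "android"},
    "system": {
        "app only": "app_only", "app_only": "app_only",
        "both app and email": "both_app_and_email",
        "both_app_and_email": "both_app_and_email",
    },
    "infant_sex": {"male": "male", "female": "female"},
    "baseline_feeding": {
        "breastfeeding": "breastfeeding", "formula feeding": "formula_feeding",
        "formula_feeding": "formula_feeding", "mixed feeding": "mixed_feeding",
        "mixed_feeding": "mixed_feeding",
    },
    "country_of_birth": {
        "australia": "australia", "new zealand": "new_zealand",
        "new_zealand": "new_zealand", "united kingdom": "united_kingdom",
        "united_kingdom": "united_kingdom",
    },
}


def dichotomize(covariates: pd.DataFrame,
                rules: Mapping[str, Mapping[str, str]] = DEFAULT_DICHOTOMIZATION,
                ) -> pd.DataFrame:
    """Map raw covariate labels to the analysis categories.

    Unmapped labels become NaN (flagged and logged; the row then drops out of
    any model through complete-case handling). Country of birth collapses
    unlisted countries to "other" rather than flagging them.
    """
    out = covariates.copy()
    for col, mapping in rules.items():
        if col not in out.columns:
            continue
        normalized = {_norm(k): v for k, v in mapping.items()}
        vals = out[col].map(lambda x: normalized.get(_norm(x), np.nan)
                            if pd.notna(x) else np.nan)
        if col == "country_of_birth":
            vals = vals.where(vals.notna() | out[col].isna(), "other")
        bad = vals.isna() & out[col].notna()
        if bad.any():
            labels = sorted(set(out.loc[bad, col].astype(str)))
            logger.warning("%s: %d row(s) with unmapped label(s) %s excluded "
                           "from modeling", col, int(bad.sum()), labels)
        out[col] = vals
    return out


# --- univariate screening ---------------------------------------------------

@dataclass
class UnivariateResult:
    """Association of one covariate with the EI score."""

    variable: str
    test_used: str
    statistic: float
    p_value: float
    parametric_test: str = ""
    parametric_p: float = np.nan
    nonparametric_test: str = ""
    nonparametric_p: float = np.nan
    n: int = 0
    skipped: bool = False

    @property
    def passes_screen(self) -> bool:
        return (not self.skipped) and self.p_value <= SCREEN_ALPHA


def _shapiro_normal(x: np.ndarray) -> bool:
    """True when Shapiro-Wilk does not reject normality (or cannot run)."""
    x = np.asarray(x, dtype=float)
    if x.size < 3 or np.ptp(x) == 0:
        return True
    return stats.shapiro(x).pvalue > _SHAPIRO_ALPHA


def _univariate_one(y: np.ndarray, x: pd.Series,
                    spec: VariableSpec) -> UnivariateResult:
    if spec.kind == "continuous":
        xv = x.to_numpy(dtype=float)
        if np.ptp(y) == 0 or np.ptp(xv) == 0:
            pr = sr = (0.0, 1.0)
        else:
            p = stats.pearsonr(xv, y)
            s = stats.spearmanr(xv, y)
            pr, sr = (p.statistic, p.pvalue), (s.statistic, s.pvalue)
        normal = _shapiro_normal(y) and _shapiro_normal(xv)
        chosen, (stat, pval) = (("pearson", pr) if normal else ("spearman", sr))
        return UnivariateResult(spec.name, chosen, float(stat), float(pval),
                                "pearson", float(pr[1]), "spearman", float(sr[1]),
                                n=len(y))

    levels = [lv for lv in pd.unique(x) if pd.notna(lv)]
    groups = [y[(x == lv).to_numpy()] for lv in levels]
    if len(levels) < 2:
        logger.warning("%s: single observed level, skipped", spec.name)
        return UnivariateResult(spec.name, "skipped", np.nan, np.nan,
                                n=len(y), skipped=True)
    if np.ptp(y) == 0:
        para = nonp = (0.0, 1.0)
        para_name, nonp_name = (("t_test", "mann_whitney") if len(levels) == 2
                                else ("anova", "kruskal_wallis"))
    elif len(levels) == 2:
        t = stats.ttest_ind(groups[0], groups[1], equal_var=True)
        mw = stats.mannwhitneyu(groups[0], groups[1], alternative="two-sided")
        para, nonp = (t.statistic, t.pvalue), (mw.statistic, mw.pvalue)
        para_name, nonp_name = "t_test", "mann_whitney"
    else:
        f = stats.f_oneway(*groups)
        try:
            kw = stats.kruskal(*groups)
            nonp = (kw.statistic, kw.pvalue)
        except ValueError:  # all values identical within scipy's tolerance
            nonp = (0.0, 1.0)
        para = (f.statistic, f.pvalue)
        para_name, nonp_name = "anova", "kruskal_wallis"
    normal = all(_shapiro_normal(g) for g in groups if g.size >= 3)
    chosen_name, (stat, pval) = ((para_name, para) if normal
                                 else (nonp_name, nonp))
    return UnivariateResult(spec.name, chosen_name, float(stat), float(pval),
                            para_name, float(para[1]), nonp_name, float(nonp[1]),
                            n=len(y))


def univariate_screen(data: pd.DataFrame,
                      variables: Sequence[VariableSpec] = DEFAULT_VARIABLES,
                      outcome: str = "ei",
                      ) -> list[UnivariateResult]:
    """Test each covariate against the EI; complete cases per covariate."""
    results = []
    for spec in variables:
        mask = data[outcome].notna() & data[spec.name].notna()
        y = data.loc[mask, outcome].to_numpy(dtype=float)
        x = data.loc[mask, spec.name]
        if len(y) == 0:
            results.append(UnivariateResult(spec.name, "skipped", np.nan,
                                            np.nan, skipped=True))
            continue
        results.append(_univariate_one(y, x, spec))
    return results


def screened_variables(results: Sequence[UnivariateResult],
                       alpha: float = SCREEN_ALPHA) -> list[str]:
    return [r.variable for r in results
            if not r.skipped and r.p_value <= alpha]


def univariate_table(results: Sequence[UnivariateResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "variable": r.variable, "test_used": r.test_used,
        "statistic": r.statistic, "p_value": r.p_value,
        "parametric_p": r.parametric_p, "nonparametric_p": r.nonparametric_p,
        "n": r.n, "passes_screen": r.passes_screen,
    } for r in results])


# --- linear models ----------------------------------------------------------

@dataclass
class TermEstimate:
    variable: str
    level: str | None  # None for continuous terms; reference levels included
    coefficient: float
    p_value: float | None
    is_reference: bool = False


@dataclass
class ModelResult:
    """An OLS model of the EI score (full or backward-eliminated)."""

    stage: str  # "full" | "reduced"
    variables: list[str]
    terms: list[TermEstimate]
    variable_pvalues: dict[str, float]
    r_squared: float
    reference_levels: dict[str, str]
    n_obs: int

    def coefficient(self, variable: str, level: str | None = None) -> float:
        for t in self.terms:
            if t.variable == variable and t.level == level:
                return t.coefficient
        raise KeyError((variable, level))

    def to_frame(self) -> pd.DataFrame:
        """Tabular layout; reference levels rendered with B = 1.00."""
        rows = []
        for t in self.terms:
            rows.append({
                "stage": self.stage, "variable": t.variable,
                "level": "" if t.level is None else t.level,
                "B": 1.00 if t.is_reference else t.coefficient,
                "term_p_value": np.nan if t.p_value is None else t.p_value,
                "variable_p_value": self.variable_pvalues.get(t.variable, np.nan),
                "is_reference": t.is_reference,
            })
        frame = pd.DataFrame(rows)
        frame["r_squared"] = self.r_squared
        frame["n_obs"] = self.n_obs
        return frame


def _design(data: pd.DataFrame, variables: Sequence[str],
            specs: Mapping[str, VariableSpec]):
    """Intercept + dummy-coded design matrix; returns (X, var->columns, refs)."""
    X = pd.DataFrame({"Intercept": np.ones(len(data))}, index=data.index)
    var_columns: dict[str, list[str]] = {}
    refs: dict[str, str] = {}
    levels_map: dict[str, list[str]] = {}
    for name in variables:
        spec = specs[name]
        if spec.kind == "continuous":
            X[name] = data[name].astype(float)
            var_columns[name] = [name]
            continue
        observed = sorted(lv for lv in pd.unique(data[name]) if pd.notna(lv))
        ref = spec.reference if spec.reference in observed else observed[0]
        refs[name] = ref
        cols = []
        for lv in observed:
            if lv == ref:
                continue
            col = f"{name}[{lv}]"
            X[col] = (data[name] == lv).astype(float)
            cols.append(col)
        var_columns[name] = cols
        levels_map[name] = observed
    return X, var_columns, refs, levels_map


def _check_rank(X: pd.DataFrame) -> None:
    mat = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(mat)
    if rank < mat.shape[1]:
        # identify aliased columns via pivoted QR diagnostics
        _, r = np.linalg.qr(mat)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(mat.shape) * np.finfo(float).eps
        aliased = [c for c, d in zip(X.columns, diag) if d < tol]
        raise ValueError(f"design matrix is rank deficient; aliased terms: "
                         f"{aliased or 'undetermined'}")


def _fit_ols(data: pd.DataFrame, variables: Sequence[str],
             specs: Mapping[str, VariableSpec], outcome: str, stage: str,
             ) -> ModelResult:
    cols = [outcome] + list(variables)
    cc = data[cols].dropna()
    y = cc[outcome].to_numpy(dtype=float)
    X, var_columns, refs, levels_map = _design(cc, variables, specs)
    _check_rank(X)
    fit = sm.OLS(y, X.to_numpy(dtype=float)).fit()
    names = list(X.columns)

    constant_outcome = np.ptp(y) == 0 if len(y) else True
    variable_pvalues: dict[str, float] = {}
    terms: list[TermEstimate] = []
    for name in variables:
        idx = [names.index(c) for c in var_columns[name]]
        if not idx:  # factor collapsed to its reference in this subset
            variable_pvalues[name] = np.nan
            continue
        if constant_outcome:
            variable_pvalues[name] = 1.0
        else:
            R = np.zeros((len(idx), len(names)))
            for k, j in enumerate(idx):
                R[k, j] = 1.0
            variable_pvalues[name] = float(fit.f_test(R).pvalue)
        spec = specs[name]
        if spec.kind == "continuous":
            j = idx[0]
            coef = 0.0 if constant_outcome else float(fit.params[j])
            terms.append(TermEstimate(name, None, coef,
                                      float(fit.pvalues[j])))
        else:
            terms.append(TermEstimate(name, refs[name], 0.0, None,
                                      is_reference=True))
            for lv in levels_map[name]:
                if lv == refs[name]:
                    continue
                j = names.index(f"{name}[{lv}]")
                coef = 0.0 if constant_outcome else float(fit.params[j])
                terms.append(TermEstimate(name, lv, coef, float(fit.pvalues[j])))

    r2 = 0.0 if constant_outcome else float(fit.rsquared)
    if not variables:
        r2 = 0.0
    return ModelResult(stage=stage, variables=list(variables), terms=terms,
                       variable_pvalues=variable_pvalues, r_squared=r2,
                       reference_levels=refs, n_obs=len(cc))


def fit_full_model(data: pd.DataFrame, screened: Sequence[str],
                   variables: Sequence[VariableSpec] = DEFAULT_VARIABLES,
                   outcome: str = "ei") -> ModelResult:
    """OLS of EI on every screened covariate (complete cases)."""
    specs = {s.name: s for s in variables}
    return _fit_ols(data, list(screened), specs, outcome, "full")


def fit_reduced_model(data: pd.DataFrame, full_model: ModelResult,
                      variables: Sequence[VariableSpec] = DEFAULT_VARIABLES,
                      outcome: str = "ei",
                      alpha: float = RETAIN_ALPHA) -> ModelResult:
    """Backward elimination: drop the least significant whole covariate
    (largest joint p-value above ``alpha``) and refit until all remaining
    covariates are significant. May return an intercept-only model."""
    specs = {s.name: s for s in variables}
    current = list(full_model.variables)
    while current:
        model = _fit_ols(data, current, specs, outcome, "reduced")
        pvals = {v: model.variable_pvalues.get(v, np.nan) for v in current}
        worst = max(pvals, key=lambda v: (np.nan_to_num(pvals[v], nan=1.0)))
        worst_p = pvals[worst]
        if np.isnan(worst_p) or worst_p > alpha:
            current.remove(worst)
            continue
        return model
    return _fit_ols(data, [], specs, outcome, "reduced")


# --- category summary -------------------------------------------------------

def summarize_by_category(data: pd.DataFrame,
                          variables: Sequence[VariableSpec] = DEFAULT_VARIABLES,
                          category_column: str = "category",
                          screen: Sequence[UnivariateResult] | None = None,
                          ) -> pd.DataFrame:
    """Per-category descriptive summary in tidy long form.

    Continuous covariates: n, mean, SD per engagement category. Categorical
    covariates: n and % within category per level. The univariate p-value is
    attached per variable when screen results are supplied.
    """
    pmap = {r.variable: r.p_value for r in (screen or [])}
    cats = [c for c in CATEGORY_ORDER if c in set(data[category_column])]
    for c in set(data[category_column]) - set(CATEGORY_ORDER):
        cats.append(c)
    rows = []
    for spec in variables:
        for cat in cats:
            sub = data.loc[data[category_column] == cat, spec.name].dropna()
            if len(sub) == 0:
                logger.warning("category %s: no observations for %s",
                               cat, spec.name)
            if spec.kind == "continuous":
                vals = sub.astype(float)
                rows.append({
                    "variable": spec.name, "level": "", "category": cat,
                    "n": int(len(vals)),
                    "mean": float(vals.mean()) if len(vals) else 0.0,
                    "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
                    "percent": np.nan, "p_value": pmap.get(spec.name, np.nan),
                })
            else:
                total = len(sub)
                for lv in sorted(pd.unique(data[spec.name].dropna())):
                    n_lv = int((sub == lv).sum())
                    rows.append({
                        "variable": spec.name, "level": lv, "category": cat,
                        "n": n_lv, "mean": np.nan, "sd": np.nan,
                        "percent": 100.0 * n_lv / total if total else 0.0,
                        "p_value": pmap.get(spec.name, np.nan),
                    })
    return pd.DataFrame(rows)


CATEGORY_ORDER = ("poor", "moderate", "high")
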