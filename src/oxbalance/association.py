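"""Association models: lnOBS vs serum uric acid and hyperuricemia.

Three nested specifications are supported, mirroring the usual covariate
ladder of survey epidemiology:

* Model 1 — unadjusted;
* Model 2 — adjusted for age, sex and race/ethnicity;
* Model 3 — additionally adjusted for BMI, education, smoking, drinking,
  diabetes, hypertension and hyperlipidemia.

The exposure enters either as continuous lnOBS or as quartiles (Q1 reference).
Serum uric acid is modelled by (optionally weighted) least squares; the β is
the SUA change in µmol/L per unit lnOBS.  Hyperuricemia is modelled by
maximum-likelihood logistic regression; ORs are exponentiated coefficients
with Wald 95% CIs.  Crude quartile odds ratios have a closed form
(ad/bc with log-scale normal CI) used as an independent oracle for the
unadjusted categorical logistic fit.

Fits are unweighted by default; a frequency-weight column may be named, but
complex-survey (design-based) variance estimation is out of scope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats
from sklearn.base import BaseEstimator

from .errors import (
    ConfigurationError,
    SeparationError,
    SingularDesignError,
    ZeroCellError,
)

#: covariate ladder; sets are nested (Model 1 ⊂ 2 ⊂ 3)
MODEL_COVARIATES: dict[int, tuple[str, ...]] = {
    1: (),
    2: ("age", "sex", "race"),
    3: (
        "age",
        "sex",
        "race",
        "bmi_kg_m2",
        "education",
        "smoking_binary",
        "drinking_binary",
        "diabetes",
        "hypertension",
        "hyperlipidemia",
    ),
}

#: reference levels for categorical covariates
REFERENCE_LEVELS = {
    "sex": "female",
    "race": "Non-Hispanic White",
    "education": "Less than 9th grade",
}

#: covariates made redundant by a given stratifier in subgroup analysis
_STRATIFIER_COVARIATES = {
    "sex": ("sex",),
    "age_group": ("age",),
    "bmi_group": ("bmi_kg_m2",),
    "hypertension": ("hypertension",),
    "diabetes": ("diabetes",),
    "hyperlipidemia": ("hyperlipidemia",),
}

OUTCOME_COLUMNS = {"sua": "sua_umol_l", "hyperuricemia": "hyperuricemia"}


@dataclass(frozen=True)
class ModelSpec:
    """Which regression to run: outcome, exposure coding, covariate ladder."""

    model_id: int = 1  # 1 | 2 | 3
    outcome: str = "sua"  # 'sua' | 'hyperuricemia'
    exposure: str = "lnobs_continuous"  # 'lnobs_continuous' | 'lnobs_quartile'
    weights: str | None = None  # optional frequency-weight column

    def __post_init__(self):
        if self.model_id not in MODEL_COVARIATES:
            raise ConfigurationError(f"model_id must be 1, 2 or 3, got {self.model_id}")
        if self.outcome not in OUTCOME_COLUMNS:
            raise ConfigurationError(f"unknown outcome {self.outcome!r}")
        if self.exposure not in ("lnobs_continuous", "lnobs_quartile"):
            raise ConfigurationError(f"unknown exposure {self.exposure!r}")

    @property
    def covariates(self) -> tuple[str, ...]:
        return MODEL_COVARIATES[self.model_id]


@dataclass(frozen=True)
class AssociationResult:
    """One effect estimate: β (µmol/L per unit exposure) or OR, with Wald 95% CI."""

    term: str
    estimate: float
    ci_low: float
    ci_high: float
    p_value: float
    n_used: int
    measure: str = "beta"  # 'beta' | 'or'
    is_reference: bool = False


@dataclass
class SubgroupResult:
    """Per-stratum refits plus an interaction p-value from the pooled model."""

    stratifier: str
    strata: dict[str, list[AssociationResult]]
    p_interaction: float
    skipped: list[str] = field(default_factory=list)


def _covariate_term(name: str) -> str:
    if name in REFERENCE_LEVELS:
        return f"C({name}, Treatment('{REFERENCE_LEVELS[name]}'))"
    if name in ("smoking_binary", "drinking_binary", "diabetes", "hypertension", "hyperlipidemia"):
        return f"C({name}, Treatment('no'))"
    return name  # continuous: age, bmi_kg_m2


def _exposure_term(spec_exposure: str) -> str:
    if spec_exposure == "lnobs_continuous":
        return "ln_obs"
    return "C(obs_quartile, Treatment('Q1'))"


def _build_formula(outcome_col: str, exposure: str, covariates: Sequence[str]) -> str:
    terms = [_exposure_term(exposure)] + [_covariate_term(c) for c in covariates]
    return f"{outcome_col} ~ " + " + ".join(terms)


def _check_rank(model) -> None:
    exog = np.asarray(model.exog, dtype=float)
    rank = np.linalg.matrix_rank(exog)
    if rank < exog.shape[1]:
        # identify columns loading on the null space
        _, s, vt = np.linalg.svd(exog, full_matrices=False)
        tol = s.max() * max(exog.shape) * np.finfo(float).eps
        null_vecs = vt[s < tol]
        involved = np.any(np.abs(null_vecs) > 1e-8, axis=0)
        names = [n for n, m in zip(model.exog_names, involved) if m]
        raise SingularDesignError(names or model.exog_names)


def _term_label(name: str) -> str:
    # "C(obs_quartile, Treatment('Q1'))[T.Q2]" -> "Q2"; "ln_obs" unchanged
    if "[T." in name:
        return name.split("[T.")[1].rstrip("]")
    return name


def _extract(res, exposure: str, measure: str) -> list[AssociationResult]:
    params = res.params
    conf = res.conf_int()
    pvals = res.pvalues
    n_used = int(res.nobs)
    results: list[AssociationResult] = []
    if exposure == "lnobs_quartile":
        results.append(
            AssociationResult(
                term="Q1",
                estimate=1.0 if measure == "or" else 0.0,
                ci_low=np.nan,
                ci_high=np.nan,
                p_value=np.nan,
                n_used=n_used,
                measure=measure,
                is_reference=True,
            )
        )
        wanted = [n for n in params.index if n.startswith("C(obs_quartile")]
    else:
        wanted = ["ln_obs"]
    for name in wanted:
        est, lo, hi = params[name], conf.loc[name, 0], conf.loc[name, 1]
        if measure == "or":
            est, lo, hi = np.exp(est), np.exp(lo), np.exp(hi)
        results.append(
            AssociationResult(
                term=_term_label(name),
                estimate=float(est),
                ci_low=float(lo),
                ci_high=float(hi),
                p_value=float(pvals[name]),
                n_used=n_used,
                measure=measure,
            )
        )
    return results


def _prepare(records: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    df = records.copy()
    if spec.outcome == "hyperuricemia":
        df["hyperuricemia"] = df["hyperuricemia"].astype(int)
        if df["hyperuricemia"].nunique() < 2:
            raise SeparationError("outcome has a single class; logistic fit is undefined")
    return df


def _fit_linear_model(df: pd.DataFrame, formula: str, weights: str | None):
    if weights:
        model = smf.wls(formula, data=df, weights=df[weights])
    else:
        model = smf.ols(formula, data=df)
    _check_rank(model)
    return model.fit()


def fit_linear(records: pd.DataFrame, spec: ModelSpec) -> list[AssociationResult]:
    """Least-squares fit of serum uric acid on lnOBS (continuous or quartile)
    with the spec's covariates; returns exposure-term estimates with large-
    sample 95% CIs."""
    if spec.outcome != "sua":
        raise ConfigurationError("fit_linear requires outcome='sua'")
    df = _prepare(records, spec)
    formula = _build_formula(OUTCOME_COLUMNS["sua"], spec.exposure, spec.covariates)
    res = _fit_linear_model(df, formula, spec.weights)
    return _extract(res, spec.exposure, "beta")


def _fit_logistic_model(df: pd.DataFrame, formula: str, weights: str | None):
    from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

    kwargs = {}
    if weights:
        kwargs["freq_weights"] = df[weights]
    model = smf.glm(formula, data=df, family=sm.families.Binomial(), **kwargs)
    _check_rank(model)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            res = model.fit(maxiter=200)
        except PerfectSeparationError as exc:
            raise SeparationError(f"perfect separation in logistic fit: {exc}") from exc
    for w in caught:
        if issubclass(w.category, PerfectSeparationWarning):
            raise SeparationError(f"perfect separation in logistic fit: {w.message}")
    if not res.converged or np.abs(res.params).max() > 30:
        raise SeparationError(
            "logistic fit did not converge (largest |coef| "
            f"{np.abs(res.params).max():.2f}); check for separation"
        )
    return res


def fit_logistic(records: pd.DataFrame, spec: ModelSpec) -> list[AssociationResult]:
    """Maximum-likelihood logistic fit of hyperuricemia on lnOBS; ORs are
    exponentiated coefficients with Wald 95% CIs."""
    if spec.outcome != "hyperuricemia":
        raise ConfigurationError("fit_logistic requires outcome='hyperuricemia'")
    df = _prepare(records, spec)
    formula = _build_formula("hyperuricemia", spec.exposure, spec.covariates)
    res = _fit_logistic_model(df, formula, spec.weights)
    return _extract(res, spec.exposure, "or")


def crude_quartile_or(
    cases: Sequence[int],
    noncases: Sequence[int],
    labels: Sequence[str] = ("Q1", "Q2", "Q3", "Q4"),
) -> list[AssociationResult]:
    """Closed-form crude odds ratios per quartile versus the first.

    OR_k = (cases_k · noncases_1) / (noncases_k · cases_1); the 95% CI uses
    the log-OR normal approximation with SE = sqrt(sum of reciprocal cells).
    A zero cell raises (apply a continuity correction upstream if wanted).
    """
    cases = list(cases)
    noncases = list(noncases)
    if len(cases) != len(noncases) or len(cases) != len(labels):
        raise ConfigurationError("cases, noncases and labels must have equal length")
    if any(c <= 0 for c in cases + noncases):
        raise ZeroCellError(
            "all contingency cells must be positive; apply a continuity "
            "correction explicitly if a cell is zero"
        )
    a1, b1 = cases[0], noncases[0]
    n_used = int(sum(cases) + sum(noncases))
    out = [
        AssociationResult(
            term=labels[0],
            estimate=1.0,
            ci_low=np.nan,
            ci_high=np.nan,
            p_value=np.nan,
            n_used=n_used,
            measure="or",
            is_reference=True,
        )
    ]
    for label, a, b in zip(labels[1:], cases[1:], noncases[1:]):
        log_or = np.log(a * b1 / (b * a1))
        se = np.sqrt(1 / a + 1 / b + 1 / a1 + 1 / b1)
        z = log_or / se
        out.append(
            AssociationResult(
                term=label,
                estimate=float(np.exp(log_or)),
                ci_low=float(np.exp(log_or - 1.959963984540054 * se)),
                ci_high=float(np.exp(log_or + 1.959963984540054 * se)),
                p_value=float(2 * stats.norm.sf(abs(z))),
                n_used=n_used,
                measure="or",
            )
        )
    return out


def _interaction_p(res, stratifier: str) -> float:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        table = res.wald_test_terms().table
    inter_rows = [i for i in table.index if ":" in i and stratifier in i]
    if not inter_rows:
        raise ConfigurationError("no interaction term found in pooled model")
    pcol = [c for c in table.columns if "pvalue" in str(c) or str(c).startswith("P>")][0]
    return float(table.loc[inter_rows[0], pcol])


def subgroup_analysis(
    records: pd.DataFrame,
    spec: ModelSpec,
    stratifier: str,
    min_n: int = 50,
    test: str = "wald",
) -> SubgroupResult:
    """Stratified refits plus an effect-modification test.

    The spec is refitted within each stratum (covariates redundant with the
    stratifier removed); ``p_interaction`` comes from a Wald test of the
    exposure x stratifier product term in the pooled model (or a likelihood-
    ratio test with ``test='lrt'``).  Strata with fewer than ``min_n`` records
    or a single outcome class are skipped and recorded.
    """
    levels = [lv for lv in pd.unique(records[stratifier]) if pd.notna(lv)]
    if len(levels) < 2:
        raise ValueError(f"stratifier {stratifier!r} has fewer than 2 levels")
    drop = set(_STRATIFIER_COVARIATES.get(stratifier, (stratifier,)))
    covariates = tuple(c for c in spec.covariates if c not in drop)
    outcome_col = OUTCOME_COLUMNS[spec.outcome]
    df = _prepare(records, spec)

    strata: dict[str, list[AssociationResult]] = {}
    skipped: list[str] = []
    formula_stratum = _build_formula(outcome_col, spec.exposure, covariates)
    for level in levels:
        sub = df[df[stratifier] == level]
        if len(sub) < min_n or (
            spec.outcome == "hyperuricemia" and sub["hyperuricemia"].nunique() < 2
        ):
            warnings.warn(f"stratum {stratifier}={level!r} skipped (too small or degenerate)")
            skipped.append(str(level))
            continue
        if spec.outcome == "sua":
            res = _fit_linear_model(sub, formula_stratum, spec.weights)
            strata[str(level)] = _extract(res, spec.exposure, "beta")
        else:
            res = _fit_logistic_model(sub, formula_stratum, spec.weights)
            strata[str(level)] = _extract(res, spec.exposure, "or")

    pooled_terms = [f"{_exposure_term(spec.exposure)} * C({stratifier})"] + [
        _covariate_term(c) for c in covariates
    ]
    pooled_formula = f"{outcome_col} ~ " + " + ".join(pooled_terms)
    if spec.outcome == "sua":
        pooled = _fit_linear_model(df, pooled_formula, spec.weights)
    else:
        pooled = _fit_logistic_model(df, pooled_formula, spec.weights)

    if test == "wald":
        p_int = _interaction_p(pooled, stratifier)
    elif test == "lrt":
        reduced_terms = [
            _exposure_term(spec.exposure),
            f"C({stratifier})",
        ] + [_covariate_term(c) for c in covariates]
        reduced_formula = f"{outcome_col} ~ " + " + ".join(reduced_terms)
        if spec.outcome == "sua":
            reduced = _fit_linear_model(df, reduced_formula, spec.weights)
        else:
            reduced = _fit_logistic_model(df, reduced_formula, spec.weights)
        lr = 2 * (pooled.llf - reduced.llf)
        df_diff = pooled.df_model - reduced.df_model
        p_int = float(stats.chi2.sf(lr, df_diff))
    else:
        raise ConfigurationError(f"unknown interaction test {test!r}")

    return SubgroupResult(
        stratifier=stratifier, strata=strata, p_interaction=p_int, skipped=skipped
    )


class _AssociationBase(BaseEstimator):
    """Shared fit machinery for the linear and logistic association estimators."""

    _outcome: str = ""

    def __init__(self, model=1, exposure="continuous", weights=None):
        self.model = model
        self.exposure = exposure
        self.weights = weights

    def _spec(self) -> ModelSpec:
        exposure = (
            "lnobs_continuous" if self.exposure in ("continuous", "lnobs_continuous")
            else "lnobs_quartile"
        )
        return ModelSpec(
            model_id=self.model, outcome=self._outcome, exposure=exposure, weights=self.weights
        )

    def fit(self, X: pd.DataFrame, y=None):
        spec = self._spec()
        if self._outcome == "sua":
            self.results_ = fit_linear(X, spec)
        else:
            self.results_ = fit_logistic(X, spec)
        self.spec_ = spec
        self.n_used_ = self.results_[0].n_used if self.results_ else 0
        return self

    def summary_frame(self) -> pd.DataFrame:
        if not hasattr(self, "results_"):
            raise ConfigurationError("estimator is not fitted; call fit first")
        return pd.DataFrame(
            [
                {
                    "term": r.term,
                    "estimate": r.estimate,
                    "ci_low": r.ci_low,
                    "ci_high": r.ci_high,
                    "p_value": r.p_value,
                    "n_used": r.n_used,
                    "measure": r.measure,
                    "is_reference": r.is_reference,
                }
                for r in self.results_
            ]
        )


class LinearAssociation(_AssociationBase):
    """Least-squares association of serum uric acid (µmol/L) with lnOBS.

    Parameters: ``model`` (1/2/3 covariate ladder), ``exposure``
    ('continuous' or 'quartile'), ``weights`` (optional frequency-weight
    column).  After :meth:`fit`, ``results_`` holds exposure-term
    :class:`AssociationResult` rows (β scale)."""

    _outcome = "sua"


class LogisticAssociation(_AssociationBase):
    """Logistic association of hyperuricemia with lnOBS; ``results_`` on the
    odds-ratio scale."""

    _outcome = "hyperuricemia"
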