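"""Regression battery, survival analysis, multiplicity and meta-analysis.

Relates prematurity (as WHO category dummies vs term, or standardised
continuous gestation), a monogenic diagnosis, and covariates to binary,
continuous and count phenotypes; Kaplan-Meier / log-rank and Cox models
for milestone attainment; Bonferroni ledgers; and fixed-effect
inverse-variance-weighted (IVW) meta-analysis across cohorts.

Model fitting goes through statsmodels (logistic / OLS / negative
binomial) and lifelines (Kaplan-Meier, log-rank, Cox with Efron ties).
Non-convergence and separation are flagged on the result, never
silently dropped.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .config import CATEGORIES
from .exceptions import DataError, DegenerateModelError

logger = logging.getLogger(__name__)

PRETERM_CATEGORIES = ("moderate", "very", "extreme")


@dataclass
class ModelSpec:
    """Declarative description of one phenotype regression.

    ``family`` is ``binary`` (logistic), ``continuous`` (linear) or
    ``count`` (negative binomial with ML dispersion, Poisson fallback).
    Antenatal outcomes adjust for maternal age; all other outcomes for
    proband age at assessment and sex. ``gestation`` chooses category
    dummies vs term ("categorical") or standardised continuous weeks
    ("continuous").
    """

    outcome: str
    family: str
    antenatal: bool = False
    gestation: str = "categorical"
    diagnosis_interaction: bool = False
    extra_covariate: str | None = None

    def covariates(self) -> list[str]:
        if self.antenatal:
            cov = ["maternal_age_years"]
        else:
            cov = ["age_at_assessment_years", "sex"]
        if self.extra_covariate:
            cov.append(self.extra_covariate)
        return cov


@dataclass
class AssocResult:
    """One model term: estimate (log-odds / mean difference / log IRR /
    log HR), its SE, p, and sample size."""

    term: str
    estimate: float
    se: float
    p: float
    n: int
    family: str
    converged: bool = True
    note: str = ""

    @property
    def ratio(self) -> float:
        """exp(estimate): OR, IRR or HR depending on family."""
        return float(np.exp(self.estimate))


@dataclass
class MetaResult:
    term: str
    estimate: float
    se: float
    p: float
    inputs: list[AssocResult] = field(default_factory=list)


def standardise_gestation(values, cohorts=None) -> pd.Series:
    """Standardise gestational weeks to mean 0, SD 1 within each cohort."""
    v = pd.Series(values, dtype=float)
    groups = pd.Series(cohorts) if cohorts is not None else pd.Series("all", index=v.index)

    def _z(x: pd.Series) -> pd.Series:
        sd = x.std(ddof=1)
        if not sd > 0:
            raise DataError("gestational duration constant within a cohort")
        return (x - x.mean()) / sd

    return v.groupby(groups.values).transform(_z)


def bonferroni_threshold(n_tests: int, alpha: float = 0.05) -> float:
    """alpha / n_tests."""
    if n_tests < 1:
        raise DataError("n_tests must be >= 1")
    return alpha / n_tests


def ivw_meta(results: list[AssocResult]) -> MetaResult:
    """Fixed-effect inverse-variance-weighted pooling of one term.

    pooled beta = sum(w*b)/sum(w) with w = 1/SE^2; pooled SE =
    1/sqrt(sum w); two-sided normal p. Non-converged inputs are dropped.
    """
    usable = [r for r in results if r.converged and np.isfinite(r.se) and r.se > 0]
    if not usable:
        raise DataError("no converged inputs with positive SE for IVW pooling")
    w = np.array([1.0 / r.se**2 for r in usable])
    b = np.array([r.estimate for r in usable])
    est = float(np.sum(w * b) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    z = est / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return MetaResult(term=usable[0].term, estimate=est, se=se, p=p, inputs=usable)


def _prematurity_design(data: pd.DataFrame, spec: ModelSpec) -> tuple[pd.DataFrame, list[str]]:
    X = pd.DataFrame(index=data.index)
    if spec.gestation == "continuous":
        X["gestation_z"] = standardise_gestation(
            data["gestational_weeks"], data.get("cohort_label")
        )
        prem_terms = ["gestation_z"]
    else:
        for cat in PRETERM_CATEGORIES:
            X[f"prematurity[{cat}]"] = (
                (data["prematurity_category"] == cat).astype(float)
            )
        prem_terms = [f"prematurity[{c}]" for c in PRETERM_CATEGORIES]
    for cov in spec.covariates():
        if cov not in data.columns:
            raise DataError(f"covariate {cov!r} missing from data")
        X[cov] = data[cov].astype(float)
    if spec.diagnosis_interaction:
        X["diagnosed"] = data["diagnosed"].astype(float)
        for t in prem_terms:
            X[f"{t}:diagnosed"] = X[t] * X["diagnosed"]
    return X, prem_terms


def _fit(y: np.ndarray, X: pd.DataFrame, family: str):
    Xc = sm.add_constant(X, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if family == "binary":
            res = sm.GLM(y, Xc, family=sm.families.Binomial()).fit(maxiter=100)
            converged = bool(getattr(res, "converged", True))
            note = ""
            if np.abs(res.params).max() > 15:
                converged, note = False, "possible separation (diverging coefficient)"
            return res, converged, note, family
        if family == "continuous":
            res = sm.OLS(y, Xc).fit()
            return res, True, "", family
        if family == "count":
            try:
                res = sm.NegativeBinomial(y, Xc).fit(disp=False, maxiter=200)
                alpha = float(res.params.get("alpha", np.nan))
                conv = bool(res.mle_retvals.get("converged", True))
                if conv and np.isfinite(alpha) and alpha > 1e-6:
                    return res, True, "", family
            except Exception:  # noqa: BLE001 - fall through to Poisson
                pass
            logger.warning("negative-binomial dispersion pinned at zero; Poisson fallback")
            res = sm.GLM(y, Xc, family=sm.families.Poisson()).fit()
            return res, True, "dispersion ~ 0; Poisson fallback", "count(poisson)"
    raise DataError(f"unknown model family {family!r}")


def _collect(res, converged: bool, note: str, family: str, n: int,
             X: pd.DataFrame) -> list[AssocResult]:
    out = []
    for term in X.columns:
        if term == "alpha":
            continue
        est = float(res.params[term])
        se = float(res.bse[term])
        p = float(res.pvalues[term])
        term_note = note
        term_conv = converged
        if not np.isfinite(se) or se <= 0 or not np.isfinite(est):
            term_conv = False
            term_note = note or "inestimable term"
        out.append(
            AssocResult(term=term, estimate=est, se=se, p=p, n=n,
                        family=family, converged=term_conv, note=term_note)
        )
    return out


def fit_phenotype_model(data: pd.DataFrame, spec: ModelSpec) -> list[AssocResult]:
    """Fit one phenotype regression and return a result per model term.

    Logistic for binary outcomes, linear for continuous, negative
    binomial for counts (Poisson fallback when the ML dispersion pins at
    zero). A constant outcome raises; an empty prematurity category cell
    yields a flagged, non-converged result for that dummy.
    """
    if spec.outcome not in data.columns:
        raise DataError(f"outcome {spec.outcome!r} missing from data")
    work = data.dropna(subset=[spec.outcome]).copy()
    y = work[spec.outcome].to_numpy(float)
    if len(work) == 0 or np.all(y == y[0]):
        raise DegenerateModelError(f"outcome {spec.outcome!r} is constant or empty")
    if spec.family == "binary" and len(np.unique(y)) != 2:
        raise DataError(f"binary outcome {spec.outcome!r} must have 2 levels")
    X, prem_terms = _prematurity_design(work, spec)

    # empty category cells make the dummy inestimable; drop and flag
    flagged: list[AssocResult] = []
    for t in list(X.columns):
        if X[t].abs().sum() == 0:
            X = X.drop(columns=[t])
            flagged.append(
                AssocResult(term=t, estimate=np.nan, se=np.nan, p=np.nan,
                            n=len(work), family=spec.family, converged=False,
                            note="empty cell; term inestimable")
            )
    if spec.diagnosis_interaction and "diagnosed" not in X.columns:
        flagged.append(
            AssocResult(term="diagnosed", estimate=np.nan, se=np.nan, p=np.nan,
                        n=len(work), family=spec.family, converged=False,
                        note="no diagnosed probands; interaction inestimable")
        )
    res, converged, note, fam = _fit(y, X, spec.family)
    return _collect(res, converged, note, fam, len(work), X) + flagged


def fit_interaction_model(data: pd.DataFrame, spec: ModelSpec) -> list[AssocResult]:
    """The extended model with diagnosis main effect and prematurity x
    diagnosis interaction terms."""
    spec2 = ModelSpec(
        outcome=spec.outcome, family=spec.family, antenatal=spec.antenatal,
        gestation=spec.gestation, diagnosis_interaction=True,
        extra_covariate=spec.extra_covariate,
    )
    return fit_phenotype_model(data, spec2)


def km_logrank(times, events, groups):
    """Kaplan-Meier curves per group plus the k-group log-rank test.

    Returns ``(curves, statistic, p)`` where ``curves`` maps group label
    to a survival-function DataFrame. Raises on data with no events.
    """
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import multivariate_logrank_test

    times = np.asarray(times, float)
    events = np.asarray(events, int)
    groups = np.asarray(groups)
    if events.sum() == 0:
        raise DataError("no events: log-rank test undefined")
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise DataError("log-rank requires >= 2 groups")
    curves = {}
    for g in labels:
        mask = groups == g
        kmf = KaplanMeierFitter()
        kmf.fit(times[mask], events[mask], label=str(g))
        curves[g] = kmf.survival_function_
    res = multivariate_logrank_test(times, groups, events)
    return curves, float(res.test_statistic), float(res.p_value)


def cox_milestone_model(
    data: pd.DataFrame,
    time_col: str,
    event_col: str,
    diagnosis_interaction: bool = True,
) -> list[AssocResult]:
    """Cox proportional-hazards model for milestone attainment.

    Prematurity-category dummies vs term, adjusted for proband age at
    assessment, sex, diagnostic status, and (optionally) the prematurity
    x diagnosis interaction. Efron handling of tied event times.
    Estimates are log hazard ratios (``.ratio`` gives the HR).
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    spec = ModelSpec(outcome=time_col, family="continuous",
                     diagnosis_interaction=diagnosis_interaction)
    X, _ = _prematurity_design(data, spec)
    flagged: list[AssocResult] = []
    for c in list(X.columns):
        if X[c].nunique() <= 1:
            if c.startswith("prematurity[") or ":diagnosed" in c or c == "diagnosed":
                # empty category cell: term inestimable, flagged not dropped
                X = X.drop(columns=[c])
                flagged.append(AssocResult(
                    term=c, estimate=np.nan, se=np.nan, p=np.nan, n=len(data),
                    family="cox", converged=False,
                    note="empty cell; term inestimable"))
            else:
                raise DataError(f"constant covariate {c!r} in Cox design")
    df = X.copy()
    df["_T"] = data[time_col].to_numpy(float)
    df["_E"] = data[event_col].to_numpy(int)
    if (df["_T"] <= 0).any():
        raise DataError("milestone times must be > 0")
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="_T", event_col="_E")
    except ConvergenceError as exc:
        return [
            AssocResult(term=t, estimate=np.nan, se=np.nan, p=np.nan, n=len(df),
                        family="cox", converged=False, note=f"non-convergence: {exc}")
            for t in X.columns
        ] + flagged
    out = []
    for term in X.columns:
        est = float(cph.params_[term])
        se = float(cph.standard_errors_[term])
        conv, note = True, ""
        if not np.isfinite(se) or se <= 0 or abs(est) > 15:
            conv, note = False, "possible separation / non-convergence"
        out.append(
            AssocResult(term=term, estimate=est, se=se,
                        p=float(cph.summary.loc[term, "p"]), n=len(df),
                        family="cox", converged=conv, note=note)
        )
    return out + flagged


def results_to_frame(results, **extra) -> pd.DataFrame:
    """Flatten AssocResult/MetaResult lists to a tidy table."""
    rows = []
    for r in results:
        row = {
            "term": r.term,
            "estimate": r.estimate,
            "se": r.se,
            "p": r.p,
            "n": getattr(r, "n", np.nan),
            "family": getattr(r, "family", "meta"),
            "converged": getattr(r, "converged", True),
            "note": getattr(r, "note", ""),
        }
        row.update(extra)
        rows.append(row)
    return pd.DataFrame(rows)
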