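"""Regression battery, IVW meta-analysis, multiplicity, survival models."""

import numpy as np
import pandas as pd
import pytest

from pretermdd import DataError, DegenerateModelError, MilestoneParams, SimConfig
from pretermdd import associations as A
from pretermdd import simulate as sim


def _with_binary_outcome(cohort, log_or_by_cat=None, log_or_diag=0.0,
                         base_logit=-1.0, seed=0):
    rng = np.random.default_rng(seed)
    c = cohort.copy()
    eta = np.full(len(c), base_logit)
    if log_or_by_cat:
        for cat, b in log_or_by_cat.items():
            eta = eta + b * (c["prematurity_category"] == cat).to_numpy()
    eta = eta + log_or_diag * c["diagnosed"].to_numpy()
    p = 1 / (1 + np.exp(-eta))
    c["y"] = (rng.random(len(c)) < p).astype(int)
    return c


# --- phenotype models --------------------------------------------------------

def test_null_prematurity_coefficients_are_null():
    cfg = SimConfig(n_probands=5000, seed=31)
    c = _with_binary_outcome(sim.simulate_cohort(cfg), seed=31)
    res = A.fit_phenotype_model(c, A.ModelSpec(outcome="y", family="binary"))
    for r in res:
        if r.term.startswith("prematurity"):
            assert r.converged and abs(r.estimate) < 4 * r.se, r


def test_binary_or_recovery_moderate_prematurity():
    """An injected OR of 2 for moderate prematurity is recovered at
    n = 10,000."""
    cfg = SimConfig(n_probands=10_000, seed=32)
    c = _with_binary_outcome(sim.simulate_cohort(cfg),
                             log_or_by_cat={"moderate": np.log(2)}, seed=32)
    res = A.fit_phenotype_model(c, A.ModelSpec(outcome="y", family="binary"))
    r = next(x for x in res if x.term == "prematurity[moderate]")
    assert 1.7 < r.ratio < 2.35


def test_constant_outcome_is_degenerate(small_cohort):
    c = small_cohort.copy()
    c["y"] = 0
    with pytest.raises(DegenerateModelError):
        A.fit_phenotype_model(c, A.ModelSpec(outcome="y", family="binary"))


def test_continuous_and_count_families(small_cohort):
    rng = np.random.default_rng(3)
    c = small_cohort.copy()
    c["cont"] = rng.normal(size=len(c)) + 0.1 * c["sex"]
    mu = np.exp(0.5 + 0.3 * (c["prematurity_category"] != "term"))
    c["cnt"] = rng.negative_binomial(2, 2 / (2 + mu))
    res_c = A.fit_phenotype_model(c, A.ModelSpec(outcome="cont", family="continuous"))
    assert all(r.converged for r in res_c)
    res_n = A.fit_phenotype_model(c, A.ModelSpec(outcome="cnt", family="count"))
    r = next(x for x in res_n if x.term == "prematurity[moderate]")
    assert r.converged and r.se > 0


def test_interaction_null_when_effects_additive():
    cfg = SimConfig(n_probands=10_000, seed=33)
    c = _with_binary_outcome(
        sim.simulate_cohort(cfg),
        log_or_by_cat={"moderate": 0.4}, log_or_diag=np.log(1.5), seed=33,
    )
    res = A.fit_interaction_model(c, A.ModelSpec(outcome="y", family="binary"))
    diag = next(r for r in res if r.term == "diagnosed")
    assert 1.27 < diag.ratio < 1.77  # main-effect recovery
    for r in res:
        if ":diagnosed" in r.term and r.converged:
            assert abs(r.estimate) < 4 * r.se, r


def test_interaction_flagged_without_diagnosed_probands(small_cohort):
    c = _with_binary_outcome(small_cohort, seed=1)
    c["diagnosed"] = 0
    res = A.fit_interaction_model(c, A.ModelSpec(outcome="y", family="binary"))
    flagged = [r for r in res if not r.converged]
    assert flagged and any("diagnosed" in r.term for r in flagged)


def test_empty_category_cell_flagged_not_dropped(small_cohort):
    c = _with_binary_outcome(small_cohort, seed=2)
    c = c[c["prematurity_category"] != "extreme"]
    res = A.fit_phenotype_model(c, A.ModelSpec(outcome="y", family="binary"))
    r = next(x for x in res if x.term == "prematurity[extreme]")
    assert not r.converged and np.isnan(r.estimate) and "empty cell" in r.note


# --- gestation standardisation ----------------------------------------------

def test_standardise_gestation_definition_and_idempotence():
    z = A.standardise_gestation([36.0, 38.0, 40.0])
    assert z.mean() == pytest.approx(0.0, abs=1e-12)
    assert z.std(ddof=1) == pytest.approx(1.0)
    z2 = A.standardise_gestation(z)
    assert np.allclose(z, z2, atol=1e-10)


def test_standardise_gestation_per_cohort():
    vals = [30.0, 40.0, 35.0, 20.0, 30.0, 25.0]
    cohorts = ["a", "a", "a", "b", "b", "b"]
    z = A.standardise_gestation(vals, cohorts)
    assert z[:3].mean() == pytest.approx(0, abs=1e-12)
    assert z[3:].mean() == pytest.approx(0, abs=1e-12)
    assert z.mean() == pytest.approx(0, abs=1e-12)
    with pytest.raises(DataError):
        A.standardise_gestation([30.0, 30.0])


def test_continuous_gestation_model_runs(small_cohort):
    c = _with_binary_outcome(small_cohort, seed=5)
    res = A.fit_phenotype_model(
        c, A.ModelSpec(outcome="y", family="binary", gestation="continuous")
    )
    assert any(r.term == "gestation_z" for r in res)


# --- IVW meta-analysis -------------------------------------------------------

def _ar(beta, se):
    return A.AssocResult("t", beta, se, 0.5, 100, "binary")


def test_ivw_single_study_passthrough():
    m = A.ivw_meta([_ar(0.25, 0.1)])
    assert m.estimate == pytest.approx(0.25) and m.se == pytest.approx(0.1)


def test_ivw_equal_weights_average():
    assert A.ivw_meta([_ar(0.1, 0.05), _ar(0.3, 0.05)]).estimate == pytest.approx(0.2)


def test_ivw_closed_form():
    m = A.ivw_meta([_ar(0.1, 0.05), _ar(0.3, 0.1)])
    assert m.estimate == pytest.approx(0.14, abs=1e-12)
    assert m.se == pytest.approx(1 / np.sqrt(500), abs=1e-6)  # 0.04472


@pytest.mark.parametrize("seed", range(5))
def test_ivw_pooled_se_never_exceeds_smallest_input(seed):
    rng = np.random.default_rng(seed)
    inputs = [_ar(rng.normal(), float(rng.uniform(0.01, 1))) for _ in range(4)]
    m = A.ivw_meta(inputs)
    assert m.se <= min(r.se for r in inputs) + 1e-15


def test_ivw_requires_converged_input():
    bad = A.AssocResult("t", 0.1, np.nan, 0.5, 10, "binary", converged=False)
    with pytest.raises(DataError):
        A.ivw_meta([bad])


# --- Bonferroni ledgers ------------------------------------------------------

def test_bonferroni_printed_thresholds():
    assert A.bonferroni_threshold(522) == pytest.approx(9.58e-5, rel=5e-3)
    assert A.bonferroni_threshold(16) == pytest.approx(3.13e-3, rel=5e-3)
    assert A.bonferroni_threshold(1) == 0.05
    with pytest.raises(DataError):
        A.bonferroni_threshold(0)


# --- survival ----------------------------------------------------------------

def manual_logrank_2group(times_a, times_b):
    """Hand-computed 2-group log-rank chi-square (no censoring):
    sum of hypergeometric observed-minus-expected increments."""
    events = sorted(set(times_a) | set(times_b))
    na, nb = len(times_a), len(times_b)
    OE, V = 0.0, 0.0
    for t in events:
        da = times_a.count(t)
        db = times_b.count(t)
        d, n = da + db, na + nb
        if n > 1:
            OE += da - d * na / n
            V += d * (na / n) * (1 - na / n) * (n - d) / (n - 1)
        na -= da
        nb -= db
    return OE * OE / V


def test_logrank_identical_groups_is_null():
    t = [1.0, 2.0, 3.0, 4.0]
    times = t + t
    groups = ["a"] * 4 + ["b"] * 4
    _, stat, p = A.km_logrank(times, [1] * 8, groups)
    assert stat == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)


def test_logrank_matches_hand_computed_oracle():
    ta, tb = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
    _, stat, _ = A.km_logrank(ta + tb, [1] * 6, ["a"] * 3 + ["b"] * 3)
    assert stat == pytest.approx(manual_logrank_2group(ta, tb), rel=1e-9)


def test_km_no_censoring_equals_empirical_survival():
    times = [2.0, 4.0, 4.0, 7.0, 9.0]
    curves, _, _ = A.km_logrank(times + [1.0, 1.0], [1] * 7,
                                ["a"] * 5 + ["b"] * 2)
    surv = curves["a"].iloc[:, 0]
    emp = [np.mean(np.array(times) > t) for t in surv.index]
    assert np.allclose(surv.to_numpy(), emp)


def test_cox_recovers_hazard_ratio():
    """Diagnosis log-HR of log(0.5) injected into milestone times is
    recovered by the Cox model within [0.4, 0.6] at n=5,000."""
    cfg = SimConfig(
        n_probands=5000, seed=35,
        milestone_params=MilestoneParams(log_hr_diagnosis=np.log(0.5)),
    )
    c = sim.simulate_cohort(cfg)
    m = sim.simulate_milestones(c, cfg)
    res = A.cox_milestone_model(m, "walking_months", "walking_event")
    r = next(x for x in res if x.term == "diagnosed")
    assert 0.4 < r.ratio < 0.6


def test_cox_null_covariate_ci_coverage():
    """A zero-effect covariate's 95% CI covers HR=1 in >= 93/100
    simulated datasets."""
    cover = 0
    for rep in range(100):
        cfg = SimConfig(n_probands=300, seed=1000 + rep)
        c = sim.simulate_cohort(cfg)
        m = sim.simulate_milestones(c, cfg)
        # drop sparse categories so every replicate is estimable
        m = m[m["prematurity_category"].isin(["term", "moderate"])]
        res = A.cox_milestone_model(m, "sitting_months", "sitting_event",
                                    diagnosis_interaction=False)
        r = next(x for x in res if x.term == "sex")
        if r.converged and abs(r.estimate) < 1.96 * r.se:
            cover += 1
    assert cover >= 93


def test_cox_degenerate_events_flagged():
    n = 60
    df = pd.DataFrame({
        "prematurity_category": ["moderate"] * 30 + ["term"] * 30,
        "age_at_assessment_years": np.linspace(1, 10, n),
        "sex": [0, 1] * 30,
        "diagnosed": [1] * 30 + [0] * 30,
        "t": [0.001] * 30 + [50.0] * 30,
        "e": [1] * 30 + [0] * 30,
    })
    res = A.cox_milestone_model(df, "t", "e")
    assert any(not r.converged for r in res)


def test_cox_constant_covariate_rejected(small_cohort):
    cfg = SimConfig(n_probands=len(small_cohort), seed=2)
    m = sim.simulate_milestones(small_cohort, cfg)
    m["sex"] = 1
    with pytest.raises(DataError):
        A.cox_milestone_model(m, "walking_months", "walking_event")
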