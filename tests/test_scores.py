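"""Polygenic scoring, RVBS filtering, RINT, score regressions, trio model."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pretermdd import DataError, SimConfig, TrioParams
from pretermdd import scores as S
from pretermdd import simulate as sim


def _weights(ids, w, ea="A", oa="G"):
    return pd.DataFrame({"variant_id": ids, "effect_allele": ea,
                         "other_allele": oa, "weight": w})


# --- polygenic scores --------------------------------------------------------

def test_pgs_single_variant_raw():
    d = pd.DataFrame({"v1": [2.0]}, index=["i1"])
    s = S.compute_pgs(d, _weights(["v1"], [0.5]), standardise=False)
    assert s["i1"] == pytest.approx(1.0)


def test_pgs_zero_weights_zero_scores():
    d = pd.DataFrame({"v1": [2.0, 1.0], "v2": [0.0, 2.0]}, index=["a", "b"])
    s = S.compute_pgs(d, _weights(["v1", "v2"], [0.0, 0.0]), standardise=False)
    assert (s == 0).all()


def test_pgs_matches_per_individual_loop():
    rng = np.random.default_rng(8)
    ids = [f"v{i}" for i in range(100)]
    d = pd.DataFrame(rng.integers(0, 3, size=(30, 100)).astype(float),
                     columns=ids, index=[f"i{k}" for k in range(30)])
    w = rng.normal(size=100)
    s = S.compute_pgs(d, _weights(ids, w), standardise=False)
    for k in range(0, 30, 7):  # brute-force loop oracle
        expected = sum(d.iloc[k, j] * w[j] for j in range(100))
        assert s.iloc[k] == pytest.approx(expected)


def test_pgs_allele_orientation():
    d = pd.DataFrame({"v1": [2.0], "v2": [0.5], "v3": [1.0]}, index=["i"])
    alleles = pd.DataFrame({"variant_id": ["v1", "v2", "v3"],
                            "a1": ["A", "G", "C"], "a2": ["G", "A", "T"]})
    w = _weights(["v1", "v2", "v3"], [1.0, 1.0, 1.0])
    # v1 aligned (d=2); v2 swapped (2-0.5=1.5); v3 mismatched pair -> dropped
    s = S.compute_pgs(d, w, variant_alleles=alleles, standardise=False)
    assert s["i"] == pytest.approx(2.0 + 1.5)


def test_pgs_missing_imputed_to_twice_frequency():
    d = pd.DataFrame({"v1": [2.0, 0.0, np.nan]}, index=["a", "b", "c"])
    s = S.compute_pgs(d, _weights(["v1"], [1.0]), standardise=False)
    assert s["c"] == pytest.approx(1.0)  # 2 x freq 0.5


def test_pgs_no_overlap_rejected():
    d = pd.DataFrame({"vX": [1.0]}, index=["i"])
    with pytest.raises(DataError):
        S.compute_pgs(d, _weights(["v1"], [1.0]))


def test_pgs_standardised_within_cohort():
    rng = np.random.default_rng(1)
    d = pd.DataFrame({"v1": rng.integers(0, 3, 200).astype(float)})
    s = S.compute_pgs(d, _weights(["v1"], [2.0]),
                      cohorts=["x"] * 100 + ["y"] * 100)
    assert s[:100].mean() == pytest.approx(0, abs=1e-12)
    assert s[100:].std(ddof=0) == pytest.approx(1)


# --- rare-variant burden score ----------------------------------------------

PASSING = {
    "proband_id": "p1", "gene": "G", "consequence": "ptv", "loftee": "HC",
    "mpc": np.nan, "pli": 0.95, "gnomad_max_maf": 0.0, "cohort_maf": 0.0,
    "inherited": True, "autosomal": True, "zygosity": "het",
}


def _variants(*overrides):
    return pd.DataFrame([{**PASSING, **o} for o in overrides])


def test_rvbs_passing_variant_counts():
    assert S.compute_rvbs(_variants({}))["p1"] == 1


@pytest.mark.parametrize("override", [
    {"consequence": "missense", "loftee": "", "mpc": 1.9},  # MPC boundary
    {"pli": 0.9},
    {"gnomad_max_maf": 2e-5},
    {"cohort_maf": 2e-4},
    {"inherited": False},
    {"autosomal": False},
    {"zygosity": "hom"},
    {"loftee": "LC", "mpc": np.nan},  # LC PTV without MPC is not damaging
])
def test_rvbs_single_filter_violation_excluded(override):
    assert S.compute_rvbs(_variants(override))["p1"] == 0


def test_rvbs_mpc_boundary_inclusive():
    v = _variants({"consequence": "missense", "loftee": "", "mpc": 2.0})
    assert S.compute_rvbs(v)["p1"] == 1


def test_rvbs_matches_hand_filter_oracle(small_cohort):
    v = sim.simulate_rare_variants(small_cohort.head(200), n_genes=20, seed=9,
                                   pass_fraction=0.4)
    got = S.compute_rvbs(v, proband_ids=small_cohort.head(200)["proband_id"])
    # independent row-by-row re-application of the published cascade
    manual = {}
    for r in v.itertuples():
        ok = (
            ((r.consequence == "ptv" and r.loftee == "HC")
             or (r.consequence in S.MISSENSE_LIKE and not np.isnan(r.mpc)
                 and r.mpc >= 2)
             or (r.consequence == "ptv" and r.loftee == "LC"
                 and not np.isnan(r.mpc) and r.mpc >= 2))
            and r.pli > 0.9 and r.gnomad_max_maf < 1e-5 and r.cohort_maf < 1e-4
            and r.inherited and r.autosomal and r.zygosity == "het"
        )
        manual[r.proband_id] = manual.get(r.proband_id, 0) + int(ok)
    for pid, k in manual.items():
        assert got[pid] == k


def test_rvbs_monotone_when_variant_relaxed():
    """Making any failing variant pass never decreases a score."""
    for override in ({"pli": 0.5}, {"gnomad_max_maf": 1e-3}, {"inherited": False}):
        failing = _variants(override, {})
        relaxed = _variants({}, {})
        assert (S.compute_rvbs(failing)["p1"]
                <= S.compute_rvbs(relaxed)["p1"])


def test_rvbs_missing_column_rejected():
    with pytest.raises(DataError):
        S.compute_rvbs(_variants({}).drop(columns=["mpc"]))


# --- RINT --------------------------------------------------------------------

def test_rint_examples_and_properties():
    z = S.rint([5.0, 1.0, 3.0])
    assert z[2] == pytest.approx(0.0)  # middle rank of n=3
    assert z[1] == pytest.approx(stats.norm.ppf(0.625 / 3.25), abs=1e-9)
    assert f"{z[1]:.4f}" == "-0.8694"
    rng = np.random.default_rng(0)
    x = rng.normal(size=101)
    zx = S.rint(x)
    assert abs(zx.mean()) < 1e-8
    assert stats.spearmanr(x, zx).statistic == pytest.approx(1.0)
    assert np.allclose(S.rint(-x), -zx)  # rank-reversal symmetry
    out = S.rint([1.0, np.nan, 2.0, 3.0])
    assert np.isnan(out[1]) and out.notna().sum() == 3
    with pytest.raises(DataError):
        S.rint([2.0, 2.0, 2.0])


# --- score regressions -------------------------------------------------------

def _score_data(n, beta, interaction=0.0, seed=0, n_pcs=0):
    rng = np.random.default_rng(seed)
    score = rng.normal(size=n)
    diag = rng.random(n) < 0.4
    y = beta * score + interaction * score * diag + rng.normal(size=n)
    df = pd.DataFrame({"score": score, "diagnosed": diag.astype(int),
                       "sex": rng.integers(0, 2, n), "gd_rint": S.rint(y)})
    for i in range(1, n_pcs + 1):
        df[f"PC{i}"] = rng.normal(size=n)
    return df


def test_gd_regression_null():
    df = _score_data(5000, beta=0.0, seed=20, n_pcs=20)
    r = S.gd_score_regression(df, "score")[0]
    assert r.term == "score" and abs(r.estimate) < 4 * r.se


def test_gd_regression_recovers_effect_scale():
    df = _score_data(10_000, beta=0.05, seed=21, n_pcs=20)
    r = S.gd_score_regression(df, "score")[0]
    assert 0.01 < r.estimate < 0.09


def test_gd_regression_interaction_sign_recovery():
    """A score x diagnosis interaction of -0.05 is sign-correct and
    within 4 SE in >= 90/100 replicates."""
    good = 0
    for rep in range(100):
        df = _score_data(8000, beta=0.05, interaction=-0.05, seed=300 + rep)
        res = S.gd_score_regression(df, "score", n_pcs=0, interaction=True)
        r = next(x for x in res if x.term == "score:diagnosed")
        if r.estimate < 0 and abs(r.estimate - (-0.05)) < 4 * r.se:
            good += 1
    assert good >= 90


def test_gd_regression_strata_and_errors():
    df = _score_data(500, beta=0.0, seed=22, n_pcs=2)
    r_d = S.gd_score_regression(df, "score", stratum="diagnosed", n_pcs=2)
    r_u = S.gd_score_regression(df, "score", stratum="undiagnosed", n_pcs=2)
    assert r_d[0].n + r_u[0].n == len(df)
    df["dup"] = df["score"]
    with pytest.raises(DataError):
        S.gd_score_regression(df.assign(PC1=df["score"]), "score", n_pcs=2)


# --- trio decomposition ------------------------------------------------------

def _trio(n, bd, bp, seed):
    cfg = SimConfig(n_probands=n, seed=seed,
                    trio_params=TrioParams(n_variants=300, beta_direct=bd,
                                           beta_parental=bp))
    t = sim.simulate_trios(sim.simulate_cohort(cfg), cfg)
    return (t.child @ t.weights, t.mother @ t.weights, t.father @ t.weights,
            t.phenotype)


def test_trio_pure_direct_effect():
    c, m, f, y = _trio(3000, bd=0.1, bp=0.0, seed=40)
    res = {r.term: r for r in S.trio_decomposition(c, m, f, y)}
    assert abs(res["child"].estimate - 0.1) < 4 * res["child"].se
    assert abs(res["mother"].estimate) < 4 * res["mother"].se
    assert abs(res["father"].estimate) < 4 * res["father"].se


def test_trio_pure_parental_effect():
    """With only a parental effect the child coefficient is null: the
    marginal child association is confounding, not a direct effect."""
    c, m, f, y = _trio(3000, bd=0.0, bp=0.1, seed=41)
    res = {r.term: r for r in S.trio_decomposition(c, m, f, y)}
    assert abs(res["child"].estimate) < 4 * res["child"].se
    for parent in ("mother", "father"):
        r = res[parent]
        assert abs(r.estimate - 0.1) < 4 * r.se  # recovers the parental signal
        assert r.estimate > 2 * r.se  # and is clearly positive


def test_trio_marginal_attenuation_identity():
    """The marginal child-score slope equals beta_direct + beta_parental
    (transmission makes corr(child, each parent) = 1/2)."""
    import statsmodels.api as sm

    c, m, f, y = _trio(4000, bd=0.1, bp=0.1, seed=42)
    zc = (c - c.mean()) / c.std(ddof=0)
    fit = sm.OLS(np.asarray(y), sm.add_constant(np.asarray(zc))).fit()
    assert abs(fit.params[1] - 0.2) < 4 * fit.bse[1]


def test_trio_null_calibration_over_replicates():
    rejections = 0
    n_terms = 0
    for rep in range(60):
        cfg = SimConfig(n_probands=400, seed=500 + rep,
                        trio_params=TrioParams(n_variants=60))
        t = sim.simulate_trios(sim.simulate_cohort(cfg), cfg)
        res = S.trio_decomposition(t.child @ t.weights, t.mother @ t.weights,
                                   t.father @ t.weights, t.phenotype)
        for r in res:
            n_terms += 1
            rejections += abs(r.estimate) > 1.96 * r.se
    rate = rejections / n_terms
    assert rate <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_terms)


def test_trio_collinear_child_rejected():
    rng = np.random.default_rng(2)
    m = rng.normal(size=200)
    f = rng.normal(size=200)
    child = (m + f) / 2  # no segregation variance
    with pytest.raises(DataError):
        S.trio_decomposition(child, m, f, rng.normal(size=200))
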