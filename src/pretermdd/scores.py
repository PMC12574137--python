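"""Polygenic scores, rare-variant burden scores, and their association
with gestational duration.

A polygenic score (PGS) is the weighted sum of effect-allele dosages
over the variants shared between a scoring file and a dosage table.
The rare-variant burden score (RVBS) counts inherited autosomal
heterozygous variants that are high-confidence protein-truncating, or
missense-like with MPC >= 2, in loss-of-function-intolerant genes
(pLI > 0.9), rare in every gnomAD super-population (MAF < 1e-5) and in
the cohort (MAF < 1e-4).

Gestational duration is rank-based inverse-normal transformed (RINT,
Blom offset 3/8) before regression on a score plus sex and 20 genetic
principal components; the trio model adds maternal and paternal scores
so the child coefficient isolates the direct genetic effect from
parental (non-transmitted / confounding) components.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .associations import AssocResult
from .exceptions import DataError

logger = logging.getLogger(__name__)

RVBS_REQUIRED_COLUMNS = [
    "proband_id", "gene", "consequence", "loftee", "mpc", "pli",
    "gnomad_max_maf", "cohort_maf", "inherited", "autosomal", "zygosity",
]

#: VEP consequences collapsed to the expanded "missense-like" class
#: (missense, stop/start lost, inframe indels, low-confidence LoF).
MISSENSE_LIKE = {
    "missense", "missense_variant", "stop_lost", "start_lost",
    "inframe_insertion", "inframe_deletion",
}
PTV_CONSEQUENCES = {"ptv", "stop_gained", "frameshift_variant",
                    "splice_acceptor_variant", "splice_donor_variant"}


def compute_pgs(
    dosages: pd.DataFrame,
    weights: pd.DataFrame,
    variant_alleles: pd.DataFrame | None = None,
    cohorts=None,
    standardise: bool = True,
) -> pd.Series:
    """Weighted sum of effect-allele dosages per individual.

    ``dosages``: individuals x variant-ID matrix of effect-allele counts
    in [0, 2] (NaN = missing). ``weights``: scoring table with columns
    variant_id / effect_allele / other_allele / weight. If
    ``variant_alleles`` (variant_id, a1, a2) is supplied, dosage columns
    are assumed to count a1: a scoring row with (effect, other) ==
    (a2, a1) flips the dosage to 2 - d; a mismatched allele pair is
    dropped with a warning (no strand flipping). Missing dosages are
    imputed to twice the effect-allele frequency estimated from
    non-missing carriers. Scores are standardised (mean 0, SD 1) within
    cohort unless ``standardise=False``.
    """
    w = weights.drop_duplicates("variant_id").set_index("variant_id")
    shared = [v for v in dosages.columns if v in w.index]
    if not shared:
        raise DataError("no overlapping variants between dosages and scoring file")
    orient = pd.Series(1.0, index=shared)
    if variant_alleles is not None:
        va = variant_alleles.drop_duplicates("variant_id").set_index("variant_id")
        keep = []
        for v in shared:
            if v not in va.index:
                keep.append(v)
                continue
            a1, a2 = va.loc[v, "a1"], va.loc[v, "a2"]
            ea, oa = w.loc[v, "effect_allele"], w.loc[v, "other_allele"]
            if (ea, oa) == (a1, a2):
                keep.append(v)
            elif (ea, oa) == (a2, a1):
                orient[v] = -1.0
                keep.append(v)
            else:
                logger.warning("variant %s allele pair mismatch; dropped", v)
        shared = keep
        if not shared:
            raise DataError("no allele-consistent overlapping variants")
    D = dosages[shared].astype(float).copy()
    flip = orient[shared].to_numpy() < 0
    D.loc[:, np.array(shared)[flip]] = 2.0 - D.loc[:, np.array(shared)[flip]]
    # impute missing to 2 x effect-allele frequency from non-missing carriers
    D = D.fillna(D.mean())
    score = pd.Series(D.to_numpy() @ w.loc[shared, "weight"].to_numpy(float),
                      index=dosages.index, name="pgs")
    if not standardise:
        return score
    groups = pd.Series(cohorts, index=score.index) if cohorts is not None else pd.Series(
        "all", index=score.index
    )

    def _z(x):
        sd = x.std(ddof=0)
        return (x - x.mean()) / sd if sd > 0 else x * 0.0

    return score.groupby(groups.values).transform(_z)


def rvbs_filter_mask(variants: pd.DataFrame) -> pd.Series:
    """Boolean mask of variants passing the full RVBS filter cascade."""
    missing = [c for c in RVBS_REQUIRED_COLUMNS if c not in variants.columns]
    if missing:
        raise DataError(f"variant table missing columns: {missing}")
    cons = variants["consequence"].astype(str)
    is_hc_ptv = cons.isin(PTV_CONSEQUENCES) & (variants["loftee"] == "HC")
    is_missense_like = cons.isin(MISSENSE_LIKE) | (
        cons.isin(PTV_CONSEQUENCES) & (variants["loftee"] == "LC")
    )
    damaging = is_hc_ptv | (is_missense_like & (variants["mpc"] >= 2.0))
    return (
        damaging
        & (variants["pli"] > 0.9)
        & (variants["gnomad_max_maf"] < 1e-5)
        & (variants["cohort_maf"] < 1e-4)
        & variants["inherited"].astype(bool)
        & variants["autosomal"].astype(bool)
        & (variants["zygosity"] == "het")
    )


def compute_rvbs(variants: pd.DataFrame, proband_ids=None) -> pd.Series:
    """Per-proband count of variants passing every RVBS filter.

    ``proband_ids`` fixes the output index (probands with no qualifying
    variants score 0); defaults to the probands present in the table.
    """
    mask = rvbs_filter_mask(variants)
    counts = variants.loc[mask].groupby("proband_id").size()
    if proband_ids is None:
        proband_ids = variants["proband_id"].unique()
    return counts.reindex(proband_ids, fill_value=0).rename("rvbs").astype(int)


def rint(values) -> pd.Series:
    """Rank-based inverse normal transform, Blom offset:
    z_i = Phi^-1((r_i - 3/8)/(n + 1/4)), average ranks for ties,
    missing values propagated."""
    v = pd.Series(values, dtype=float)
    mask = v.notna()
    x = v[mask]
    if x.size < 2:
        raise DataError("RINT requires >= 2 non-missing values")
    if x.nunique() == 1:
        raise DataError("RINT undefined for constant input")
    ranks = stats.rankdata(x, method="average")
    z = stats.norm.ppf((ranks - 0.375) / (x.size + 0.25))
    out = pd.Series(np.nan, index=v.index, name="rint")
    out[mask] = z
    return out


def _design(df: pd.DataFrame, cols: list[str]) -> pd.DataFrame:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise DataError(f"missing covariate columns: {missing}")
    X = sm.add_constant(df[cols].astype(float), has_constant="add")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise DataError("rank-deficient design matrix")
    return X


def gd_score_regression(
    data: pd.DataFrame,
    score_col: str,
    outcome_col: str = "gd_rint",
    n_pcs: int = 20,
    stratum: str = "all",
    interaction: bool = False,
) -> list[AssocResult]:
    """Linear regression of RINT gestational duration on a genetic score.

    Covariates: proband sex and the first ``n_pcs`` principal
    components. The score is standardised so the coefficient is the
    change in SD of RINT gestational duration per SD of score.
    ``stratum`` restricts to all / diagnosed / undiagnosed probands;
    ``interaction=True`` adds diagnostic status and score x diagnosis.
    """
    work = data
    if stratum == "diagnosed":
        work = data[data["diagnosed"] == 1]
    elif stratum == "undiagnosed":
        work = data[data["diagnosed"] == 0]
    elif stratum != "all":
        raise DataError(f"unknown stratum {stratum!r}")
    work = work.dropna(subset=[outcome_col, score_col]).copy()
    sd = work[score_col].std(ddof=0)
    if not sd > 0:
        raise DataError(f"score {score_col!r} is constant")
    work["_score"] = (work[score_col] - work[score_col].mean()) / sd
    cols = ["_score", "sex"] + [f"PC{i}" for i in range(1, n_pcs + 1)]
    if interaction:
        work["_diag"] = work["diagnosed"].astype(float)
        work["_score_x_diag"] = work["_score"] * work["_diag"]
        cols += ["_diag", "_score_x_diag"]
    X = _design(work, cols)
    res = sm.OLS(work[outcome_col].to_numpy(float), X).fit()
    rename = {"_score": score_col, "_diag": "diagnosed",
              "_score_x_diag": f"{score_col}:diagnosed"}
    return [
        AssocResult(term=rename.get(t, t), estimate=float(res.params[t]),
                    se=float(res.bse[t]), p=float(res.pvalues[t]),
                    n=len(work), family="linear")
        for t in cols
    ]


def trio_decomposition(
    child_score, mother_score, father_score, phenotype,
    covariates: pd.DataFrame | None = None,
) -> list[AssocResult]:
    """Joint regression of a phenotype on child, maternal and paternal PGS.

    All three scores are standardised; the child coefficient estimates
    the direct genetic effect, the parental coefficients the
    non-transmitted / confounding component. (Regressing on parental
    full scores is an affine reparameterisation of regressing on
    non-transmitted scores: parent = transmitted + non-transmitted, and
    the child score is the sum of transmitted alleles, so the two
    parameterisations give the same child coefficient.)
    """
    df = pd.DataFrame({
        "child": np.asarray(child_score, float),
        "mother": np.asarray(mother_score, float),
        "father": np.asarray(father_score, float),
    })
    for c in df.columns:
        sd = df[c].std(ddof=0)
        if not sd > 0:
            raise DataError(f"{c} score is constant")
        df[c] = (df[c] - df[c].mean()) / sd
    resid = sm.OLS(df["child"], sm.add_constant(df[["mother", "father"]])).fit().resid
    if resid.std(ddof=0) < 1e-8:
        raise DataError("no segregation variance: child score collinear with parents")
    cols = ["child", "mother", "father"]
    if covariates is not None:
        for c in covariates.columns:
            df[c] = np.asarray(covariates[c], float)
        cols += list(covariates.columns)
    X = _design(df, cols)
    res = sm.OLS(np.asarray(phenotype, float), X).fit()
    return [
        AssocResult(term=t, estimate=float(res.params[t]), se=float(res.bse[t]),
                    p=float(res.pvalues[t]), n=len(df), family="linear")
        for t in cols
    ]
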