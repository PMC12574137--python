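"""Synthetic developmental-disorder cohort generator.

Every simulator here is a pure function of its inputs and the named
random substream derived from ``SimConfig.seed``; rerunning with the
same configuration reproduces the output bit for bit. The generator
emulates the statistical structure that the downstream analyses assume:

* gestational age drawn per WHO category, then uniformly over the
  category's completed-week range;
* diagnostic yield declining with prematurity (Bernoulli per category);
* de novo mutation (DNM) counts as independent Poisson draws from a
  per-gene, per-consequence-class null rate table, with an injectable
  excess of nonsynonymous DNMs in chosen gene sets among diagnosed
  probands;
* Mendelian transmission of scored alleles in parent-offspring trios
  with configurable direct (child) and indirect (parental) effects;
* milestone attainment times with proportional-hazards shifts per
  category and diagnosis, under independent right-censoring.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import (
    CATEGORIES,
    CATEGORY_WEEK_RANGE,
    SimConfig,
)
from .exceptions import ConfigurationError, DataError

logger = logging.getLogger(__name__)

DNM_CLASSES = ("synonymous", "missense", "ptv")
NONSYNONYMOUS_CLASSES = ("missense", "ptv")

COHORT_COLUMNS = [
    "proband_id",
    "cohort_label",
    "sex",
    "gestational_weeks",
    "prematurity_category",
    "birthweight_g",
    "maternal_age_years",
    "age_at_assessment_years",
    "diagnosed",
    "hpo_terms",
    "deprivation_index",
]

VARIANT_COLUMNS = [
    "proband_id",
    "gene",
    "consequence",
    "loftee",
    "mpc",
    "pli",
    "gnomad_max_maf",
    "cohort_maf",
    "inherited",
    "autosomal",
    "zygosity",
]


def _birthweight_median(weeks: np.ndarray, sex: np.ndarray) -> np.ndarray:
    """Median birthweight (g) by gestation and sex.

    Log-linear fetal growth, ~3550 g at 40 weeks, ~1150 g at 28 weeks,
    with a +/- 2.5% sex offset (male heavier).
    """
    base = 3550.0 * np.exp(0.094 * (np.asarray(weeks, float) - 40.0))
    return base * np.where(np.asarray(sex) == 1, 1.025, 0.975)


def synthetic_lms_reference() -> pd.DataFrame:
    """LMS growth reference matching the generator's birthweight model.

    L = 1 (no skew), M = the generator's median, S = 0.12, for each sex
    and completed week 22-44. Synthetic stand-in for a national growth
    reference; shaped like one (columns sex, gestational_weeks, L, M, S)
    so the z-score machinery is exercised end to end.
    """
    rows = []
    for sex in (0, 1):
        for wk in range(22, 45):
            rows.append(
                {
                    "sex": sex,
                    "gestational_weeks": wk,
                    "L": 1.0,
                    "M": float(_birthweight_median(np.array([wk]), np.array([sex]))[0]),
                    "S": 0.12,
                }
            )
    return pd.DataFrame(rows)


def simulate_cohort(config: SimConfig) -> pd.DataFrame:
    """Draw a synthetic proband table.

    Returns one row per proband with demographic, gestational and
    diagnostic columns (see ``COHORT_COLUMNS``); ``hpo_terms`` is left
    empty (annotate separately if needed).
    """
    config.validate()
    n = config.n_probands
    rng = config.rng("cohort")
    if n == 0:
        return pd.DataFrame(columns=COHORT_COLUMNS).astype(
            {"sex": int, "gestational_weeks": int, "diagnosed": int}, errors="ignore"
        )

    cat_idx = rng.choice(4, size=n, p=list(config.category_probs))
    categories = np.array(CATEGORIES)[cat_idx]
    lo = np.array([CATEGORY_WEEK_RANGE[c][0] for c in categories])
    hi = np.array([CATEGORY_WEEK_RANGE[c][1] for c in categories])
    weeks = rng.integers(lo, hi + 1)

    sex = (rng.random(n) < config.p_male).astype(int)
    diag_p = np.array(config.diag_prob_by_category)[cat_idx]
    diagnosed = (rng.random(n) < diag_p).astype(int)

    med = _birthweight_median(weeks, sex)
    birthweight = np.maximum(med * (1.0 + 0.12 * rng.standard_normal(n)), 300.0)

    maternal_age = np.clip(rng.normal(29.5, 5.6, size=n), 16.0, 48.0)
    age_assess = np.clip(rng.normal(7.3, 6.1, size=n), 0.25, 30.0)
    deprivation = rng.standard_normal(n)

    return pd.DataFrame(
        {
            "proband_id": [f"P{i:06d}" for i in range(n)],
            "cohort_label": config.cohort_label,
            "sex": sex,
            "gestational_weeks": weeks.astype(int),
            "prematurity_category": pd.Categorical(categories, categories=CATEGORIES),
            "birthweight_g": birthweight,
            "maternal_age_years": maternal_age,
            "age_at_assessment_years": age_assess,
            "diagnosed": diagnosed,
            "hpo_terms": ["" for _ in range(n)],
            "deprivation_index": deprivation,
        }
    )


def summarise_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Per-category composition summary: n, %, n diagnosed, % diagnosed.

    Percentages of the category composition are relative to the whole
    cohort; diagnostic percentages are within category. The ``overall``
    row gives totals.
    """
    rows = []
    total = len(cohort)
    diag_total = int(cohort["diagnosed"].sum()) if total else 0
    for cat in CATEGORIES:
        sub = cohort[cohort["prematurity_category"] == cat]
        n = len(sub)
        nd = int(sub["diagnosed"].sum()) if n else 0
        rows.append(
            {
                "category": cat,
                "n": n,
                "pct": 100.0 * n / total if total else np.nan,
                "n_diagnosed": nd,
                "pct_diagnosed": 100.0 * nd / n if n else np.nan,
            }
        )
    rows.append(
        {
            "category": "overall",
            "n": total,
            "pct": 100.0 if total else np.nan,
            "n_diagnosed": diag_total,
            "pct_diagnosed": 100.0 * diag_total / total if total else np.nan,
        }
    )
    return pd.DataFrame(rows).set_index("category")


def synthetic_gene_rate_table(
    n_genes: int = 100,
    seed: int = 0,
    ddg2p_fraction: float = 0.3,
    total_rates: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Per-gene null mutation-rate table (long format).

    Total per-proband expected DNM counts default to ~0.3 synonymous,
    0.65 missense and 0.08 protein-truncating per generation, spread
    over genes with random (Dirichlet) relative sizes. The first
    ``ddg2p_fraction`` of genes are tagged as known DD-associated
    (``DDG2P``), the rest as ``non-DDG2P``.
    """
    if n_genes < 1:
        raise ConfigurationError("n_genes must be >= 1")
    totals = total_rates or {"synonymous": 0.30, "missense": 0.65, "ptv": 0.08}
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x67656E65]))
    share = rng.dirichlet(np.ones(n_genes))
    n_ddg2p = max(int(round(ddg2p_fraction * n_genes)), 1)
    rows = []
    for g in range(n_genes):
        gene = f"G{g + 1:04d}"
        tag = "DDG2P" if g < n_ddg2p else "non-DDG2P"
        # class split varies a little per gene
        jitter = rng.dirichlet(np.ones(3) * 20)
        ref = np.array([totals[c] for c in DNM_CLASSES])
        mus = share[g] * ref * (3 * jitter)
        for c, mu in zip(DNM_CLASSES, mus):
            rows.append({"gene": gene, "consequence_class": c, "mu": float(mu), "gene_set": tag})
    return pd.DataFrame(rows)


def _rate_matrix(rates: pd.DataFrame) -> tuple[list[str], dict[str, np.ndarray]]:
    required = {"gene", "consequence_class", "mu"}
    if not required.issubset(rates.columns):
        raise DataError(f"rate table must have columns {sorted(required)}")
    if (rates["mu"] < 0).any():
        raise DataError("negative mutation rate in rate table")
    missing = set(DNM_CLASSES) - set(rates["consequence_class"])
    if missing:
        raise DataError(f"rate table missing classes: {sorted(missing)}")
    genes = sorted(rates["gene"].unique())
    wide = rates.pivot_table(
        index="gene", columns="consequence_class", values="mu", aggfunc="sum", fill_value=0.0
    ).reindex(genes, fill_value=0.0)
    mats = {c: wide.get(c, pd.Series(0.0, index=genes)).to_numpy(float) for c in DNM_CLASSES}
    return genes, mats


def simulate_dnms(
    cohort: pd.DataFrame, rates: pd.DataFrame, config: SimConfig
) -> pd.DataFrame:
    """Draw a DNM table (one row per mutation) from the null rate table.

    Baseline counts per proband, gene and class are independent Poisson
    with the tabulated rate. Diagnosed probands then receive extra
    *nonsynonymous* DNMs in each gene set named in ``config.dnm_excess``
    (keys match the rate table's ``gene_set`` tags) at the configured
    per-proband rate: the target gene is uniform within the set and the
    class is missense vs ptv proportionally to the gene's null rates.
    Synonymous counts never receive excess, and the excess draws use a
    separate substream, so the baseline is identical between zero-excess
    and excess runs at the same seed.
    """
    config.validate()
    genes, mats = _rate_matrix(rates)
    n = len(cohort)
    rng = config.rng("dnm_base")
    frames = []
    proband_ids = cohort["proband_id"].to_numpy()
    for cls in DNM_CLASSES:
        mu = mats[cls]
        counts = rng.poisson(np.broadcast_to(mu, (n, mu.size)))
        pi, gi = np.nonzero(counts)
        reps = counts[pi, gi]
        if reps.sum() == 0:
            continue
        frames.append(
            pd.DataFrame(
                {
                    "proband_id": np.repeat(proband_ids[pi], reps),
                    "gene": np.repeat(np.array(genes, dtype=object)[gi], reps),
                    "consequence_class": cls,
                }
            )
        )

    if config.dnm_excess:
        if "gene_set" not in rates.columns:
            raise DataError("dnm_excess configured but rate table has no gene_set column")
        gene_arr = np.array(genes, dtype=object)
        set_of = rates.drop_duplicates("gene").set_index("gene")["gene_set"]
        rng_x = config.rng("dnm_excess")
        diag_ids = cohort.loc[cohort["diagnosed"] == 1, "proband_id"].to_numpy()
        for set_name, rate in config.dnm_excess.items():
            members = [g for g in genes if set_of.get(g) == set_name]
            if rate > 0 and not members:
                raise DataError(f"dnm_excess names unknown gene set {set_name!r}")
            if rate == 0 or not len(diag_ids):
                continue
            member_idx = np.array([genes.index(g) for g in members])
            k = rng_x.poisson(rate, size=diag_ids.size)
            tot = int(k.sum())
            if tot == 0:
                continue
            pid = np.repeat(diag_ids, k)
            gsel = member_idx[rng_x.integers(0, member_idx.size, size=tot)]
            p_ptv = np.where(
                mats["missense"][gsel] + mats["ptv"][gsel] > 0,
                mats["ptv"][gsel] / np.maximum(mats["missense"][gsel] + mats["ptv"][gsel], 1e-300),
                0.5,
            )
            cls = np.where(rng_x.random(tot) < p_ptv, "ptv", "missense")
            frames.append(
                pd.DataFrame(
                    {"proband_id": pid, "gene": gene_arr[gsel], "consequence_class": cls}
                )
            )

    if not frames:
        return pd.DataFrame(columns=["proband_id", "gene", "consequence_class"])
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["proband_id", "gene", "consequence_class"]).reset_index(drop=True)


@dataclass
class TrioSimulation:
    """Output of :func:`simulate_trios`.

    ``child``/``mother``/``father`` are dosage tables (one row per trio,
    one column per variant, values in {0, 1, 2}); ``transmitted`` holds
    the per-parent transmitted allele so non-transmitted scores can be
    reconstructed; ``phenotype`` is the simulated quantitative outcome.
    """

    child: pd.DataFrame
    mother: pd.DataFrame
    father: pd.DataFrame
    transmitted_mother: pd.DataFrame
    transmitted_father: pd.DataFrame
    phenotype: pd.Series
    weights: np.ndarray


def _standardise(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def simulate_trios(cohort: pd.DataFrame, config: SimConfig) -> TrioSimulation:
    """Simulate parent-offspring trios under Mendelian transmission.

    Parental genotypes are Binomial(2, f) per variant; each parent
    transmits one of its alleles at random (Binomial(1, g/2)); the child
    dosage is the sum of the two transmitted alleles. The phenotype is

        beta_direct * PGS_child + beta_parental * (PGS_mother + PGS_father) + noise

    with all polygenic scores standardised before use.
    """
    config.validate()
    tp = config.trio_params
    n = len(cohort)
    rng = config.rng("trios")
    freqs = tp.resolved_freqs()
    weights = tp.resolved_weights()
    m = tp.n_variants
    cols = [f"v{j + 1:05d}" for j in range(m)]
    idx = cohort["proband_id"].to_numpy()

    gm = rng.binomial(2, freqs, size=(n, m)) if m else np.zeros((n, 0), int)
    gf = rng.binomial(2, freqs, size=(n, m)) if m else np.zeros((n, 0), int)
    tm = rng.binomial(1, gm / 2.0) if m else np.zeros((n, 0), int)
    tf = rng.binomial(1, gf / 2.0) if m else np.zeros((n, 0), int)
    gc = tm + tf

    raw_c = gc @ weights if m else np.zeros(n)
    raw_m = gm @ weights if m else np.zeros(n)
    raw_f = gf @ weights if m else np.zeros(n)
    noise = rng.normal(0.0, tp.noise_sd, size=n)
    pheno = (
        tp.beta_direct * _standardise(raw_c)
        + tp.beta_parental * (_standardise(raw_m) + _standardise(raw_f))
        + noise
    )

    def frame(a: np.ndarray) -> pd.DataFrame:
        return pd.DataFrame(a, index=idx, columns=cols)

    return TrioSimulation(
        child=frame(gc),
        mother=frame(gm),
        father=frame(gf),
        transmitted_mother=frame(tm),
        transmitted_father=frame(tf),
        phenotype=pd.Series(pheno, index=idx, name="phenotype"),
        weights=weights,
    )


def simulate_milestones(cohort: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Fill milestone attainment times (months) with right-censoring.

    Event times are exponential with rate ln2/median shifted on the log
    scale by the category and diagnosis log hazard ratios. With
    probability ``censor_prob`` an observation is censored at a uniform
    fraction of its (unobserved) event time. Adds ``<m>_months`` and
    ``<m>_event`` columns per milestone.
    """
    config.validate()
    mp = config.milestone_params
    out = cohort.copy()
    rng = config.rng("milestones")
    n = len(cohort)
    lhr_cat = np.array(
        [mp.log_hr_by_category.get(c, 0.0) for c in cohort["prematurity_category"]]
    ) if n else np.zeros(0)
    lhr = lhr_cat + mp.log_hr_diagnosis * cohort["diagnosed"].to_numpy(float) if n else np.zeros(0)
    for m, median in mp.baseline_median_months.items():
        rate = (np.log(2.0) / median) * np.exp(lhr)
        t = rng.exponential(1.0 / rate) if n else np.zeros(0)
        censored = rng.random(n) < mp.censor_prob if n else np.zeros(0, bool)
        u = rng.random(n) if n else np.zeros(0)
        out[f"{m}_months"] = np.where(censored, t * u, t)
        out[f"{m}_event"] = (~censored).astype(int)
    return out


def simulate_rare_variants(
    cohort: pd.DataFrame,
    n_genes: int = 50,
    seed: int = 0,
    variants_per_proband: int = 5,
    pass_fraction: float = 0.5,
) -> pd.DataFrame:
    """Fixture generator for the rare-variant burden-score filter.

    Emits ``variants_per_proband`` candidate variants per proband, each
    passing the complete filter cascade with probability
    ``pass_fraction``. A failing variant starts from a passing template
    and violates exactly one filter (low MPC, tolerant gene, common in
    gnomAD, common in cohort, de novo, or homozygous), chosen uniformly.
    """
    if n_genes < 1:
        raise ConfigurationError("n_genes must be >= 1")
    if not 0 <= pass_fraction <= 1:
        raise ConfigurationError("pass_fraction must lie in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x72766273]))
    n_hi = max(n_genes // 2, 1)
    hi_genes = [f"RG{g + 1:04d}" for g in range(n_hi)]
    lo_genes = [f"RG{g + 1:04d}" for g in range(n_hi, n_genes)] or hi_genes
    hi_pli = {g: float(p) for g, p in zip(hi_genes, rng.uniform(0.92, 1.0, len(hi_genes)))}
    lo_pli = {g: float(p) for g, p in zip(lo_genes, rng.uniform(0.0, 0.5, len(lo_genes)))}

    rows: list[dict] = []
    for pid in cohort["proband_id"]:
        for _ in range(variants_per_proband):
            passing = rng.random() < pass_fraction
            gene = hi_genes[rng.integers(len(hi_genes))]
            is_ptv = rng.random() < 0.5
            row = {
                "proband_id": pid,
                "gene": gene,
                "consequence": "ptv" if is_ptv else "missense",
                "loftee": "HC" if is_ptv else "",
                "mpc": np.nan if is_ptv else float(rng.uniform(2.0, 4.0)),
                "pli": hi_pli[gene],
                "gnomad_max_maf": float(rng.uniform(0, 5e-6)),
                "cohort_maf": float(rng.uniform(0, 5e-5)),
                "inherited": True,
                "autosomal": True,
                "zygosity": "het",
            }
            if not passing:
                mode = rng.integers(6)
                if mode == 0:  # low MPC missense
                    row["consequence"] = "missense"
                    row["loftee"] = ""
                    row["mpc"] = float(rng.uniform(0.0, 1.9))
                elif mode == 1:  # tolerant gene
                    g = lo_genes[rng.integers(len(lo_genes))]
                    row["gene"] = g
                    row["pli"] = lo_pli.get(g, 0.1)
                elif mode == 2:
                    row["gnomad_max_maf"] = float(rng.uniform(1e-4, 1e-2))
                elif mode == 3:
                    row["cohort_maf"] = float(rng.uniform(2e-4, 1e-2))
                elif mode == 4:
                    row["inherited"] = False
                else:
                    row["zygosity"] = "hom"
            rows.append(row)
    return pd.DataFrame(rows, columns=VARIANT_COLUMNS)
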