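"""De novo mutation (DNM) burden analysis.

Compares observed DNM counts with expectations under a null mutational
model (a per-gene, per-consequence-class rate table), calibrated by the
synonymous correction factor

    lambda = O_synonymous / E_synonymous   (over ALL probands, pooled),

tests for a nonsynonymous excess with one-sided exact Poisson tests,
and estimates the attributable fraction

    AF = (O_nonsynonymous - lambda * E_nonsynonymous) / N_probands,

the proportion of cases explained by nonsynonymous DNMs, per stratum
(gestational group x diagnostic group x gene set). AF differences
between gestational groups are compared with z-tests.

AF uncertainty treats O as Poisson with lambda*E fixed, giving
SE(AF) = sqrt(O)/N and a normal 95% CI; a proband-level bootstrap is
available as an alternative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import DNM_CLASSES, NONSYNONYMOUS_CLASSES, _rate_matrix
from .exceptions import DataError

logger = logging.getLogger(__name__)

GESTATION_GROUPS = ("term", "preterm")
PROBAND_GROUPS = ("all", "diagnosed", "undiagnosed")
GENE_SETS = ("exome", "DDG2P", "non-DDG2P")

#: Multiplicity ledgers of the burden battery.
N_EXCESS_TESTS = 18  # 2 gestational groups x 3 proband groups x 3 gene sets
N_AF_COMPARISONS = 9  # 3 proband groups x 3 gene sets


@dataclass
class DnmBurdenResult:
    """Observed/expected DNM burden for one stratum."""

    gestation_group: str
    proband_group: str
    gene_set: str
    classes: tuple
    observed: int
    expected: float
    lam: float
    excess_p: float
    af: float
    af_se: float
    af_ci95: tuple
    n_probands: int
    note: str = ""


def expected_dnm_counts(
    rates: pd.DataFrame, n_probands: int, gene_set=None, classes=NONSYNONYMOUS_CLASSES
) -> float:
    """E = N x sum of per-gene rates over the gene set and classes."""
    genes, mats = _rate_matrix(rates)
    if gene_set is None:
        idx = np.arange(len(genes))
    else:
        gene_set = list(gene_set)
        unknown = set(gene_set) - set(genes)
        if unknown:
            raise DataError(f"genes absent from rate table: {sorted(unknown)[:5]}")
        pos = {g: i for i, g in enumerate(genes)}
        idx = np.array([pos[g] for g in gene_set], dtype=int)
    total = 0.0
    for c in classes:
        if c not in DNM_CLASSES:
            raise DataError(f"unknown consequence class {c!r}")
        total += mats[c][idx].sum() if idx.size else 0.0
    return float(n_probands) * total


def synonymous_correction_factor(
    dnms: pd.DataFrame, rates: pd.DataFrame, n_probands: int
) -> float:
    """lambda = observed / expected synonymous count, over all probands."""
    e_syn = expected_dnm_counts(rates, n_probands, classes=("synonymous",))
    if not e_syn > 0:
        raise DataError("expected synonymous count is zero; lambda undefined")
    o_syn = int((dnms["consequence_class"] == "synonymous").sum())
    if o_syn == 0:
        logger.warning("no observed synonymous DNMs; lambda = 0 (flagged)")
    return o_syn / e_syn


def poisson_excess_test(observed: int, expected_corrected: float) -> float:
    """One-sided exact Poisson p = P(X >= O | mean = corrected E)."""
    if observed < 0:
        raise DataError("observed count must be >= 0")
    if not expected_corrected > 0:
        raise DataError("corrected expectation must be > 0")
    return float(stats.poisson.sf(observed - 1, expected_corrected))


def attributable_fraction(
    o_nonsyn: int, e_nonsyn: float, lam: float, n_probands: int
) -> tuple[float, float, tuple]:
    """AF = (O - lambda*E)/N with SE = sqrt(O)/N and normal 95% CI.

    AF may be negative (observed deficit); it is returned as computed.
    """
    if n_probands <= 0:
        raise DataError("n_probands must be > 0")
    if lam < 0:
        raise DataError("lambda must be >= 0")
    af = (o_nonsyn - lam * e_nonsyn) / n_probands
    se = np.sqrt(o_nonsyn) / n_probands
    ci = (af - 1.96 * se, af + 1.96 * se)
    return float(af), float(se), (float(ci[0]), float(ci[1]))


def attributable_fraction_bootstrap(
    dnm_counts_per_proband: np.ndarray,
    e_per_proband: float,
    lam: float,
    n_boot: int = 1000,
    seed: int = 0,
) -> tuple[float, float, tuple]:
    """Proband-level bootstrap alternative for the AF uncertainty."""
    x = np.asarray(dnm_counts_per_proband, float)
    n = x.size
    if n == 0:
        raise DataError("no probands to bootstrap")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    afs = (x[idx].sum(axis=1) - lam * e_per_proband * n) / n
    af = float((x.sum() - lam * e_per_proband * n) / n)
    se = float(afs.std(ddof=1))
    lo, hi = np.percentile(afs, [2.5, 97.5])
    return af, se, (float(lo), float(hi))


def compare_attributable_fractions(res1, res2) -> tuple[float, float]:
    """z-test for a difference in attributable fractions.

    z = (AF1 - AF2)/sqrt(SE1^2 + SE2^2), two-sided normal p. The caller
    applies the 9-test Bonferroni ledger.
    """
    for r in (res1, res2):
        se = r.af_se if hasattr(r, "af_se") else r[1]
        if not np.isfinite(se):
            raise DataError("missing AF standard error")
    af1, se1 = (res1.af, res1.af_se) if hasattr(res1, "af") else res1[:2]
    af2, se2 = (res2.af, res2.af_se) if hasattr(res2, "af") else res2[:2]
    denom = np.sqrt(se1**2 + se2**2)
    if denom == 0:
        return (0.0, 1.0) if af1 == af2 else (np.inf, 0.0)
    z = (af1 - af2) / denom
    return float(z), float(2.0 * stats.norm.sf(abs(z)))


def _gene_sets_from_rates(rates: pd.DataFrame) -> dict[str, list[str]]:
    genes = rates.drop_duplicates("gene")
    sets: dict[str, list[str]] = {"exome": sorted(genes["gene"])}
    if "gene_set" in genes.columns:
        for tag in ("DDG2P", "non-DDG2P"):
            sets[tag] = sorted(genes.loc[genes["gene_set"] == tag, "gene"])
    return sets


def run_dnm_analysis(
    cohort: pd.DataFrame,
    dnms: pd.DataFrame,
    rates: pd.DataFrame,
    gene_sets: dict[str, list[str]] | None = None,
    apply_lambda_in_test: bool = True,
) -> pd.DataFrame:
    """The full stratified burden table.

    Strata: {term, preterm} x {all, diagnosed, undiagnosed} x
    {exome, DDG2P, non-DDG2P}. A single synonymous lambda (all probands,
    exome-wide) is reused across strata. Poisson excess tests run
    against lambda-corrected expectations by default
    (``apply_lambda_in_test=False`` tests against the raw expectation).
    Attaches the 18-test (excess) and 9-test (AF comparison) Bonferroni
    ledgers as DataFrame attrs.
    """
    if gene_sets is None:
        gene_sets = _gene_sets_from_rates(rates)
    for name in GENE_SETS:
        if name not in gene_sets:
            raise DataError(f"gene set {name!r} required (got {sorted(gene_sets)})")

    n_all = len(cohort)
    lam = synonymous_correction_factor(dnms, rates, n_all)

    merged = dnms.merge(
        cohort[["proband_id", "prematurity_category", "diagnosed"]],
        on="proband_id", how="left", validate="many_to_one",
    )
    if merged["prematurity_category"].isna().any():
        raise DataError("DNM table contains proband IDs absent from the cohort")
    merged["gestation_group"] = np.where(
        merged["prematurity_category"] == "term", "term", "preterm"
    )
    cohort = cohort.assign(
        gestation_group=np.where(cohort["prematurity_category"] == "term", "term", "preterm")
    )

    rows = []
    for gg in GESTATION_GROUPS:
        for pg in PROBAND_GROUPS:
            cmask = cohort["gestation_group"] == gg
            dmask = merged["gestation_group"] == gg
            if pg != "all":
                want = 1 if pg == "diagnosed" else 0
                cmask &= cohort["diagnosed"] == want
                dmask &= merged["diagnosed"] == want
            n_sub = int(cmask.sum())
            sub = merged[dmask]
            for gs in GENE_SETS:
                genes = set(gene_sets[gs])
                note = ""
                if n_sub == 0:
                    rows.append(dict(
                        gestation_group=gg, proband_group=pg, gene_set=gs,
                        observed=0, expected=np.nan, lam=lam, excess_p=np.nan,
                        af=np.nan, af_se=np.nan, af_lo=np.nan, af_hi=np.nan,
                        n_probands=0, note="empty stratum",
                    ))
                    continue
                o = int(
                    (sub["gene"].isin(genes)
                     & sub["consequence_class"].isin(NONSYNONYMOUS_CLASSES)).sum()
                )
                e = expected_dnm_counts(rates, n_sub, gene_sets[gs], NONSYNONYMOUS_CLASSES)
                e_test = lam * e if apply_lambda_in_test else e
                p = poisson_excess_test(o, e_test) if e_test > 0 else np.nan
                af, se, ci = attributable_fraction(o, e, lam, n_sub)
                rows.append(dict(
                    gestation_group=gg, proband_group=pg, gene_set=gs,
                    observed=o, expected=e, lam=lam, excess_p=p,
                    af=af, af_se=se, af_lo=ci[0], af_hi=ci[1],
                    n_probands=n_sub, note=note,
                ))
    table = pd.DataFrame(rows)

    # 9 AF comparisons: term vs preterm per proband group x gene set
    comps = []
    for pg in PROBAND_GROUPS:
        for gs in GENE_SETS:
            r_term = table.query(
                "gestation_group=='term' and proband_group==@pg and gene_set==@gs"
            ).iloc[0]
            r_pre = table.query(
                "gestation_group=='preterm' and proband_group==@pg and gene_set==@gs"
            ).iloc[0]
            if np.isfinite(r_term["af_se"]) and np.isfinite(r_pre["af_se"]):
                z, p = compare_attributable_fractions(
                    (r_term["af"], r_term["af_se"]), (r_pre["af"], r_pre["af_se"])
                )
            else:
                z, p = np.nan, np.nan
            comps.append(dict(proband_group=pg, gene_set=gs, z=z, p=p,
                              af_term=r_term["af"], af_preterm=r_pre["af"]))
    table.attrs["af_comparisons"] = pd.DataFrame(comps)
    table.attrs["bonferroni_excess"] = 0.05 / N_EXCESS_TESTS
    table.attrs["bonferroni_af"] = 0.05 / N_AF_COMPARISONS
    table.attrs["lambda"] = lam
    return table
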