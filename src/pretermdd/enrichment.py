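"""Per-gene and gene-set enrichment of monogenic diagnoses by prematurity.

Among diagnosed probands with single-gene diagnoses: logistic
regression of prematurity (binary) on carrying a diagnosis in each
sufficiently common gene (>= 30 diagnostic variants by default, the
count at which a Monte-Carlo power analysis shows adequate power for an
odds ratio of about six), and exact Fisher tests of gene-set membership
across three gestational groups (term / moderately preterm / very-or-
extremely preterm) with post hoc pairwise contrasts vs term.

The k x 2 exact test enumerates all tables with the observed margins
and sums the probabilities of tables no more likely than the observed
one (the standard two-sided Fisher convention); for 2 x 2 tables this
coincides with scipy's implementation, which serves as an independent
cross-check in the test-suite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.special import gammaln

from .exceptions import DataError

logger = logging.getLogger(__name__)

#: overall + up to 3 pairwise tests per gene set, 4 sets -> 16 tests
TESTS_PER_GENE_SET = 4

GROUP3 = ("term", "moderate", "very_or_extreme")


@dataclass
class EnrichmentResult:
    unit: str
    contrast: str
    odds_ratio: float
    ci95: tuple
    p: float
    table: np.ndarray
    n: int
    method: str
    converged: bool = True
    note: str = ""
    extra: dict = field(default_factory=dict)


def select_testable_genes(diag: pd.DataFrame, min_count: int = 30) -> list[str]:
    """Genes with >= min_count single-gene diagnoses, by count desc then ID."""
    if len(diag) == 0:
        return []
    counts = diag["diagnosed_gene"].value_counts()
    eligible = counts[counts >= min_count]
    return sorted(eligible.index, key=lambda g: (-int(eligible[g]), g))


def _two_by_two(diag: pd.DataFrame, carrier: np.ndarray) -> np.ndarray:
    preterm = diag["preterm"].to_numpy(int)
    a = int(((carrier == 1) & (preterm == 1)).sum())
    b = int(((carrier == 1) & (preterm == 0)).sum())
    c = int(((carrier == 0) & (preterm == 1)).sum())
    d = int(((carrier == 0) & (preterm == 0)).sum())
    return np.array([[a, b], [c, d]])


def per_gene_prematurity_association(
    diag: pd.DataFrame, gene: str, confirmed_only: bool = False
) -> EnrichmentResult:
    """Logistic regression of prematurity on carrying a diagnosis in ``gene``.

    Run among diagnosed probands; ``confirmed_only`` restricts to
    clinically confirmed pathogenic / likely pathogenic annotations
    (``tier == 'P/LP'``). On a zero cell the Wald fit is degenerate, so
    the exact (Fisher) test and conditional-MLE odds ratio are reported
    instead, flagged.
    """
    work = diag
    if confirmed_only:
        work = diag[diag["tier"] == "P/LP"]
    carrier = (work["diagnosed_gene"] == gene).to_numpy(int)
    table = _two_by_two(work, carrier)
    n = len(work)
    if table.min() == 0:
        orr = stats.contingency.odds_ratio(table)
        p = stats.fisher_exact(table)[1]
        ci = orr.confidence_interval(0.95)
        return EnrichmentResult(
            unit=gene, contrast="preterm_vs_term", odds_ratio=float(orr.statistic),
            ci95=(float(ci.low), float(ci.high)), p=float(p), table=table, n=n,
            method="fisher_exact", converged=False,
            note="zero cell / separation; exact-test fallback",
        )
    X = sm.add_constant(pd.DataFrame({"carrier": carrier.astype(float)}))
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.Logit(work["preterm"].to_numpy(int), X).fit(disp=False, maxiter=100)
    beta = float(res.params["carrier"])
    se = float(res.bse["carrier"])
    converged = bool(res.mle_retvals.get("converged", True)) and abs(beta) < 15
    return EnrichmentResult(
        unit=gene, contrast="preterm_vs_term", odds_ratio=float(np.exp(beta)),
        ci95=(float(np.exp(beta - 1.96 * se)), float(np.exp(beta + 1.96 * se))),
        p=float(res.pvalues["carrier"]), table=table, n=n, method="logistic",
        converged=converged, note="" if converged else "possible separation",
        extra={"log_or": beta, "se": se},
    )


def kx2_fisher_exact(table: np.ndarray) -> float:
    """Exact two-sided Fisher test for a k x 2 contingency table.

    Enumerates every table with the observed margins; the p-value is the
    total probability of tables whose multivariate-hypergeometric
    probability does not exceed the observed table's (with a small
    relative tolerance for ties). Exact but exponential in k; intended
    for the k <= 4 group schemes used here.
    """
    t = np.asarray(table, dtype=int)
    if t.ndim != 2 or t.shape[1] != 2 or (t < 0).any():
        raise DataError("k x 2 table of non-negative counts required")
    row = t.sum(axis=1)
    col = t.sum(axis=0)
    N = int(t.sum())
    if N == 0:
        raise DataError("empty contingency table")

    logC = lambda n, k: gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)  # noqa: E731
    denom = logC(N, col[0])

    def log_prob(first_col: np.ndarray) -> float:
        return float(np.sum(logC(row, first_col)) - denom)

    obs_lp = log_prob(t[:, 0])
    k = len(row)

    total = 0.0
    stack = [(0, int(col[0]), [])]
    while stack:
        i, remaining, acc = stack.pop()
        if i == k - 1:
            if 0 <= remaining <= row[i]:
                lp = log_prob(np.array(acc + [remaining]))
                if lp <= obs_lp + 1e-9:
                    total += np.exp(lp)
            continue
        tail_capacity = int(row[i + 1:].sum())
        lo = max(0, remaining - tail_capacity)
        hi = min(int(row[i]), remaining)
        for a in range(lo, hi + 1):
            stack.append((i + 1, remaining - a, acc + [a]))
    return float(min(total, 1.0))


def gene_set_fisher(
    diag: pd.DataFrame, gene_set, set_name: str = "gene_set"
) -> list[EnrichmentResult]:
    """Exact enrichment tests of gene-set diagnoses across gestational groups.

    Groups are term, moderately preterm, and very-or-extremely preterm
    (pooled). The overall k x 2 exact test comes first, followed by post
    hoc pairwise 2 x 2 exact contrasts of each preterm group vs term,
    with conditional-MLE odds ratios. The multiplicity ledger is
    ``TESTS_PER_GENE_SET`` tests per set (overall + pairwise).
    """
    genes = set(gene_set)
    cat = diag["gestational_category"].astype(str)
    group = np.where(
        cat == "term", "term",
        np.where(cat == "moderate", "moderate", "very_or_extreme"),
    )
    in_set = diag["diagnosed_gene"].isin(genes).to_numpy(int)

    counts = []
    for g in GROUP3:
        mask = group == g
        counts.append([int(in_set[mask].sum()), int((mask).sum() - in_set[mask].sum())])
    table = np.array(counts)
    results = []
    if (table.sum(axis=1) == 0).any():
        empty = [g for g, r in zip(GROUP3, table) if r.sum() == 0]
        results.append(EnrichmentResult(
            unit=set_name, contrast="overall", odds_ratio=np.nan, ci95=(np.nan, np.nan),
            p=np.nan, table=table, n=len(diag), method="fisher_kx2", converged=False,
            note=f"empty group(s): {empty}",
        ))
        return results
    p_overall = kx2_fisher_exact(table)
    results.append(EnrichmentResult(
        unit=set_name, contrast="overall", odds_ratio=np.nan, ci95=(np.nan, np.nan),
        p=p_overall, table=table, n=len(diag), method="fisher_kx2",
    ))
    term_row = table[0]
    for gi, g in enumerate(GROUP3[1:], start=1):
        sub = np.array([table[gi], term_row])
        orr = stats.contingency.odds_ratio(sub)
        ci = orr.confidence_interval(0.95)
        results.append(EnrichmentResult(
            unit=set_name, contrast=f"{g}_vs_term",
            odds_ratio=float(orr.statistic), ci95=(float(ci.low), float(ci.high)),
            p=float(stats.fisher_exact(sub)[1]), table=sub,
            n=int(sub.sum()), method="fisher_exact",
        ))
    return results


def power_to_detect(
    n_diagnosed: int,
    carriers: int,
    baseline_preterm_frac: float,
    odds_ratio: float,
    alpha: float,
    n_sims: int = 500,
    seed: int = 0,
) -> float:
    """Monte-Carlo power of the per-gene prematurity test.

    Simulates carrier / non-carrier preterm counts with the carrier
    preterm probability implied by the odds ratio, applies the Wald test
    on the 2 x 2 log odds ratio (the single-binary-predictor logistic
    model in closed form; Haldane 0.5 correction on zero cells), and
    returns the fraction of simulations significant at ``alpha``.
    """
    if not 0 < baseline_preterm_frac < 1:
        raise DataError("baseline_preterm_frac must lie in (0, 1)")
    if carriers == 0:
        return 0.0
    if carriers > n_diagnosed:
        raise DataError("carriers cannot exceed n_diagnosed")
    rng = np.random.default_rng(seed)
    p0 = baseline_preterm_frac
    odds1 = odds_ratio * p0 / (1 - p0)
    p1 = odds1 / (1 + odds1)
    non = n_diagnosed - carriers
    a = rng.binomial(carriers, p1, size=n_sims).astype(float)
    c = rng.binomial(non, p0, size=n_sims).astype(float)
    b, d = carriers - a, non - c
    cells = np.stack([a, b, c, d])
    zero = (cells == 0).any(axis=0)
    cells = cells + 0.5 * zero  # Haldane correction only where needed
    a, b, c, d = cells
    log_or = np.log(a * d / (b * c))
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    p = 2 * stats.norm.sf(np.abs(log_or / se))
    return float((p < alpha).mean())
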