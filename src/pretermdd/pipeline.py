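"""Pipeline orchestration: configuration, stage execution, manifests.

``run_pipeline`` executes the enabled stages in dependency order —
synthetic-data generation, phenotype derivation, phenotype association
battery, milestone survival analysis, DNM burden, diagnostic
enrichment, genetic-score associations — writing per-stage TSVs, a JSON
run manifest (seed, inputs, the machine-readable ledger of every fitted
model), and a plain-text summary. Reruns with the same configuration
and seed are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import associations as assoc
from . import dnm as dnm_mod
from . import enrichment as enr
from . import ontology as ont
from . import scores as sc
from . import simulate as sim
from .config import MilestoneParams, SimConfig, TrioParams
from .exceptions import ConfigurationError, DataError
from .io import write_tsv

logger = logging.getLogger(__name__)

STAGES = ("simulate", "phenotypes", "associations", "milestones", "dnm",
          "enrichment", "scores")

_KNOWN_TOP = {"seed", "outdir", "stages", "simulate", "inputs", "options"}


@dataclasses.dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "pretermdd_out"
    stages: dict = dataclasses.field(default_factory=lambda: {s: True for s in STAGES})
    simulate: dict = dataclasses.field(default_factory=dict)
    inputs: dict = dataclasses.field(default_factory=dict)
    options: dict = dataclasses.field(default_factory=dict)


def validate_config(path) -> RunConfig:
    """Parse and schema-check a YAML run configuration.

    All problems are collected and reported in a single error.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    errors: list[str] = []
    if not isinstance(raw, dict):
        raise ConfigurationError("config must be a YAML mapping")
    for key in raw:
        if key not in _KNOWN_TOP:
            errors.append(f"unknown key {key!r}")
    seed = raw.get("seed", 0)
    if not isinstance(seed, int) or isinstance(seed, bool) or seed < 0:
        errors.append(f"seed must be a non-negative integer, got {seed!r}")
    stages = {s: True for s in STAGES}
    for s, on in (raw.get("stages") or {}).items():
        if s not in STAGES:
            errors.append(f"unknown stage {s!r}")
        elif not isinstance(on, bool):
            errors.append(f"stage toggle {s!r} must be boolean")
        else:
            stages[s] = on
    inputs = raw.get("inputs") or {}
    for name, p in inputs.items():
        if p is not None and not Path(p).exists():
            errors.append(f"input path for {name!r} does not exist: {p}")
    if not stages.get("simulate", True):
        if stages.get("phenotypes") and not inputs.get("ontology"):
            errors.append("phenotypes stage enabled without simulate: "
                          "inputs.ontology is required")
        if stages.get("phenotypes") and not inputs.get("cohort"):
            errors.append("phenotypes stage enabled without simulate: "
                          "inputs.cohort is required")
        if stages.get("dnm") and not (inputs.get("dnms") and inputs.get("rates")):
            errors.append("dnm stage enabled without simulate: inputs.dnms "
                          "and inputs.rates are required")
    if errors:
        raise ConfigurationError("invalid configuration:\n- " + "\n- ".join(errors))
    return RunConfig(
        seed=seed,
        outdir=str(raw.get("outdir", "pretermdd_out")),
        stages=stages,
        simulate=raw.get("simulate") or {},
        inputs=inputs,
        options=raw.get("options") or {},
    )


def _sim_config(cfg: RunConfig) -> SimConfig:
    s = dict(cfg.simulate)
    trio = TrioParams(**s.pop("trio_params", {}))
    mile = MilestoneParams(**s.pop("milestone_params", {}))
    s.pop("n_genes", None)
    return SimConfig(seed=cfg.seed, trio_params=trio, milestone_params=mile, **s)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the enabled stages; returns the run manifest."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": cfg.seed, "stages": {}, "models": [], "outputs": {},
                      "ledgers": {}}
    simcfg = _sim_config(cfg)
    n_genes = int(cfg.simulate.get("n_genes", 60))

    if not cfg.stages.get("simulate", True) and cfg.inputs.get("cohort"):
        cohort = pd.read_csv(cfg.inputs["cohort"], sep="\t")
        rates = pd.read_csv(cfg.inputs["rates"], sep="\t") if cfg.inputs.get("rates") else None
        dnms = pd.read_csv(cfg.inputs["dnms"], sep="\t") if cfg.inputs.get("dnms") else None
        trios = variants = None
    else:
        cohort = sim.simulate_cohort(simcfg)
        rates = sim.synthetic_gene_rate_table(n_genes=n_genes, seed=cfg.seed)
        dnms = sim.simulate_dnms(cohort, rates, simcfg)
        cohort = sim.simulate_milestones(cohort, simcfg)
        trios = sim.simulate_trios(cohort, simcfg)
        variants = sim.simulate_rare_variants(cohort, n_genes=max(n_genes // 2, 1),
                                              seed=cfg.seed)
        if cfg.stages.get("simulate", True):
            write_tsv(cohort, out / "cohort.tsv")
            write_tsv(rates, out / "gene_rates.tsv")
            write_tsv(dnms, out / "dnms.tsv")
            write_tsv(variants, out / "rare_variants.tsv")
            manifest["stages"]["simulate"] = {
                "n_probands": len(cohort), "n_genes": n_genes, "n_dnms": len(dnms),
            }

    graph, roots = ont.toy_ontology()
    osm = ont.assign_organ_systems(graph, roots)

    if cfg.stages.get("phenotypes", True):
        rng = simcfg.rng("hpo_annotation")
        mapped_terms = sorted(osm.assignment)
        n_terms = rng.poisson(
            2.0 + 1.0 * (cohort["prematurity_category"] != "term").astype(float)
        ) if len(cohort) else np.zeros(0, int)
        terms_col = [
            ";".join(sorted(rng.choice(mapped_terms, size=k, replace=True)))
            if k else "" for k in n_terms
        ]
        pheno = cohort.copy()
        pheno["hpo_terms"] = terms_col
        pheno["n_affected_systems"] = [
            ont.count_affected_systems(t.split(";") if t else [], osm)
            for t in terms_col
        ]
        ref = ont.LmsReference(sim.synthetic_lms_reference())
        pheno["birthweight_z"] = [
            ont.birthweight_zscore(r.birthweight_g, r.sex, r.gestational_weeks, ref)
            for r in pheno.itertuples()
        ] if len(pheno) else []
        n_before = len(pheno)
        pheno = ont.filter_birthweight_outliers(pheno, ref)
        write_tsv(pheno, out / "phenotypes.tsv")
        manifest["stages"]["phenotypes"] = {
            "n": len(pheno), "outliers_removed": n_before - len(pheno),
        }
        cohort = pheno

    if cfg.stages.get("associations", True):
        cohort = cohort.copy()
        cohort["low_birthweight"] = (cohort["birthweight_g"] < 2500).astype(int)
        specs = []
        for outcome, family in (
            ("low_birthweight", "binary"),
            ("birthweight_g", "continuous"),
        ):
            for gest in ("categorical", "continuous"):
                specs.append(assoc.ModelSpec(outcome=outcome, family=family,
                                             gestation=gest))
        if "n_affected_systems" in cohort.columns:
            specs.append(assoc.ModelSpec(outcome="n_affected_systems", family="count"))
        frames = []
        for spec_i, spec in enumerate(specs):
            for interaction in (False, True):
                fit = (assoc.fit_interaction_model if interaction
                       else assoc.fit_phenotype_model)
                try:
                    res = fit(cohort, spec)
                except DataError as exc:
                    logger.warning("model %s skipped: %s", spec.outcome, exc)
                    continue
                model_id = f"m{spec_i:02d}{'x' if interaction else ''}"
                manifest["models"].append({
                    "model_id": model_id, "outcome": spec.outcome,
                    "family": spec.family, "gestation": spec.gestation,
                    "interaction": interaction,
                })
                frames.append(assoc.results_to_frame(
                    res, model_id=model_id, outcome=spec.outcome,
                    cohort=simcfg.cohort_label,
                ))
        table = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
        write_tsv(table, out / "associations.tsv")
        n_models = len(manifest["models"])
        manifest["ledgers"]["associations"] = {
            "n_models": n_models,
            "bonferroni": assoc.bonferroni_threshold(max(n_models, 1)),
        }
        manifest["stages"]["associations"] = {"n_results": len(table)}

    if cfg.stages.get("milestones", True):
        milestones = [c[:-7] for c in cohort.columns if c.endswith("_months")]
        rows = []
        for m in milestones:
            t = cohort[f"{m}_months"]
            e = cohort[f"{m}_event"]
            try:
                _, stat, p = assoc.km_logrank(t, e, cohort["prematurity_category"])
            except DataError as exc:
                rows.append({"milestone": m, "term": "logrank", "estimate": np.nan,
                             "se": np.nan, "p": np.nan, "note": str(exc)})
                continue
            rows.append({"milestone": m, "term": "logrank", "estimate": stat,
                         "se": np.nan, "p": p, "note": ""})
            for r in assoc.cox_milestone_model(cohort, f"{m}_months", f"{m}_event"):
                rows.append({"milestone": m, "term": r.term, "estimate": r.estimate,
                             "se": r.se, "p": r.p, "note": r.note})
        write_tsv(pd.DataFrame(rows), out / "milestones.tsv")
        manifest["ledgers"]["milestones"] = {
            "logrank_bonferroni": assoc.bonferroni_threshold(4),
            "cox_bonferroni": assoc.bonferroni_threshold(24),
        }
        manifest["stages"]["milestones"] = {"n_milestones": len(milestones)}

    if cfg.stages.get("dnm", True) and dnms is not None and rates is not None:
        burden = dnm_mod.run_dnm_analysis(cohort, dnms, rates)
        write_tsv(burden, out / "dnm_burden.tsv")
        write_tsv(burden.attrs["af_comparisons"], out / "dnm_af_comparisons.tsv")
        manifest["ledgers"]["dnm"] = {
            "excess_bonferroni": burden.attrs["bonferroni_excess"],
            "af_bonferroni": burden.attrs["bonferroni_af"],
        }
        manifest["stages"]["dnm"] = {"lambda": burden.attrs["lambda"],
                                     "n_strata": len(burden)}

    if cfg.stages.get("enrichment", True) and rates is not None:
        rng = simcfg.rng("diagnosis_genes")
        diag_pro = cohort[cohort["diagnosed"] == 1]
        genes = sorted(rates["gene"].unique())
        probs = rng.dirichlet(np.full(len(genes), 0.3))
        diag = pd.DataFrame({
            "proband_id": diag_pro["proband_id"].to_numpy(),
            "diagnosed_gene": rng.choice(genes, size=len(diag_pro), p=probs),
            "tier": rng.choice(["P/LP", "broader"], size=len(diag_pro), p=[0.8, 0.2]),
            "preterm": (diag_pro["prematurity_category"] != "term").astype(int).to_numpy(),
            "gestational_category": diag_pro["prematurity_category"].astype(str).to_numpy(),
        })
        min_count = int(cfg.options.get("min_gene_count", 30))
        testable = enr.select_testable_genes(diag, min_count=min_count)
        rows = []
        for g in testable:
            r = enr.per_gene_prematurity_association(diag, g)
            rows.append({"unit": g, "contrast": r.contrast, "odds_ratio": r.odds_ratio,
                         "p": r.p, "method": r.method, "note": r.note})
        ddg2p = rates.loc[rates.get("gene_set") == "DDG2P", "gene"].unique() \
            if "gene_set" in rates.columns else []
        if len(ddg2p):
            for r in enr.gene_set_fisher(diag, ddg2p, set_name="DDG2P"):
                rows.append({"unit": r.unit, "contrast": r.contrast,
                             "odds_ratio": r.odds_ratio, "p": r.p,
                             "method": r.method, "note": r.note})
        write_tsv(pd.DataFrame(rows), out / "enrichment.tsv")
        manifest["ledgers"]["enrichment"] = {
            "per_gene_bonferroni": assoc.bonferroni_threshold(max(len(testable), 1)),
            "gene_set_bonferroni": assoc.bonferroni_threshold(
                4 * enr.TESTS_PER_GENE_SET),
        }
        manifest["stages"]["enrichment"] = {"n_testable_genes": len(testable),
                                            "n_diagnosed": len(diag)}

    if cfg.stages.get("scores", True) and trios is not None:
        rng = simcfg.rng("pcs")
        n = len(cohort)
        pcs = pd.DataFrame(rng.standard_normal((n, 20)),
                           columns=[f"PC{i}" for i in range(1, 21)],
                           index=cohort.index)
        data = pd.concat([cohort.reset_index(drop=True),
                          pcs.reset_index(drop=True)], axis=1)
        data["gd_rint"] = sc.rint(data["gestational_weeks"]
                                  + rng.uniform(0, 1e-9, size=n))  # tie-break jitter
        weights = pd.DataFrame({
            "variant_id": trios.child.columns,
            "effect_allele": "A", "other_allele": "G",
            "weight": trios.weights,
        })
        child_pgs = sc.compute_pgs(trios.child, weights)
        data["pgs_child"] = child_pgs.to_numpy()
        rows = []
        for stratum in ("all", "diagnosed", "undiagnosed"):
            try:
                res = sc.gd_score_regression(data, "pgs_child", stratum=stratum)
            except DataError as exc:
                logger.warning("score model (%s) skipped: %s", stratum, exc)
                continue
            for r in res:
                rows.append({"stratum": stratum, "term": r.term, "estimate": r.estimate,
                             "se": r.se, "p": r.p, "n": r.n})
        mother_pgs = sc.compute_pgs(trios.mother, weights)
        father_pgs = sc.compute_pgs(trios.father, weights)
        for r in sc.trio_decomposition(child_pgs, mother_pgs, father_pgs,
                                       data["gd_rint"]):
            rows.append({"stratum": "trios", "term": r.term, "estimate": r.estimate,
                         "se": r.se, "p": r.p, "n": r.n})
        write_tsv(pd.DataFrame(rows), out / "score_associations.tsv")
        manifest["ledgers"]["scores"] = {
            "bonferroni": assoc.bonferroni_threshold(15),
        }
        manifest["stages"]["scores"] = {"n_results": len(rows)}

    for p in sorted(out.glob("*.tsv")):
        manifest["outputs"][p.name] = _sha256(p)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    summary = [f"pretermdd run (seed={cfg.seed})"]
    for stage, info in manifest["stages"].items():
        summary.append(f"  {stage}: {info}")
    (out / "summary.txt").write_text("\n".join(summary) + "\n")
    return manifest
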