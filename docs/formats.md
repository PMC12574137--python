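# On-disk formats

All tables are tab-separated with a header row. Gene sets travel as
GMT (`name<TAB>description<TAB>gene1<TAB>gene2...`), ontologies as OBO
(is_a edges only; obsolete terms ignored), term lists as
newline-delimited files, and run configurations as YAML.

## Cohort table (`cohort.tsv`)

| column | type | notes |
|---|---|---|
| proband_id | str | unique |
| cohort_label | str | standardisation / meta-analysis grouping |
| sex | int | 1 = male, 0 = female |
| gestational_weeks | int | completed weeks, 22–44 |
| prematurity_category | str | term / moderate / very / extreme (WHO rule) |
| birthweight_g | float | grams |
| maternal_age_years | float | |
| age_at_assessment_years | float | |
| diagnosed | int | 0/1 monogenic diagnosis |
| hpo_terms | str | `;`-joined term IDs, may be empty |
| deprivation_index | float | optional covariate |
| `<milestone>_months`, `<milestone>_event` | float, int | added by the milestone simulator; event 0 = censored |

## Gene rate table (`gene_rates.tsv`)

`gene`, `consequence_class` (synonymous / missense / ptv), `mu`
(expected DNMs per proband per generation, diploid-scaled),
optional `gene_set` (DDG2P / non-DDG2P).

## DNM table (`dnms.tsv`)

One row per mutation: `proband_id`, `gene`, `consequence_class`.
Group labels are joined from the cohort at analysis time.

## Rare-variant table (`rare_variants.tsv`)

`proband_id`, `gene`, `consequence` (ptv / missense / ...), `loftee`
(HC / LC / empty), `mpc`, `pli`, `gnomad_max_maf` (max over
super-populations), `cohort_maf`, `inherited` (bool), `autosomal`
(bool), `zygosity` (het / hom).

## Scoring file (PGS-catalog-style)

`variant_id`, `effect_allele`, `other_allele`, `weight`. Dosage tables
are individuals × variant-ID matrices of effect-allele counts in
[0, 2]; an optional allele sidecar (`variant_id`, `a1`, `a2`) declares
which allele the dosage counts.

## Diagnosis table (enrichment input)

`proband_id`, `diagnosed_gene` (single-gene diagnoses only), `tier`
(`P/LP` = clinically confirmed, else broader), `preterm` (0/1),
`gestational_category`.

## Results

Association results: `term`, `estimate` (log-odds / mean difference /
log IRR / log HR), `se`, `p`, `n`, `family`, `converged`, `note`, plus
`model_id` / `outcome` / `cohort` context columns. The DNM burden table
mirrors the stratified analysis (gestation group × proband group ×
gene set with O, E, λ, excess p, AF and its CI); the run manifest
(`manifest.json`) records the seed, every fitted model, the
multiplicity ledgers and SHA-256 hashes of all written tables.
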