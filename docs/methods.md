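# Methods

## Scope and model

`sigreverse` chains four statistical procedures around one scientific idea:
a transcriptional disease signature (here, hepatic stellate cell
activation) can be *reversed* by a drug, and candidate reversers can be
found by scoring the signature against a corpus of drug-perturbation
expression rankings. The stages are independent models with a
`Model.fit() -> Results` surface:

1. `SignatureModel` — permutation-t-test differential expression with FDR
   control, yielding a directional up/down tag-list signature;
2. `ConnectivityScreen` — KS tag-enrichment connectivity of that signature
   against an instances × genes rank database, aggregated to compounds with
   permutation p-values;
3. `GeneSetOverlap` — exact hypergeometric overlap of two gene sets in a
   protein-coding background;
4. `BiomarkerSurvival` — mean+1SD biomarker stratification compared by
   Kaplan–Meier estimation and the log-rank test.

## Differential expression

The test statistic is the Welch (unequal-variance) t, case minus control.
The reference distribution is the permutation null over random group-label
shuffles, shared across genes within a call, with the add-one estimator
`p = (1 + #{|t*| ≥ |t_obs|})/(1 + B)` so p never returns 0 and is valid at
any B. Defaults: B = 1,000; the seed is mandatory wherever randomness
enters. A gene constant across all samples is flagged
(`zero_variance = True`) and assigned t = 0, p = 1 rather than dropped; a
zero-variance gene with unequal group means gets t = ±inf, which compares
correctly inside the permutation count. FDR adjustment is
Benjamini–Hochberg step-up (via statsmodels). Signature construction keeps
genes with q < threshold (default 0.05), splits by sign(t), and optionally
maps through an ortholog table; only one-to-one orthologs are translated —
zero- or multi-partner genes are dropped and counted in a mapping report,
because expanding many-to-many orthologs would double-count tags in the KS
statistic. A signature left one-sided after selection or mapping is usable
but flagged with a warning.

## Connectivity scoring

Rank convention: rank 1 = most up-regulated by the treatment. For a tag
list of size t in a ranking of n genes with sorted tag ranks V(j),

    a = max_j [ j/t − V(j)/n ],  b = max_j [ V(j)/n − (j−1)/t ],
    ES = a if a ≥ b else −b.

Ties (a = b) resolve to the positive side. Note two consequences of this
classic form: ES is not exactly antisymmetric under list reversal (for a
single tag, ES(k) + ES(n+1−k) = −1/n away from the odd-n midpoint — the
property tests assert this exact duality), and the degenerate t = n case
yields −1/n, not 0.

Per instance, `raw = ES_up − ES_down` if the two sides differ in sign (a
zero counts as opposite to either), else 0; a missing direction contributes
0, which is also the escape hatch for single-list queries
(`--collapse-direction`). Raw scores are rescaled per side — positives by
the maximum positive, negatives by |minimum negative| — into [−1, 1].
Compound enrichment orders all instances by raw score (descending, ties
broken by instance id ascending for bit-reproducibility) and applies the
same KS statistic to the compound's instance positions. Its p-value draws B
random same-size instance subsets (default B = 10,000, seeded) and is
two-sided on |ES| by default; the screen then selects enrichment < 0 and
p ≤ alpha (default 0.05), sorted most-negative first. One-sided p-values
(`p_sided: one`) are available as a config option. Tags absent from the
database universe are dropped with a warning and the effective tag size is
reported; an entirely absent tag list is an error.

## Overlap statistics

Point probability P(X = k) and upper tail P(X ≥ k) are both always
reported: a lone printed "hypergeometric p" is ambiguous between the two
readings (for the 160/122/20,354 worked example they are 0.37 and 0.62),
so the report labels each rather than preferring one. Probabilities come
from scipy's log-space hypergeometric and are validated against exact
big-integer binomial arithmetic over all parameters with N ≤ 60. Expected
overlap is K·n/N. The background is ideally an explicit gene universe (sets
are restricted to it, with warnings for dropped symbols); a bare background
size of 20,354 protein-coding genes ships as the documented headless
default.

## Survival

Dichotomization uses mean + 1 sample SD (n−1 denominator) with a strict
`>`; the rule is recorded in the output metadata since "higher than one SD
above the mean" leaves both choices open. A zero-SD cohort is all-"low"
with a warning. The Kaplan–Meier estimator and two-group log-rank test are
implemented directly because the results objects carry per-event-time risk
sets and per-group observed/expected totals; both are cross-checked against
lifelines in the test suite and the log-rank against an independent
2×2-table-iterating oracle. Tied event times are pooled at a single
risk-set update; censored subjects leave the risk set just after their
time. The log-rank p comes from chi-square with 1 df.

## Synthetic data

`SimulationConfig` drives three generators, each on its own RNG stream
derived from the master seed by a fixed offset (adding a generator never
perturbs another's output; all outputs are bit-reproducible given the
config).

* **Expression**: null genes Normal(0, noise SD) in both groups; planted
  genes get a ±effect·SD mean shift in cases (effect 2.0 SD by default,
  `de_fraction_up` controls the direction split). This emulates a
  normalized two-group microarray; it has no probe-level noise, batch
  structure, gene–gene correlation or heavy tails, so passing tests
  demonstrate correctness of the inference machinery, not robustness to
  real microarray artifacts.
* **Rank database**: null instances are independent uniform permutations.
  A planted antagonist starts from a uniform permutation and displaces the
  signature's up-tags toward the bottom and down-tags toward the top by
  geometric interpolation, key = r^(1−s)·target^s with targets n+0.5 /
  0.5, followed by a stable re-rank — at strength s = 1 tags are fully
  displaced past every non-tag gene, at s = 0 the instance is exactly null.
  Agonists mirror the displacement. Doses and cell lines are constant
  placeholders; the real corpus's dose/cell-line design is not modelled.
* **Survival**: biomarker Normal(0, 1); subjects above mean + 1 sample SD
  get exponential event times at the baseline hazard (0.1 per time unit),
  the rest at baseline × hazard ratio (2.5 by default — high expression
  protective); a configured fraction of subjects (30%) is censored at a
  uniform fraction of its event time, making censoring independent of the
  biomarker but not of follow-up length.

Defaults emulate the study shapes the pipeline targets: a 2,000-gene,
10 + 10-sample two-group matrix; a 200-instance, 40-compound rank corpus;
a 216-patient cohort.

## Validation scales and numerical choices

The acceptance checks and `scripts/acceptance.py` use these problem sizes,
chosen as the smallest scales at which each statistical claim is
well-powered:

* Null p-value uniformity: 2,000 genes, 10 vs 10, B = 1,000 (KS test
  against Uniform(0,1)).
* Planted-DE recovery: 200 genes with 50 planted 2-SD effects, 10 vs 10,
  B = 1,000, FDR 0.05. A power analysis of the Welch/BH combination at
  these sample sizes shows ≥ 90% sensitivity requires a focused panel:
  mean sensitivity is ≈ 0.95 at 200 genes but falls to ≈ 0.67 at 2,000
  genes because the BH cutoff tightens with the number of tests while the
  per-gene noncentrality stays fixed. The 200-gene panel is therefore the
  documented recovery condition; specificity (null genes selected) stays
  ≈ 1% there.
* Screen calibration: 200 null compounds (2 instances each, 400 instances,
  500-gene universe), B = 1,000 — the fraction of compounds at p ≤ 0.05 is
  checked against 0.05 ± 3 binomial SEs. Planted recovery: a strength-1
  antagonist owning 5 of 200 instances among 40 compounds, selected in
  ≥ 18/20 seeds.
* Survival: 500 replicates of 200-per-group exponential cohorts with 30%
  censoring — null rejection within 3 binomial SEs of 0.05 and power
  ≥ 0.95 at hazard ratio 2.5.

Other numerical choices: permutation p-values never return 0 (add-one);
KS ties resolve positive; instance-order ties resolve by id; BH q-values
are returned in input order; gene symbols match case-insensitively with
original case preserved on output; TSV dialect is UTF-8, tab-separated,
`#` comments, no quoting.

## Known limitations

* The screen validates by planted-truth recovery and calibration only; the
  published compound list from the real perturbation corpus is not
  reproducible without that corpus and is not a claim of this package.
* Signature size on real accession data is recorded but not asserted — it
  depends on the upstream normalization pipeline, which is out of scope.
* No Cox regression, covariate adjustment or competing risks in the
  survival stage; no dose–response or cell-line-stratified connectivity
  scoring; no microarray preprocessing or batch correction.
* Permutation p-values are exchangeability-based; with strong
  heteroscedasticity between groups the label-shuffle null is approximate
  even though the Welch statistic is used.
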