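# Methods

## Scope and data model

The unit of analysis is the gene target–indication pair. Each pair
carries an ordinal latest development phase (0 preclinical, 1–3
clinical, 4 US/EU approved, or unknown), an approval flag, an
active-development flag, and genetic-evidence scores per source (GWAS
and curated/OMIM-style associations are always analyzed separately,
since their effects differ systematically). All tables are plain TSV
with documented columns; nothing in the package touches proprietary
exports or network services.

## Ontology similarity

Headings form a rooted DAG; edges point from broader to narrower terms.
Information content uses descendant counts over the full DAG (a node
reachable along several paths counts once):

    IC(c) = −ln((|descendants(c)| + 1) / N)

so the root (which subsumes everything) has IC 0 and leaves are maximal.
Natural logarithms are used; the base only rescales IC by a constant
that cancels in Lin similarity and in per-trait-normalized Resnik
similarity.

The combined similarity for a pair (t₁, t₂) is the mean of

* Lin: 2·IC(MICA)/(IC(t₁) + IC(t₂)), and
* normalized Resnik: IC(MICA)/IC(t), computed per argument order and
  averaged over the two orders,

clipped to [0, 1]. The normalization makes every non-root term's
self-similarity exactly 1. The hierarchy alone cannot relate a disease
to its quantitative endophenotype (e.g. osteoporosis vs. bone density),
so the similarity function accepts a manual-override table; overrides
are provenance-flagged and every evaluation can be rerun with them
excluded to measure their influence.

Design choices made where the convention was genuinely open:

* MICA ties are broken lexicographically so results are deterministic.
* Per-trait Resnik normalization divides by the *first* argument's IC
  and symmetrizes by averaging the two orders (rather than normalizing
  by a max over all partners); this is the variant for which
  self-similarity is identically 1.
* Pairs involving the root (IC 0) score 0, including the root's
  self-pair, since they cannot be normalized.

## Gene–trait links

Curated links are used directly after removing provisional,
drug-response, and somatic-variant entries. SNP-level associations are
filtered to genome-wide significance (p ≤ 10⁻⁸, boundary kept), lead
SNPs are LD-expanded (r² ≥ 0.5, inclusive; every lead is its own
partner at r² = 1), and LD SNPs map to genes through three channels:

* distance — SNP position within a closed 5000 bp window around the
  gene body [start, end], 1-based coordinates;
* eQTL — any tissue record with p strictly below 10⁻⁶ (a 10⁻¹²
  variant is a supported configuration);
* DHS correlation — permutation p at or below a configurable cutoff.
  The upstream description of this filter is internally inconsistent
  ("permutation p-value 1.000 from 1000 replicates"); the default
  cutoff is 0.001, the resolution of a 1000-replicate test, and the
  value is exposed as a flag rather than guessed at.

Links to non-protein-coding genes are dropped; duplicates on
(gene, trait, source) collapse with channels accumulated and dates
kept as [earliest, latest] contributing association dates. Each GWAS
link records the maximum r² from a contributing lead SNP to an LD
partner with HIGH or MODERATE predicted consequence; the
"deleterious subset" keeps GWAS links with that value ≥ 0.9
(inclusive), emulating the coding-variant-proximal slice where
SNP-to-gene assignment is most trustworthy. LD itself is an input
table: computing r² from genotype panels is out of scope.

## Evidence scores

E_C(g, t) is the maximum trait similarity between the indication and
the traits linked to the gene within one source; E_D thresholds it at
0.7 (boundary included). A 0.73 preset exists because recomputing
similarities under a different vocabulary version shifts the scale
slightly; 0.73 on the recomputed scale corresponds to 0.7 on the
original. A gene absent from the association set yields a distinct
no-association marker rather than 0: the approval model's evidence term
is switched by association *existence*, and a gene linked only to a
dissimilar trait (E_C = 0) must remain distinguishable from a gene with
no link at all.

Two-by-two analyses additionally require at least 5 associations to
traits similar to the indication. The reference data do not pin down
the set over which this count runs; the default counts associations
across all genes (per-indication gate), and a per-gene variant is
available via the `gene` argument.

## Phase assignment and collapse

Per drug–indication, the latest historical phase comes from (1) country
status for single-indication or preclinical drugs, then (2) the most
advanced phase implied by dated events, then (3) clinical-details
phrases only as a fallback (that field can describe planned trials).
Phrase-to-phase mapping is a configurable vocabulary table. A drug is
US/EU approved for an indication when it has a US or EU approval and
the indication is approved in any country — indication-level approval
data is not country-resolved, so partial approvals are knowingly
over-assigned. Unknown phases propagate as missing (never as 0):
two-by-two analyses exclude them, while the approval model keeps
unknown-phase unapproved pairs as failures. Collapse to pairs takes the
maximum phase over drugs, ORs the approval and activity flags, and is
idempotent and order-independent.

## Risk ratios and the bootstrap

For phases x > y, the risk ratio is
(N_ev,x/N_ev,y)/(N_no,x/N_no,y) with at-or-beyond counts; in-progress
programs are included. A zero denominator raises an explicit error
rather than yielding NaN. Confidence intervals are percentile
bootstrap, default 2000 replicates, resampling pairs with replacement;
since the statistic depends on the data only through the 2×5
(evidence × phase) contingency table, the resample is drawn as a
multinomial over cells — distributionally identical to pair resampling
and fast enough for coverage studies. Resamples with an undefined ratio
are dropped and counted; more than 50% undefined aborts. Pairs already
approved in the earlier snapshot cannot progress and are excluded from
progression testing.

Validation-set partitioning mirrors the two-snapshot design: pairs with
a known phase in the old snapshot form the progression set (outcome:
advanced by the new snapshot); pairs absent or unknown-phase in the old
snapshot form the new-pipeline set; the new-genetic analysis rescoring
uses only links whose latest contributing association postdates the
per-source cut dates (defaults 2013-05-21 for GWAS, 2013-10-01 for
curated links).

## Approval model

    yᵢ ~ Bernoulli(logit⁻¹(α + ηᵢ + xᵢ′β)),
    ηᵢ = Σ_{j=0..p} γⱼ z(E_C(gᵢ,tᵢ))ʲ  if the gene has any association,
         0 otherwise

with p = 2 by default, one η block (existence indicator + γ vector) per
evidence source in a single joint model, and priors α ~ N(−2.2, 0.75²)
— logit⁻¹(−2.2) ≈ 0.0997, the long-run fraction of Phase I compounds
reaching approval — and β, γ ~ N(0, 2²). Continuous covariates and E_C
are standardized to mean 0, SD 1; E_C standardization uses the pairs
whose gene has an association (the only pairs where E_C enters the
linear predictor; an all-pairs variant is a flag). One-hot encoding
drops the alphabetically first level; levels with fewer than 20 pairs
pool into "other". Missing continuous covariates are imputed at the
standardized mean with a missingness-indicator column. The model
universe keeps pairs that are approved or have no active drug (an
active unapproved program has an unresolved outcome) and keeps
unknown-phase unapproved pairs with y = 0.

### Sampler

The posterior is sampled with an independence Metropolis–Hastings
kernel: the proposal is a multivariate t (df 8) centered on the
posterior mode (found by L-BFGS) with the Laplace inverse-Hessian
covariance inflated by 1.2. Warmup doubles as one adaptation round —
pilot chains run with the Laplace proposal and the final proposal is
moment-matched to the pooled pilot draws, after which the kernel is
fixed, so the kept phase is exact MCMC regardless of approximation
quality. Because proposals are state-independent, all density
evaluations vectorize and only the accept/reject scan is sequential; a
fit at N = 4000 with ~15 parameters takes about a second. Defaults: 4
chains, 500 warmup + 1500 kept draws each. Convergence is enforced, not
assumed: split-R̂ ≤ 1.01 and ESS ≥ 400 per parameter (ArviZ), with a
hard error otherwise. For this posterior — smooth, unimodal,
low-dimensional logistic regression with Gaussian priors — the Laplace
proposal keeps acceptance near 50% and draws nearly independent.

WAIC is computed on the deviance scale, −2(lppd − p_WAIC), with p_WAIC
the summed pointwise posterior variance of log-likelihood and SE from
the pointwise spread, on up to 1000 subsampled draws (cross-checked
against ArviZ in the tests). Odds-ratio curves evaluate exp(η(s)) per
draw over a similarity grid, reporting pointwise median and 95%
credible band relative to the no-association reference (η = 0).

## Synthetic data

The generator emulates every input: a random rooted DAG with
cross-links (so multi-parent MICA search is exercised), a gene universe
with coordinates, coding flags, RVIS percentiles (10% missing) and
development dates, dated GWAS/curated association tables with LD, eQTL,
DHS, and consequence side tables, and drug bundles over two snapshots.
Approval outcomes are drawn from the package's own logistic model:
E_C for each sampled pair is computed through the real
similarity/evidence code, the linear predictor uses generating
parameters on the standardized scale, and phases are back-filled
consistently (approved ⇒ 4; otherwise sampled from configurable
marginals and realized through country status, events, or
clinical-details phrases so each precedence branch is exercised).
Defaults encode the study conditions: α = −2.2 (≈10% baseline
approval), quadratic evidence terms per source, association dates
straddling the 2013 cut dates, a 30% deleterious-partner fraction, and
a 20% snapshot-progression fraction. Everything is deterministic under
the seed, to the byte in the written files.

What the generator does **not** emulate — and hence what green tests do
not establish about real data: realistic LD structure (partners are
synthetic labels, not population haplotypes), realistic ontology
topology or term frequencies, correlations between covariates and
evidence (covariate classes are drawn independently), informative
missingness, and any confounding not representable in the fitted model.
Passing recovery tests show the statistical machinery is correct and
calibrated on data from its own model class, not that the model is
correct for pipeline data.

## Problem sizes in the tests and acceptance script

Parameter recovery runs 20 seeds at N = 4000 pairs (the test suite) and
10 seeds in the acceptance script; WAIC degree selection uses N = 1500;
bootstrap coverage uses 500 (tests) or 200 (script) replications of
n = 600 pairs with 2000 bootstrap resamples each; oracle equivalence
uses 200 random DAGs of ≤ 12 terms. These sizes give binomial noise
comfortably inside the asserted tolerances while keeping a full run in
tens of seconds.

A 100-seed calibration study of the recovery harness showed
per-coefficient 95%-interval coverage between 92% and 97%, consistent
with nominal frequentist calibration of Bayesian intervals at fixed
truth.

## Known limitations

* The independence sampler is tailored to unimodal, roughly Gaussian
  posteriors; it would mix poorly on multimodal targets. The diagnostic
  contract would catch this loudly rather than silently.
* Approval over-assignment for partially approved multi-indication
  drugs is inherited from the indication-level granularity of the data
  model.
* The similarity function is quadratic in vocabulary size when fully
  materialized; for large vocabularies evaluate lazily (the default) or
  restrict the pair list.
* Entrez/Ensembl identifier reconciliation, genome-assembly liftover,
  and r² computation from genotypes are deliberately out of scope; the
  corresponding tables are inputs.
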