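# genesupport

Tools for quantifying how **human genetic evidence** predicts whether a
drug **target–indication pair** reaches approval.

Drug programs whose target gene is genetically linked to a trait similar
to the treated indication succeed more often. This package implements
the full analysis chain needed to measure that effect on pipeline-style
data — and, because the real inputs (commercial pipeline databases, GWAS
Catalog, OMIM, LD and eQTL reference panels, the MeSH vocabulary) are
licensed or large, it ships a synthetic-data generator that emulates
every input with known ground truth, so the whole chain is testable at
the desk.

It is aimed at computational genomics / drug-discovery analysts who want
to score their own target–indication pairs or study the method itself.

## What it computes

**Trait similarity.** Traits and indications live in a rooted DAG of
headings (a MeSH-style hierarchy). Each heading's information content is
taken from its descendant count, IC(c) = −ln((|desc(c)|+1)/N). Pairwise
similarity S_T averages Lin similarity, 2·IC(MICA)/(IC(t₁)+IC(t₂)), with
Resnik similarity IC(MICA) normalized so each trait's self-similarity
is 1, and supports curated manual overrides.

**Genetic evidence.** Given an association set A of (gene, trait) links
— built from curated (OMIM-style) tables and from GWAS-style SNP
associations mapped to genes via LD expansion (r² ≥ 0.5) plus
distance (≤ 5000 bp), eQTL (p < 10⁻⁶) and DHS channels — continuous
evidence is

    E_C(g, t) = max { S_T(t, tₐ) : (g, tₐ) ∈ A },

the similarity between the indication and the most similar trait linked
to the gene, and binary evidence E_D(g,t) = 1 iff E_C(g,t) ≥ 0.7.

**Progression risk ratios.** With pairs carrying an ordinal latest phase
h ∈ {0..4} (0 preclinical … 4 US/EU approved), the risk ratio of
reaching phase x from phase y compares at-or-beyond proportions between
evidence strata, with percentile-bootstrap CIs.

**Approval model.** A Bayesian logistic regression

    yᵢ ~ Bernoulli(logit⁻¹(α + ηᵢ + xᵢ′β)),
    ηᵢ = Σⱼ γⱼ E_C(gᵢ,tᵢ)ʲ  if gene gᵢ has any association, else 0,

with priors α ~ N(−2.2, 0.75²) (a ~10% baseline approval rate),
β, γ ~ N(0, 2²), degree p = 2 (supported by WAIC), covariates =
indication class, target class, development time, RVIS. Output includes
posterior summaries and odds-ratio-vs-similarity curves with credible
bands.

## Worked example

```python
import numpy as np
from genesupport.simulate import SimulationConfig, simulate_model_dataset
from genesupport.approval_model import ModelSpec, fit_approval_model, odds_ratio_curve, waic
from genesupport.progression import progression_risk_ratio

ds = simulate_model_dataset(SimulationConfig(seed=42), n_pairs=2000)
print(f"pairs: {len(ds.y)}, approval rate: {ds.y.mean():.3f}")

fit = fit_approval_model(ds.y, ds.design, ModelSpec(seed=42))
print(f"max split-Rhat: {fit.rhat.max():.4f}, min ESS: {fit.ess.min():.0f}")
s = fit.summary().set_index("parameter")
for p in ["alpha", "gamma_OMIM[1]", "gamma_OMIM[2]"]:
    row = s.loc[p]
    print(f"{p:>15}: {row['median']:+.2f}  [{row['ci_low']:+.2f}, {row['ci_high']:+.2f}]")
w, se = waic(fit)
print(f"WAIC: {w:.1f} (SE {se:.1f})")
curve = odds_ratio_curve(fit, "OMIM")
for i, sim in ((100, 1.0), (0, 0.0)):
    row = curve.iloc[i]
    print(f"odds ratio at similarity {sim} (OMIM): "
          f"{row.or_median:.2f}  [{row.or_lo:.2f}, {row.or_hi:.2f}]")

omim = ds.evidence.loc[ds.evidence.source == "OMIM"]
data = ds.pairs.merge(omim, on=["gene_id", "indication"])
data["phase"] = np.where(data["y"] == 1, 4, 1)
data["evidence"] = (data["e_c"].fillna(0) >= 0.7).astype(int)
est = progression_risk_ratio(data, to_phase=4, from_phase=1, n_boot=2000, seed=42)
print(f"approval risk ratio (OMIM evidence): {est.rr:.2f}  [{est.ci_low:.2f}, {est.ci_high:.2f}]")
```

prints

```
pairs: 1882, approval rate: 0.123
max split-Rhat: 1.0075, min ESS: 1218
          alpha: -2.33  [-2.77, -1.89]
  gamma_OMIM[1]: +0.83  [+0.44, +1.25]
  gamma_OMIM[2]: -0.14  [-0.37, +0.07]
WAIC: 1272.3 (SE 55.2)
odds ratio at similarity 1.0 (OMIM): 5.73  [1.71, 17.27]
odds ratio at similarity 0.0 (OMIM): 0.90  [0.59, 1.35]
approval risk ratio (OMIM evidence): 3.34  [1.92, 4.95]
```

Read: the sampler converged (split-R̂ ≤ 1.01); the intercept puts the
baseline approval probability near 10%; the positive linear evidence
coefficient means approval odds rise with trait similarity — a pair
whose target has a curated link to a maximally similar trait has ~5.7×
the approval odds of a pair with no genetic association, while a link to
a completely dissimilar trait is, if anything, slightly unfavorable.
The classical two-by-two analysis on the same data gives a risk ratio
of 3.3 for binary evidence at the 0.7 cutoff.

## Command line

Every stage is also a subcommand (`genesupport simulate | similarity |
map-genes | assemble | score | partition | riskratio | fit | curve`),
and `genesupport run --config run.yaml` executes the whole chain into a
run directory with a manifest and a markdown report.

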