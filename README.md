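# vmtopics

Mixed-membership analysis of longitudinal vaginal microbiota profiles.

The vaginal microbiota is commonly summarized by assigning each sample to a
community state type (CST) — a single cluster label defined by the nearest
reference centroid. Cluster labels hide sub-structure within the diverse,
*Lactobacillus*-poor communities that are linked to preterm birth and
infection risk, they cannot represent gradual transitions, and they split
"functionally equivalent" species that occupy the same niche but rarely
co-occur into artificial extra clusters. `vmtopics` implements the
alternative: topic models (latent Dirichlet allocation), in which each topic
is a distribution over taxa (a sub-community, `β_k`) and each sample is a
mixture of topics with weights `γ_i` summing to 1,

```
counts_i ~ Multinomial(N_i,  Σ_k γ_ik β_k) ,   γ_i ~ Dir(α),   β_k ~ Dir(η).
```

It is written for microbiome researchers analysing longitudinal 16S count
tables together with daily bleeding diaries, pH, and immunoassay /
metabolomics panels.

## What it does

- **Topic inference** — blocked Gibbs sampling with an annealed-EM warm
  start; counts enter the likelihood directly (no normalization).
- **Topic alignment across resolutions** — product weights
  `W_{kk'} = (1/N) Σ_i γ^m_{ik} γ^{m+1}_{ik'}` connect models at K = 1…K_max;
  per-topic coherence and refinement scores select the working resolution.
- **Reference sub-CST comparison** — Bray–Curtis dissimilarity labels topics
  by nearest centroid; samples are assigned to the centroid maximizing the
  Yue–Clayton similarity θ.
- **Composition prediction** — `p̂ = γβ` vs the assigned centroid's
  composition, compared by per-sample Bray–Curtis and a paired t-test.
- **Stability & dominance-loss risk** — run-based local stability; weighted
  logistic prediction of losing *Lactobacillus* dominance (next-sample
  *Lactobacillus* total < 50%), evaluated by F1 over participant-grouped
  80/20 splits.
- **Menstrual cycles** — hidden semi-Markov segmentation of bleeding
  diaries, standardized cycledays −18…+7 (day 0 = first day of menses), RV
  coefficients with permutation tests for between-cycle agreement, and
  periodic-spline (4 d.f.) cyclicity tests for topics, metabolites and
  cytokines with Benjamini–Hochberg correction.
- **Host associations** — Dirichlet regression of participant-mean topic
  proportions on race, pregnancy and site; per-topic logistic regression for
  preterm birth.
- **Synthetic cohorts** — a first-class generator with ground truth for
  every stage (topic mixtures with AR(1) dynamics, participant-level
  mutually exclusive "synonym" genera, semi-Markov diaries, menses-coupled
  shifts, LOQ-censored cyclic assay signals).

See `docs/methods.md` for models, assumptions and numerical choices.

## Worked example

```python
import vmtopics as v

# simulate a 300-sample cohort with 6 known sub-communities
cohort = v.simulate_cohort(v.GeneratorConfig(seed=1))

# fit and label topics
fit = v.fit_lda(cohort.counts, K=6, seed=11)
labels, dissim = v.label_topics_fit(fit, v.default_centroids())
print(labels)

# compare mixed-membership vs nearest-centroid composition prediction
rel = v.to_relative(cohort.counts)
subcst = v.assign_subcst(rel, v.default_centroids())
rep = v.representation_error(
    rel, v.predict_from_topics(fit),
    v.predict_from_subcst(subcst, v.default_centroids(),
                          sample_ids=cohort.counts.sample_ids))
print(f"mean BC topics {rep.bc_topics.mean():.3f} "
      f"vs sub-CST {rep.bc_subcst.mean():.3f}  (p = {rep.p_value:.2e})")
```

Output:

```
{'T3': 'I', 'T6': 'II', 'T2': 'III', 'T5': 'IV-B', 'T4': 'IV-C', 'T1': 'V'}
mean BC topics 0.061 vs sub-CST 0.148  (p = 4.37e-19)
```

Each fitted topic maps onto one reference community type — the four
*Lactobacillus*-dominated types I/II/III/V, the diverse anaerobe type IV-B,
and IV-C, the topic holding the four mutually exclusive genera. The
mixed-membership prediction reconstructs sample composition substantially
more accurately than the single-centroid prediction (mean Bray–Curtis 0.06
vs 0.15, a ~0.09 mean difference).

The same pipeline runs end to end from the shell:

```bash
vmtopics run --seed 7 --outdir results/demo     # TSV artifacts + manifest
vmtopics report --outdir results/demo           # plain-text summary
```

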