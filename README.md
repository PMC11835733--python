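# bmidiscord

Probabilistic subclassification of BMI–biomarker discordance for
precision prediction of cardiometabolic disease.

People with the same BMI can carry very different cardiometabolic risk.
`bmidiscord` quantifies, for each individual, how far ten routine
biomarkers (fasting glucose, HDL, LDL, triglycerides, systolic/diastolic
blood pressure, serum creatinine, ALT, CRP, waist-to-hip ratio) deviate
from their BMI-based expectation — adjusted for age and smoking and
standardized within sex — and partitions the population into a
**concordant** profile plus **discordant** profiles (e.g. adverse-lipid,
hyperglycemic, hypertensive) by soft clustering on a nearest-neighbour
graph of the standardized deviations $\delta_i \in \mathbb{R}^{10}$:

- multivariate discordance per person: $D_i^2 = \delta_i^\top \Sigma^{-1}
  \delta_i \sim \chi^2_{10}$ under concordance;
- graph communities (leading-eigenvector seeds + repeated Leiden) become
  Gaussian components $(\mu_k, \Sigma_k)$ via eigenvector-centrality
  weighted moments; a fixed concordant component $(\mu = 0,\ \Sigma = I)$
  is always included; only the weights $\pi_k$ are fitted by EM;
- each individual gets allocation probabilities
  $p_{ik} = \pi_k \varphi(\delta_i; \mu_k, \Sigma_k) / \sum_j \pi_j
  \varphi(\delta_i; \mu_j, \Sigma_j)$, rows summing to 1;
- profiles are kept only if they replicate (median cross-allocation
  probability > 0.8) in every validation cohort;
- downstream, allocation probabilities weight descriptive statistics,
  prevalence/incidence, OR/RR regressions and meta-analysis, enter Cox
  models as log-contrasts $z_k = \ln(p_k / p_{\text{concordant}})$ for
  nested-model comparison (LRT, explained variation, ΔC), and feed
  decision-curve analysis (net benefit, net interventions avoided).

It is aimed at epidemiologists and biostatisticians who want to run the
full discordance-profiling pipeline on their own cohort tables, or to
study its behaviour on the built-in synthetic cohorts.

## Worked example

```python
import bmidiscord as bd

config = bd.default_config("separated", n_individuals=20_000, seed=7)
cohort, truth = bd.generate_cohort(config)

model = bd.DiscordanceProfileModel(cohort)
result = model.fit(seed=0, n_leiden=20)
print(result.summary())
```

```
BMI-discordance profile partition
==========================================================
stratum: female    n = 19996    profiles = 4
graph: nn = 15, modularity = 0.632
relative entropy (separation index): 0.976
----------------------------------------------------------
profile             weight  transitivity  top deviations
hdl_low              0.075         0.215  hdl=-2.36, tg=+2.36, ldl=+1.92
fg_high              0.058         0.227  fg=+2.75, ldl=-1.96, tg=-0.23
sbp_high             0.043         0.236  sbp=+2.79, dbp=+2.72, fg=-0.21
concordant           0.824         0.167  (none)
----------------------------------------------------------
substantial discordance: 8.6% observed vs 5.0% expected (binomial p = 7.49e-99)
```

The generator planted an 80% concordant population plus adverse-lipid
(8%), hyperglycemic (7%) and hypertensive (5%) profiles; the pipeline
recovers all three (named by their dominant deviation: low HDL with high
TG/LDL, high fasting glucose with low LDL, high blood pressure), with
weights close to — and, for the discordant profiles, characteristically
slightly below — the planted proportions (see `docs/methods.md` on the
fixed-identity reference bias). The separation index 0.976 means
allocations are nearly one-hot; the excess of multivariate discordance
over the 5% null expectation reflects the planted discordant mass.

Replication across cohorts and the survival/decision-curve layers follow
the same pattern:

```python
cohorts = bd.generate_multicohort(config, 4, [20_000, 3_000, 3_000, 3_000])
fits = [bd.DiscordanceProfileModel(c).fit(seed=0) for c, _ in cohorts]
final = fits[0].replicate(fits[1:])      # keep profiles found everywhere

lr = bd.log_contrast(final.alloc)        # Cox-ready log-ratio terms
```

A command-line interface mirrors the library
(`bmidiscord simulate|qc|residualize|cluster|replicate|stats|survival|dca`).

## Layout

```
src/bmidiscord/
  simulate.py     synthetic cohorts (profiles, biomarkers, survival outcomes)
  discordance.py  QC, residualization, Mahalanobis discordance
  graph.py        kNN proximity graph, 2-D embedding (figures only)
  cluster.py      communities -> Gaussian mixture -> allocations, quality
  replicate.py    cross-cohort profile matching and replication
  stats.py        probability-weighted estimates, meta-analysis
  survival.py     log-contrast Cox models, nested comparison, risk shifts
  dca.py          decision curves, net benefit
  model.py        DiscordanceProfileModel / DiscordanceProfileResults
  cli.py          command-line interface
docs/methods.md   model, assumptions, numerical choices, limitations
```
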