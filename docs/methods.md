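# Methods

`bmidiscord` partitions a population into a *concordant* profile — people
whose cardiometabolic biomarkers sit where a linear BMI relationship
predicts them — and *discordant* profiles with systematic multivariate
deviations from that expectation, then evaluates what those profiles add
epidemiologically and predictively. This note records the model, the
numerical choices, and what the synthetic cohorts do and do not
demonstrate.

## Discordance model

Within one sex stratum, each biomarker $y_j$ is residualized by two-stage
least squares in the Frisch–Waugh sense: age and current smoking are
partialled out of both the biomarker and BMI, and the adjusted biomarker
is regressed on the adjusted BMI. The resulting deviations equal the
residuals of the joint regression on age, smoking and BMI; they are
centered and scaled to unit SD on the stratum, giving the standardized
deviation matrix $\delta \in \mathbb{R}^{N \times 10}$. All fitted
coefficients and the centering/scaling constants are stored so the
transform can be re-applied to new raw data bit-identically (validation
scoring, biomarker back-mapping).

Multivariate discordance is the squared Mahalanobis distance
$D_i^2 = \delta_i^\top \Sigma^{-1} \delta_i$ against the stratum residual
covariance; under multivariate normality $D^2 \sim \chi^2_{10}$, so the
fraction of individuals with upper-tail $p < 0.05$ has expectation 5%,
tested against the observed fraction with an exact binomial test.

Outlier QC drops whole rows with any biomarker beyond 5 SD of the stratum
mean (complete-case analysis).

## Graph-seeded soft clustering

A k-nearest-neighbour graph is built on $\delta$ (Euclidean metric) with
$nn = \max(10,\, 10 + 15(\log_{10} N - 4))$ rounded to the nearest
integer, symmetrized by union, all edge weights 1. The search is exact
(KD-tree) at every size: at the cohort sizes used here exact search costs
seconds, is fully deterministic, and removes an approximation parameter;
the `seed` argument is retained for interface stability.

Communities come from the leading-eigenvector method (stable seeds)
followed by repeated Leiden modularity optimization; the best-modularity
partition over the restarts is kept (default 500 restarts; the
aggregation rule across restarts is a design choice — best-of-restarts
was preferred over co-clustering consensus for determinism and cost).
Within each community, members are weighted by eigenvector centrality
(normalized to max 1), and the weighted mean and covariance become a
Gaussian component.

Two classes of communities are *not* promoted to components and are
instead represented by the reference component:

- communities with fewer than `10 × dim` members (too small to estimate a
  10×10 covariance), and
- communities whose weighted mean lies within `min_mean_norm = 2` z-units
  of the origin. Sub-communities of the central cloud are unstable between
  restarts and have mean norms up to ≈1.6 even when no discordant
  structure exists (a partitioned standard normal has cells with non-zero
  means); 2 z-units is the aggregate separation that defines a discordant
  profile in the first place.

A fixed *concordant* component with $\mu = 0$, $\Sigma = I$ is always
added. Component moments stay fixed; only the mixture weights $\pi_k$
(population proportions) are estimated, by EM on the responsibilities
(tolerance $10^{-8}$ on $\max|\Delta\pi|$, at most 1000 iterations; the
log-likelihood is non-decreasing and is recorded). Allocation
probabilities are the posterior responsibilities, computed in log space
with log-sum-exp; rows sum to 1 by construction.

Partition quality is summarized by the relative-entropy separation index
$E = 1 - \sum_{ik} -p_{ik}\ln p_{ik} / (N \ln K) \in [0,1]$ (1 = one-hot,
0 = uniform) and by the global transitivity of each profile's
maximum-probability subgraph.

### A known bias of the fixed identity reference

Because $\delta$ is standardized on the whole stratum, the *actual*
concordant cloud has per-coordinate variance
$1/(1 + w(1-w)\Delta^2) < 1$ on coordinates where a discordant profile
of weight $w$ is shifted by $\Delta$. The fixed $\Sigma = I$ reference is
therefore slightly too wide and systematically claims spike-boundary
mass: discordant weights are underestimated by $O(1)$ percentage points
independent of $N$. This is intrinsic to the combination of full-stratum
standardization and the identity-covariance reference; users comparing
recovered weights against external proportions should expect this bias.

## Replication across cohorts

Each cohort is profiled independently (its own residualization, graph and
mixture). Discordant components are matched one-to-one across cohorts by
cosine similarity of mean vectors, greedily, with pairs below similarity
0.5 never matched (the matching rule is a documented package choice; no
canonical criterion exists for it). A discovery profile *replicates* when
its confident members (allocation > 0.8) receive a median probability
> 0.8 for the matched profile under **every** validation mixture.
Non-replicated components are removed, weights refit, allocations
refreshed. Cross-scoring direction is discovery-individuals-under-
validation-mixtures; note the boundary semantics: posteriors of
well-separated profiles saturate arbitrarily close to 1, so "no profile
replicates" is only guaranteed at a threshold of exactly 1.

## Profile-specific estimation

All per-profile estimators weight individuals by allocation probability,
so they degenerate to plain subgroup statistics under one-hot
allocations: weighted means/SDs, weighted quantiles (cumulative-weight
interpolation at positions $(\mathrm{cum}w - w/2)/W$), weighted least
squares for BMI slopes, prevalence $\sum c_i p_{ik} / \sum p_{ik}$ and
incidence $\sum e_i p_{ik} / \sum t_i p_{ik}$. Ratios versus the
concordant profile come from probability-weighted binomial (OR) or
Poisson with log-follow-up offset (RR) GLMs. Because the weights are
themselves estimated quantities, all weighted regressions use robust
(sandwich) standard errors; prevalence/incidence CIs use Kish's effective
sample size. Detected separation in the binomial model falls back to an
own Jeffreys-penalized (Firth-style) Newton solver. Batches of estimates
are FDR-adjusted by Benjamini–Hochberg at 5%.

Per-cohort estimates are pooled by inverse-variance fixed-effect or
DerSimonian–Laird random-effects meta-analysis (τ² truncated at zero);
random effects are the reported default as the more conservative choice.

## Log-contrast survival analysis

Allocation probabilities sum to 1 and are unidentifiable as raw
regression terms, so discordant probabilities enter Cox models as
log-ratios to the concordant reference, $z_k = \ln(p_k/p_c)$
(probabilities floored at $\varepsilon = 10^{-6}$ and renormalized
first). A one-unit increase in $z_k$ scales $p_k$ by $\sqrt{e}$ relative
to every other profile. The floor is inert whenever no probability falls
below it — then the log-ratio matrix is identical for any
$\varepsilon \in [10^{-8}, 10^{-4}]$; once posteriors saturate beneath
the floor, the transform necessarily truncates at $\ln\varepsilon$ and
coefficients scale with the choice, which is why the floor is a
documented constant rather than a free knob.

Cox fits use Efron tie handling (via lifelines), time in years, age as a
covariate rather than the timescale; rows with prevalent disease are
excluded upstream. Nested models (base risk factors vs base + log-ratios)
are compared by:

- likelihood-ratio test, df = number of added log-ratio terms;
- likelihood-based explained variation $R^2 = 1 - \exp(-\mathrm{LR}_{\text{vs null}}/n)$
  per model, with the profile contribution reported as a percentage of
  the full-model $R^2$ (the base-denominator version is also reported;
  the null partial likelihood is computed by a closed-form Efron-at-β=0
  routine);
- ΔC (Harrell), with the SE from a 200-replicate paired bootstrap over
  individuals holding risk scores fixed, which captures the covariance of
  the two C-statistics; two-sided normal p.

The Lasso variant fits an L1-penalized partial likelihood over a penalty
path, choosing the penalty by seeded K-fold cross-validated held-out
deviance (10 folds by default); covariates should be on comparable
scales since the penalty applies to raw coefficients.

Risk-shift estimates answer "what if this person's probability of profile
k were 10 points higher at the expense of the concordant profile, other
discordant profiles held at their population values?" for a reference
individual (age 55, BMI 30, non-smoker). The biomarker values consistent
with a target probability are found by monotone root-finding (Brent,
tolerance $10^{-8}$) along the segment from the concordant center toward
the component mean, mapped back to raw units through the stored
residualization parameters. The HR is $\exp$ of the linear-predictor
difference between the shifted and baseline covariate vectors (log-ratio
*and* biomarker terms both move), with a delta-method CI from the
coefficient covariance.

## Decision curves

Net benefit $\mathrm{NB}(t) = TP/N - (FP/N)\,t/(1-t)$ and net
interventions avoided $TN/N - (FN/N)(1-t)/t$ on a threshold grid of
0.001–0.15 (step 0.001; the clinically plotted range). At $t = 0.10$ the
implied exchange rate is nine false positives per true positive. Curves
are computed per cohort, then averaged unweighted across cohorts
(eventless cohorts skipped with a warning); per-profile curves replace
each count by its probability-weighted version, and the profile-weight
average of per-profile net benefits reproduces the overall curve exactly.
Model deltas are reported per 10,000 individuals
($10^4 \times \Delta\mathrm{NB}$).

## Synthetic cohorts

The generator emulates exactly the structure the analysis assumes: age
uniform on 38–73 y, smoking Bernoulli(0.12), BMI lognormal
(median 26.5 kg/m², σ_log = 0.16), each biomarker linear in age, smoking
and BMI with a residual drawn — in standardized units — from a mixture of
one N(0, I) concordant component and shifted discordant components.
Event times are exponential with log-hazard linear in the residual
z-units and in the true-posterior log-ratio terms, administratively
censored at 10 years (baseline rates 0.008/person-year for MACE,
0.005/py for type 2 diabetes).

Scenarios: `null` (concordant only), `separated` (concordant 80% +
adverse-lipid 8%, hyperglycemic 7%, hypertensive 5%), `overlapping`
(same shifts halved), `survival` (separated plus hazard effects, log-HR
ln 2 on the adverse-lipid log-ratio). The separated shifts (e.g. TG +3.5,
HDL −3.5, LDL +2.8 z) were calibrated once against the Bayes-oracle
classifier so that the argmax of the true posterior recovers planted
labels with adjusted Rand ≈ 0.98 — i.e. the scenario actually is
well separated — and then frozen.

What the synthetic cohorts do **not** emulate: non-Gaussian biomarker
skew, nonlinear BMI relationships, measurement error and regression to
the mean, correlated comorbidity/medication structure, non-proportional
hazards, or informative censoring. Passing recovery tests therefore
demonstrates correctness of the pipeline under its own assumptions, not
robustness to their violation.

## Problem sizes and test design

Tests run the full pipeline at N up to 50,000 (discovery recovery) and
replication over twenty 4-cohort systems of 4,000/2,000/2,000/2,000;
survival recovery uses 20 seeds at n = 10,000 and 200 null replicates at
n = 1,500 with the true-mixture allocations standing in for the graph
step (clustering recovery is tested separately). Leiden restarts are
reduced in tests (6–10) relative to the 500-restart default: restarts
only ever improve modularity, and the well-separated test graphs reach
the optimum immediately, so fewer restarts is the conservative choice.

## Known limitations

- Discordant mixture weights carry the O(1 pp) underestimation bias
  described above; it does not shrink with N.
- Greedy cosine matching can mispair profiles whose mean directions are
  similar; the 0.5 similarity floor mitigates but does not eliminate this.
- The Firth-style fallback reports penalized-likelihood Wald SEs, which
  are approximate in very small samples.
- `embed_2d` exists for inspection only; no inference consumes the
  coordinates.
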