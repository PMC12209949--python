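# Methods

`tiernet` implements a complete inference chain for linking a binary
baseline exposure (e.g. current major depressive disorder) to a later
binary outcome (e.g. incident cardiovascular disease) through a panel of
continuous immunometabolic biomarkers: preprocessing, machine-learning
biomarker refinement, tiered constraint-based causal discovery on mixed
data, bootstrap edge stability with betweenness-based mediator nomination,
and counterfactual mediation analysis.  Because the motivating cohort data
are access-restricted, the package ships a first-class synthetic cohort
generator with known causal ground truth; every claim the test suite makes
is a claim about recovery of that known truth.

## The generative model

The synthetic generator draws cohorts from a tier-respecting DAG with
conditional-Gaussian/logistic parameterization:

* continuous children: `x_v = mu_v + sum_p w_pv * x_p + eps_v`,
  `eps_v ~ N(0, sigma_v^2)`;
* binary children: `x_v ~ Bernoulli(logit^-1(mu_v + sum_p w_pv * x_p))`.

This is the data-generating family under which the pipeline's CI test is
exactly specified, so structure-recovery results measure the algorithm, not
model mismatch.  (The binary outcome's logistic link is itself a mild
departure from a strict CG joint — conditioning continuous variables on a
logistic child tilts their Gaussian law — which is the same approximation
any CG analysis of a binary follow-up outcome makes.)

The default `nesda_like_truth` layout mirrors a clinical depression cohort:

* 1 binary exposure (tier 0) calibrated to 49% prevalence (the scale of
  1115 exposed among 2256 participants);
* 24 continuous biomarkers (tier 1), three of them inflammatory-role with
  log-normal raw-scale marginals; latent intercept 3.0 and unit noise SD so
  `exp(latent)` gives plausibly skewed concentrations;
* 1 binary outcome (tier 2) calibrated by intercept bisection (tolerance
  0.01, 100k Monte-Carlo draws) to 10% prevalence (~210 events);
* a designed backbone: a two-step chain exposure→B1→B2→outcome, three
  single-mediator paths (including the CRP-like marker), a direct
  exposure→outcome edge, and one exposure child with no outcome path (the
  designated non-mediator used to probe nomination specificity);
* seeded random biomarker→biomarker background edges (probability 0.5,
  weights ±U(0.4, 0.7)) among the non-backbone markers.

Backbone weights (0.8 exposure→biomarker, 0.6 within-chain, 0.8 on the
outcome's logit) are fixed once at a "moderate effect" scale: strong enough
that n≈4000 cohorts carry recoverable signal, weak enough that recovery is
not trivial.  Exposure tier precedes the biomarker tier, which forces
exposure→biomarker orientations — the configuration consistent with a
network whose exposure→biomarker edges are all directed; putting both in
one tier is possible through `VariableSpec` and leaves those orientations
to v-structures and Meek propagation.

What the generator does **not** emulate: the covariance structure of real
NMR metabolomics (dozens of highly collinear lipoprotein measures),
platform batch effects, or instrument-based phenotyping.  Passing tests
therefore demonstrate correctness of the algorithms under their stated
assumptions, not field performance on real cohort data.

### Data pathologies

* **Missingness** — MCAR masks eligible cells uniformly; MAR masks
  biomarker cells at a 3:1 probability ratio between exposed and unexposed
  rows.  Overall rates are rescaled so the target fraction refers to the
  whole table even though exposure and outcome columns are never masked.
* **Outliers** — "acute inflammation" rows: a chosen set of rows has all
  inflammatory columns shifted by +8 column SDs (default), preserving each
  row's own noise.  The true indices are returned for recall scoring.

## Preprocessing

* **Little's MCAR test.**  EM estimation of the grand mean/covariance of
  the continuous block under multivariate normality, then the classic
  chi-square: `sum_j n_j (ybar_j - mu_obs)' Sigma_obs^{-1} (ybar_j -
  mu_obs)` over missingness patterns with `sum_j p_j - p` degrees of
  freedom.  EM tolerance 1e-5, max 100 sweeps.  The statistic is invariant
  to affine rescaling of columns.
* **Imputation.**  scikit-learn's iterative (chained-equations) imputer
  with its ridge-regularized Bayesian linear conditional models;
  convergence tolerance 1e-3, default 10 sweeps.  Observed cells are never
  modified; binary columns are thresholded at 0.5 after imputation.
* **Outlier detection.**  A two-pass isolation forest (500 trees per pass)
  over biomarker+inflammatory columns: a provisional top-k pass, then a
  refit on the remaining bulk and re-scoring of all rows against it.  The
  refinement pass is what handles *clustered* anomalies: identical additive
  spikes form a dense clump that partially masks itself in a single fit
  (measured recall ~0.86 single-pass vs ~0.95 two-pass on the default
  +8 SD contamination).  Exactly `ceil(contamination*n)` rows are flagged.
* **Biomarker cleaning.**  `ln(1+x)` on biomarker and inflammatory
  columns; cells beyond 5 post-transform SDs set missing for
  metabolite-role columns only, following NMR-platform quantification
  protocols.  Inflammatory assay extremes are deliberately retained — they
  are the signature the row-level outlier stage detects.
* **Outcome residualization.**  Logistic regression of the outcome on the
  adjusters; the column is replaced by Pearson residuals
  `(y - p)/sqrt(p(1-p))` (deviance residuals by option) and re-marked
  continuous; the raw column is kept under a `_raw` suffix.

Default stage order: clean → missingness diagnosis → impute → detect and
remove outliers → (optional) residualize.  Operations record provenance
and the outlier detector refuses tables that still contain missing cells.

## Mixed-data conditional independence

The CI engine fits conditional-Gaussian models: binary subsets get a
saturated multinomial; continuous subsets get stratum-specific means with
stratum-specific covariances (default), falling back to a pooled
within-stratum covariance whenever a stratum has fewer than c+2 rows, and
a `pooled` mode by configuration.  The test of x ⟂ y | S is

    G2 = 2 [ l(x,y,S) + l(S) - l(x,S) - l(y,S) ],   df = matching parameter-count difference,

referred to the upper chi-square tail.  Special cases fall out exactly:
df = 1 Gaussian partial-correlation LR for all-continuous sets, and the
classical G-test for all-binary sets.  Tiny negative statistics (numerical
round-off) are clamped to zero; a singular saturated covariance with sound
null terms signals a deterministic x–y relation and is reported as maximal
dependence; degenerate tests (empty strata, non-positive df) are reported
as independence with a logged warning — the conservative choice for
constraint-based deletion.  Measured type-I error at n=2000 is within
~0.003 of nominal across all kind combinations and |S| ≤ 2.

Log-likelihoods are cached per variable subset and test results per
(pair, conditioning set), so a PC run and a multi-alpha sensitivity sweep
recompute nothing.

## Tiered PC

PC-stable skeleton search: at each conditioning size, candidate sets come
from an adjacency snapshot taken at the start of that size, making edge
deletion order-independent.  Tier knowledge enters twice: conditioning
candidates exclude nodes in tiers strictly later than both endpoints (such
nodes cannot d-separate them), and every cross-tier edge is oriented
earlier→later before sepset-based v-structure orientation and Meek rules
1–4 run to closure.  Orientation conflicts are resolved with tier
knowledge always winning, first-found winning among v-structures, and
every conflict recorded on the output graph; the tier invariant and
acyclicity are asserted after every single orientation.  Against a
brute-force enumeration of tier-respecting Markov-equivalent DAGs the
oracle output is exact on hundreds of random 5–6-node problems, which in
particular exercises Meek rule 4 (only reachable with background
knowledge).

`max_cond` is unbounded by default, as PC prescribes; a cap is available
for speed on dense problems.

## Stability and centrality

Bootstrap stability follows the 100-iterations-per-drop-rate × {0%, 10%,
20%} design (300 graphs): each iteration drops `floor(rate*n)` rows without
replacement, resamples the kept rows with replacement, and reruns tiered
PC.  A directed edge's frequency is its share of all graphs; an edge left
undirected contributes 0.5 to each direction (configurable to `skip`).
Drop-rate monotonicity of frequencies is deliberately *not* asserted
anywhere — the method does not imply it.  The alpha sensitivity sweep
(0.01 / 0.05 / 0.075) shares one CI cache, which makes skeleton presence
exactly monotone in alpha and gives each edge its ✔/– flag vector.
Frequencies render as the stability table prints them ("100%", "99.7%");
the emitted TSV round-trips to the exact report.  Downstream selection
uses a default stability threshold of 0.8.

Betweenness is computed on the directed subgraph (undirected leftovers are
dropped with a warning), unnormalized by default — the above-mean
highlighting rule is scale-invariant either way.  Mediator nomination:
nodes with above-mean betweenness lying on at least one directed
exposure→outcome path, excluding the endpoints.

## Counterfactual mediation

Two-model estimation: OLS for mediator ~ exposure + covariates, logistic
(or OLS, for the continuous-outcome linear variant) for outcome ~ exposure
+ mediator + covariates.  Counterfactual mediator draws use the fitted
mean plus Gaussian noise with the ML residual SD, with common random
numbers across exposure arms; ACME under arm d is the mean over units and
draws of `P(Y=1 | d, M(1), C) - P(Y=1 | d, M(0), C)` on the
risk-difference scale, reported as the average of the two arms
(arm-specific values are also exposed).  With common draws the estimator
satisfies total = ACME + ADE *exactly*, for the nonlinear case as well as
the linear one, and the linear variant reproduces the product-of-
coefficients identity a·b to numerical precision in expectation.

Inference is a nonparametric bootstrap (default 1000 row resamples; both
models refit and the counterfactual integral recomputed per resample) with
percentile 95% intervals and the two-sided sign p-value
`2·min(P(ACME* <= 0), P(ACME* >= 0))`.  Resamples with a constant binary
outcome are redrawn (max 10 retries).  A quasi-Bayesian parameter-draw
mode was considered and not implemented; row resampling matches the
bootstrap design the pipeline states.

`adjusted_associations` provides the companion forest-plot contract:
per-predictor standardized logistic coefficients with Wald 95% intervals,
adjusted for a caller-supplied covariate list.

## Problem sizes used in the checks

The test suite and `scripts/acceptance.py` run at sizes chosen to make
each property measurable with comfortable margins on a single CPU: oracle
equivalence on 100 random 5–6-node DAGs; CI calibration at n=2000 with
4000 replicates per kind-combination (tolerance stated at the 1000-rep
Monte-Carlo resolution); structure recovery on ten n=4000 cohorts of the
26-node default truth; mediation coverage on n=5000 cohorts with 200
bootstrap resamples and a 10^6-draw generative oracle; preprocessing
calibration with 300–500 replicates at n=2000–2256.

## Known limitations

* The CG likelihood-ratio test is exact in neither tail at finite n; its
  small (+0.003) size inflation is inherited by edge counts.
* Stratum-specific covariances need every stratum populated; with more
  than a handful of binary variables in one conditioning set the pooling
  fallback engages often, and with empty cells the test degrades to the
  conservative "independent" report.
* Betweenness on the directed subgraph ignores genuinely undirectable
  (Markov-equivalent) edges; a mediator whose edges stay undirected at
  every alpha cannot be nominated.
* The ACME estimator assumes no exposure-mediator interaction in the
  outcome model and Gaussian mediator errors, as the two-model design
  prescribes.
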