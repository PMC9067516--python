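# Methods

This note documents the models implemented in `gutdev`, the synthetic
cohort they are exercised on, the numerical choices that matter, and
the limits of what the shipped tests demonstrate.

## The synthetic cohort

The generator (`gutdev.simulate`) emulates an age-structured
early-childhood cohort (6–36 months) with three phenotype arms: a
healthy reference (non-AD) and two atopic-dermatitis arms (mild,
moderate-to-severe), in roughly equal proportions. Ages are drawn per
age bin (6 months is a single visit age; the 7–12, 13–24 and 25–36
month bins are sampled with probabilities 0.15/0.25/0.30/0.30 and
uniform integer months within the bin), mirroring the visit structure
of birth-cohort studies.

**Latent maturity.** Each child carries a developmental state

  m = logistic((age − 12)/τ + η),  τ = 6 months, η ~ N(0, σ²), σ = 1

where η is a subject-level maturation deviation: children genuinely
mature at different speeds, and with τ = 6 an η SD of 1 corresponds to
roughly ±6 months of developmental spread. This spread is what the
within-group heterogeneity analyses measure in real cohorts, and it is
also the shared latent signal that couples the taxonomic and metabolite
maturity scores within an age bin. In the AD arms m is shifted
+δ·severity before 12 months (over-maturation) and −δ·severity after
(delay), with δ = 0.15 and severity 0.7 (mild) / 1.0 (moderate-severe),
clamped to (0, 1).

**Composition.** Two archetype compositions over 40 genera span the
developmental axis: an early community dominated by *Bifidobacterium*,
*Veillonella* and *Escherichia* (facultative-anaerobe rich) and a late
community dominated by *Bacteroides* and *Faecalibacterium* (strict
anaerobes). The weights in `default_cohort.yaml` are qualitative
dominance patterns, not fitted to any dataset. A sample's expected
composition is the m-interpolation of the archetypes; the realised
composition is Dirichlet-distributed around it with concentration 200,
and counts are multinomial at a log-normal depth (median 5000,
σ = 0.3).

**SCFAs.** Each of the six short-chain fatty acids is a linear function
of the realised *producer load* — the summed relative abundance of the
butyrate-producing strict anaerobes (*Faecalibacterium*, *Roseburia*,
*Anaerostipes*, *Subdoligranulum*, *Coprococcus*, *Eubacterium*,
*Butyricicoccus*, *Ruminococcus*) — plus Gaussian noise, in µmol/g
feces. Butyrate carries the steepest coupling; acetate declines with
load. Noise SDs are deliberately small (e.g. 0.3 µmol/g for butyrate)
so that the latent maturity signal dominates the metabolite profile:
the design goal is that maturity explains ≥ 80 % of the variance of the
derived maturity scores, which is what makes the SAZ–MAZ coupling
observable at cohort scale. Real assay noise is larger, so the
metabolite–taxonomy coupling in real data will be weaker than in these
simulations.

**What the generator does not model:** sequencing error and chimeras,
strain-level variation, longitudinal within-subject correlation (one
sample per subject), batch effects, and covariate–composition
confounding (sex, delivery mode, feeding and IgE covariates are drawn
independently of composition, except that IgE levels rise with AD
severity). Passing tests therefore demonstrate correctness of the
statistical machinery under the stated generative model, not
robustness to the full messiness of real metagenomes.

## Community typing (DMM)

Counts are modelled by a K-component mixture of Dirichlet-multinomial
densities (multinomial coefficient omitted throughout; only density
ratios matter). Fitting is EM: soft assignment in the E-step, and in
the M-step a weighted fixed-point iteration on the digamma moment
equations for each component's α (five inner iterations), which
increases a minorising bound and so makes the whole procedure a
monotone generalised EM. Initialisation is k-means on relative
abundances (pseudocount 0.5 at initialisation only) followed by
method-of-moments α matching; three random restarts, best final
objective kept. A component whose weight collapses below 1/(10N) is
re-seeded once from a random sample (the objective trace restarts
there, since re-seeding jumps to a new EM trajectory); if it collapses
again the fit is flagged non-converged.

The fit is a MAP fit: each α parameter carries a weakly-informative
Exponential(rate = 3) prior. The prior's data-side bias is negligible
(the data term in the fixed-point denominator is ~10³ for cohort-scale
counts), but it matters for model selection: the number of community
types is chosen by the lowest Laplace-approximated negative log
evidence around the MAP,

  −log p(D) ≈ −(ll̂ + log prior) − (d/2)·log 2π + ½·Σ log h,

with the Hessian of the negative log posterior taken in log-α
coordinates and approximated by its diagonal; mixture weights
contribute log N each. Two guards keep the score honest: curvatures are
floored at 1 (the prior is improper in log space, so flat directions
must not inflate the evidence), and collapsed components are excluded
from both the parameter count and the curvature — a K = 5 request that
empties to two occupied components *is* a two-type model, and model
selection compares and reports the occupied number. Without the prior's
per-component concentration cost, evidence keeps improving as surplus
components subdivide the smooth age gradient, and a developmental
continuum would be reported as 3+ types; the prior form was chosen so
that the selected K matches the number of planted archetypes across
seeded cohorts (the score's absolute value is not meaningful and is not
used as one).

## Maturity scoring (EMA / MAZ / SAZ)

Random-forest regression (1000 trees, `min_samples_leaf = 5` — the
regression default of the R ranger implementation; leaf size 1 inflates
out-of-bag noise enough to destabilise the per-bin reference SDs) of
age on relative abundances, trained on the reference group only.
Reference samples are scored with out-of-bag predictions so the per-bin
reference statistics (median, sample SD with n−1) are not optimistically
biased; other samples use the full forest. MAZ is the per-age-bin
z-score of EMA against these reference statistics; a bin with zero
reference SD is flagged unusable and its samples receive missing scores
rather than infinities. SAZ applies the identical machinery to the six
measured SCFA concentrations (a flag in the pipeline allows predicted
SCFAs instead). Feature selection, when enabled, is recursive
elimination halving the feature set by forest importance and keeping
the smallest set that attains the minimum cross-validated MSE.

## Ecology statistics

Bray–Curtis on relative abundances; Shannon in nats. NMDS minimises
Kruskal stress-1 by monotone regression (scikit-learn's non-metric MDS)
from a classical-scaling initialisation plus seeded jitter, best of 10
restarts. PERMANOVA partitions squared distances (pseudo-F), EnvFit
fits covariate vectors (continuous: least-squares projection r²) or
factor centroids (categorical: explained coordinate variation) onto
the ordination; both use seeded label/value permutations with the
add-one convention p = (1 + #extreme)/(B + 1), so the smallest
achievable p is 1/(B+1). The heterogeneity curve LOESS-smooths
(tricube, locally linear, span 0.75) each sample's mean within-group
dissimilarity against age, with percentile bootstrap 95 % CIs over
samples. Power analysis subsamples n per group, reruns PERMANOVA, and
reports the rejection fraction plus ω² = (SS_b − (k−1)·MS_w)/(SS_t + MS_w).

## Indicators and differential abundance

IndVal = specificity × fidelity (A·B convention; √(A·B) is a
documented alternative), maximised over single groups (no group-combination
search), permutation-tested with 10,000 permutations by default.
Kruskal–Wallis (tie-corrected) with Dunn's two-sided normal-approximation
post hoc tests; BH adjustment across features, and across pairs within
a feature separately. The covariate-adjusted association model is a
fixed-effects OLS on arcsine-square-root (or log10) transformed
abundances — a deliberate simplification of mixed-model frameworks,
adequate for one-sample-per-subject designs.

## Co-occurrence networks

The SparCC estimator: t_ij = var(log x_i/x_j) computed from
Dirichlet-resampled fractions (unit pseudocounts, 20 inner resamples,
element-wise median), basis variances solved from the sparsity-assumption
linear system with up to 10 exclusion rounds of the strongest pair
(threshold |ρ| > 0.1). Pseudo p-values bootstrap-resample each feature's
counts independently (breaking all association) and count
|ρ_boot| ≥ |ρ_obs| with the add-one rule; when calibration matters the
observed and bootstrap estimates should use the same number of inner
resamples, since a mismatch makes the test conservative. Networks keep
edges with p < α among a node subset (the pipeline supplies the top-10
taxa per community type by forest importance; the "common" set is their
intersection); display weights are clamped to ±0.4 without altering
stored ρ. Hubs are the top five nodes by PageRank (damping 0.85) on the
|ρ|-weighted graph — absolute weights keep negative edges influential —
with eigenvector centrality reported for node scaling. SparCC's
sparsity assumption fails for dense correlation structures; the
two-cluster recovery test embeds its clusters in a mostly-independent
background for this reason, and users should be wary of interpreting
dense networks.

## Metabolite prediction

Per metabolite, concentrations are scaled by the training maximum
("relative concentration"; a divide-by-sample-total normalisation was
rejected because compositional closure leaks signal from predictable
into unpredictable metabolites), arcsine-square-root transformed
(log10 optional), and regressed on prevalence/abundance-filtered
gene-family relative abundances with elastic net (mixing grid
0.1–0.9 step 0.2, 50-value penalty path, hyperparameters by fold-wise
CV). Predictability is the Spearman correlation between pooled
out-of-fold predictions and observations; r > 0.3 flags a metabolite
well-predicted. Permutation significance reruns the whole pipeline on
sample-shuffled data. RTSI projects a sample onto the training PCA
(top 10 components) and maps its RMS eigenvalue-standardised score
distance d to exp(−4·max(0, d − d₀)/d₀) with d₀ the maximum training
distance — training samples score 1, far outliers decay toward 0. RTSI
is an interpretation of a PCA-representativeness score, pinned by its
boundary behaviour rather than by external reference values.

## Problem sizes and determinism

Every stochastic routine takes an explicit seed; the pipeline derives
per-stage child seeds from one root seed and records them in the run
manifest alongside SHA-256 hashes of every artifact, so reruns are
byte-identical. The shipped acceptance checks use cohort sizes of
200–500 samples, 20 seeded replicates for recovery rates, and reduced
permutation counts (199–399) with 500–1000 null replicates for
calibration — sizes chosen to give the binomial comparisons adequate
resolution while keeping a full run in the minutes range.
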