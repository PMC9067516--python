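# gutdev

Developmental analysis of the early-childhood gut microbiome, built
around the question of how microbiome maturation goes wrong in atopic
dermatitis (AD): community typing, microbiota- and metabolite-for-age
z-scores, indicator species, compositional co-occurrence networks, and
elastic-net prediction of short-chain fatty acids (SCFA) from
metagenome features — all exercisable on a built-in synthetic cohort
generator, so every stage is testable without access to restricted
human data.

## Who this is for

Microbiome researchers analysing age-structured infant/toddler cohorts
(taxonomic profiles from shotgun or amplicon sequencing, per-sample
metadata, optionally SCFA concentrations and gene-family tables) who
want one reproducible, seeded pipeline for the standard developmental
analyses.

## The models at the core

**Community typing.** Sample counts *x* are modelled by a
Dirichlet-multinomial mixture (DMM): component *k* has parameters
α<sub>k</sub>, and

  log DM(x | α) = log Γ(A) − log Γ(A + n) + Σ<sub>j</sub> [log Γ(α<sub>j</sub> + x<sub>j</sub>) − log Γ(α<sub>j</sub>)],  A = Σα<sub>j</sub>, n = Σx<sub>j</sub>.

The mixture is fitted by MAP EM (Exponential prior on each α) and the
number of gut microbiota types (GMTs) is chosen by the lowest
Laplace-approximated negative log evidence.

**Maturity scoring.** Estimated microbiota age (EMA) is a random-forest
regression of chronological age on taxon relative abundances, trained
on the healthy reference group only, with out-of-bag (OOB) predictions
for the reference samples. The microbiota-for-age z-score is

  MAZ = (EMA − median EMA<sub>ref, bin</sub>) / SD EMA<sub>ref, bin</sub>

within the sample's age bin (6, 7–12, 13–24, 25–36 months); negative
MAZ means delayed maturation. The same machinery applied to the six
SCFA concentrations gives the SCFA-for-age z-score (SAZ).

**Networks.** Correlations between taxa are inferred on compositions
with the SparCC log-ratio-variance estimator, significance by
feature-wise bootstrap pseudo *p*-values, hubs by PageRank on
|ρ|-weighted graphs.

**Further stages.** Bray–Curtis / NMDS / PERMANOVA / EnvFit ordination
statistics, LOESS heterogeneity curves, PERMANOVA-based power
estimation, IndVal indicator species with permutation tests,
Kruskal–Wallis + Dunn + Benjamini–Hochberg differential abundance,
covariate-adjusted linear associations, and MelonnPan-style elastic-net
prediction of SCFAs from gene families with an RTSI
training-representativeness score.

## Worked example

```python
import pandas as pd
from gutdev import default_config, generate_cohort, dmm_select_k, to_relative
from gutdev.maturity import (fit_age_model, fit_scfa_age_model, predict_ema,
                             predict_scfa_age, z_score_by_age, maturity_correlation)

cohort = generate_cohort(default_config(n_samples=300, seed=7))

model = dmm_select_k(cohort.counts, range(1, 6), seed=7, max_iter=300)
print("community types:", model.K)

rel = to_relative(cohort.counts)
am = fit_age_model(rel, cohort.metadata, n_trees=1000, seed=7, select_features=False)
maz = z_score_by_age(predict_ema(am, rel), cohort.metadata, am.reference_stats)
sm = fit_scfa_age_model(cohort.scfa, cohort.metadata, n_trees=1000, seed=7)
saz = z_score_by_age(predict_scfa_age(sm, cohort.scfa), cohort.metadata,
                     sm.reference_stats)
r, p = maturity_correlation(pd.DataFrame({"maz": maz, "saz": saz}))
print(f"SAZ-MAZ Pearson r = {r:.3f} (p = {p:.2e})")
```

Output:

```
community types: 2
SAZ-MAZ Pearson r = 0.861 (p = 1.32e-89)
```

Two community types (an early *Bifidobacterium*/*Veillonella*-dominated
and a late *Bacteroides*/*Faecalibacterium*-dominated state) are
recovered from the age gradient, and the taxonomic and metabolite
maturity scores are strongly coupled — the expected signature of a
cohort whose SCFA production tracks the butyrate-producer load.

The same analysis runs from the shell:

```bash
gutdev run-all --seed 7 --n-samples 300 --outdir results/cohort7
```

which writes per-stage TSV artifacts (GMT assignments, maturity scores,
indicator tables, network edge lists and hubs, SCFA predictability) and
a `manifest.json` with SHA-256 hashes and per-stage seeds; reruns with
the same configuration are byte-identical.

## Limitations

The synthetic cohort emulates the statistical structure the analyses
assume (two compositional archetypes, a logistic maturation gradient
with subject-level spread, SCFA coupling to producer load, planted
disorder in the AD groups); it does not simulate sequencing error,
strain-level variation, or longitudinal within-subject sampling. See
`docs/methods.md` for the full model description and design choices.
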