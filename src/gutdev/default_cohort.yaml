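# Default synthetic-cohort constants.
#
# Two compositional archetypes span early-childhood gut development:
# archetype_1 is the early community (Bifidobacterium / Veillonella /
# Escherichia dominated, facultative-anaerobe rich) and archetype_2 the
# late community (Bacteroides / Faecalibacterium dominated, strict
# anaerobes).  Weights are qualitative dominance patterns, normalised to
# probability vectors at load time — they are not fitted to any dataset.
n_taxa: 40
age_min: 6
age_max: 36
# Cohort visit structure: the 6-month visit is a single age, later bins
# span wider ranges; bins are sampled with these probabilities and the
# age drawn uniformly (integer months) within the bin.
age_bin_probs:
  m6: 0.15
  m7_12: 0.25
  m13_24: 0.30
  m25_36: 0.30
maturity_tau: 6.0          # months; steepness of the logistic maturation curve
maturity_sd: 1.0           # subject-level maturation spread (logit scale, ~ +-6 months)
disorder_delta: 0.15       # latent-maturity shift in the AD groups
severity_weight:           # scales disorder_delta per phenotype
  nonAD: 0.0
  mildAD: 0.7
  modsevAD: 1.0
subject_concentration: 200.0   # Dirichlet concentration around the expected composition
depth_mean: 5000           # median sequencing depth (counts per sample)
depth_sigma: 0.3           # log-normal sigma of depth
group_probs:               # roughly equal study arms
  nonAD: 0.334
  mildAD: 0.318
  modsevAD: 0.348

taxa:
  #                     early  late
  g__Bifidobacterium:   [0.320, 0.100]
  g__Veillonella:       [0.120, 0.020]
  g__Escherichia:       [0.100, 0.015]
  g__Enterococcus:      [0.060, 0.005]
  g__Klebsiella:        [0.050, 0.005]
  g__Streptococcus:     [0.050, 0.020]
  g__Lactobacillus:     [0.030, 0.010]
  g__Clostridium:       [0.030, 0.020]
  g__Citrobacter:       [0.020, 0.003]
  g__Enterobacter:      [0.020, 0.003]
  g__Staphylococcus:    [0.010, 0.002]
  g__Rothia:            [0.010, 0.002]
  g__Bacteroides:       [0.020, 0.220]
  g__Faecalibacterium:  [0.005, 0.220]
  g__Ruminococcus:      [0.003, 0.060]
  g__Alistipes:         [0.002, 0.050]
  g__Roseburia:         [0.002, 0.065]
  g__Blautia:           [0.010, 0.050]
  g__Anaerostipes:      [0.002, 0.055]
  g__Subdoligranulum:   [0.002, 0.055]
  g__Eubacterium:       [0.003, 0.050]
  g__Coprococcus:       [0.002, 0.040]
  g__Parabacteroides:   [0.003, 0.030]
  g__Dialister:         [0.002, 0.020]
  g__Oscillibacter:     [0.001, 0.020]
  g__Prevotella:        [0.002, 0.020]
  g__Dorea:             [0.003, 0.020]
  g__Fusicatenibacter:  [0.002, 0.020]
  g__Agathobacter:      [0.002, 0.020]
  g__Collinsella:       [0.010, 0.020]
  g__Lachnospira:       [0.001, 0.015]
  g__Odoribacter:       [0.001, 0.010]
  g__Megamonas:         [0.001, 0.010]
  g__Butyricicoccus:    [0.001, 0.020]
  g__Akkermansia:       [0.002, 0.010]
  g__Phascolarctobacterium: [0.001, 0.010]
  g__Holdemanella:      [0.001, 0.005]
  g__Eggerthella:       [0.002, 0.003]
  g__Haemophilus:       [0.010, 0.003]
  g__Actinomyces:       [0.005, 0.002]

# Butyrate-producing strict anaerobes; their summed realised relative
# abundance is the "producer load" that drives the SCFA couplings below.
producer_taxa:
  - g__Faecalibacterium
  - g__Roseburia
  - g__Anaerostipes
  - g__Subdoligranulum
  - g__Coprococcus
  - g__Eubacterium
  - g__Butyricicoccus
  - g__Ruminococcus

# concentration = intercept + slope * producer_load + N(0, noise_sd),
# clipped at zero; units umol per g feces.  Noise levels are set so the
# latent maturity signal dominates the metabolite profile (>= 80 % of
# the variance of the derived maturity scores), with butyrate carrying
# the strongest coupling to the producer load.
scfa_coupling:
  acetate:      {intercept: 65.0, slope: -60.0, noise_sd: 2.0}
  propionate:   {intercept: 4.0,  slope: 28.0,  noise_sd: 0.4}
  butyrate:     {intercept: 1.5,  slope: 50.0,  noise_sd: 0.3}
  iso-butyrate: {intercept: 0.6,  slope: 4.0,   noise_sd: 0.12}
  valerate:     {intercept: 0.4,  slope: 5.0,   noise_sd: 0.12}
  iso-valerate: {intercept: 0.8,  slope: 3.5,   noise_sd: 0.15}

# Covariate generation (independent of composition unless stated).
covariates:
  p_male: 0.58
  p_cesarean: 0.256
  p_ebf: 0.45
  p_family_history: 0.40
  # log10 total IgE mean rises with AD severity
  log_ige_mean: {nonAD: 1.3, mildAD: 1.7, modsevAD: 2.0}
  log_ige_sd: 0.45
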