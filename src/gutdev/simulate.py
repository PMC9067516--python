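"""Synthetic age-structured cohort generation.

The generator emulates the statistical structure that the downstream
analyses assume about early-childhood gut microbiome development:

* a latent maturity ``m(age) = logistic((age - 12) / tau)`` moving each
  child's expected composition from an early archetype (facultative
  anaerobes: *Bifidobacterium*, *Veillonella*, *Escherichia*) to a late
  archetype (strict anaerobes: *Bacteroides*, *Faecalibacterium*);
* a maturation *disorder* in the atopic-dermatitis groups: maturity is
  shifted upward before 12 months (over-maturation) and downward after
  (delay), scaled by severity;
* SCFA concentrations linearly coupled to the realised load of
  butyrate-producing taxa, so metabolite and taxonomic maturity share
  the same latent signal;
* Dirichlet compositional noise around the expected composition and
  multinomial count noise at a log-normal sequencing depth.

All randomness flows from a single root seed through named child
streams, so identical configurations reproduce bit-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .data import AbundanceTable, SCFA_NAMES, validate_metadata

__all__ = [
    "CohortConfig",
    "Cohort",
    "default_config",
    "generate_cohort",
    "generate_correlated_counts",
    "generate_genefamily_metabolite",
]

_DEFAULT_YAML = Path(__file__).with_name("default_cohort.yaml")


@dataclass
class CohortConfig:
    """All knobs of the synthetic cohort; defaults ship in ``default_cohort.yaml``."""

    n_samples: int
    taxa: list[str]
    archetype_early: np.ndarray
    archetype_late: np.ndarray
    producer_taxa: list[str]
    scfa_coupling: dict[str, tuple[float, float, float]]
    age_min: int = 6
    age_max: int = 36
    maturity_tau: float = 6.0
    maturity_sd: float = 0.5  # subject-level maturation spread, logit scale
    disorder_delta: float = 0.15
    severity_weight: Mapping[str, float] = field(
        default_factory=lambda: {"nonAD": 0.0, "mildAD": 0.7, "modsevAD": 1.0}
    )
    subject_concentration: float = 200.0
    depth_mean: int = 5000
    depth_sigma: float = 0.3
    group_probs: Mapping[str, float] = field(
        default_factory=lambda: {"nonAD": 0.334, "mildAD": 0.318, "modsevAD": 0.348}
    )
    age_bin_probs: Mapping[str, float] | None = None
    covariates: Mapping[str, object] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        a1 = np.asarray(self.archetype_early, dtype=float)
        a2 = np.asarray(self.archetype_late, dtype=float)
        if len(self.taxa) != a1.size or len(self.taxa) != a2.size:
            raise ValueError(
                f"n_taxa mismatch: {len(self.taxa)} taxa vs archetypes of length "
                f"{a1.size} and {a2.size}"
            )
        if (a1 < 0).any() or (a2 < 0).any():
            raise ValueError("archetype weights must be non-negative")
        self.archetype_early = a1 / a1.sum()
        self.archetype_late = a2 / a2.sum()
        if self.disorder_delta < 0:
            raise ValueError("disorder_delta must be non-negative")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be positive")
        missing = set(self.producer_taxa) - set(self.taxa)
        if missing:
            raise ValueError(f"producer taxa not in taxon list: {sorted(missing)}")


@dataclass
class Cohort:
    """A generated cohort: counts, metadata, SCFA profiles and ground truth."""

    counts: AbundanceTable
    metadata: pd.DataFrame
    scfa: pd.DataFrame
    truth: pd.DataFrame
    config: CohortConfig


def default_config(n_samples: int = 300, seed: int = 0, **overrides) -> CohortConfig:
    """Load the shipped default cohort constants, with optional overrides."""
    raw = yaml.safe_load(_DEFAULT_YAML.read_text())
    taxa = list(raw["taxa"])
    early = np.array([raw["taxa"][t][0] for t in taxa], dtype=float)
    late = np.array([raw["taxa"][t][1] for t in taxa], dtype=float)
    coupling = {
        name: (c["intercept"], c["slope"], c["noise_sd"])
        for name, c in raw["scfa_coupling"].items()
    }
    cfg = CohortConfig(
        n_samples=n_samples,
        taxa=taxa,
        archetype_early=early,
        archetype_late=late,
        producer_taxa=list(raw["producer_taxa"]),
        scfa_coupling=coupling,
        age_min=raw["age_min"],
        age_max=raw["age_max"],
        maturity_tau=raw["maturity_tau"],
        maturity_sd=raw.get("maturity_sd", 0.5),
        disorder_delta=raw["disorder_delta"],
        severity_weight=raw["severity_weight"],
        subject_concentration=raw["subject_concentration"],
        depth_mean=raw["depth_mean"],
        depth_sigma=raw["depth_sigma"],
        group_probs=raw["group_probs"],
        age_bin_probs=raw.get("age_bin_probs"),
        covariates=raw["covariates"],
        seed=seed,
    )
    return replace(cfg, **overrides) if overrides else cfg


def latent_maturity(
    age_months: np.ndarray,
    group: Sequence[str],
    cfg: CohortConfig,
    eta: np.ndarray | None = None,
) -> np.ndarray:
    """Latent maturity in (0, 1) for given ages and groups.

    Healthy maturation is ``logistic((age - 12) / tau)``; AD groups are
    shifted ``+delta * severity`` at <= 12 months and ``-delta * severity``
    afterwards, reproducing over-maturation before 12 months and delay
    after.  ``eta`` is an optional per-subject maturation deviation on
    the logit scale (children mature at different speeds; with tau = 6
    months an ``eta`` SD of 0.5 corresponds to roughly +-3 months of
    developmental spread), which both the composition and the SCFA
    profile inherit.
    """
    age = np.asarray(age_months, dtype=float)
    z = (age - 12.0) / cfg.maturity_tau
    if eta is not None:
        z = z + np.asarray(eta, dtype=float)
    m = 1.0 / (1.0 + np.exp(-z))
    sev = np.array([cfg.severity_weight[g] for g in group], dtype=float)
    shift = np.where(age <= 12.0, 1.0, -1.0) * cfg.disorder_delta * sev
    return np.clip(m + shift, 1e-6, 1.0 - 1e-6)


#: Age-bin sampling probabilities and month ranges (the 6-month visit is
#: a single age; later bins span the printed ranges).
_AGE_BIN_RANGES = {"m6": (6, 6), "m7_12": (7, 12), "m13_24": (13, 24), "m25_36": (25, 36)}
_DEFAULT_BIN_PROBS = {"m6": 0.15, "m7_12": 0.25, "m13_24": 0.30, "m25_36": 0.30}


def _sample_ages(rng: np.random.Generator, n: int, cfg: CohortConfig) -> np.ndarray:
    probs = dict(cfg.age_bin_probs) if cfg.age_bin_probs else dict(_DEFAULT_BIN_PROBS)
    bins = list(_AGE_BIN_RANGES)
    p = np.array([probs.get(b, _DEFAULT_BIN_PROBS[b]) for b in bins], dtype=float)
    chosen = rng.choice(len(bins), size=n, p=p / p.sum())
    lo = np.array([_AGE_BIN_RANGES[bins[c]][0] for c in chosen])
    hi = np.array([_AGE_BIN_RANGES[bins[c]][1] for c in chosen])
    return lo + (rng.random(n) * (hi - lo + 1)).astype(int)


def generate_cohort(cfg: CohortConfig) -> Cohort:
    """Draw a full synthetic cohort from the configured model."""
    root = np.random.SeedSequence(cfg.seed)
    streams = {
        name: np.random.default_rng(child)
        for name, child in zip(
            ("design", "maturity", "composition", "depth", "scfa", "covariates"),
            root.spawn(6),
        )
    }
    n = cfg.n_samples
    rng = streams["design"]
    ages = _sample_ages(rng, n, cfg)
    group_names = list(cfg.group_probs)
    probs = np.array([cfg.group_probs[g] for g in group_names], dtype=float)
    groups = rng.choice(group_names, size=n, p=probs / probs.sum())

    eta = streams["maturity"].normal(0.0, cfg.maturity_sd, size=n)
    m = latent_maturity(ages, groups, cfg, eta=eta)
    expected = (1.0 - m)[:, None] * cfg.archetype_early + m[:, None] * cfg.archetype_late

    comp_rng = streams["composition"]
    composition = np.vstack(
        [comp_rng.dirichlet(cfg.subject_concentration * p) for p in expected]
    )
    depth_rng = streams["depth"]
    depths = np.maximum(
        depth_rng.lognormal(np.log(cfg.depth_mean), cfg.depth_sigma, size=n), 500
    ).astype(int)
    counts = np.vstack(
        [comp_rng.multinomial(d, p) for d, p in zip(depths, composition)]
    )

    sample_ids = [f"S{i:04d}" for i in range(n)]
    table = AbundanceTable(
        pd.DataFrame(counts, index=sample_ids, columns=cfg.taxa), kind="counts"
    )

    producer_idx = [cfg.taxa.index(t) for t in cfg.producer_taxa]
    load = composition[:, producer_idx].sum(axis=1)
    scfa_rng = streams["scfa"]
    scfa = {}
    for name in SCFA_NAMES:
        b0, b1, sd = cfg.scfa_coupling[name]
        scfa[name] = np.clip(b0 + b1 * load + scfa_rng.normal(0.0, sd, size=n), 0.0, None)
    scfa_df = pd.DataFrame(scfa, index=sample_ids)

    cov_rng = streams["covariates"]
    cov = dict(cfg.covariates) if cfg.covariates else {}
    p_male = cov.get("p_male", 0.5)
    p_cs = cov.get("p_cesarean", 0.25)
    p_ebf = cov.get("p_ebf", 0.45)
    p_fh = cov.get("p_family_history", 0.4)
    ige_mean = cov.get("log_ige_mean", {"nonAD": 1.3, "mildAD": 1.7, "modsevAD": 2.0})
    ige_sd = cov.get("log_ige_sd", 0.45)
    log_ige = np.array(
        [cov_rng.normal(ige_mean[g], ige_sd) for g in groups], dtype=float
    )
    meta = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "subject_id": [f"subj{i:04d}" for i in range(n)],  # one sample per subject
            "age_months": ages,
            "group": groups,
            "sex": np.where(cov_rng.random(n) < p_male, "male", "female"),
            "delivery": np.where(cov_rng.random(n) < p_cs, "cesarean", "vaginal"),
            "ebf": np.where(cov_rng.random(n) < p_ebf, "yes", "no"),
            "family_history": np.where(cov_rng.random(n) < p_fh, "yes", "no"),
            "total_ige": 10.0 ** log_ige,
            "egg_ige": 10.0 ** (log_ige - 1.0 + cov_rng.normal(0, 0.3, n)),
            "milk_ige": 10.0 ** (log_ige - 1.2 + cov_rng.normal(0, 0.3, n)),
        }
    )
    meta = validate_metadata(meta)

    truth = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "latent_maturity": m,
            "producer_load": load,
            "late_archetype_mass": composition[:, :].dot(
                _late_mass_weights(cfg)
            ),
        }
    ).set_index("sample_id", drop=False)
    return Cohort(table, meta, scfa_df, truth, cfg)


def _late_mass_weights(cfg: CohortConfig) -> np.ndarray:
    """Weight vector whose dot with a composition tracks late-archetype mass.

    Uses taxa where the late archetype clearly dominates the early one.
    """
    return (cfg.archetype_late > 2.0 * cfg.archetype_early).astype(float)


# ---------------------------------------------------------------------------
# benchmark generators
# ---------------------------------------------------------------------------

def generate_correlated_counts(
    n_samples: int,
    sigma: np.ndarray,
    depth: int = 5000,
    seed: int = 0,
    log_mean: np.ndarray | None = None,
) -> tuple[AbundanceTable, np.ndarray]:
    """Compositional counts with a known basis correlation structure.

    Basis abundances are ``exp(MVN(log_mean, sigma))`` (``sigma`` given
    as a correlation matrix of the log-basis), closed to a composition
    and multinomially sampled at ``depth``.  Returns the count table and
    the ground-truth basis correlation matrix for recovery tests.
    """
    sigma = np.asarray(sigma, dtype=float)
    if not np.allclose(sigma, sigma.T):
        raise ValueError("sigma must be symmetric")
    try:
        chol = np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError as e:
        raise ValueError("sigma must be positive definite") from e
    f = sigma.shape[0]
    rng = np.random.default_rng(seed)
    mu = np.zeros(f) if log_mean is None else np.asarray(log_mean, dtype=float)
    logs = rng.standard_normal((n_samples, f)) @ chol.T + mu
    basis = np.exp(logs)
    comp = basis / basis.sum(axis=1, keepdims=True)
    counts = np.vstack([rng.multinomial(depth, p) for p in comp])
    table = AbundanceTable(
        pd.DataFrame(
            counts,
            index=[f"S{i:04d}" for i in range(n_samples)],
            columns=[f"sp{j:02d}" for j in range(f)],
        ),
        kind="counts",
    )
    return table, sigma


def generate_genefamily_metabolite(
    n_samples: int,
    n_genes: int = 200,
    n_informative: int = 10,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> tuple[AbundanceTable, pd.DataFrame, np.ndarray]:
    """Gene-family table plus a metabolite that is a sparse linear function of it.

    Butyrate is the planted metabolite — a positive sparse linear
    combination of ``n_informative`` gene families plus Gaussian noise —
    while the remaining five SCFAs are pure noise, so the same dataset
    exercises both the recovery and the no-signal paths of the
    metabolite predictor.  Returns (gene table, SCFA table, true weights).
    """
    if n_informative > n_genes:
        raise ValueError("n_informative cannot exceed n_genes")
    rng = np.random.default_rng(seed)
    basis = np.exp(rng.standard_normal((n_samples, n_genes)))
    genes = basis / basis.sum(axis=1, keepdims=True)
    weights = np.zeros(n_genes)
    informative = rng.choice(n_genes, size=n_informative, replace=False)
    weights[informative] = rng.uniform(0.5, 1.5, size=n_informative)
    signal = genes @ weights
    signal = signal / (signal.std() + 1e-12)
    y = 10.0 + 4.0 * signal + rng.normal(0.0, noise_sd, size=n_samples)
    sample_ids = [f"S{i:04d}" for i in range(n_samples)]
    scfa = pd.DataFrame(
        {name: np.clip(rng.normal(5.0, 1.0, n_samples), 0, None) for name in SCFA_NAMES},
        index=sample_ids,
    )
    scfa["butyrate"] = np.clip(y, 0.0, None)
    table = AbundanceTable(
        pd.DataFrame(
            genes, index=sample_ids, columns=[f"UniRef90_G{j:04d}" for j in range(n_genes)]
        ),
        kind="relative",
    )
    return table, scfa, weights
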