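"""End-to-end analysis pipeline with a run manifest.

Stage order mirrors the analysis flow: data (synthetic cohort or user
tables) -> community typing -> ordination statistics -> maturity
scoring -> indicator species -> co-occurrence network -> SCFA
prediction.  Every artifact is a TSV/JSON file recorded in
``manifest.json`` with its SHA-256 hash and the seed of the stage that
produced it, so a rerun with the same configuration is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .data import (
    AbundanceTable,
    filter_features,
    read_abundance_table,
    read_metadata,
    to_relative,
    validate_scfa,
    write_abundance_table,
)
from .dmm import dmm_assign, dmm_select_k
from .ecology import bray_curtis, envfit, heterogeneity_curve, nmds, permanova, shannon_diversity
from .indicators import indval_indicators, kruskal_dunn_bh
from .maturity import (
    fit_age_model,
    fit_scfa_age_model,
    maturity_correlation,
    predict_ema,
    predict_scfa_age,
    z_score_by_age,
)
from .metabolites import predict_metabolites, rtsi_scores, train_predictor
from .network import bootstrap_pseudo_pvalues, build_network, rank_hubs, sparcc_correlations
from .simulate import default_config, generate_cohort

log = logging.getLogger(__name__)

ALL_STAGES = ("data", "typing", "stats", "maturity", "indicators", "network", "predict-scfa")

_KNOWN_KEYS = {
    "outdir",
    "seed",
    "stages",
    "synthetic",
    "inputs",
    "reference_group",
    "typing",
    "stats",
    "maturity",
    "indicators",
    "network",
    "predict_scfa",
}


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


@dataclass
class PipelineConfig:
    outdir: str = "gutdev_run"
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    synthetic: dict | None = None     # synthetic-cohort overrides (n_samples, ...)
    inputs: dict | None = None        # paths: abundance, metadata, scfa
    reference_group: str = "nonAD"
    typing: dict = field(default_factory=lambda: {"k_min": 1, "k_max": 5, "max_iter": 300, "restarts": 3})
    stats: dict = field(default_factory=lambda: {"n_perm": 999})
    maturity: dict = field(default_factory=lambda: {"n_trees": 1000, "select_features": False})
    indicators: dict = field(default_factory=lambda: {"n_perm": 10000, "alpha": 0.05})
    network: dict = field(default_factory=lambda: {"n_boot": 1000, "alpha": 0.05, "top_n": 5, "n_nodes": 10})
    predict_scfa: dict = field(default_factory=lambda: {"folds": 10})

    def __post_init__(self) -> None:
        if self.synthetic is not None and self.inputs is not None:
            raise ConfigError("supply exactly one of 'synthetic' and 'inputs'")
        unknown = [s for s in self.stages if s not in ALL_STAGES]
        if unknown:
            raise ConfigError(f"unknown stage(s): {unknown}")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ConfigError(f"unknown configuration key(s): {sorted(unknown)}")
        raw.update(overrides)
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)


class PipelineRun:
    """Holds in-memory state and writes manifest-tracked artifacts."""

    def __init__(self, cfg: PipelineConfig):
        self.cfg = cfg
        self.outdir = Path(cfg.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.manifest: dict = {
            "version": __version__,
            "seed": cfg.seed,
            "stages": [],
            "artifacts": {},
        }
        self.summary: dict = {}
        root = np.random.SeedSequence(cfg.seed)
        self.stage_seeds = {
            s: int(child.generate_state(1)[0] % (2**31))
            for s, child in zip(ALL_STAGES, root.spawn(len(ALL_STAGES)))
        }
        self.counts: AbundanceTable | None = None
        self.meta: pd.DataFrame | None = None
        self.scfa: pd.DataFrame | None = None
        self.gmt: pd.Series | None = None

    # -- bookkeeping -----------------------------------------------------
    def _record(self, stage: str, path: Path) -> None:
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        self.manifest["artifacts"][path.name] = {
            "stage": stage,
            "sha256": digest,
            "seed": self.stage_seeds.get(stage),
        }

    def write_df(self, stage: str, name: str, df: pd.DataFrame, index: bool = True) -> Path:
        path = self.outdir / name
        df.to_csv(path, sep="\t", index=index, float_format="%.10g")
        self._record(stage, path)
        return path

    def write_json(self, stage: str, name: str, obj: dict) -> Path:
        path = self.outdir / name
        path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=str))
        self._record(stage, path)
        return path

    # -- stages ----------------------------------------------------------
    def stage_data(self) -> None:
        seed = self.stage_seeds["data"]
        if self.cfg.inputs is not None:
            paths = self.cfg.inputs
            self.counts = read_abundance_table(paths["abundance"])
            self.meta = read_metadata(paths["metadata"])
            if "scfa" in paths:
                self.scfa = validate_scfa(
                    pd.read_csv(paths["scfa"], sep="\t", index_col=0)
                )
        else:
            overrides = dict(self.cfg.synthetic or {})
            n = overrides.pop("n_samples", 300)
            cohort = generate_cohort(default_config(n_samples=n, seed=seed, **overrides))
            self.counts, self.meta, self.scfa = cohort.counts, cohort.metadata, cohort.scfa
            path = self.outdir / "counts.tsv"
            write_abundance_table(self.counts, path)
            self._record("data", path)
            self.write_df("data", "metadata.tsv", self.meta.drop(columns=["sample_id"]))
            self.write_df("data", "scfa.tsv", self.scfa)
            self.write_df("data", "ground_truth.tsv", cohort.truth.drop(columns=["sample_id"]))

    def stage_typing(self) -> None:
        p = self.cfg.typing
        model = dmm_select_k(
            self.counts,
            range(p.get("k_min", 1), p.get("k_max", 5) + 1),
            seed=self.stage_seeds["typing"],
            max_iter=p.get("max_iter", 300),
            restarts=p.get("restarts", 3),
        )
        labels, posterior = dmm_assign(model, self.counts)
        self.gmt = labels.map(lambda k: f"GMT{k + 1}")
        out = posterior.copy()
        out.insert(0, "gmt", self.gmt)
        self.write_df("typing", "gmt_assignments.tsv", out)
        self.write_json("typing", "dmm_model.json", model.to_json_dict())
        self.summary["selected_k"] = model.K
        self.summary["laplace_scores"] = {str(k): v for k, v in model.k_scores.items()}

    def stage_stats(self) -> None:
        seed = self.stage_seeds["stats"]
        n_perm = self.cfg.stats.get("n_perm", 999)
        rel = to_relative(self.counts)
        dist = bray_curtis(rel)
        self.write_df("stats", "bray_curtis.tsv", dist.to_frame())
        self.write_df("stats", "shannon.tsv", shannon_diversity(rel).to_frame())
        ord_ = nmds(dist, seed=seed)
        coords = pd.DataFrame(
            ord_.coordinates, index=ord_.ids,
            columns=[f"NMDS{i+1}" for i in range(ord_.coordinates.shape[1])],
        )
        self.write_df("stats", "nmds.tsv", coords)
        res = permanova(dist, self.meta["group"], n_perm=n_perm, seed=seed)
        self.summary["permanova_group"] = {
            "pseudo_F": res.pseudo_F, "R2": res.R2, "p": res.p, "stress": ord_.stress,
        }
        covs = [c for c in ("age_months", "sex", "delivery", "ebf", "family_history",
                            "total_ige", "egg_ige", "milk_ige", "group")
                if c in self.meta.columns]
        ef = envfit(ord_, self.meta[covs], n_perm=n_perm, seed=seed)
        self.write_df("stats", "envfit.tsv", ef)
        curves = []
        for g in sorted(self.meta["group"].unique()):
            if (self.meta["group"] == g).sum() >= 10:
                c = heterogeneity_curve(dist, self.meta, g, seed=seed)
                c.insert(0, "group", g)
                curves.append(c)
        if curves:
            self.write_df("stats", "heterogeneity.tsv", pd.concat(curves), index=False)

    def stage_maturity(self) -> None:
        p = self.cfg.maturity
        seed = self.stage_seeds["maturity"]
        rel = to_relative(self.counts)
        am = fit_age_model(
            rel, self.meta,
            reference_group=self.cfg.reference_group,
            n_trees=p.get("n_trees", 1000),
            seed=seed,
            select_features=p.get("select_features", False),
        )
        ema = predict_ema(am, rel)
        maz = z_score_by_age(ema, self.meta, am.reference_stats)
        scores = pd.DataFrame({"ema": ema, "maz": maz})
        scfa_for_saz = self.scfa
        if self.scfa is not None and p.get("saz_source", "measured") == "predicted":
            # SAZ from metagenome-predicted SCFAs instead of measured ones
            import warnings as _w

            with _w.catch_warnings():
                _w.simplefilter("ignore")
                predictor = train_predictor(rel, self.scfa, seed=seed)
                scfa_for_saz = predict_metabolites(predictor, rel)
        if self.scfa is not None:
            sm = fit_scfa_age_model(
                scfa_for_saz, self.meta,
                reference_group=self.cfg.reference_group,
                n_trees=p.get("n_trees", 1000),
                seed=seed,
            )
            sage = predict_scfa_age(sm, scfa_for_saz)
            scores["scfa_age"] = sage
            scores["saz"] = z_score_by_age(sage, self.meta, sm.reference_stats)
            r, pv = maturity_correlation(scores)
            self.summary["saz_maz_pearson_r"] = r
            self.summary["saz_maz_p"] = pv
            self.write_df(
                "maturity", "scfa_importance.tsv", sm.feature_importances.to_frame("importance")
            )
        self.write_df("maturity", "maturity_scores.tsv", scores)
        self.write_df(
            "maturity", "taxa_importance.tsv", am.feature_importances.to_frame("importance")
        )
        self._age_model = am

    def stage_indicators(self) -> None:
        p = self.cfg.indicators
        seed = self.stage_seeds["indicators"]
        rel = to_relative(self.counts)
        # indicators are defined on the reference (non-AD) samples per age bin
        ref_ids = [s for s in rel.sample_ids
                   if self.meta.loc[s, "group"] == self.cfg.reference_group]
        ref = rel.subset_samples(ref_ids)
        ref.kind = "relative"
        kept = filter_features(ref, self.meta.loc[ref_ids, "age_bin"])
        kept.kind = "relative"
        res = indval_indicators(
            kept, self.meta.loc[ref_ids, "age_bin"],
            n_perm=p.get("n_perm", 10000), seed=seed, alpha=p.get("alpha", 0.05),
        )
        self.write_df("indicators", "indicators.tsv", res)
        sig = res.index[res["significant"]].tolist()
        self.summary["n_indicators"] = len(sig)
        if sig:
            # compare indicator abundances across phenotype groups
            sub = AbundanceTable(rel.values.loc[:, sig], kind="counts")
            sub.kind = "relative"
            diff = kruskal_dunn_bh(sub, self.meta["group"])
            diff["pairwise"] = diff["pairwise"].map(json.dumps)
            self.write_df("indicators", "indicator_group_differences.tsv", diff)

    def stage_network(self) -> None:
        p = self.cfg.network
        seed = self.stage_seeds["network"]
        if self.gmt is None:
            labels, _ = dmm_assign(
                dmm_select_k(self.counts, range(1, 4), seed=seed), self.counts
            )
            self.gmt = labels.map(lambda k: f"GMT{k + 1}")
        rel = to_relative(self.counts)
        kept = filter_features(rel, self.meta["group"])
        kept.kind = "relative"
        counts_kept = AbundanceTable(
            self.counts.values.loc[:, kept.feature_ids], kind="counts"
        )
        # top-n features per community type by forest importance
        from sklearn.ensemble import RandomForestClassifier

        tops: dict[str, list[str]] = {}
        for g in sorted(self.gmt.unique()):
            rf = RandomForestClassifier(n_estimators=500, random_state=seed, n_jobs=1)
            rf.fit(kept.matrix(), (self.gmt == g).to_numpy())
            order = np.argsort(rf.feature_importances_)[::-1][: p.get("n_nodes", 10)]
            tops[g] = [kept.feature_ids[i] for i in order]
        # "common" taxa across community types: intersection by default,
        # union behind a flag
        if len(tops) > 1 and p.get("common", "intersection") == "union":
            common = sorted(set().union(*(set(v) for v in tops.values())))
        elif len(tops) > 1:
            common = sorted(set.intersection(*(set(v) for v in tops.values())))
        else:
            common = []
        nodes = sorted(set().union(*tops.values()))
        rho, _ = sparcc_correlations(counts_kept, seed=seed)
        pseudo = bootstrap_pseudo_pvalues(
            counts_kept, rho, n_boot=p.get("n_boot", 1000), seed=seed
        )
        net = build_network(rho, pseudo, alpha=p.get("alpha", 0.05), node_subset=nodes)
        if net.graph.number_of_edges() > 0:
            net = rank_hubs(net, top_n=p.get("top_n", 5))
            hubs = pd.DataFrame(
                {"pagerank": net.pagerank, "eigencentrality": net.eigencentrality}
            )
            hubs["hub"] = hubs.index.isin(net.hubs)
            self.write_df("network", "network_centrality.tsv", hubs)
            self.summary["hubs"] = net.hubs
        self.write_df("network", "network_edges.tsv", net.edges, index=False)
        self.write_json(
            "network",
            "network_groups.json",
            {"top_per_gmt": tops, "common": common},
        )
        import networkx as nx

        nx.write_graphml(net.graph, self.outdir / "network.graphml")
        self._record("network", self.outdir / "network.graphml")

    def stage_predict_scfa(self) -> None:
        if self.scfa is None:
            log.warning("no SCFA table; predict-scfa stage skipped")
            return
        p = self.cfg.predict_scfa
        seed = self.stage_seeds["predict-scfa"]
        rel = to_relative(self.counts)
        import warnings as _w

        with _w.catch_warnings():
            _w.simplefilter("ignore")
            model = train_predictor(rel, self.scfa, folds=p.get("folds", 10), seed=seed)
            preds = predict_metabolites(model, rel)
            rtsi = rtsi_scores(model, rel)
        self.write_df("predict-scfa", "scfa_predictability.tsv", model.predictability())
        self.write_df("predict-scfa", "scfa_predicted.tsv", preds)
        self.write_df("predict-scfa", "rtsi.tsv", rtsi.to_frame())
        self.summary["well_predicted"] = [
            m for m, mod in model.models.items() if mod.well_predicted
        ]


_STAGE_FUNCS = {
    "data": PipelineRun.stage_data,
    "typing": PipelineRun.stage_typing,
    "stats": PipelineRun.stage_stats,
    "maturity": PipelineRun.stage_maturity,
    "indicators": PipelineRun.stage_indicators,
    "network": PipelineRun.stage_network,
    "predict-scfa": PipelineRun.stage_predict_scfa,
}


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the enabled stages in dependency order; returns the manifest."""
    run = PipelineRun(cfg)
    stages = [s for s in ALL_STAGES if s in cfg.stages]
    if "data" not in stages:
        stages = ["data"] + stages  # every stage needs the data
    for stage in stages:
        log.info("stage %s (seed %d)", stage, run.stage_seeds[stage])
        try:
            _STAGE_FUNCS[stage](run)
        except Exception:
            run.manifest["stages"].append({"stage": stage, "status": "failed"})
            run.write_json("manifest", "manifest.json", run.manifest)
            raise
        run.manifest["stages"].append({"stage": stage, "status": "complete"})
    run.write_json("summary", "summary.json", run.summary)
    run.write_json("manifest", "manifest.json", run.manifest)
    return run.manifest
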