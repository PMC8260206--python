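"""End-to-end orchestration: simulate -> burden -> cluster -> tree -> spatial.

``run_pipeline`` executes the stages against either a simulated gland
or user-supplied tables, writes every stage's artefacts into the
output directory and returns (and writes) a summary report.  All
randomness flows from the single pipeline seed, so two runs with the
same configuration produce byte-identical reports.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as gio
from .burden import ClockError, SensitivityModel, estimate_burdens, fit_clock
from .cluster import ClusterConfig, cluster_mutations
from .ductal import DuctalGraph
from .matrix import VafMatrix
from .phylogeny import (
    CloneTree,
    adult_coalescences,
    build_tree,
    classify_tree_epochs,
    infer_nesting,
    supporting_samples,
)
from .simulate import SimulationConfig, simulate_gland
from .spatial import (
    adult_clone_span,
    all_path_distances,
    clone_territory,
    gradient_regression,
    mds_2d,
    multiclonal_fraction,
    multiclonality_vs_distance,
)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class PipelineConfig:
    out_dir: str = "glandphylo_out"
    seed: int = 0
    simulate: bool = True
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    mutations_path: str | None = None
    samples_path: str | None = None
    duct_path: str | None = None
    sensitivity_mode: str = "binomial_tail"
    genome_fraction: float = 0.75
    cluster: ClusterConfig = field(default_factory=ClusterConfig)
    min_cluster_size: int = 10
    cc_presence: float = 0.10
    pigeonhole_tolerance: float = 0.1
    epoch_boundaries: tuple[float, float, float] = (20.0, 300.0, 500.0)
    max_adult_samples: int = 5

    def validate(self) -> None:
        if not 0 <= self.cc_presence <= 1 or not 0 <= self.genome_fraction <= 1:
            raise ValueError("thresholds must lie in [0, 1]")
        b = self.epoch_boundaries
        if not (b[0] < b[1] < b[2]):
            raise ValueError("epoch boundaries must be strictly increasing")
        if not self.simulate and not (self.mutations_path and self.samples_path):
            raise ValueError("without simulation, mutation and sample tables are required")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimulationConfig(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in raw.pop("sim", {}).items()
        })
        cluster = ClusterConfig(**raw.pop("cluster", {}))
        if "epoch_boundaries" in raw:
            raw["epoch_boundaries"] = tuple(raw["epoch_boundaries"])
        return cls(sim=sim, cluster=cluster, **raw)

    def config_hash(self) -> str:
        def default(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            raise TypeError

        payload = dataclasses.asdict(self)
        # hash the scientific configuration, not file locations
        for key in ("out_dir", "mutations_path", "samples_path", "duct_path"):
            payload.pop(key, None)
        blob = json.dumps(payload, sort_keys=True, default=default)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "thresholds": {
            "cc_presence": config.cc_presence,
            "min_cluster_size": config.min_cluster_size,
            "genome_fraction": config.genome_fraction,
            "epoch_boundaries": list(config.epoch_boundaries),
            "pigeonhole_tolerance": config.pigeonhole_tolerance,
        },
    }

    # -- inputs -------------------------------------------------------
    try:
        if config.simulate:
            sim_cfg = dataclasses.replace(config.sim, seed=config.seed)
            sim = simulate_gland(sim_cfg)
            vm, samples, graph = sim.vaf_matrix, sim.samples, sim.graph
            gio.write_mutation_table(vm, out / "mutations.tsv")
            gio.write_samples(samples, out / "samples.tsv")
            gio.write_duct(graph, out / "duct.json")
            gio.write_truth(sim.truth, out / "truth.json")
        else:
            vm = gio.read_mutation_table(config.mutations_path)
            samples = gio.read_samples(config.samples_path)
            graph = gio.read_duct(config.duct_path) if config.duct_path else None
    except gio.SchemaError:
        raise
    except Exception as exc:
        raise StageError("simulate", exc) from exc
    samples = samples.reset_index(drop=True)

    # -- burden + clock ----------------------------------------------
    try:
        model = SensitivityModel(mode="binomial_tail") \
            if config.sensitivity_mode in ("binomial_tail", "binomial") \
            else _trained_glm(config.seed)
        burden = estimate_burdens(vm, model=model, genome_fraction=config.genome_fraction)
        burden = burden.merge(
            samples[["sample_id", "donor_id", "age_years"]], on="sample_id", how="left"
        ).rename(columns={"donor_id": "donor", "age_years": "age"})
        gio.write_burden(burden, out / "burden.tsv")
        included = burden[burden["included"]]
        clock = None
        if included["age"].nunique() >= 2:
            tab = included.rename(columns={"b_c": "b_c"})
            try:
                clock = fit_clock(tab)
            except ClockError:
                clock = None
        gio.write_clock_fit(clock, out / "clockfit.json")
        report["clock_fit"] = None if clock is None else clock.to_dict()
        if clock is None:
            report["clock_note"] = "single donor age: clock not identifiable"
        report["burden"] = {
            "n_samples": int(len(burden)),
            "n_included": int(burden["included"].sum()),
            "median_b_c": float(np.nanmedian(burden["b_c"])),
            "median_clonality": float(np.nanmedian(burden["c"])),
        }
    except Exception as exc:
        raise StageError("burden", exc) from exc

    # -- clustering ---------------------------------------------------
    try:
        ccfg = dataclasses.replace(config.cluster, seed=config.seed)
        result = cluster_mutations(vm, ccfg)
        filtered = result.filtered(config.min_cluster_size)
        gio.write_clusters(
            filtered, out / "clusters.tsv", out / "cluster_cc.tsv",
            out / "diagnostics.json",
        )
        report["clusters"] = {
            "n_clusters": int(len(filtered.clusters)),
            "n_mutations_clustered": int(len(filtered.assignments)),
            "converged": bool(result.converged),
        }
    except Exception as exc:
        raise StageError("cluster", exc) from exc

    # -- clone tree ---------------------------------------------------
    try:
        cc = filtered.cc
        n_mut = filtered.clusters.set_index("cluster_id")["n_mutations"]
        evidence, conflicts = infer_nesting(cc, tolerance=config.pigeonhole_tolerance)
        tree = build_tree(cc, n_mut, evidence, tolerance=config.pigeonhole_tolerance)
        epochs = classify_tree_epochs(tree, config.epoch_boundaries)
        gio.write_tree(tree, out / "tree.nwk")
        gio.write_evidence(
            evidence, conflicts, out / "nesting_evidence.tsv", out / "conflicts.tsv"
        )
        coal = [c for c in tree.clusters if len(tree.children(c)) >= 2]
        epoch_hist: dict[str, int] = {}
        for c in coal:
            epoch_hist[epochs[c]] = epoch_hist.get(epochs[c], 0) + 1
        support = {
            c: supporting_samples(cc.loc[c], config.cc_presence) for c in tree.clusters
        }
        report["tree"] = {
            "n_clusters": len(tree.clusters),
            "n_conflicts": len(conflicts),
            "n_ambiguous": len(tree.ambiguous),
            "coalescence_epochs": dict(sorted(epoch_hist.items())),
            "adult_coalescences": adult_coalescences(tree),
            "mean_supporting_samples": float(np.mean(list(support.values())))
            if support
            else 0.0,
        }
    except Exception as exc:
        raise StageError("tree", exc) from exc

    # -- spatial ------------------------------------------------------
    try:
        spatial_report: dict = {}
        xyz = samples[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)
        emb = None
        if len(samples) >= 3:
            emb, _ = mds_2d(xyz)
        dist = None
        if graph is not None:
            dists = all_path_distances(graph)
            dist = samples["duct_node"].map(dists)
        spatial_df = pd.DataFrame(
            {
                "sample_id": samples["sample_id"],
                "path_distance_um": np.nan if dist is None else dist,
                "mds1": np.nan if emb is None else emb[:, 0],
                "mds2": np.nan if emb is None else emb[:, 1],
            }
        )
        gio.write_spatial(spatial_df, out / "spatial.tsv")

        gradients: dict = {}
        merged = burden.set_index("sample_id")
        if dist is not None:
            ok = merged.loc[samples["sample_id"], "b_c"].notna()
            if ok.sum() >= 3 and np.ptp(dist[ok.to_numpy()]) > 0:
                gradients["burden_vs_distance"] = gradient_regression(
                    merged.loc[samples["sample_id"], "b_c"].to_numpy()[ok.to_numpy()],
                    dist.to_numpy()[ok.to_numpy()],
                ).to_dict()
                gradients["telomere_vs_distance"] = gradient_regression(
                    samples["telomere_bp"].to_numpy()[ok.to_numpy()],
                    dist.to_numpy()[ok.to_numpy()],
                ).to_dict()
        bc = merged.loc[samples["sample_id"], "b_c"]
        if bc.notna().sum() >= 3:
            gradients["telomere_vs_burden"] = gradient_regression(
                samples["telomere_bp"].to_numpy()[bc.notna().to_numpy()],
                bc.to_numpy()[bc.notna().to_numpy()],
            ).to_dict()
        territories = []
        if graph is not None:
            node_series = samples.set_index("sample_id")["duct_node"]
            for cid in cc.index:
                territories.append(
                    clone_territory(
                        graph, cc.loc[cid], node_series, config.cc_presence, cid
                    )
                )
            gio.write_territories(territories, out / "territories.tsv")
            spans = adult_clone_span(
                epochs, {t.cluster_id: t for t in territories},
                config.max_adult_samples,
            )
            spatial_report["adult_expansion_flags"] = sorted(
                spans[spans["flagged_expansion"]]["cluster_id"]
            )
        emb_clusters = [c for c, e in epochs.items() if e == "embryonic"]
        if emb_clusters:
            mc = multiclonal_fraction(cc.loc[emb_clusters], config.cc_presence)
            spatial_report["multiclonal"] = {
                "numerator": mc.numerator,
                "denominator": mc.denominator,
                "percent": mc.percent,
            }
            if dist is not None:
                flags = (
                    (cc.loc[emb_clusters] > config.cc_presence).sum(axis=0) >= 2
                ).reindex(samples["sample_id"]).astype(float)
                spatial_report["multiclonality_vs_distance"] = (
                    multiclonality_vs_distance(flags.to_numpy(), dist.to_numpy())
                )
        gio.write_gradients(gradients, out / "gradients.json")
        spatial_report["gradients"] = gradients
        report["spatial"] = spatial_report
    except Exception as exc:
        raise StageError("spatial", exc) from exc

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, sort_keys=True, indent=1)
    return report


def _trained_glm(seed: int) -> SensitivityModel:
    from .burden import train_sensitivity_glm

    return train_sensitivity_glm(np.random.default_rng(seed))
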