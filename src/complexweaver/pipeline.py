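"""End-to-end orchestration: configuration schema, run manifest, and
the two-step pipeline (rank pairs, then reconstruct + detect +
evaluate)."""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .core import ComplexSet
from .detection import MCLParams, filter_complexes, mcl_cluster
from .evaluation import match_and_score
from .features import (
    FeatureSchema,
    apply_binning,
    assemble_features,
    filter_pairs,
    fit_binning,
)
from .io_formats import write_complexes, write_edge_list, write_ranked_pairs
from .lpu import EnsembleSpec, build_ensemble, score_and_rank
from .reconstruction import ReconstructionRecipe, reconstruct_network
from .synthetic import NoiseSpec, generate_evidence, generate_pool, generate_truth

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "load_config"]

_ALLOWED_KEYS = {
    "seed", "outdir",
    "simulate", "features", "lpu", "reconstruct", "detect", "evaluate",
}
_ALLOWED_SUBKEYS = {
    "simulate": {
        "n_proteins", "n_complexes", "size_range", "within_p", "between_p",
        "noise",
    },
    "features": {"bins_per_feature", "filter_enabled", "type2_threshold", "pearson_threshold"},
    "lpu": {"m", "n", "mode", "ratios", "fixed_ratio", "normalize"},
    "reconstruct": {"top_n", "copy_scores_as_weights"},
    "detect": {"inflation", "expansion", "max_iterations", "tolerance",
               "prune_threshold", "min_cluster_size"},
    "evaluate": {"omega", "min_size"},
}


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "run"
    simulate: dict = field(default_factory=dict)
    features: dict = field(default_factory=dict)
    lpu: dict = field(default_factory=dict)
    reconstruct: dict = field(default_factory=dict)
    detect: dict = field(default_factory=dict)
    evaluate: dict = field(default_factory=dict)


def load_config(path: str | Path) -> PipelineConfig:
    """Load a YAML config, rejecting unknown keys (typo safety)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    unknown = set(raw) - _ALLOWED_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for section, allowed in _ALLOWED_SUBKEYS.items():
        bad = set(raw.get(section, {}) or {}) - allowed
        if bad:
            raise ValueError(f"unknown keys in {section!r}: {sorted(bad)}")
    return PipelineConfig(**raw)


@dataclass
class RunManifest:
    """Provenance record tying every pipeline product to the run that
    made it: config snapshot, derived per-stage seeds, package version,
    stage timings and output digests."""

    config: dict
    version: str
    stage_seeds: dict[str, int]
    timings: dict[str, float] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)
    digests: dict[str, str] = field(default_factory=dict)
    completed: list[str] = field(default_factory=list)

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage_seeds(master: int) -> dict[str, int]:
    names = ["truth", "evidence", "pool", "lpu"]
    children = np.random.SeedSequence(master).spawn(len(names))
    return {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(names, children)
    }


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Simulate -> features -> rank -> reconstruct -> detect -> evaluate.

    All intermediate files are persisted under ``config.outdir``;
    re-running with identical config reproduces byte-identical outputs.
    Returns the manifest (also written to ``manifest.json``).
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    manifest = RunManifest(
        config=asdict(config), version=__version__, stage_seeds=seeds
    )

    def finish(stage: str, t0: float, *paths: Path) -> None:
        manifest.timings[stage] = round(time.perf_counter() - t0, 3)
        for p in paths:
            manifest.outputs[p.stem] = str(p)
            manifest.digests[p.name] = _sha256(p)
        manifest.completed.append(stage)
        manifest.save(outdir / "manifest.json")

    try:
        t0 = time.perf_counter()
        sim = dict(config.simulate)
        noise = NoiseSpec(**(sim.pop("noise", {}) or {}))
        if "size_range" in sim:
            sim["size_range"] = tuple(sim["size_range"])
        truth = generate_truth(seed=seeds["truth"], **sim)
        store = generate_evidence(truth, noise=noise, seed=seeds["evidence"])
        pool, hidden = generate_pool(truth, seed=seeds["pool"])
        planted_path = outdir / "planted_complexes.txt"
        write_complexes(truth.complexes, planted_path)
        finish("simulate", t0, planted_path)

        t0 = time.perf_counter()
        fcfg = config.features
        schema = FeatureSchema.from_store(store)
        pairs = sorted(pool.positives | pool.unlabeled)
        feats = assemble_features(pairs, store, schema)
        if fcfg.get("filter_enabled", True):
            kept = filter_pairs(
                feats,
                type2_threshold=fcfg.get("type2_threshold", 0.002),
                pearson_threshold=fcfg.get("pearson_threshold", 0.5),
            )
            kept_set = set(kept) | pool.positives
            feats = feats.loc[sorted(kept_set)]
        spec_bins = fit_binning(feats, fcfg.get("bins_per_feature", 5))
        binary = apply_binning(feats, spec_bins)
        features_path = outdir / "features.tsv"
        feats.to_csv(features_path, sep="\t")
        finish("features", t0, features_path)

        t0 = time.perf_counter()
        lcfg = dict(config.lpu)
        spec = EnsembleSpec(seed=seeds["lpu"], **lcfg)
        pool_kept = type(pool)(
            positives=pool.positives,
            unlabeled=pool.unlabeled & set(binary.index),
        )
        members = build_ensemble(pool_kept, binary, spec)
        ranked = score_and_rank(
            members, binary, pool_kept.unlabeled, normalize=spec.normalize
        )
        ranked_path = outdir / "ranked.tsv"
        write_ranked_pairs(ranked, ranked_path)
        finish("rank", t0, ranked_path)

        t0 = time.perf_counter()
        rcfg = config.reconstruct
        top_n = rcfg.get("top_n", min(len(hidden), len(ranked)))
        recipe = ReconstructionRecipe(
            reliable=pool.positives,
            ranked=ranked,
            top_n=top_n,
            copy_scores_as_weights=rcfg.get("copy_scores_as_weights", False),
        )
        network = reconstruct_network(recipe)
        network_path = outdir / "network.tsv"
        write_edge_list(network, network_path)
        finish("reconstruct", t0, network_path)

        t0 = time.perf_counter()
        params = MCLParams(**config.detect)
        result = mcl_cluster(network, params)
        clusters_path = outdir / "clusters.txt"
        write_complexes(result.clusters, clusters_path)
        finish("detect", t0, clusters_path)

        t0 = time.perf_counter()
        ecfg = config.evaluate
        benchmark = filter_complexes(truth.complexes, ecfg.get("min_size", 3))
        match = match_and_score(
            result.clusters, benchmark, omega=ecfg.get("omega", 0.25)
        )
        report = {
            "omega": match.omega,
            "precision": match.precision,
            "recall": match.recall,
            "f_measure": match.f_measure,
            "n_cp": match.n_cp,
            "n_cb": match.n_cb,
            "n_predicted": len(result.clusters),
            "n_reference": len(benchmark),
        }
        report_path = outdir / "report.json"
        with open(report_path, "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        finish("evaluate", t0, report_path)
    except Exception:
        manifest.save(outdir / "manifest.json")  # record partial completion
        raise
    return manifest
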