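"""Run configuration: validation with defaults, and the end-to-end pipeline.

A run config is a small YAML/JSON document::

    network:
      generate: {n_nodes: 10, n_partial: 8, n_random: 8, partial_fraction: 0.2}
      # or: path: DIR containing *.graphml
    kernel: {a: 0.1, b: -0.0430, mode: distance_dependent, eval_range_mm: [15, 190]}
    demography: {repro_prob: 0.15, ...}          # optional overrides
    duration: 200
    replicates: 50
    n0: 200
    source: 0
    seed: 1

Unknown keys are rejected with their full key path, so typos fail loudly.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .analysis import occupancy_vs_connectivity, run_occupancy_experiment, speedup_ratios
from .connectivity import connectivity_report
from .io import read_network_graphml, write_network_csv, write_network_graphml
from .kernel import DispersalKernel
from .networks import SpatialHabitatNetwork, generate_topology_set
from .simulate import DemographicParams, simulate

__all__ = ["ConfigError", "RunConfig", "validate_config", "run_pipeline"]


class ConfigError(ValueError):
    """Invalid run configuration; the message names the offending key path."""


_DEMOGRAPHY_KEYS = {
    "n_stages",
    "stage_advance_prob",
    "repro_prob",
    "clutch_size_mean",
    "mortality_prob",
    "density_ceiling",
    "juvenile_age_threshold",
}
_KERNEL_KEYS = {"a", "b", "mode", "eval_range_mm"}
_GENERATE_KEYS = {"n_nodes", "n_partial", "n_random", "partial_fraction"}
_TOP_KEYS = {"network", "kernel", "demography", "duration", "replicates", "n0", "source", "seed", "out"}


@dataclass(frozen=True)
class RunConfig:
    """Fully defaulted, validated configuration for one pipeline run."""

    seed: int
    kernel: DispersalKernel
    demography: DemographicParams
    duration: int = 200
    replicates: int = 50
    n0: int = 200
    source: int = 0
    network_path: str | None = None
    generate: dict = field(default_factory=dict)
    out: str | None = None


def _reject_unknown(block: dict, allowed: set[str], path: str) -> None:
    for key in block:
        if key not in allowed:
            raise ConfigError(f"unknown key {path}{key!r}")


def validate_config(raw: str | dict) -> RunConfig:
    """Parse and validate a config document, filling documented defaults."""
    if isinstance(raw, str):
        try:
            doc = yaml.safe_load(raw)
        except yaml.YAMLError as exc:
            raise ConfigError(f"config is not parseable YAML/JSON: {exc}") from exc
    else:
        doc = dict(raw)
    if not isinstance(doc, dict):
        raise ConfigError("config root must be a mapping")
    _reject_unknown(doc, _TOP_KEYS, "")

    if "seed" not in doc:
        raise ConfigError("missing required key 'seed'")
    seed = doc["seed"]
    if not isinstance(seed, int) or isinstance(seed, bool):
        raise ConfigError("'seed' must be an integer")

    net_block = doc.get("network")
    if not isinstance(net_block, dict) or not net_block:
        raise ConfigError("missing required key 'network' (path or generate block)")
    _reject_unknown(net_block, {"path", "generate"}, "network.")
    network_path = net_block.get("path")
    generate = net_block.get("generate")
    if (network_path is None) == (generate is None):
        raise ConfigError("network must set exactly one of 'network.path' or 'network.generate'")
    if generate is not None:
        _reject_unknown(generate, _GENERATE_KEYS, "network.generate.")
        generate = {
            "n_nodes": generate.get("n_nodes", 10),
            "n_partial": generate.get("n_partial", 8),
            "n_random": generate.get("n_random", 8),
            "partial_fraction": generate.get("partial_fraction", 0.2),
        }
        if generate["n_nodes"] < 5:
            raise ConfigError("'network.generate.n_nodes' must be >= 5")
    else:
        generate = {}

    kernel_block = dict(doc.get("kernel") or {})
    _reject_unknown(kernel_block, _KERNEL_KEYS, "kernel.")
    eval_range = tuple(kernel_block.pop("eval_range_mm", (15.0, 190.0)))
    try:
        kernel = DispersalKernel(
            a=float(kernel_block.get("a", 0.1)),
            b=float(kernel_block.get("b", -0.0430)),
            mode=str(kernel_block.get("mode", "distance_dependent")),
            eval_range=eval_range,
        )
    except ValueError as exc:
        raise ConfigError(f"kernel: {exc}") from exc

    demo_block = dict(doc.get("demography") or {})
    _reject_unknown(demo_block, _DEMOGRAPHY_KEYS, "demography.")
    try:
        demography = DemographicParams(**demo_block)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"demography: {exc}") from exc

    duration = doc.get("duration", 200)
    replicates = doc.get("replicates", 50)
    n0 = doc.get("n0", 200)
    source = doc.get("source", 0)
    if not isinstance(duration, int) or duration < 1:
        raise ConfigError("'duration' must be an integer >= 1")
    if not isinstance(replicates, int) or replicates < 1:
        raise ConfigError("'replicates' must be an integer >= 1")
    if not isinstance(n0, int) or n0 < 1:
        raise ConfigError("'n0' must be an integer >= 1")
    if not isinstance(source, int) or source < 0:
        raise ConfigError("'source' must be a nonnegative integer")
    if network_path is not None and not Path(network_path).exists():
        raise ConfigError(f"'network.path' does not exist: {network_path}")

    return RunConfig(
        seed=seed,
        kernel=kernel,
        demography=demography,
        duration=duration,
        replicates=replicates,
        n0=n0,
        source=source,
        network_path=network_path,
        generate=generate,
        out=doc.get("out"),
    )


def _load_networks(cfg: RunConfig) -> list[SpatialHabitatNetwork]:
    if cfg.network_path is not None:
        paths = sorted(Path(cfg.network_path).glob("*.graphml"))
        if not paths:
            raise ConfigError(f"no *.graphml files under {cfg.network_path}")
        return [read_network_graphml(p) for p in paths]
    return generate_topology_set(cfg.seed, **cfg.generate)


def run_pipeline(cfg: RunConfig, out_dir: str | Path | None = None, write_counts: bool = True) -> dict:
    """Generate → simulate → connectivity → analyze, writing CSVs + manifest.

    Re-running with the same config and seed reproduces identical CSV
    content.  Returns the manifest (also written as ``manifest.json``).
    """
    out = Path(out_dir if out_dir is not None else (cfg.out or "."))
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "started_unix": time.time(),
        "files": [],
        "stages": [],
    }

    def _write(df: pd.DataFrame, name: str) -> None:
        path = out / name
        df.to_csv(path, index=False)
        manifest["files"].append(name)

    stage = "generate-networks"
    try:
        nets = _load_networks(cfg)
        net_dir = out / "networks"
        net_dir.mkdir(exist_ok=True)
        for net in nets:
            write_network_graphml(net, net_dir / f"{net.topology_id}.graphml", seed=cfg.seed)
            write_network_csv(
                net,
                net_dir / f"{net.topology_id}.nodes.csv",
                net_dir / f"{net.topology_id}.edges.csv",
            )
            manifest["files"].append(f"networks/{net.topology_id}.graphml")
        manifest["stages"].append(stage)

        stage = "simulate"
        occ = run_occupancy_experiment(
            nets,
            cfg.demography,
            cfg.kernel,
            replicates=cfg.replicates,
            duration=cfg.duration,
            seed=cfg.seed,
            n0=cfg.n0,
            source=cfg.source,
            stop_when_occupied=not write_counts,
        )
        _write(
            occ[["topology_id", "replicate", "occupancy_day", "censored"]],
            "occupancy.csv",
        )
        if write_counts:
            root = np.random.SeedSequence(cfg.seed)
            children = root.spawn(len(nets) * cfg.replicates)
            frames = []
            for ni, net in enumerate(nets):
                for rep in range(cfg.replicates):
                    res = simulate(
                        net, cfg.demography, cfg.kernel, duration=cfg.duration,
                        seed=children[ni * cfg.replicates + rep],
                        source=cfg.source, n0=cfg.n0,
                    )
                    days, nodes = np.meshgrid(
                        np.arange(res.counts.shape[0]), np.arange(net.n_nodes), indexing="ij"
                    )
                    frames.append(
                        pd.DataFrame(
                            {
                                "topology_id": net.topology_id,
                                "replicate": rep,
                                "day": days.ravel(),
                                "node_id": nodes.ravel(),
                                "count": res.counts.ravel(),
                            }
                        )
                    )
            _write(pd.concat(frames, ignore_index=True), "counts.csv")
        manifest["stages"].append(stage)

        stage = "connectivity"
        reports = [connectivity_report(net, cfg.kernel) for net in nets]
        _write(
            pd.DataFrame(
                {
                    "topology_id": [r.topology_id for r in reports],
                    "rewire_fraction": [r.rewire_fraction for r in reports],
                    "lambda2": [r.algebraic_connectivity for r in reports],
                    "diameter_links": [r.diameter_links for r in reports],
                    "diameter_mm": [r.diameter_mm for r in reports],
                }
            ),
            "connectivity.csv",
        )
        manifest["stages"].append(stage)

        stage = "analyze"
        summary: dict = {}
        configs = set(occ["config_label"])
        if {"lattice", "partial", "random"} <= configs:
            ratios = speedup_ratios(occ, seed=cfg.seed)
            summary["random_vs_lattice"] = ratios.random_vs_lattice
            summary["random_vs_partial"] = ratios.random_vs_partial
            summary["mean_by_config"] = ratios.mean_by_config
            summary["censored_fraction"] = ratios.censored_fraction
        if occ["lambda2"].nunique() >= 3:
            reg = occupancy_vs_connectivity(occ)
            summary["ols_slope"] = reg.slope
            summary["ols_r_squared"] = reg.r_squared
            summary["anova_r_squared"] = reg.anova_r_squared
        (out / "summary.json").write_text(json.dumps(summary, indent=2))
        manifest["files"].append("summary.json")
        manifest["stages"].append(stage)
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    manifest["finished_unix"] = time.time()
    manifest["config"] = {
        "seed": cfg.seed,
        "duration": cfg.duration,
        "replicates": cfg.replicates,
        "n0": cfg.n0,
        "source": cfg.source,
        "kernel": {
            "a": cfg.kernel.a,
            "b": cfg.kernel.b,
            "mode": cfg.kernel.mode,
            "eval_range_mm": list(cfg.kernel.eval_range),
        },
        "demography": asdict(cfg.demography),
        "network_path": cfg.network_path,
        "generate": cfg.generate,
    }
    (out / "config.echo.yaml").write_text(yaml.safe_dump(manifest["config"]))
    manifest["files"].append("config.echo.yaml")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
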