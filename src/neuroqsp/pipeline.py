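"""Config-driven orchestration of the full in-silico analysis.

A run config (YAML mapping or dict) names the model and the stages to execute:
continuous simulation, the multi-arm attractor frequency panel, minimal
intervention analysis, and direction-of-change qualification. Each stage
writes its own CSV/JSON artifact into the output directory, the config is
echoed verbatim, and a summary JSON collects the headline numbers (node/edge
counts, nu per arm, intervention counts by size, agreement fraction). Runs
are deterministic for fixed seeds and the summary is re-derivable from the
stage outputs alone.
"""

from __future__ import annotations

import hashlib
import json
import pathlib
from typing import Mapping

import pandas as pd
import yaml

from . import __version__
from .attractors import perturbation_panel
from .hillcube import HillCubeParams, simulate_hillcube
from .interventions import InterventionGoal, enumerate_minimal_interventions
from .logic import parse_bnet
from .qualification import collapse_probes, direction_agreement, predict_node_directions
from .synthetic import toy_cipn_network

__all__ = ["load_config", "run_pipeline"]


def load_config(path: str | pathlib.Path) -> dict:
    with open(path) as fh:
        config = yaml.safe_load(fh)
    if not isinstance(config, Mapping):
        raise ValueError("run config must be a mapping")
    return dict(config)


def _load_model(spec: str, base_dir: pathlib.Path):
    if spec == "fixture:toy_cipn":
        return toy_cipn_network()
    path = pathlib.Path(spec)
    if not path.is_absolute():
        path = base_dir / path
    if not path.exists():
        raise FileNotFoundError(f"model file not found: {path}")
    return parse_bnet(path.read_text())


def run_pipeline(config: Mapping, outdir: str | pathlib.Path, base_dir: str | pathlib.Path = ".") -> dict:
    """Execute the configured stages and return the summary dict.

    Raises on the first failing stage (its name is in the message); artifacts
    of completed stages are preserved in ``outdir``.
    """
    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    base_dir = pathlib.Path(base_dir)
    config = dict(config)
    if "model" not in config:
        raise ValueError("config must name a model")

    config_text = yaml.safe_dump(config, sort_keys=True)
    (outdir / "config.yaml").write_text(config_text)
    summary: dict = {
        "version": __version__,
        "config_sha256": hashlib.sha256(config_text.encode()).hexdigest(),
    }

    network = _load_model(config["model"], base_dir)
    summary["network"] = {"n_nodes": len(network.nodes), "n_edges": network.n_edges}

    stage = "simulate"
    try:
        if stage in config:
            spec = config[stage]
            x0 = spec.get("x0") or {n: 0.0 for n in network.nodes}
            x0 = {n: float(x0.get(n, 0.0)) for n in network.nodes}
            params = HillCubeParams(**spec.get("hill_params", {}))
            traj = simulate_hillcube(
                network, x0, clamps=spec.get("clamps", {}), params=params,
                t_end=float(spec.get("t_end", 25.0)),
                n_out=int(spec.get("n_out", 101)),
            )
            traj.states.to_csv(outdir / "trajectory.csv")
            summary["simulate"] = {
                "steady_state": traj.steady_state,
                "final": {k: round(v, 6) for k, v in traj.final.items()},
            }

        stage = "attractors"
        if stage in config:
            spec = config[stage]
            arms = [(arm["label"], arm.get("clamps", {})) for arm in spec["arms"]]
            panel = perturbation_panel(
                network, arms,
                n_samples=int(spec.get("n_samples", 10_000)),
                seed=int(spec.get("seed", 0)),
                goal=spec.get("goal"),
                exhaustive=bool(spec.get("exhaustive", False)),
                cycle_stat=spec.get("cycle_stat", "mean"),
            )
            panel.table.to_csv(outdir / "frequencies.csv", index=False)
            census = {
                label: {"n_attractors": len(s.attractor_census), "mode": s.mode}
                for label, s in panel.samples.items()
            }
            (outdir / "attractors.json").write_text(
                json.dumps(census, indent=2, sort_keys=True)
            )
            summary["attractors"] = {
                "nu_goal": {k: round(v, 6) for k, v in panel.nu_goal.items()},
                "census": census,
            }

        stage = "mia"
        if stage in config:
            spec = config[stage]
            goal = InterventionGoal(
                goal_node=spec["goal"]["node"],
                goal_value=int(spec["goal"]["value"]),
                base_clamps=spec.get("base_clamps", {}),
                max_size=int(spec.get("max_size", 3)),
            )
            sets = enumerate_minimal_interventions(
                network, goal,
                intervention_values=spec.get("values", "both"),
                n_samples=spec.get("n_samples", 10_000),
                seed=int(spec.get("seed", 0)),
            )
            records = [
                {"set_id": i, "size": s.size, "members": s.members,
                 "verified_mode": s.verified_mode}
                for i, s in enumerate(sets, start=1)
            ]
            pd.DataFrame(records, columns=["set_id", "size", "members", "verified_mode"]).to_csv(
                outdir / "mis.csv", index=False
            )
            by_size: dict[str, int] = {}
            for s in sets:
                by_size[str(s.size)] = by_size.get(str(s.size), 0) + 1
            summary["mia"] = {"n_sets": len(sets), "by_size": by_size}

        stage = "qualification"
        if stage in config:
            spec = config[stage]
            calls = predict_node_directions(
                network, spec.get("clamps", {}),
                t_end=float(spec.get("t_end", 25.0)),
            )
            de_path = base_dir / spec["de_table"]
            de = pd.read_csv(de_path, sep="\t")
            map_path = base_dir / spec["node_gene_map"]
            node_map = (
                pd.read_csv(map_path, sep="\t")
                .set_index("node")["gene_symbol"]
                .to_dict()
            )
            genes = collapse_probes(de, mode=spec.get("collapse", "min_adj_p"))
            report = direction_agreement(calls, genes, node_map)
            report["table"].to_csv(outdir / "agreement.csv", index=False)
            summary["qualification"] = {
                "n_agree": report["n_agree"],
                "n_total": report["n_total"],
                "fraction": round(report["fraction"], 6),
            }
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
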