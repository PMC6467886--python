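"""End-to-end pipeline orchestration and report writing.

``run_pipeline`` drives the whole analysis from one validated
configuration: read the observation table, assemble proportion matrices,
estimate the daily transition matrix, extract the transition graph,
classify states, compute the stationary composition and per-start
relaxation times, score hierarchy, and test marker independence.  Every
output embeds the configuration (and its hash) for provenance.
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

from . import __version__
from .equilibrium import (
    Composition,
    classify_states,
    stationary_distribution,
    time_to_equilibrium,
)
from .hierarchy import krackhardt_hierarchy, reciprocity_summary
from .independence import DEFAULT_VERDICT_THRESHOLD, marker_independence_test
from .inference import TransitionGraph, estimate_transition_matrix, extract_graph
from .io import build_proportion_matrix, read_observation_table, write_proportion_matrix
from .states import build_state_space

__all__ = ["RunConfig", "run_pipeline", "write_dot"]


class PipelineError(RuntimeError):
    """Stage-tagged pipeline failure."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Validated configuration for one pipeline run."""

    input_path: str
    markers: list[str]
    time_points: list[int]
    output_dir: str = "phenotrans_out"
    condition: str | None = None
    value_kind: str = "counts"
    percent: bool = False
    tau: float = 0.0
    eps: float = 0.01
    metric: str = "tv"
    t_max: int = 1000
    hierarchy_mode: str = "reachability"
    independence_threshold: float = DEFAULT_VERDICT_THRESHOLD
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.markers:
            raise ValueError("markers must be non-empty")
        if not self.time_points:
            raise ValueError("time_points must be non-empty")
        if any(int(t) < 1 for t in self.time_points):
            raise ValueError("time_points must be >= 1 day")
        if self.eps <= 0 or self.tau < 0 or self.t_max < 1:
            raise ValueError("invalid tau/eps/t_max")
        self.time_points = [int(t) for t in self.time_points]

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        blob = yaml.safe_load(Path(path).read_text()) or {}
        blob.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**blob)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def write_dot(graph: TransitionGraph, path: str | Path) -> None:
    """Graphviz DOT export with mutual edges drawn bold."""
    g = graph.graph
    lines = ["digraph transitions {"]
    for node in g.nodes:
        lines.append(f'  "{node}";')
    for u, v, d in g.edges(data=True):
        style = ' style="bold"' if g.has_edge(v, u) else ""
        lines.append(f'  "{u}" -> "{v}" [label="{d["weight"]:.4f}"{style}];')
    lines.append("}")
    Path(path).write_text("\n".join(lines) + "\n")


def _json_dump(obj: dict, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, default=float))


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the summary dict it writes.

    Artifacts written under ``config.output_dir``: per-day proportion
    matrices, the averaged transition matrix, edge list and DOT graph,
    equilibrium/classification/hierarchy/independence reports, run
    diagnostics, and a plain-text summary.  Any stage failure raises a
    :class:`PipelineError` naming the stage.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {
        "phenotrans_version": __version__,
        "config": config.to_dict(),
        "config_hash": config.hash(),
    }

    try:
        space = build_state_space(config.markers)
    except ValueError as e:
        raise PipelineError("state-space", str(e)) from e

    try:
        table = read_observation_table(
            config.input_path, value_kind=config.value_kind, percent=config.percent
        )
    except (OSError, ValueError) as e:
        raise PipelineError("read", f"{config.input_path}: {e}") from e

    try:
        snaps = [
            build_proportion_matrix(table, space, t=t, condition=config.condition)
            for t in config.time_points
        ]
        for w in snaps:
            write_proportion_matrix(w, out / f"proportions_day{w.t}.csv")
    except ValueError as e:
        raise PipelineError("proportions", str(e)) from e

    try:
        p_hat, raws = estimate_transition_matrix(snaps, seed=config.seed)
        pd.DataFrame(p_hat.values, index=p_hat.labels, columns=p_hat.labels).to_csv(
            out / "transition_matrix.csv", index_label="from_state"
        )
    except (ValueError, np.linalg.LinAlgError) as e:
        raise PipelineError("estimate", str(e)) from e

    diagnostics = {
        **meta,
        "max_imag_discarded": max(r.max_imag for r in raws),
        "fallback_used": [r.t for r in raws if r.fallback_used],
        "residuals": {r.t: r.residual for r in raws if r.residual is not None},
    }
    _json_dump(diagnostics, out / "diagnostics.json")

    graph = extract_graph(p_hat, tau=config.tau)
    pd.DataFrame(graph.edges(), columns=["from", "to", "probability"]).to_csv(
        out / "graph_edges.csv", index=False
    )
    write_dot(graph, out / "graph.dot")

    classification = classify_states(p_hat, tau=config.tau)
    _json_dump(
        {**meta, **dataclasses.asdict(classification)}, out / "classification.json"
    )

    eq = stationary_distribution(p_hat)
    relax = {}
    trajectory_rows = []
    if eq.unique:
        for lab in space.labels:
            res = time_to_equilibrium(
                p_hat,
                Composition.pure(space, lab),
                eps=config.eps,
                metric=config.metric,
                t_max=config.t_max,
            )
            relax[lab] = {
                "days": res.days,
                "reached": res.reached,
                "last_distance": res.last_distance,
            }
        x = np.eye(space.n_states)
        for t in range(0, min(config.t_max, 200) + 1):
            for i, lab in enumerate(space.labels):
                trajectory_rows.append(
                    {"initial_state": lab, "day": t, **dict(zip(space.labels, x[i]))}
                )
            x = x @ p_hat.values
        pd.DataFrame(trajectory_rows).to_csv(out / "trajectories.csv", index=False)
    _json_dump(
        {
            **meta,
            "unique": eq.unique,
            "stationary": None if not eq.unique else dict(zip(space.labels, eq.pi.x)),
            "extremal_solutions": [dict(zip(space.labels, s.x)) for s in eq.solutions],
            "eps": config.eps,
            "metric": config.metric,
            "relaxation_days": relax,
        },
        out / "equilibrium.json",
    )

    h_reach = krackhardt_hierarchy(graph, mode="reachability")
    h_direct = krackhardt_hierarchy(graph, mode="direct")
    census = reciprocity_summary(graph)
    _json_dump(
        {
            **meta,
            "reachability": dataclasses.asdict(h_reach),
            "direct": dataclasses.asdict(h_direct),
            "dyad_census": dataclasses.asdict(census),
        },
        out / "hierarchy.json",
    )

    indep = marker_independence_test(
        snaps, p_hat, space, threshold=config.independence_threshold, seed=config.seed
    )
    indep_rows = [
        {
            "marker": r.marker,
            "steady_plus_2state": r.steady_2state[0],
            "steady_plus_marginal": r.steady_marginal[0],
            "abs_difference": r.abs_difference,
            "verdict": indep.verdicts[r.marker],
        }
        for r in indep.results
    ]
    pd.DataFrame(indep_rows).to_csv(out / "independence.csv", index=False)
    _json_dump({**meta, "threshold": indep.threshold, "markers": indep_rows},
               out / "independence.json")

    summary = {
        **meta,
        "n_states": space.n_states,
        "days_used": config.time_points,
        "direct_transitions_occurring": graph.n_edges,
        "direct_transitions_possible": graph.n_possible,
        "irreducible": classification.irreducible,
        "transient_states": classification.transient,
        "absorbing_states": classification.absorbing,
        "krackhardt_reachability": h_reach.score,
        "krackhardt_direct": h_direct.score,
        "stationary_unique": eq.unique,
        "relaxation_days": {k: v["days"] for k, v in relax.items()},
        "independence_verdicts": indep.verdicts,
    }
    _json_dump(summary, out / "summary.json")

    lines = [
        f"phenotrans {__version__}  (config {config.hash()})",
        f"states: {space.n_states} ({', '.join(space.markers)})",
        f"snapshots: days {config.time_points}",
        f"direct transitions occurring: {graph.n_edges} of {graph.n_possible}",
        f"irreducible: {classification.irreducible}; transient: "
        f"{classification.transient or 'none'}; absorbing: "
        f"{classification.absorbing or 'none'}",
        f"Krackhardt hierarchy (reachability): {h_reach.score}",
        f"Krackhardt hierarchy (direct): {h_direct.score}",
        f"stationary unique: {eq.unique}",
    ]
    if eq.unique:
        top = sorted(zip(space.labels, eq.pi.x), key=lambda kv: -kv[1])[:5]
        lines.append(
            "equilibrium (top states): "
            + ", ".join(f"{lab} {frac:.3f}" for lab, frac in top)
        )
        shown = {k: v["days"] for k, v in relax.items()}
        lines.append(f"relaxation times (days, eps={config.eps} {config.metric}): {shown}")
    lines.append(
        "marker independence: "
        + ", ".join(f"{m}={v}" for m, v in indep.verdicts.items())
    )
    (out / "summary.txt").write_text("\n".join(lines) + "\n")
    return summary
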