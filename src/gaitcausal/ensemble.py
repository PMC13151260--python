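"""Bootstrap stabilization of a learned causal graph.

One structure-learning run on a modest clinical sample is fragile, so the
graph is rebuilt on bootstrap resamples and aggregated:

resample -> learn -> threshold (|effect| > 0.05 per iteration) ->
average across all iterations -> resolve bidirectional pairs (keep the
stronger direction) -> repair cycles (iteratively drop the weakest edge of
a detected cycle) -> report per-edge retention frequency and
sign-stability -> read off the parents of the outcome node.

Defaults follow the study protocol: 1,000 bootstrap iterations, edge
threshold 0.05, and a reporting rule of absolute mean weight > 0.05 with
sign-stability >= 0.20.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "EnsembleConfig",
    "WeightedDigraph",
    "EnsembleGraph",
    "bootstrap_adjacencies",
    "aggregate",
    "resolve_bidirectional",
    "make_acyclic",
    "select_outcome_parents",
    "stability_report",
    "build_ensemble_graph",
]


@dataclass
class EnsembleConfig:
    """Bootstrap-aggregation settings (study defaults)."""

    n_boot: int = 1000
    edge_threshold: float = 0.05
    stability_min: float = 0.20
    seed: int = 0
    #: "all": average over every iteration, zeroed entries included
    #: (the default reading of the protocol); "retained": average only
    #: over iterations where the edge survived its per-iteration threshold.
    mean_mode: str = "all"
    #: reporting style cut: |mean weight| above this renders solid.
    solid_threshold: float = 0.20

    def __post_init__(self) -> None:
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")
        if self.edge_threshold < 0:
            raise ValueError("edge_threshold must be >= 0")
        if not (0.0 <= self.stability_min <= 1.0):
            raise ValueError("stability_min must be in [0, 1]")
        if self.mean_mode not in ("all", "retained"):
            raise ValueError("mean_mode must be 'all' or 'retained'")


@dataclass
class WeightedDigraph:
    """Named-node digraph with nonzero edge weights; at most one edge per
    ordered pair and no self-loops."""

    nodes: list[str]
    edges: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for (s, t), w in self.edges.items():
            if s == t:
                raise ValueError(f"self-loop on {s!r}")
            if w == 0:
                raise ValueError(f"zero-weight edge {s!r}->{t!r}")
            if s not in self.nodes or t not in self.nodes:
                raise ValueError(f"edge {s!r}->{t!r} references unknown node")

    def copy(self) -> "WeightedDigraph":
        return WeightedDigraph(list(self.nodes), dict(self.edges))

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for (s, t), w in self.edges.items():
            g.add_edge(s, t, weight=w)
        return g

    def is_acyclic(self) -> bool:
        return nx.is_directed_acyclic_graph(self.to_networkx())

    @classmethod
    def from_matrix(cls, W: np.ndarray, names: Sequence[str]) -> "WeightedDigraph":
        """W[i, j] != 0 becomes edge names[j] -> names[i]."""
        edges = {}
        tgt, src = np.nonzero(W)
        for i, j in zip(tgt.tolist(), src.tolist()):
            if i != j:
                edges[(names[j], names[i])] = float(W[i, j])
        return cls(list(names), edges)

    def to_edge_frame(self) -> pd.DataFrame:
        rows = [{"source": s, "target": t, "weight": w}
                for (s, t), w in sorted(self.edges.items())]
        return pd.DataFrame(rows, columns=["source", "target", "weight"])

    def to_dot(self) -> str:
        lines = ["digraph G {"]
        for n in self.nodes:
            lines.append(f'  "{n}";')
        for (s, t), w in sorted(self.edges.items()):
            style = "solid" if abs(w) > 0.20 else "dashed"
            lines.append(f'  "{s}" -> "{t}" [label="{w:.3f}", style={style}];')
        lines.append("}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# bootstrap and aggregation
# ---------------------------------------------------------------------------

def bootstrap_adjacencies(
    X: np.ndarray,
    learner: Callable[[np.ndarray], np.ndarray],
    config: EnsembleConfig,
) -> tuple[list[np.ndarray], int]:
    """Learn an adjacency matrix on each of ``n_boot`` row-resamples.

    Each iteration draws ``n`` rows with replacement using a child seed
    derived from ``(config.seed, iteration)``, runs ``learner`` and zeroes
    entries with ``|effect| <= edge_threshold``.  Learner failures are
    logged and skipped; the failure count is returned alongside.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    mats: list[np.ndarray] = []
    failures = 0
    for b in range(config.n_boot):
        rng = np.random.default_rng(
            np.random.SeedSequence([int(config.seed) % (2**31), b]))
        idx = rng.integers(0, n, n)
        try:
            W = np.asarray(learner(X[idx]), dtype=float)
        except Exception as exc:  # noqa: BLE001 - resample-level robustness
            failures += 1
            logger.warning("bootstrap iteration %d failed: %s", b, exc)
            continue
        W = W.copy()
        W[np.abs(W) <= config.edge_threshold] = 0.0
        mats.append(W)
    if not mats:
        raise RuntimeError("every bootstrap iteration failed")
    return mats, failures


@dataclass
class EnsembleGraph:
    """Aggregated bootstrap result over named variables."""

    names: list[str]
    mean_weight: np.ndarray
    retention_freq: np.ndarray
    sign_stability: np.ndarray
    n_boot_effective: int
    final_dag: WeightedDigraph | None = None
    removal_log: list[dict] = field(default_factory=list)

    def to_edge_frame(self) -> pd.DataFrame:
        rows = []
        p = len(self.names)
        for i in range(p):
            for j in range(p):
                if i == j:
                    continue
                if (self.mean_weight[i, j] != 0 or self.retention_freq[i, j] > 0):
                    rows.append({
                        "source": self.names[j],
                        "target": self.names[i],
                        "mean_weight": float(self.mean_weight[i, j]),
                        "retention_freq": float(self.retention_freq[i, j]),
                        "sign_stability": float(self.sign_stability[i, j]),
                    })
        return pd.DataFrame(
            rows, columns=["source", "target", "mean_weight",
                           "retention_freq", "sign_stability"])

    def to_json(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump({
                "names": self.names,
                "edges": self.to_edge_frame().to_dict(orient="records"),
                "n_boot_effective": self.n_boot_effective,
                "removal_log": self.removal_log,
            }, fh, indent=2)


def aggregate(
    matrices: Sequence[np.ndarray],
    config: EnsembleConfig,
    names: Sequence[str] | None = None,
) -> EnsembleGraph:
    """Average thresholded per-iteration effects and score edge stability.

    ``mean_weight`` averages over all iterations (zeroed entries included)
    under the default ``mean_mode="all"``; ``retention_freq`` is the
    fraction of iterations in which the edge survived its per-iteration
    threshold; ``sign_stability`` is the fraction in which it appeared
    with the sign of its ensemble mean (hence <= retention_freq).
    """
    if len(matrices) == 0:
        raise ValueError("no adjacency matrices to aggregate")
    A = np.stack([np.asarray(m, dtype=float) for m in matrices])
    if names is None:
        names = [f"x{i}" for i in range(A.shape[1])]
    nonzero = A != 0
    retention = nonzero.mean(axis=0)
    if config.mean_mode == "all":
        mean_w = A.mean(axis=0)
    else:
        cnt = np.maximum(nonzero.sum(axis=0), 1)
        mean_w = A.sum(axis=0) / cnt
    sign = np.sign(mean_w)
    agree = (np.sign(A) == sign[None, :, :]) & nonzero
    stability = agree.mean(axis=0)
    return EnsembleGraph(list(names), mean_w, retention, stability, len(matrices))


# ---------------------------------------------------------------------------
# graph repair
# ---------------------------------------------------------------------------

def resolve_bidirectional(g: WeightedDigraph) -> WeightedDigraph:
    """Where both a->b and b->a are present keep the direction with the
    larger absolute weight.  Exact ties are broken toward the
    lexicographically smaller (source, target) pair, with a warning."""
    out = g.copy()
    for (s, t) in sorted(g.edges):
        if (s, t) not in out.edges or (t, s) not in out.edges:
            continue
        w_st, w_ts = out.edges[(s, t)], out.edges[(t, s)]
        if abs(w_st) > abs(w_ts):
            drop = (t, s)
        elif abs(w_ts) > abs(w_st):
            drop = (s, t)
        else:
            drop = max((s, t), (t, s))
            warnings.warn(
                f"bidirectional tie {s!r}<->{t!r} (|w|={abs(w_st):.4g}); "
                f"kept lexicographically smaller direction")
        del out.edges[drop]
    return out


def make_acyclic(g: WeightedDigraph) -> tuple[WeightedDigraph, list[dict]]:
    """Iteratively delete the weakest edge of a detected cycle until the
    graph is acyclic.  Deterministic: node iteration is sorted and, within
    a cycle, weight ties break toward the lexicographically smaller edge.
    Returns the repaired graph and a removal log."""
    out = g.copy()
    removal_log: list[dict] = []
    while True:
        nxg = out.to_networkx()
        try:
            cycle = nx.find_cycle(nxg, source=sorted(out.nodes), orientation="original")
        except nx.NetworkXNoCycle:
            break
        cyc_edges = [(s, t) for s, t, _ in cycle]
        weakest = min(cyc_edges, key=lambda e: (abs(out.edges[e]), e))
        removal_log.append({
            "edge": list(weakest),
            "weight": out.edges[weakest],
            "cycle": [list(e) for e in cyc_edges],
        })
        del out.edges[weakest]
    return out, removal_log


def select_outcome_parents(g: WeightedDigraph, outcome: str) -> list[str]:
    """Sources of edges into the outcome node, strongest first."""
    if outcome not in g.nodes:
        raise KeyError(f"outcome {outcome!r} not in graph")
    parents = [(s, w) for (s, t), w in g.edges.items() if t == outcome]
    parents.sort(key=lambda sw: (-abs(sw[1]), sw[0]))
    return [s for s, _ in parents]


def stability_report(eg: EnsembleGraph, config: EnsembleConfig) -> pd.DataFrame:
    """Edges passing BOTH reporting criteria (|mean| > edge_threshold and
    sign-stability >= stability_min), tagged solid/dashed at the
    |mean| > solid_threshold display cut."""
    df = eg.to_edge_frame()
    if df.empty:
        return df.assign(style=pd.Series(dtype=str))
    keep = (df["mean_weight"].abs() > config.edge_threshold) & \
           (df["sign_stability"] >= config.stability_min)
    out = df[keep].copy()
    out["style"] = np.where(out["mean_weight"].abs() > config.solid_threshold,
                            "solid", "dashed")
    return out.sort_values(
        "mean_weight", key=lambda s: -s.abs()).reset_index(drop=True)


def build_ensemble_graph(
    X: np.ndarray,
    learner: Callable[[np.ndarray], np.ndarray],
    config: EnsembleConfig,
    names: Sequence[str] | None = None,
) -> tuple[EnsembleGraph, int]:
    """Full stabilization pipeline: bootstrap, aggregate, threshold the
    mean graph, resolve bidirectional pairs, repair cycles.  The final
    DAG is asserted acyclic."""
    mats, failures = bootstrap_adjacencies(X, learner, config)
    eg = aggregate(mats, config, names)
    W = eg.mean_weight.copy()
    W[np.abs(W) <= config.edge_threshold] = 0.0
    g = WeightedDigraph.from_matrix(W, eg.names)
    g = resolve_bidirectional(g)
    dag, removal_log = make_acyclic(g)
    assert dag.is_acyclic()
    eg.final_dag = dag
    eg.removal_log = removal_log
    return eg, failures
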