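"""Synthetic knockout benchmarks: ground-truth networks plus steady states.

The generator emulates the structure of the in-silico DREAM knockout
challenges: a sparse directed gene network, a wild-type steady state, and
one steady-state measurement per single-gene deletion, all written in the
same tab-delimited dialect the readers consume.

Steady states follow a multiplicative regulation model: each regulator
scales its target's basal expression through a saturating Hill response of
coefficient 2,

    x_j = basal_j * prod_{u -> j, gain > 0} (1 + g_uj * h_u(x_u))
                  / prod_{u -> j, gain < 0} (1 + |g_uj| * h_u(x_u)),
    h_u(x) = x^2 / (K_u^2 + x^2),   K_u = basal_u.

Deleting a regulator therefore changes its direct targets by an order-one
*relative* amount (h drops from ~0.5-1 to 0), matching the effect sizes of
real knockout compendia, while genes outside the knockout's downstream
closure are untouched. The quadratic rise of h near zero gives target
responses genuine curvature with a small slope, the regime the direction
test's second-order expansion assumes. A knockout clamps one gene to zero
and re-solves the steady state; measurement noise is multiplicative
lognormal (larger absolute noise at larger expression), applied to every
measured value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np

from .dream_io import (
    ExpressionPanel,
    GoldStandard,
    write_expression_panel,
    write_gold_standard,
)

logger = logging.getLogger(__name__)

__all__ = ["SyntheticSpec", "sample_network", "simulate_panel", "write_dream_files"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic benchmark instance.

    Defaults mirror a small DREAM-style problem: 10 genes, 10 regulatory
    edges with gains of magnitude 0.5-2 and random sign, basal expression
    between 1 and 10 (arbitrary expression units), an acyclic topology and
    noise-free measurements.
    """

    n_genes: int = 10
    n_edges: int = 10
    edge_gain_range: tuple[float, float] = (0.5, 2.0)
    wild_type_range: tuple[float, float] = (1.0, 10.0)
    noise_sigma: float = 0.0
    allow_cycles: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 2:
            raise ValueError("need at least 2 genes")
        cap = self.n_genes * (self.n_genes - 1)
        if not self.allow_cycles:
            cap //= 2
        if not 0 <= self.n_edges <= cap:
            raise ValueError(
                f"n_edges={self.n_edges} infeasible for n_genes={self.n_genes} "
                f"(max {cap} with allow_cycles={self.allow_cycles})"
            )
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")
        lo, hi = self.edge_gain_range
        if not 0 < lo <= hi:
            raise ValueError("edge_gain_range must be a positive interval")
        lo, hi = self.wild_type_range
        if not 0 < lo <= hi:
            raise ValueError("wild_type_range must be a positive interval")

    @property
    def gene_names(self) -> tuple[str, ...]:
        return tuple(f"G{i + 1}" for i in range(self.n_genes))


def sample_network(spec: SyntheticSpec) -> list[tuple[int, int, float]]:
    """Sample a simple directed network as (source, target, gain) triples.

    Without cycles the edges respect a random topological order of the
    genes, so the graph is a DAG by construction. Deterministic per seed.
    """
    rng = np.random.default_rng([spec.seed, 0])
    n = spec.n_genes
    if spec.allow_cycles:
        pairs = [(u, v) for u in range(n) for v in range(n) if u != v]
    else:
        order = rng.permutation(n)
        rank = np.empty(n, dtype=int)
        rank[order] = np.arange(n)
        pairs = [(u, v) for u in range(n) for v in range(n) if rank[u] < rank[v]]
    chosen = rng.choice(len(pairs), size=spec.n_edges, replace=False)
    lo, hi = spec.edge_gain_range
    gains = rng.uniform(lo, hi, size=spec.n_edges)
    signs = rng.choice([-1.0, 1.0], size=spec.n_edges)
    return [
        (pairs[int(c)][0], pairs[int(c)][1], float(g * s))
        for c, g, s in zip(chosen, gains, signs)
    ]


def _hill(x: np.ndarray, k: np.ndarray) -> np.ndarray:
    return x**2 / (k**2 + x**2)


def _regulated_level(
    j: int,
    x: np.ndarray,
    basal: np.ndarray,
    k: np.ndarray,
    gain: np.ndarray,
    graph: nx.DiGraph,
) -> float:
    level = basal[j]
    for u in graph.predecessors(j):
        factor = 1.0 + abs(gain[u, j]) * _hill(x[u], k[u])
        level = level * factor if gain[u, j] > 0 else level / factor
    return float(level)


def _steady_state(
    basal: np.ndarray,
    k: np.ndarray,
    gain: np.ndarray,
    graph: nx.DiGraph,
    clamp: int | None,
    max_iter: int = 5000,
    tol: float = 1e-12,
) -> np.ndarray:
    n = basal.shape[0]

    if nx.is_directed_acyclic_graph(graph):
        # exact forward solve in topological order
        x = np.zeros(n)
        for j in nx.topological_sort(graph):
            if clamp is not None and j == clamp:
                x[j] = 0.0
                continue
            x[j] = _regulated_level(j, x, basal, k, gain, graph)
        return x

    x = basal.copy()
    if clamp is not None:
        x[clamp] = 0.0
    for _ in range(max_iter):
        x_new = np.array(
            [
                0.0
                if clamp is not None and j == clamp
                else _regulated_level(j, x, basal, k, gain, graph)
            for j in range(n)
            ]
        )
        x_new = 0.5 * x + 0.5 * x_new
        if np.max(np.abs(x_new - x)) < tol * max(1.0, np.max(np.abs(x_new))):
            return x_new
        x = x_new
    raise RuntimeError(
        "steady-state iteration did not converge; try smaller regulatory gains"
    )


def simulate_panel(
    network: list[tuple[int, int, float]], spec: SyntheticSpec
) -> tuple[ExpressionPanel, GoldStandard]:
    """Solve wild-type and per-knockout steady states for a sampled network."""
    rng = np.random.default_rng([spec.seed, 1])
    n = spec.n_genes
    lo, hi = spec.wild_type_range
    basal = rng.uniform(lo, hi, size=n)
    k = basal / 3.0  # regulators near saturation (h ~ 0.9) at wild type
    gain = np.zeros((n, n))
    graph = nx.DiGraph()
    graph.add_nodes_from(range(n))
    for u, v, g in network:
        if u == v:
            raise ValueError("self-loop in network")
        gain[u, v] = g
        graph.add_edge(u, v)

    wild = _steady_state(basal, k, gain, graph, clamp=None)
    knockout = np.empty((n, n))
    for i in range(n):
        knockout[i] = _steady_state(basal, k, gain, graph, clamp=i)

    if spec.noise_sigma > 0:
        wild = wild * np.exp(rng.normal(0.0, spec.noise_sigma, size=wild.shape))
        knockout = knockout * np.exp(
            rng.normal(0.0, spec.noise_sigma, size=knockout.shape)
        )

    names = spec.gene_names
    panel = ExpressionPanel(gene_names=names, wild_type=wild, knockout=knockout)
    gold = GoldStandard(
        gene_names=names,
        positives=frozenset((names[u], names[v]) for u, v, _ in network),
    )
    return panel, gold


def write_dream_files(
    panel: ExpressionPanel, gold: GoldStandard, outdir
) -> dict[str, Path]:
    """Write knockouts.tsv, wildtype.tsv and goldstandard.tsv into outdir."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "knockout": outdir / "knockouts.tsv",
        "wildtype": outdir / "wildtype.tsv",
        "gold": outdir / "goldstandard.tsv",
    }
    write_expression_panel(panel, paths["knockout"], paths["wildtype"])
    write_gold_standard(gold, paths["gold"])
    logger.info("synthetic benchmark written to %s", outdir)
    return paths
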