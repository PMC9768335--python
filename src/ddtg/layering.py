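"""Two-layer dissection of a regulator's downstream targets.

A regulator's candidate targets mix genes it regulates directly with genes
reached through an intermediate. If candidate k carries all the information
candidate j has about regulator i — i.e. the conditional mutual information
I(g_i; g_j | g_k) is (near) zero — then j is an *indirect* target mediated
by k, implying the edges i -> k and k -> j. Candidates that no other
candidate can explain away stay in the *direct* (first) layer.

Observations are the rows of the knockout matrix: one steady-state sample
per single-gene deletion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .dream_io import ExpressionPanel
from .infotheory import DEFAULT_RIDGE, gaussian_cmi

logger = logging.getLogger(__name__)

__all__ = ["LayeredTargets", "split_layers", "split_layers_from_samples", "implied_edges"]


@dataclass(frozen=True)
class LayeredTargets:
    """Partition of one regulator's candidates into direct/indirect layers.

    ``indirect`` holds (target, mediator, cmi) triples; every mediator is a
    member of ``direct`` and each indirect target appears exactly once.
    """

    regulator: int
    direct: tuple[int, ...]
    indirect: tuple[tuple[int, int, float], ...]
    cmi_threshold: float

    def __post_init__(self) -> None:
        direct = set(self.direct)
        ind_targets = [j for j, _, _ in self.indirect]
        if len(ind_targets) != len(set(ind_targets)):
            raise ValueError("an indirect target has multiple mediators")
        if direct & set(ind_targets):
            raise ValueError("direct and indirect layers overlap")
        for j, k, _ in self.indirect:
            if k not in direct:
                raise ValueError(f"mediator {k} of target {j} is not direct")

    @property
    def indirect_targets(self) -> tuple[int, ...]:
        return tuple(j for j, _, _ in self.indirect)

    @property
    def candidates(self) -> tuple[int, ...]:
        return tuple(sorted(set(self.direct) | set(self.indirect_targets)))


def split_layers_from_samples(
    samples: np.ndarray,
    regulator: int,
    candidates: Sequence[int],
    epsilon_cmi: float,
    ridge: float = DEFAULT_RIDGE,
    mediator_ok=None,
) -> LayeredTargets:
    """Classify candidates as direct/indirect from an m x n observation table.

    For each candidate j the mediator k* minimising I(g_i; g_j | g_k) over
    the other candidates is found; j is proposed indirect when that minimum
    falls below ``epsilon_cmi``. Proposals are then accepted greedily in
    order of increasing CMI (ties by gene index): a proposal is dropped when
    its target has already been used as a mediator, or when its mediator has
    itself been accepted as indirect. This resolves mutual nominations
    deterministically — the pair with the smaller CMI wins — and guarantees
    every mediator stays in the direct layer.

    ``mediator_ok(k, j)``, when given, restricts which candidates may mediate
    a path to j. The pipeline passes the method's own target relation
    (|s_kj| > theta0): a gene whose deletion does not perturb j cannot be the
    intermediate through which the regulator reaches j.
    """
    samples = np.asarray(samples, dtype=float)
    cands = sorted(dict.fromkeys(int(c) for c in candidates))
    if regulator in cands:
        raise ValueError(f"regulator {regulator} listed among its own candidates")
    if not cands:
        raise ValueError("candidate set is empty")
    if len(cands) == 1 or samples.shape[0] < 4:
        if len(cands) > 1:
            logger.warning(
                "only %d observations: too few for CMI, all candidates kept direct",
                samples.shape[0],
            )
        return LayeredTargets(
            regulator=regulator,
            direct=tuple(cands),
            indirect=(),
            cmi_threshold=epsilon_cmi,
        )

    m = samples.shape[0]
    proposals: list[tuple[float, int, int]] = []  # (cmi, target, mediator)
    for j in cands:
        # drop the row that deletes target j itself: its forced zero is an
        # intervention on j, not a response carrying regulatory information.
        # The mediator's own row stays - it is the interventional evidence
        # that separates a mediated path from a direct edge.
        rows = [r for r in range(m) if r != j] if j < m else list(range(m))
        if len(rows) < 4:
            continue
        x_i = samples[rows, regulator]
        x_j = samples[rows, j]
        best_cmi = np.inf
        best_k = -1
        for k in cands:
            if k == j:
                continue
            if mediator_ok is not None and not mediator_ok(k, j):
                continue
            cmi = gaussian_cmi(x_i, x_j, samples[rows, k], ridge=ridge)
            if cmi < best_cmi:
                best_cmi = cmi
                best_k = k
        if best_cmi < epsilon_cmi:
            proposals.append((best_cmi, j, best_k))

    proposals.sort(key=lambda t: (t[0], t[1]))
    indirect: list[tuple[int, int, float]] = []
    indirect_set: set[int] = set()
    mediators: set[int] = set()
    for cmi, j, k in proposals:
        if j in mediators:
            logger.warning(
                "gene %d nominated as both mediator and indirect target; kept direct",
                j,
            )
            continue
        if k in indirect_set:
            logger.warning(
                "mediator %d of target %d already classified indirect; %d kept direct",
                k,
                j,
                j,
            )
            continue
        indirect.append((j, k, float(cmi)))
        indirect_set.add(j)
        mediators.add(k)

    direct = tuple(c for c in cands if c not in indirect_set)
    return LayeredTargets(
        regulator=regulator,
        direct=direct,
        indirect=tuple(indirect),
        cmi_threshold=epsilon_cmi,
    )


def split_layers(
    panel: ExpressionPanel,
    regulator: int,
    candidates: Sequence[int],
    epsilon_cmi: float,
    ridge: float = DEFAULT_RIDGE,
    mediator_ok=None,
) -> LayeredTargets:
    """Layer a regulator's candidates using the knockout rows as samples."""
    return split_layers_from_samples(
        panel.knockout,
        regulator,
        candidates,
        epsilon_cmi,
        ridge=ridge,
        mediator_ok=mediator_ok,
    )


def implied_edges(lt: LayeredTargets) -> list[tuple[int, int, str]]:
    """Edges implied by the layering: regulator->direct and mediator->target.

    Returns deduplicated (source, target, provenance) index triples with
    provenance "regulator-direct" or "mediated"; never a self-edge.
    """
    edges: dict[tuple[int, int], str] = {}
    for d in lt.direct:
        if d != lt.regulator:
            edges[(lt.regulator, d)] = "regulator-direct"
    for j, k, _ in lt.indirect:
        if j != k and (k, j) not in edges:
            edges[(k, j)] = "mediated"
    return [(u, v, p) for (u, v), p in edges.items()]
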