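"""Knockout response quantification and downstream-target selection.

Knocking out regulator ``g_i`` perturbs every gene downstream of it. For a
panel with knockout matrix ``A`` (row i = steady state after deleting gene i)
and wild type ``A0``, the response of gene j is the change
``delta[i, j] = a_ij - a_0j``. Changes are normalised per target gene by the
gene's mean change across all knockouts, and each gene's column of relative
changes is damped by a sigmoid weight

    w_j = 1 / (1 + exp(r * (b_j - u))),   r < 0,  0 < u < 1,

where ``b_j`` is the gene's maximum response strength relative to its
wild-type level. Weak responders (likely noise) get weights near 0, strong
responders near 1. Entries of the weighted matrix ``S`` whose magnitude
exceeds a threshold ``theta0`` mark candidate downstream targets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .dream_io import ExpressionPanel

logger = logging.getLogger(__name__)

__all__ = [
    "ResponseConfig",
    "ResponseMatrix",
    "change_matrix",
    "relative_change",
    "response_strength",
    "sigmoid_weight",
    "response_matrix",
    "select_targets",
]

DENOM_MODES = ("signed-mean", "abs-mean")
B_MODES = ("abs", "signed")


@dataclass(frozen=True)
class ResponseConfig:
    """Tunables of the response stage.

    r, u
        Sigmoid steepness (negative integer) and midpoint (in (0, 1)). These
        shape the weight, not the ranking of responses, and are fixed rather
        than estimated.
    theta0
        Threshold on |s_ij| above which gene j is a candidate target of
        regulator i. Dimensionless; 1.0 means "at least the gene's mean
        response magnitude".
    denom_mode
        "signed-mean" divides by the signed mean change (the literal
        definition); "abs-mean" divides by the mean absolute change, which is
        more stable when activating and repressing knockouts cancel.
    b_mode
        "abs" scores the maximum |change|/wild-type (a strong repression is a
        strong response); "signed" is the literal signed maximum.
    eps
        Floor protecting divisions by near-zero denominators.
    """

    r: float = -10.0
    u: float = 0.5
    theta0: float = 1.0
    denom_mode: str = "signed-mean"
    b_mode: str = "abs"
    eps: float = 1e-12

    def __post_init__(self) -> None:
        if not self.r < 0:
            raise ValueError("sigmoid steepness r must be negative")
        if not 0 < self.u < 1:
            raise ValueError("sigmoid midpoint u must lie in (0, 1)")
        if self.theta0 < 0:
            raise ValueError("theta0 must be nonnegative")
        if self.denom_mode not in DENOM_MODES:
            raise ValueError(f"denom_mode must be one of {DENOM_MODES}")
        if self.b_mode not in B_MODES:
            raise ValueError(f"b_mode must be one of {B_MODES}")
        if self.eps <= 0:
            raise ValueError("eps must be positive")


@dataclass(frozen=True)
class ResponseMatrix:
    """Weighted relative-change matrix with its intermediate quantities."""

    gene_names: tuple[str, ...]
    S: np.ndarray              # n x n weighted relative changes
    delta: np.ndarray          # n x n raw changes a_ij - a_0j
    mean_change: np.ndarray    # per-gene denominator
    b: np.ndarray              # per-gene maximum response strength
    w: np.ndarray              # per-gene sigmoid weight in (0, 1)

    @property
    def n(self) -> int:
        return len(self.gene_names)


def change_matrix(panel: ExpressionPanel) -> np.ndarray:
    """Raw change matrix: entry (i, j) = a_ij - a_0j."""
    return panel.knockout - panel.wild_type[np.newaxis, :]


def _guard_denominator(d: np.ndarray, eps: float, what: str) -> np.ndarray:
    small = np.abs(d) < eps
    if np.any(small):
        logger.warning(
            "%s below %.1e for %d gene(s); replaced by sign-preserving floor",
            what,
            eps,
            int(small.sum()),
        )
        sign = np.where(d[small] < 0, -1.0, 1.0)
        d = d.copy()
        d[small] = sign * eps
    return d


def relative_change(
    delta: np.ndarray,
    denom_mode: str = "signed-mean",
    eps: float = 1e-12,
    exclude_self: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Normalise each column of changes by the gene's mean change.

    The mean quantifies a gene's typical response to the knockouts of the
    *other* genes, so for a square change matrix the diagonal entry (the
    gene's own deletion, a forced drop to -a_0j rather than a regulatory
    response) is excluded from the mean by default.

    Returns the relative-change matrix and the per-gene denominators used
    (after the near-zero guard).
    """
    delta = np.asarray(delta, dtype=float)
    weights = np.ones_like(delta)
    if exclude_self and delta.shape[0] == delta.shape[1]:
        np.fill_diagonal(weights, 0.0)
    base = np.abs(delta) if denom_mode == "abs-mean" else delta
    if denom_mode not in DENOM_MODES:
        raise ValueError(f"denom_mode must be one of {DENOM_MODES}")
    d = (base * weights).sum(axis=0) / weights.sum(axis=0)
    d = _guard_denominator(d, eps, "mean change")
    return delta / d[np.newaxis, :], d


def response_strength(
    panel: ExpressionPanel, b_mode: str = "abs", eps: float = 1e-12
) -> np.ndarray:
    """Maximum response strength b_j of each gene to knockouts of the others.

    The gene's own knockout row is excluded: the forced drop to zero is an
    intervention, not a response to another gene.
    """
    delta = change_matrix(panel)
    a0 = _guard_denominator(panel.wild_type.copy(), eps, "wild-type level")
    ratio = delta / a0[np.newaxis, :]
    mask = ~np.eye(panel.n, dtype=bool)
    if b_mode == "abs":
        scored = np.abs(ratio)
    elif b_mode == "signed":
        scored = ratio
    else:
        raise ValueError(f"b_mode must be one of {B_MODES}")
    return np.where(mask, scored, -np.inf).max(axis=0)


def sigmoid_weight(b, r: float = -10.0, u: float = 0.5):
    """Sigmoid weight w = 1 / (1 + exp(r (b - u))); increasing in b for r < 0."""
    b = np.asarray(b, dtype=float)
    w = expit(-r * (b - u))
    return float(w) if w.ndim == 0 else w


def response_matrix(panel: ExpressionPanel, cfg: ResponseConfig | None = None) -> ResponseMatrix:
    """Compose change -> relative change -> sigmoid weighting into S."""
    cfg = cfg or ResponseConfig()
    delta = change_matrix(panel)
    rel, denom = relative_change(delta, cfg.denom_mode, cfg.eps)
    b = response_strength(panel, cfg.b_mode, cfg.eps)
    w = sigmoid_weight(b, cfg.r, cfg.u)
    S = rel * w[np.newaxis, :]
    return ResponseMatrix(
        gene_names=panel.gene_names, S=S, delta=delta, mean_change=denom, b=b, w=w
    )


def select_targets(rm: ResponseMatrix, regulator: int, theta0: float) -> list[int]:
    """Candidate downstream targets of one regulator.

    Returns the indices j != regulator with |s_ij| > theta0, ordered by
    descending |s_ij| (ties by gene index). The diagonal entry (the
    regulator's own forced knockout response) is never a candidate.
    """
    n = rm.n
    if not 0 <= regulator < n:
        raise IndexError(f"regulator index {regulator} out of range for n={n}")
    row = np.abs(rm.S[regulator])
    idx = [j for j in range(n) if j != regulator and row[j] > theta0]
    idx.sort(key=lambda j: (-row[j], j))
    return idx
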