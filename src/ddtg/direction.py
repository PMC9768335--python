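"""Orienting edges between same-layer genes via a second-order expansion.

Two genes Y and Z that share a regulator (or common ancestor) X and are
strongly dependent on each other need a direction. Assume Y regulates Z:
then Y = f(X) and Z = g(X, Y). Expanding both responses to second order
around the wild-type operating point (X0, Y0, Z0), and using that the
steady-state responses are flat at the operating point (f'(X0) = h'(X0) = 0,
the wild type being a stable stationary state), the quadratic terms can be
eliminated to give the no-intercept linear model

    Z - Z0 = a (X - X0)^2 + b (Y - Y0),

where b = dZ/dY at X0 is the direct regulatory gain of Y on Z and a collects
the curvature of Z's own response to X. Fitting this model and its mirror
(Y - Y0 regressed on (X - X0)^2 and Z - Z0) yields the two cross-gains; the
direction with the larger |gain| wins: if Y truly drives Z the reverse gain
is (asymptotically) zero, and vice versa.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .dream_io import ExpressionPanel
from .response import change_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "DirectionVerdict",
    "taylor_regression",
    "decide_direction",
    "wildtype_stationarity_check",
]

FORWARD = "forward"   # Y -> Z
REVERSE = "reverse"   # Z -> Y
TIE = "tie"


@dataclass(frozen=True)
class DirectionVerdict:
    """Outcome of the direction test for one (Y, Z) pair.

    ``forward_coef`` estimates dZ/dY at the operating point, ``reverse_coef``
    estimates dY/dZ; the quadratic coefficients are the fitted curvature
    terms of each model. ``winner`` is "forward" (Y -> Z) iff
    |forward_coef| > |reverse_coef|, "reverse" iff strictly smaller, and
    "tie" otherwise.
    """

    y: int
    z: int
    forward_coef: float
    reverse_coef: float
    quad_coef_forward: float
    quad_coef_reverse: float
    winner: str
    degenerate: bool = False

    @property
    def margin(self) -> float:
        """Confidence margin |b_forward| - |b_reverse| (sign-free)."""
        return abs(self.forward_coef) - abs(self.reverse_coef)


def taylor_regression(
    x_obs, y_obs, z_obs, x0: float, y0: float, z0: float
) -> tuple[float, float, bool]:
    """Least-squares fit of z on [(X - X0)^2, (Y - Y0)] with no intercept.

    Returns (a, b, degenerate): a is the quadratic (curvature) coefficient,
    b the linear cross-gain. Rank-deficient designs are fitted with the
    pseudoinverse (minimum-norm solution; an all-zero regressor gets
    coefficient 0) and flagged degenerate.
    """
    x = np.asarray(x_obs, dtype=float).reshape(-1)
    y = np.asarray(y_obs, dtype=float).reshape(-1)
    z = np.asarray(z_obs, dtype=float).reshape(-1)
    if not (x.shape == y.shape == z.shape):
        raise ValueError("observation columns must have equal length")
    if x.shape[0] < 3:
        raise ValueError("need at least 3 observations for the regression")
    for v in (x0, y0, z0):
        if not np.isfinite(v):
            raise ValueError("wild-type operating point must be finite")
    design = np.column_stack(((x - x0) ** 2, y - y0))
    target = z - z0
    rank = np.linalg.matrix_rank(design)
    coef, *_ = np.linalg.lstsq(design, target, rcond=None)
    return float(coef[0]), float(coef[1]), rank < 2


def decide_direction(
    x_obs,
    y_obs,
    z_obs,
    x0: float,
    y0: float,
    z0: float,
    y_index: int = 0,
    z_index: int = 1,
) -> DirectionVerdict:
    """Run the forward and mirrored regressions and compare the cross-gains.

    The forward model regresses Z's deviation on [(X-X0)^2, Y's deviation];
    the reverse model swaps the roles of Y and Z. The ordered winning pair is
    invariant under swapping the (y, z) argument order.
    """
    a_f, b_f, deg_f = taylor_regression(x_obs, y_obs, z_obs, x0, y0, z0)
    a_r, b_r, deg_r = taylor_regression(x_obs, z_obs, y_obs, x0, z0, y0)
    if abs(b_f) > abs(b_r):
        winner = FORWARD
    elif abs(b_f) < abs(b_r):
        winner = REVERSE
    else:
        winner = TIE
        if deg_f and deg_r:
            logger.warning(
                "direction test for pair (%d, %d): both fits degenerate, tie verdict",
                y_index,
                z_index,
            )
    return DirectionVerdict(
        y=y_index,
        z=z_index,
        forward_coef=b_f,
        reverse_coef=b_r,
        quad_coef_forward=a_f,
        quad_coef_reverse=a_r,
        winner=winner,
        degenerate=deg_f or deg_r,
    )


def direction_between(
    panel: ExpressionPanel, x: int, y: int, z: int
) -> DirectionVerdict:
    """Direction test for panel genes y, z with shared regulator/ancestor x.

    Observations are the knockout rows excluding the rows that delete y or z
    themselves: a knocked-out gene's zero is an intervention, not a response
    of the modelled function.
    """
    keep = [i for i in range(panel.n) if i not in (y, z)]
    ko = panel.knockout
    return decide_direction(
        ko[keep, x],
        ko[keep, y],
        ko[keep, z],
        panel.wild_type[x],
        panel.wild_type[y],
        panel.wild_type[z],
        y_index=y,
        z_index=z,
    )


def wildtype_stationarity_check(panel: ExpressionPanel, eps: float = 1e-12) -> np.ndarray:
    """Diagnose how flat each gene's response is at the wild-type point.

    For each gene the strongest perturbing regulator is taken and the gene's
    deviation is fitted on the regulator's linear and quadratic deviations
    (no intercept). The diagnostic is the ratio of the scaled linear to the
    scaled quadratic contribution: ~0 when the zero-first-derivative
    assumption holds, >> 1 when a linear response dominates. Informational
    only; inference never blocks on it.
    """
    n = panel.n
    delta = change_matrix(panel)
    diagnostics = np.zeros(n)
    for j in range(n):
        off = np.abs(delta[:, j]).copy()
        off[j] = -np.inf
        i = int(np.argmax(off))
        if not np.isfinite(off[i]) or off[i] <= 0:
            continue
        keep = [r for r in range(n) if r != j]
        dx = panel.knockout[keep, i] - panel.wild_type[i]
        dy = panel.knockout[keep, j] - panel.wild_type[j]
        design = np.column_stack((dx, dx**2))
        coef, *_ = np.linalg.lstsq(design, dy, rcond=None)
        lin = abs(coef[0]) * np.sqrt(np.mean(dx**2))
        quad = abs(coef[1]) * np.sqrt(np.mean(dx**4))
        diagnostics[j] = lin / (quad + eps)
        if diagnostics[j] > 1:
            logger.warning(
                "gene %s: linear response term dominates the quadratic "
                "(ratio %.2g); flat-operating-point assumption questionable",
                panel.gene_names[j],
                diagnostics[j],
            )
    return diagnostics
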