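"""Gaussian mutual information and conditional mutual information.

Under a joint-Gaussian model both quantities reduce to log-ratios of
covariance determinants:

    I(x; y)     = 1/2 ln( var(x) var(y) / det C_xy )  =  -1/2 ln(1 - rho^2)
    I(x; y | z) = 1/2 ln( det C_xz det C_yz / (var(z) det C_xyz) )

with C the sample covariance (denominator m - 1). Values are in nats. A
small ridge proportional to the mean variance is added to the covariance
diagonal before taking determinants so that near-singular designs (common in
noise-free knockout panels) stay finite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["gaussian_mi", "gaussian_cmi", "DEFAULT_RIDGE"]

DEFAULT_RIDGE = 1e-8


def _stack(cols, min_m: int) -> np.ndarray:
    arrs = [np.asarray(c, dtype=float).reshape(-1) for c in cols]
    m = arrs[0].shape[0]
    for a in arrs[1:]:
        if a.shape[0] != m:
            raise ValueError(
                f"observation columns have mismatched lengths {m} and {a.shape[0]}"
            )
    if m < min_m:
        raise ValueError(f"need at least {min_m} observations, got {m}")
    return np.column_stack(arrs)


def _ridged_cov(data: np.ndarray, ridge: float) -> np.ndarray:
    C = np.cov(data, rowvar=False, ddof=1)
    C = np.atleast_2d(C)
    if ridge:
        C = C + ridge * np.mean(np.diag(C)) * np.eye(C.shape[0])
    return C


def gaussian_mi(x, y, ridge: float = DEFAULT_RIDGE) -> float:
    """Mutual information (nats) of two observation columns, Gaussian model.

    Symmetric in (x, y) and invariant under affine rescaling of either
    argument (up to the ridge). Nonnegative up to ridge effects.
    """
    data = _stack((x, y), min_m=3)
    C = _ridged_cov(data, ridge)
    det = np.linalg.det(C)
    return 0.5 * float(np.log(C[0, 0] * C[1, 1] / det))


def gaussian_cmi(x, y, z, ridge: float = DEFAULT_RIDGE) -> float:
    """Conditional mutual information I(x; y | z) in nats, Gaussian model.

    Zero (up to ridge effects) exactly when x and y are conditionally
    uncorrelated given z; symmetric in (x, y). All three determinants are
    taken from submatrices of one ridged 3x3 covariance so that the exact
    Markov-chain cancellation holds at machine precision.
    """
    data = _stack((x, y, z), min_m=4)
    C = _ridged_cov(data, ridge)
    det_xz = np.linalg.det(C[np.ix_([0, 2], [0, 2])])
    det_yz = np.linalg.det(C[np.ix_([1, 2], [1, 2])])
    det_xyz = np.linalg.det(C)
    return 0.5 * float(np.log(det_xz * det_yz / (C[2, 2] * det_xyz)))
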