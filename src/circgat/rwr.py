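"""Random walk with restart over a similarity network.

Each entity's feature vector is the stationary visiting profile of a
restarting walker seeded at that entity: all rows are iterated jointly as
``P <- (1 - theta) P S_hat + theta P0`` with ``P0 = I`` and ``S_hat`` the
column-normalized similarity matrix. The restart probability ``theta``
defaults to 0.9. The update right-multiplies row vectors by a
column-stochastic matrix, so row sums are not exactly conserved; the
converged profiles are used as-is, without renormalization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RWRConfig:
    theta: float = 0.9
    tol: float = 1e-6
    max_iter: int = 1000

    def __post_init__(self) -> None:
        if not 0 < self.theta <= 1:
            raise ValueError("theta must be in (0, 1]")
        if self.tol <= 0 or self.max_iter < 1:
            raise ValueError("tol must be > 0 and max_iter >= 1")


def column_normalize(S: np.ndarray) -> np.ndarray:
    """Divide each column by its sum; all-zero columns stay zero (warned)."""
    S = np.asarray(S, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError("S must be square")
    if S.min() < 0:
        raise ValueError("S must be nonnegative")
    sums = S.sum(axis=0)
    zero = sums == 0
    if zero.any():
        logger.warning("column_normalize: %d all-zero columns left as zero", int(zero.sum()))
    out = np.divide(S, np.where(zero, 1.0, sums)[None, :])
    return out


def rwr(S: np.ndarray, cfg: RWRConfig = RWRConfig()) -> np.ndarray:
    """Iterate all one-hot seeds jointly to the restart fixed point.

    Returns the converged P (n x n, row i = profile of entity i). On
    non-convergence within ``max_iter`` the last iterate is returned with
    a logged warning reporting the residual.
    """
    S_hat = column_normalize(S)
    n = S_hat.shape[0]
    P = np.eye(n)
    restart = cfg.theta * np.eye(n)
    for _ in range(cfg.max_iter):
        P_next = (1.0 - cfg.theta) * (P @ S_hat) + restart
        delta = np.abs(P_next - P).max()
        P = P_next
        if delta < cfg.tol:
            return P
    logger.warning("rwr: no convergence after %d iterations (residual %.3g)", cfg.max_iter, delta)
    return P
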