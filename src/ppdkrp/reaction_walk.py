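"""Random-walk model of the ternary-to-binary reaction ratio.

For an N-subunit protein whose configurations stay phase separated (one
contiguous block of modified subunits), the number of modified subunits
performs a nearest-neighbour random walk on 1..N-1 driven by fast ternary
reactions (modification with probability p, de-modification with 1-p), and
only the absorbing boundary configurations (all-modified / all-unmodified)
react through slow binary events.  The mean number of ternary steps per
binary event starting one step inside the boundary, M(1), therefore measures
the ternary:binary reaction ratio.  The recursion

    M(1)     = 1 + p M(2)
    M(i)     = 1 + (1-p) M(i-1) + p M(i+1)
    M(N-1)   = 1 + (1-p) M(N-2)

is linear; at p = 1/2 (the symmetric walk near the system's steady state)
M(1) = N - 1 exactly, so avidity amplifies ternary over binary reactions in
proportion to the subunit number.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_banded

from .errors import DomainError, DegenerateWalkError

__all__ = ["WalkModel", "mean_steps_to_boundary", "simulate_reaction_ratio"]


@dataclass
class WalkModel:
    """Subunit count, modification probability, mean-step vector M(1..N-1)."""

    N: int
    p: float
    M: np.ndarray

    @property
    def ratio(self) -> float:
        """Ternary:binary reaction ratio, M(1)."""
        return float(self.M[0])


def mean_steps_to_boundary(N: int, p: float) -> WalkModel:
    """Solve the mean-first-passage recursion on the interior states 1..N-1.

    The step that reaches a boundary is counted (the recursion's "+1").
    Raises :class:`DegenerateWalkError` for p in {0, 1}.
    """
    if N < 2:
        raise DomainError("N must be >= 2")
    if not 0.0 < p < 1.0:
        raise DegenerateWalkError(f"p must be in (0, 1), got {p}")
    m = N - 1
    # tridiagonal system: M(i) - p M(i+1) - (1-p) M(i-1) = 1
    ab = np.zeros((3, m))
    ab[0, 1:] = -p  # superdiagonal
    ab[1, :] = 1.0
    ab[2, :-1] = -(1.0 - p)  # subdiagonal
    M = solve_banded((1, 1), ab, np.ones(m))
    return WalkModel(N=N, p=p, M=M)


def simulate_reaction_ratio(
    N: int,
    p: float,
    n_binary_events: int,
    seed: int,
):
    """Monte-Carlo estimate of the ternary:binary reaction ratio.

    Each cycle, a binary event kicks the protein off a boundary configuration
    (into state 1 from all-unmodified or N-1 from all-modified, both sampled
    equally) and ternary events walk the domain boundary until a boundary
    configuration is reached again; the ratio is the mean number of ternary
    steps per cycle.  Returns ``(estimate, standard_error)``; seed-reproducible.
    """
    if N < 2:
        raise DomainError("N must be >= 2")
    if not 0.0 < p < 1.0:
        raise DegenerateWalkError(f"p must be in (0, 1), got {p}")
    if n_binary_events < 100:
        raise DomainError("n_binary_events must be >= 100")
    rng = np.random.default_rng(seed)

    # Starting from N-1 with modification probability p mirrors starting from
    # 1 with probability 1-p; simulate positions directly.
    starts = np.where(rng.random(n_binary_events) < 0.5, 1, N - 1)
    pos = starts.astype(np.int64)
    steps = np.zeros(n_binary_events, dtype=np.int64)
    active = np.ones(n_binary_events, dtype=bool)
    while active.any():
        idx = np.flatnonzero(active)
        move = np.where(rng.random(idx.size) < p, 1, -1)
        pos[idx] += move
        steps[idx] += 1
        active[idx] = (pos[idx] > 0) & (pos[idx] < N)
    est = float(steps.mean())
    se = float(steps.std(ddof=1) / np.sqrt(n_binary_events))
    return est, se
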