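"""Master-equation model of PPDK subunit configurations on the tetramer ring.

Each subunit of the PPDK n-mer (n = 4 for the tetramer) is in one of the
states S0 (PPDK0), S1 (PPDK1) or S2 (PPDK2).  Configurations related by the
dihedral symmetry of the ring (rotations and reflections) are physically
identical and are lumped into equivalence classes; for the tetramer with
three states per subunit there are 21 classes.

Transitions are single-subunit events driven by RP binding:

* ternary events -- RP spans an adjacent (S1, S2) pair and flips the S1 to S2
  at rate eta1 or the S2 to S1 at rate eta2; because the avid ternary complex
  is long-lived, eta1, eta2 ~ 1 (a reaction almost always precedes
  unbinding);
* binary events -- RP bound to a single subunit flips it (S1 <-> S2) at rate
  mu, with mu/eta = (Vk/(koff1+Vk) + Vp/(koff4+Vp))/2, the probability that a
  short-lived binary complex reacts before dissociating.  These rare events
  keep the chain ergodic (they un-stick the all-S1 / all-S2 states);
* auto events (three-state model) -- auto-phosphorylation S0 -> S1 at delta1
  and phospho-transfer S1 -> S0 at delta2.

Since the ternary reaction converts a mixed neighbouring pair into a matched
pair, the steady state is bimodal: tetramers are mostly all-S1 or all-S2, and
the alternating "checkerboard" arrangement is the rarest.  The boundary-chain
reduction tracks only phase-separated configurations by their number of
modified subunits and admits closed forms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .errors import DomainError, ReducibleChainError

__all__ = [
    "TetramerConfiguration",
    "MasterModel",
    "ConfigDistribution",
    "canonical_form",
    "enumerate_configurations",
    "build_master_model",
    "master_steady_state",
    "binary_event_probability",
    "gillespie_simulate",
    "boundary_chain_distribution",
]

Config = Tuple[int, ...]


def _dihedral_orbit(states: Config):
    n = len(states)
    for k in range(n):
        rot = states[k:] + states[:k]
        yield rot
        yield rot[::-1]


def canonical_form(states: Sequence[int]) -> Config:
    """Lexicographic minimum over the 2n dihedral symmetry operations."""
    t = tuple(states)
    return min(_dihedral_orbit(t))


@dataclass(frozen=True)
class TetramerConfiguration:
    """A symmetry class of subunit-state assignments on the ring."""

    states: Config  # canonical representative
    multiplicity: int  # orbit size among the n_states**n raw assignments

    @property
    def n(self) -> int:
        return len(self.states)

    def label(self) -> str:
        return "".join(str(s) for s in self.states)


def enumerate_configurations(n_subunits: int, n_states: int) -> List[TetramerConfiguration]:
    """All dihedral equivalence classes of state rings, deterministically ordered.

    For (4, 3) this yields the 21 tetramer classes; multiplicities sum to
    ``n_states ** n_subunits``.
    """
    if n_subunits < 1 or n_states < 1:
        raise DomainError("n_subunits and n_states must be >= 1")
    counts: Dict[Config, int] = {}
    for raw in product(range(n_states), repeat=n_subunits):
        counts[canonical_form(raw)] = counts.get(canonical_form(raw), 0) + 1
    return [
        TetramerConfiguration(states=c, multiplicity=m)
        for c, m in sorted(counts.items())
    ]


@dataclass
class MasterModel:
    """Lumped continuous-time Markov chain over configuration classes.

    ``W[j, i]`` is the transition rate from class i to class j (off-diagonal
    >= 0); diagonal entries make every column sum to zero, so probability is
    conserved.  ``edges`` lists (i, j, rate, kind) with kind in
    {"binary", "ternary", "auto"} for event bookkeeping.
    """

    configs: List[TetramerConfiguration]
    W: np.ndarray
    rates: Dict[str, float]
    n_states: int
    edges: List[Tuple[int, int, float, str]] = field(default_factory=list)

    @property
    def index(self) -> Dict[Config, int]:
        return {c.states: i for i, c in enumerate(self.configs)}


@dataclass
class ConfigDistribution:
    """Steady-state (or empirical) probabilities over configuration classes."""

    configs: List[TetramerConfiguration]
    probabilities: Dict[Config, float]

    def prob(self, states: Sequence[int]) -> float:
        return self.probabilities[canonical_form(states)]

    @property
    def summary(self) -> Dict[str, float]:
        n = self.configs[0].n
        all_s1 = self.probabilities.get(tuple([1] * n), 0.0)
        all_s2 = self.probabilities.get(tuple([2] * n), 0.0)
        checker = 0.0
        if n % 2 == 0:
            checker = self.probabilities.get(canonical_form([1, 2] * (n // 2)), 0.0)
        return {
            "all_S1": all_s1,
            "all_S2": all_s2,
            "mixed": 1.0 - all_s1 - all_s2,
            "checkerboard": checker,
        }

    def as_vector(self) -> np.ndarray:
        return np.array([self.probabilities[c.states] for c in self.configs])


def binary_event_probability(Vk: float, Vp: float, koff1: float, koff4: float) -> float:
    """mu/eta: probability a binary complex reacts before dissociating.

    mu/eta = (Vk/(koff1+Vk) + Vp/(koff4+Vp)) / 2, averaging the kinase- and
    phosphatase-domain encounters.  Approaches Vk/koff for slow catalysis and
    saturates at 1.
    """
    if min(Vk, Vp, koff1, koff4) <= 0:
        raise DomainError("all rates must be positive")
    return 0.5 * (Vk / (koff1 + Vk) + Vp / (koff4 + Vp))


def _site_events(states: Config, rates: Dict[str, float], three_state: bool):
    """Yield (new_states, rate, kind) for every single-subunit event."""
    n = len(states)
    mu = rates["mu"]
    eta1 = rates["eta1"]
    eta2 = rates["eta2"]
    for i, s in enumerate(states):
        if s == 1:
            yield _flip(states, i, 2), mu, "binary"
            if three_state:
                yield _flip(states, i, 0), rates["delta2"], "auto"
        elif s == 2:
            yield _flip(states, i, 1), mu, "binary"
        elif s == 0 and three_state:
            yield _flip(states, i, 1), rates["delta1"], "auto"
    for i in range(n):
        j = (i + 1) % n
        if n == 2 and i == 1:
            break  # a dimer has a single adjacent pair, not two
        pair = (states[i], states[j])
        if pair == (1, 2):
            yield _flip(states, i, 2), eta1, "ternary"
            yield _flip(states, j, 1), eta2, "ternary"
        elif pair == (2, 1):
            yield _flip(states, j, 2), eta1, "ternary"
            yield _flip(states, i, 1), eta2, "ternary"


def _flip(states: Config, i: int, new: int) -> Config:
    return states[:i] + (new,) + states[i + 1:]


def build_master_model(
    n_subunits: int,
    rates: Dict[str, float],
    states: str = "two_state",
) -> MasterModel:
    """Assemble the lumped class-level rate matrix.

    ``rates`` requires mu, eta1, eta2 (and delta1, delta2 for the three-state
    model).  Event rates are counted on a class representative; because the
    single-site events commute with the dihedral symmetry, the class-level
    chain is an exact lumping of the full ``n_states**n`` chain.
    """
    if states not in ("two_state", "three_state"):
        raise DomainError(f"unknown state alphabet {states!r}")
    three = states == "three_state"
    required = {"mu", "eta1", "eta2"} | ({"delta1", "delta2"} if three else set())
    missing = required - rates.keys()
    if missing:
        raise DomainError(f"missing rates: {sorted(missing)}")
    for k in required:
        if rates[k] < 0:
            raise DomainError(f"rate {k} must be >= 0")

    n_states = 3 if three else 2
    if three:
        configs = enumerate_configurations(n_subunits, 3)
    else:
        # two-state model lives on the {S1, S2} alphabet
        all_classes = enumerate_configurations(n_subunits, 3)
        configs = [c for c in all_classes if 0 not in c.states]
    index = {c.states: i for i, c in enumerate(configs)}

    m = len(configs)
    W = np.zeros((m, m))
    edges: List[Tuple[int, int, float, str]] = []
    for i, conf in enumerate(configs):
        for new, rate, kind in _site_events(conf.states, rates, three):
            if rate == 0.0:
                continue
            j = index[canonical_form(new)]
            W[j, i] += rate
            edges.append((i, j, rate, kind))
    np.fill_diagonal(W, W.diagonal() - W.sum(axis=0))
    return MasterModel(configs=configs, W=W, rates=dict(rates),
                       n_states=n_states, edges=edges)


def master_steady_state(model: MasterModel) -> ConfigDistribution:
    """Normalized null vector of the rate matrix (unique when the chain is ergodic)."""
    if model.rates.get("mu", 0.0) <= 0.0:
        raise ReducibleChainError(
            "mu = 0: without single-domain binding events the all-S1/all-S2 "
            "states are absorbing and the chain is reducible"
        )
    W = model.W
    m = W.shape[0]
    u, s, vh = np.linalg.svd(W)
    if m > 1 and s[-2] < 1e-12 * max(1.0, s[0]):
        raise ReducibleChainError("rate matrix null space is degenerate")
    p = vh[-1].real
    p = p / p.sum()
    if np.min(p) < -1e-12:
        raise ReducibleChainError("null vector is not a probability vector")
    p = np.clip(p, 0.0, None)
    p /= p.sum()
    return ConfigDistribution(
        configs=model.configs,
        probabilities={c.states: float(p[i]) for i, c in enumerate(model.configs)},
    )


def gillespie_simulate(
    model: MasterModel,
    n_events: int,
    seed: int,
    initial: Optional[Sequence[int]] = None,
):
    """Exact stochastic simulation over configuration classes.

    Returns ``(ConfigDistribution, tallies)`` where the distribution is
    time-weighted over the trajectory and tallies counts fired events by kind
    ({"ternary", "binary", "auto"}).  Bit-reproducible for a given seed.
    """
    if n_events < 1:
        raise DomainError("n_events must be >= 1")
    from bisect import bisect_right

    rng = np.random.default_rng(seed)
    m = len(model.configs)
    # per-state edge tables
    inv_rate = [0.0] * m
    cum: List[List[float]] = []
    targets: List[List[int]] = []
    kinds: List[List[str]] = []
    by_state: List[List[Tuple[int, float, str]]] = [[] for _ in range(m)]
    for i, j, rate, kind in model.edges:
        by_state[i].append((j, rate, kind))
    for i in range(m):
        if not by_state[i]:  # absorbing (cannot happen with mu > 0)
            raise ReducibleChainError(f"state {i} has no outgoing events")
        r = np.array([e[1] for e in by_state[i]])
        inv_rate[i] = 1.0 / r.sum()
        cum.append(list(np.cumsum(r) / r.sum()))
        targets.append([e[0] for e in by_state[i]])
        kinds.append([e[2] for e in by_state[i]])

    if initial is None:
        state = 0
    else:
        state = model.index[canonical_form(initial)]
    occupancy = np.zeros(m)
    tallies = {"ternary": 0, "binary": 0, "auto": 0}

    chunk = 65536
    done = 0
    while done < n_events:
        k = min(chunk, n_events - done)
        exps = rng.exponential(size=k)
        unis = rng.random(size=k)
        for e, u in zip(exps.tolist(), unis.tolist()):
            occupancy[state] += e * inv_rate[state]
            c = cum[state]
            idx = bisect_right(c, u)
            if idx >= len(c):
                idx = len(c) - 1
            tallies[kinds[state][idx]] += 1
            state = targets[state][idx]
        done += k

    occupancy /= occupancy.sum()
    dist = ConfigDistribution(
        configs=model.configs,
        probabilities={c.states: float(occupancy[i])
                       for i, c in enumerate(model.configs)},
    )
    return dist, tallies


def boundary_chain_distribution(
    n: int,
    eps1: float,
    eps2: float,
    eta1: float,
    eta2: float,
) -> np.ndarray:
    """Steady state of the phase-separated boundary chain, N(0..n).

    States are labelled by the number of modified subunits; only the fully
    unmodified/modified boundary states react through (slow) binary events at
    rates n*eps1 / n*eps2, while interior states move their single domain
    boundary through ternary events at 2*eta1 (modify) and 2*eta2 (de-modify).
    With eps1 = eps2 = eps and eta1 = eta2 = eta all interior states share the
    occupancy (n eps / 2 eta) N(0); for the tetramer (n = 4) this reduces to
    N(0) = N(4) = eta/(2(n-1)eps + 2 eta) and N(i) = eps/((n-1)eps + eta).
    The bulk-to-boundary ratio is of order eps/eta for any n.
    """
    if n < 2:
        raise DomainError("n must be >= 2")
    if min(eps1, eps2, eta1, eta2) <= 0:
        raise DomainError("all rates must be positive")
    m = n + 1
    W = np.zeros((m, m))

    def add(i, j, rate):  # i -> j
        W[j, i] += rate
        W[i, i] -= rate

    add(0, 1, n * eps1)
    add(n, n - 1, n * eps2)
    for i in range(1, n):
        if i + 1 <= n:
            add(i, i + 1, 2.0 * eta1)
        if i - 1 >= 0:
            add(i, i - 1, 2.0 * eta2)
    A = np.vstack([W[:-1], np.ones(m)])
    b = np.zeros(m)
    b[-1] = 1.0
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    return sol
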