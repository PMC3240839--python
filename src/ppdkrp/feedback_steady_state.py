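"""Full-system steady state of the PPDK--RP cycle with PPi feedback.

The system couples three cycles:

* the catalytic cycle PPDK0 -> PPDK1 (auto-phosphorylation with ATP, flux F1,
  releasing PPi) and PPDK1 -> PPDK0 (phospho-transfer to pyruvate, producing
  PEP at rate F2, the system output);
* the regulatory cycle PPDK1 <-> PPDK2 catalysed by the bifunctional RP,
  mostly from the avid ternary complex [PPDK1.RP.PPDK2];
* the PPi loop: PPi produced by the auto-kinase at flux F1 is degraded by
  pyrophosphatases at rate alpha and competitively inhibits the RP
  phosphatase.

At steady state F1 = F2 (each auto-phosphorylation feeds one PEP), so
PPi = F2/alpha, and the requirement that the ternary-complex kinase and
phosphatase fluxes balance pins the phosphatase at Vp(PPi) = Vk.  Solving the
inhibition curve for PPi yields the robust rate

    F* = alpha * Ki_PPi * (Vp0/Vk(ADP) - 1),

which depends on the ADP input alone -- not on PPDK, RP, ATP, pyruvate or the
PPDK catalytic rate.  The PPDK2 pool acts as a buffer absorbing excess enzyme.
Robustness requires Vk < Vp0 and enough enzyme/substrate to supply F*;
outside that window the module classifies the breakdown regime.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, fields as dc_fields
from typing import Dict, Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import brentq, least_squares

from .errors import DomainError, InfeasibleError, SolverError
from .kinetic_core import (
    PoolState,
    RateParameters,
    complex_steady_state,
    rp_kinase_rate,
    rp_phosphatase_rate,
)

__all__ = [
    "Environment",
    "SteadyStateResult",
    "Trajectory",
    "ppi_steady",
    "robust_rate",
    "full_steady_state",
    "integrate_dynamics",
    "step_response",
    "f0_magnitude",
    "sensitivity_profile",
    "SENSITIVITY_QUANTITIES",
]

AVOGADRO = 6.02214076e23


@dataclass
class Environment:
    """Input signal, substrate levels and total enzyme pools.

    ``adp`` is the input (high ADP encodes darkness).  With
    ``adp_buffered=True`` (default) ADP is an externally clamped signal, as in
    the main robustness analysis.  With ``adp_buffered=False`` ``adp`` is a
    finite concentration pool depleted by the Thr-phosphoryl groups held on
    PPDK2 subunits, which exposes the ADP-limited breakdown at extreme PPDK
    levels.  Pi is assumed high and buffered and never enters the equations.
    """

    adp: float = 1.0
    atp: float = 10.0
    pi: float = 10.0
    pyruvate: float = 10.0
    ppdk_total: float = 100.0
    rp_total: float = 1.0
    adp_buffered: bool = True

    def __post_init__(self) -> None:
        for f in dc_fields(self):
            v = getattr(self, f.name)
            if f.name == "adp_buffered":
                continue
            if v < 0:
                raise DomainError(f"{f.name} must be >= 0, got {v}")

    def replace(self, **kwargs) -> "Environment":
        from dataclasses import replace

        return replace(self, **kwargs)


@dataclass
class SteadyStateResult:
    """Solved steady state with fluxes, regime label and stability flag."""

    pools: PoolState
    F1: float
    F2: float
    F_star: float  # closed-form robust rate; NaN when Vk >= Vp0
    regime: str  # robust | substrate_limited | dark_shutdown | adp_limited
    stable: bool
    multiple: bool = False

    def as_dict(self) -> dict:
        d = {"F1": self.F1, "F2": self.F2, "F_star": self.F_star,
             "regime": self.regime, "stable": self.stable}
        d.update(self.pools.as_dict())
        return d


@dataclass
class Trajectory:
    """Time course of the full mass-action system."""

    t: np.ndarray
    states: pd.DataFrame  # columns: PoolState fields + F2

    @property
    def F2(self) -> np.ndarray:
        return self.states["F2"].to_numpy()


SENSITIVITY_QUANTITIES = ("ppdk_total", "rp_total", "atp", "pyruvate", "V1", "adp")

_Y_COLS = ("ppdk0", "ppdk1", "ppdk2", "B1", "B2", "T", "ppi")


def ppi_steady(F1: float, alpha: float) -> float:
    """Steady-state PPi from production flux F1 and degradation rate alpha."""
    if F1 < 0:
        raise DomainError(f"F1 must be >= 0, got {F1}")
    if alpha <= 0:
        raise DomainError("alpha must be > 0: without degradation PPi has no steady state")
    return F1 / alpha


def robust_rate(params: RateParameters, adp: float) -> float:
    """Closed-form robust PEP formation rate F* = alpha*Ki_PPi*(Vp0/Vk - 1).

    Raises :class:`InfeasibleError` when Vk(ADP) >= Vp0, where no positive
    robust steady state exists (the feedback cannot lower Vp below Vp0's
    inhibited range to meet a kinase that is already faster).
    """
    Vk = rp_kinase_rate(adp, params)
    if Vk <= 0:
        raise DomainError("robust rate undefined at zero kinase rate (adp = 0)")
    if Vk > params.Vp0:
        raise InfeasibleError(
            f"Vk = {Vk} > Vp0 = {params.Vp0}: no positive robust solution"
        )
    return params.alpha * params.Ki_PPi * (params.Vp0 / Vk - 1.0)


def f0_magnitude(alpha: float = 100.0, ki_ppi: float = 160.0, volume: float = 20.0):
    """Scale of the robust rate in molecules/second per chloroplast.

    ``alpha`` in 1/s, ``ki_ppi`` in uM, ``volume`` in um^3.  Returns
    ``(rate, order)`` where rate = alpha * Ki_PPi * V * N_A (concentration
    converted to molecules) and order is the nearest power of ten.  With the
    literature values (alpha ~ 100/s from pyrophosphatase activity,
    Ki_PPi = 160 uM, 20 um^3 chloroplast) the order is 10^8.
    """
    if alpha < 0 or ki_ppi < 0 or volume < 0:
        raise DomainError("alpha, ki_ppi, volume must be >= 0")
    moles = ki_ppi * 1e-6 * volume * 1e-15  # uM * um^3 -> mol
    rate = alpha * moles * AVOGADRO
    order = int(round(math.log10(rate))) if rate > 0 else 0
    return rate, order


# ---------------------------------------------------------------------------
# internal helpers
# ---------------------------------------------------------------------------

def _saturations(params: RateParameters, env: Environment):
    s_atp = env.atp / (params.Km_atp + env.atp)
    s_pyr = env.pyruvate / (params.Km_pyr + env.pyruvate)
    return s_atp, s_pyr


def _vk_effective(params: RateParameters, env: Environment, x2_phos: float) -> float:
    """Kinase rate; with an unbuffered ADP pool, Thr-phosphates deplete it."""
    if env.adp_buffered:
        return params.Vk0 * env.adp
    return params.Vk0 * max(env.adp - x2_phos, 0.0)


def _complexes(params, env, x1, x2, Vk, Vp):
    return complex_steady_state(
        x1, x2, env.rp_total, params,
        Vk=Vk, Vp=Vp, ppdk_total=env.ppdk_total,
        eps_binary=params.eps_binary,
    )


def _robust_branch(params: RateParameters, env: Environment):
    """Solve the Vp(PPi) = Vk branch; returns pools or None if infeasible."""
    s_atp, s_pyr = _saturations(params, env)
    if s_atp == 0.0 or s_pyr == 0.0:
        return None
    PT = env.ppdk_total

    def parts(x2):
        Vk = _vk_effective(params, env, x2)
        if Vk >= params.Vp0 or Vk <= 0.0:
            return None
        ppi = params.Ki_PPi * (params.Vp0 / Vk - 1.0)
        F2 = params.alpha * ppi
        x1 = F2 / (params.V1 * s_pyr)
        x0 = F2 / (params.delta1 * s_atp)
        pools = _complexes(params, env, x1, x2, Vk, Vk)
        if not env.adp_buffered:
            # second pass: bound PPDK2 subunits also hold a Thr-phosphate
            Vk = _vk_effective(params, env, x2 + pools.B2 + pools.T)
            if Vk >= params.Vp0 or Vk <= 0.0:
                return None
            ppi = params.Ki_PPi * (params.Vp0 / Vk - 1.0)
            F2 = params.alpha * ppi
            x1 = F2 / (params.V1 * s_pyr)
            x0 = F2 / (params.delta1 * s_atp)
            pools = _complexes(params, env, x1, x2, Vk, Vk)
        return x0, x1, pools, ppi

    def g(x2):
        p = parts(x2)
        if p is None:
            return np.inf
        x0, x1, pools, _ = p
        return x0 + x1 + x2 + pools.bound_subunits() - PT

    if env.adp_buffered:
        x2_lo = 0.0
        if _vk_effective(params, env, 0.0) >= params.Vp0:
            return None
    else:
        x2_lo = max(0.0, env.adp - params.Vp0 / params.Vk0)
        x2_lo = x2_lo + 1e-12 * max(1.0, env.adp) if x2_lo > 0 else x2_lo
        while not np.isfinite(g(x2_lo)) and x2_lo < PT:
            x2_lo += 1e-9 * max(1.0, env.adp)
    g_lo = g(x2_lo)
    if not np.isfinite(g_lo) or g_lo >= 0.0:
        return None  # not enough PPDK to supply F*: substrate-limited
    x2 = brentq(g, x2_lo, PT, xtol=1e-13, rtol=8.9e-16, maxiter=200)
    x0, x1, pools, ppi = parts(x2)
    pools.ppdk0, pools.ppi = x0, ppi
    return pools


def _substrate_branch(params: RateParameters, env: Environment):
    """All-active branch: PPDK2 = 0, F2 linear in the PPDK1 pool."""
    s_atp, s_pyr = _saturations(params, env)
    PT = env.ppdk_total
    Vk0_eff = _vk_effective(params, env, 0.0)

    ratio = (params.V1 * s_pyr) / (params.delta1 * s_atp) if s_atp > 0 else 0.0

    def g(x1):
        x0 = ratio * x1
        pools = _complexes(params, env, x1, 0.0, Vk0_eff, params.Vp0)
        return x0 + x1 + pools.B1 - PT

    if s_pyr == 0.0 or s_atp == 0.0:
        # catalytic cycle stalled: everything piles into one pool
        if s_atp == 0.0:  # cannot auto-phosphorylate: all PPDK0
            pools = PoolState(ppdk0=PT, rp_free=env.rp_total)
            return pools
        x1 = brentq(lambda x: x + _complexes(params, env, x, 0.0, Vk0_eff,
                                             params.Vp0).B1 - PT, 0.0, PT)
        pools = _complexes(params, env, x1, 0.0, Vk0_eff, params.Vp0)
        pools.ppi = 0.0
        return pools

    x1 = brentq(g, 0.0, PT, xtol=1e-13, rtol=8.9e-16, maxiter=200)
    x0 = ratio * x1
    pools = _complexes(params, env, x1, 0.0, Vk0_eff, params.Vp0)
    pools.ppdk0 = x0
    pools.ppi = params.V1 * s_pyr * x1 / params.alpha
    return pools


def _shutdown_branch(params: RateParameters, env: Environment):
    """Vk >= Vp0, ideal avidity: kinase always wins, all PPDK ends inactive."""
    PT = env.ppdk_total
    Vk = _vk_effective(params, env, PT)

    def g(x2):
        pools = _complexes(params, env, 0.0, x2, Vk, params.Vp0)
        return x2 + pools.B2 - PT

    x2 = brentq(g, 0.0, PT, xtol=1e-13, rtol=8.9e-16, maxiter=200)
    pools = _complexes(params, env, 0.0, x2, Vk, params.Vp0)
    pools.ppdk0 = 0.0
    pools.ppi = 0.0
    return pools


def _polish_eps(params: RateParameters, env: Environment, x1_0: float, x2_0: float):
    """2-D solve of (flux balance, conservation) for eps_binary > 0."""
    s_atp, s_pyr = _saturations(params, env)
    PT = env.ppdk_total
    eps = params.eps_binary

    def build(u):
        x1, x2 = u
        F2 = params.V1 * s_pyr * x1
        ppi = F2 / params.alpha
        x0 = F2 / (params.delta1 * s_atp) if s_atp > 0 else 0.0
        Vk = _vk_effective(params, env, x2)
        Vp = rp_phosphatase_rate(env.adp, ppi, params)
        pools = _complexes(params, env, x1, x2, Vk, Vp)
        if not env.adp_buffered:
            Vk = _vk_effective(params, env, x2 + pools.B2 + pools.T)
            pools = _complexes(params, env, x1, x2, Vk, Vp)
        return x0, pools, ppi, Vk, Vp

    def residuals(u):
        x1, x2 = u
        x0, pools, ppi, Vk, Vp = build(u)
        jk = Vk * (pools.T + eps * pools.B1)
        jp = Vp * (pools.T + eps * pools.B2)
        scale = jk + jp + 1e-300
        r_bal = (jk - jp) / scale
        r_con = (x0 + x1 + x2 + pools.bound_subunits() - PT) / PT
        return [r_bal, r_con]

    x1_0 = min(max(x1_0, 1e-9 * PT), PT)
    x2_0 = min(max(x2_0, 1e-9 * PT), PT)
    sol = least_squares(
        residuals, [x1_0, x2_0], bounds=([0.0, 0.0], [PT, PT]),
        xtol=1e-15, ftol=1e-15, gtol=1e-15, method="trf",
    )
    if not sol.success or np.max(np.abs(sol.fun)) > 1e-9:
        raise SolverError(
            "eps-binary steady state failed to converge", residual=sol.fun
        )
    x1, x2 = sol.x
    x0, pools, ppi, Vk, Vp = build(sol.x)
    pools.ppdk0, pools.ppi = x0, ppi
    return pools


def _classify(params: RateParameters, env: Environment, pools: PoolState) -> str:
    PT = env.ppdk_total
    x2_tot = pools.ppdk2 + pools.B2 + pools.T
    Vk = _vk_effective(params, env, x2_tot)
    Vk_input = params.Vk0 * env.adp
    if x2_tot < 1e-6 * PT:
        return "substrate_limited"
    frac2 = x2_tot / PT if PT > 0 else 0.0
    if Vk_input >= params.Vp0 or (frac2 > 0.95 and Vk >= 0.9 * params.Vp0):
        return "dark_shutdown"
    if not env.adp_buffered and PT > env.adp:
        return "adp_limited"
    return "robust"


def _rhs(t, y, params: RateParameters, env: Environment):
    """Mass-action right-hand side over (x0, x1, x2, B1, B2, T, ppi)."""
    x0, x1, x2, B1, B2, T, ppi = y
    s_atp, s_pyr = _saturations(params, env)
    eps = params.eps_binary
    R = env.rp_total - B1 - B2 - T
    ptot = x0 + x1 + x2 + B1 + B2 + 2.0 * T
    p1 = x2 / ptot if ptot > 0 else 0.0
    p2 = x1 / ptot if ptot > 0 else 0.0

    Vk = _vk_effective(params, env, x2 + B2 + T)
    Vp = params.Vp0 / (1.0 + max(ppi, 0.0) / params.Ki_PPi)

    J1 = params.delta1 * s_atp * x0
    J2 = params.V1 * s_pyr * x1
    a1 = params.kon1 * x1 * R
    d1 = params.koff1 * B1
    a4 = params.kon4 * x2 * R
    d4 = params.koff4 * B2
    a2 = params.kon2 * p1 * B1
    d2 = params.koff2 * T
    a3 = params.kon3 * p2 * B2
    d3 = params.koff3 * T
    ckT = Vk * T
    cpT = Vp * T
    ckB = eps * Vk * B1
    cpB = eps * Vp * B2

    dx0 = -J1 + J2
    dx1 = J1 - J2 + d1 + d3 + 2.0 * cpT + cpB - a1 - a3
    dx2 = d4 + d2 + 2.0 * ckT + ckB - a4 - a2
    dB1 = a1 - d1 - ckB - a2 + d2
    dB2 = a4 - d4 - cpB - a3 + d3
    dT = a2 + a3 - d2 - d3 - ckT - cpT
    dppi = J1 - params.alpha * ppi
    return [dx0, dx1, dx2, dB1, dB2, dT, dppi]


def _stability(params, env, pools: PoolState):
    """Numerical Jacobian eigenvalues at the steady state (h ~ sqrt(eps))."""
    y0 = np.array([pools.ppdk0, pools.ppdk1, pools.ppdk2,
                   pools.B1, pools.B2, pools.T, pools.ppi])
    n = len(y0)
    J = np.empty((n, n))
    f0 = np.array(_rhs(0.0, y0, params, env))
    for j in range(n):
        h = 1e-7 * max(abs(y0[j]), 1e-3)
        yp = y0.copy()
        yp[j] += h
        J[:, j] = (np.array(_rhs(0.0, yp, params, env)) - f0) / h
    eig = np.linalg.eigvals(J)
    # one ~zero mode from PPDK conservation is expected
    return bool(np.max(eig.real) <= 1e-6)


# ---------------------------------------------------------------------------
# public solvers
# ---------------------------------------------------------------------------

def full_steady_state(params: RateParameters, env: Environment) -> SteadyStateResult:
    """Solve the coupled complex/feedback system for a non-negative steady state.

    Strategy: at eps_binary = 0 the flux-balance equation factorizes into two
    branches -- either the ternary complex vanishes (all-active,
    substrate-limited; or all-inactive shutdown when Vk >= Vp0) or the
    feedback pins Vp(PPi) = Vk (robust branch).  Each branch reduces to a
    one-dimensional root problem solved by bracketing.  With eps_binary > 0
    the branch solution seeds a bounded two-dimensional least-squares solve of
    (kinase/phosphatase balance, PPDK conservation).
    """
    if env.ppdk_total == 0.0:
        pools = PoolState(rp_free=env.rp_total)
        return SteadyStateResult(pools, 0.0, 0.0, _fstar_or_nan(params, env),
                                 "substrate_limited", True)

    pools = _robust_branch(params, env)
    if pools is None:
        Vk_in = _vk_effective(params, env, 0.0)
        if Vk_in >= params.Vp0:
            pools = _shutdown_branch(params, env)
        else:
            pools = _substrate_branch(params, env)

    if params.eps_binary > 0.0:
        pools = _polish_eps(params, env, pools.ppdk1, pools.ppdk2)

    s_atp, s_pyr = _saturations(params, env)
    F1 = params.delta1 * s_atp * pools.ppdk0
    F2 = params.V1 * s_pyr * pools.ppdk1

    y = [pools.ppdk0, pools.ppdk1, pools.ppdk2, pools.B1, pools.B2, pools.T,
         pools.ppi]
    resid = np.array(_rhs(0.0, y, params, env))
    scale = max(1.0, env.ppdk_total)
    if np.max(np.abs(resid)) > 1e-7 * scale:
        raise SolverError("steady-state residual too large", residual=resid)

    return SteadyStateResult(
        pools=pools,
        F1=F1,
        F2=F2,
        F_star=_fstar_or_nan(params, env),
        regime=_classify(params, env, pools),
        stable=_stability(params, env, pools),
    )


def _fstar_or_nan(params, env) -> float:
    try:
        return robust_rate(params, env.adp)
    except (InfeasibleError, DomainError):
        return float("nan")


def integrate_dynamics(
    params: RateParameters,
    env: Environment,
    initial: PoolState,
    t_grid: Sequence[float],
) -> Trajectory:
    """Integrate the mass-action ODEs from ``initial`` over ``t_grid``."""
    t_grid = np.asarray(t_grid, dtype=float)
    y0 = [initial.ppdk0, initial.ppdk1, initial.ppdk2,
          initial.B1, initial.B2, initial.T, initial.ppi]
    if min(y0) < 0:
        raise DomainError("initial state must be non-negative")
    sol = solve_ivp(
        _rhs, (t_grid[0], t_grid[-1]), y0, t_eval=t_grid,
        args=(params, env), method="LSODA", rtol=1e-10, atol=1e-12,
    )
    if not sol.success:
        raise SolverError(f"integration failed: {sol.message}")
    s_atp, s_pyr = _saturations(params, env)
    df = pd.DataFrame(sol.y.T, columns=list(_Y_COLS))
    df["rp_free"] = env.rp_total - df["B1"] - df["B2"] - df["T"]
    df["F2"] = params.V1 * s_pyr * df["ppdk1"]
    df.insert(0, "t", sol.t)
    return Trajectory(t=sol.t, states=df)


def step_response(
    params: RateParameters,
    env: Environment,
    step_var: str = "ppdk_total",
    step_fold: float = 1.5,
    t_end: float = 5e4,
    n_points: int = 400,
):
    """Steady state, step perturbation, relaxation: the adaptation experiment.

    A step in ``ppdk_total`` adds the extra protein in the PPDK0 (newly
    synthesized, unphosphorylated) pool.  Returns
    ``(pre_state, trajectory, post_env)``.
    """
    pre = full_steady_state(params, env)
    post_env = env.replace(**{step_var: getattr(env, step_var) * step_fold})
    init = PoolState(**pre.pools.as_dict())
    if step_var == "ppdk_total":
        init.ppdk0 += env.ppdk_total * (step_fold - 1.0)
    t_grid = np.concatenate([[0.0], np.geomspace(1e-2, t_end, n_points - 1)])
    traj = integrate_dynamics(params, post_env, init, t_grid)
    return pre, traj, post_env


def sensitivity_profile(
    params: RateParameters,
    env: Environment,
    rel_step: float = 0.05,
    quantities: Optional[Iterable[str]] = None,
) -> Dict[str, float]:
    """Logarithmic sensitivities S_X = d ln F2 / d ln X by central differences.

    In the robust regime the non-input sensitivities (PPDK, RP, ATP, pyruvate,
    V1) are ~0 and |S_adp| is order one and negative (more ADP, darker, less
    PEP).  If the two evaluation points straddle a regime boundary the step is
    shrunk and a warning emitted.
    """
    if rel_step <= 0 or rel_step >= 1:
        raise DomainError("rel_step must be in (0, 1)")
    quantities = tuple(quantities) if quantities else SENSITIVITY_QUANTITIES
    out: Dict[str, float] = {}
    for q in quantities:
        h = rel_step
        for _ in range(4):
            up, dn = _perturbed_pair(params, env, q, h)
            if up.regime == dn.regime:
                break
            warnings.warn(
                f"sensitivity step for {q} straddles regimes "
                f"({dn.regime} vs {up.regime}); shrinking step"
            )
            h /= 4.0
        if up.F2 <= 0 or dn.F2 <= 0:
            out[q] = float("nan")
            continue
        out[q] = (math.log(up.F2) - math.log(dn.F2)) / (2.0 * math.log1p(h))
    return out


def _perturbed_pair(params, env, quantity, h):
    def evaluate(factor):
        if hasattr(env, quantity):
            e = env.replace(**{quantity: getattr(env, quantity) * factor})
            p = params
        elif hasattr(params, quantity):
            p = params.replace(**{quantity: getattr(params, quantity) * factor})
            e = env
        else:
            raise DomainError(f"unknown sensitivity quantity {quantity!r}")
        return full_steady_state(p, e)

    return evaluate(1.0 + h), evaluate(1.0 / (1.0 + h))
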