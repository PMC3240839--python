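"""Mass-action kinetics of Regulatory Protein (RP) binding to PPDK tetramers.

PPDK (pyruvate orthophosphate dikinase) is active as a homotetramer whose
subunits occur in three phosphorylation states: PPDK0 (unphosphorylated),
PPDK1 (His-phosphorylated, catalytically active) and PPDK2 (His+Thr doubly
phosphorylated, inactive).  The bifunctional regulator RP carries a kinase
domain (PPDK1 -> PPDK2, ADP-consuming) and a phosphatase domain
(PPDK2 -> PPDK1, PPi-inhibited).  Because RP can engage two adjacent subunits
of one tetramer at the same time, binding is avid: once one domain is bound,
the second domain sees an enormously enhanced local concentration of its
substrate, so the ternary complex [PPDK1.RP.PPDK2] dominates over the binary
complexes [PPDK1.RP] and [PPDK2.RP].

This module solves the binary/ternary complex balance under mean-field
neighbour probabilities and exposes the closed-form lower bound on the
ternary-to-binary ratio that quantifies the avidity effect.

Units
-----
Unless stated otherwise everything is non-dimensionalized: time in units of
1/koff1, concentrations in units of total RP.  The default parameter set is
the one used throughout the package's worked examples
(kon1 = kon4 = 0.01 [koff1/RP_T], kon2 = kon3 = 200 [koff1], koff* = 1,
PPDK_T/RP_T = 100).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields
from typing import Optional

import numpy as np

from .errors import DomainError, SolverError

__all__ = [
    "RateParameters",
    "PoolState",
    "rp_kinase_rate",
    "rp_phosphatase_rate",
    "complex_steady_state",
    "ternary_binary_bound",
]


@dataclass
class RateParameters:
    """Kinetic constants of the PPDK--RP system (normalized units).

    Association rates ``kon1``/``kon4`` are bimolecular (per concentration per
    time); ``kon2``/``kon3`` are the intramolecular second-domain capture rates
    (per time) whose large magnitude encodes avidity.  ``Vk0`` scales the RP
    kinase rate with the ADP signal, ``Vp0`` is the maximal (uninhibited) RP
    phosphatase rate; the phosphatase is competitively product-inhibited by
    PPi with constant ``Ki_PPi`` (physical reference value 160 uM).  ``alpha``
    is the first-order PPi degradation rate by chloroplast pyrophosphatases
    (physical reference ~100 1/s).  ``delta1`` is the ATP-dependent
    auto-phosphorylation rate scale (PPDK0 -> PPDK1) and ``V1``/``delta2`` the
    pyruvate-dependent phospho-transfer rate (PPDK1 -> PPDK0); in vitro the
    auto-phosphorylation is ~1.5x faster, hence delta1/delta2 = 1.5 by
    default.  ``eps_binary`` scales catalysis from binary complexes relative
    to ternary complexes (0 = ideal avidity limit, 1 = full mass-action
    scheme).
    """

    kon1: float = 0.01
    kon2: float = 200.0
    kon3: float = 200.0
    kon4: float = 0.01
    koff1: float = 1.0
    koff2: float = 1.0
    koff3: float = 1.0
    koff4: float = 1.0
    Vk0: float = 0.01
    Vp0: float = 0.02
    Ki_PPi: float = 0.05
    alpha: float = 1.0
    delta1: float = 0.015
    delta2: float = 0.01
    V1: float = 0.01
    Km_atp: float = 1.0
    Km_pyr: float = 1.0
    eps_binary: float = 0.0
    # General (mixed) product-inhibition form; unused unless selected.
    Vp_prime: Optional[float] = None
    Ki2_PPi: Optional[float] = None
    # AMP inhibition of the RP kinase is neglected (Ki,AMP > 2 mM); the field
    # only documents the bound that justifies the neglect.
    Ki_AMP_floor: Optional[float] = None

    def __post_init__(self) -> None:
        for f in dc_fields(self):
            v = getattr(self, f.name)
            if v is None:
                continue
            if f.name in ("eps_binary",):
                if v < 0:
                    raise DomainError(f"{f.name} must be >= 0, got {v}")
            elif v <= 0:
                raise DomainError(f"{f.name} must be > 0, got {v}")

    @property
    def avidity_A(self) -> float:
        """Avidity ratio A = kon2/koff2 (derived, never stored)."""
        return self.kon2 / self.koff2

    def replace(self, **kwargs) -> "RateParameters":
        from dataclasses import replace

        return replace(self, **kwargs)


@dataclass
class PoolState:
    """Concentrations of free subunits, complexes and products.

    ``B1`` = [PPDK1.RP], ``B2`` = [PPDK2.RP], ``T`` = [PPDK1.RP.PPDK2].
    The ternary complex sequesters two PPDK subunits, the binary complexes
    one each, so PPDK conservation reads
    ``ppdk0 + ppdk1 + ppdk2 + B1 + B2 + 2T = PPDK_T``.
    """

    ppdk0: float = 0.0
    ppdk1: float = 0.0
    ppdk2: float = 0.0
    B1: float = 0.0
    B2: float = 0.0
    T: float = 0.0
    rp_free: float = 0.0
    ppi: float = 0.0
    amp: float = 0.0

    def bound_subunits(self) -> float:
        return self.B1 + self.B2 + 2.0 * self.T

    def total_ppdk(self) -> float:
        return self.ppdk0 + self.ppdk1 + self.ppdk2 + self.bound_subunits()

    def total_rp(self) -> float:
        return self.rp_free + self.B1 + self.B2 + self.T

    def as_dict(self) -> dict:
        return {
            "ppdk0": self.ppdk0,
            "ppdk1": self.ppdk1,
            "ppdk2": self.ppdk2,
            "B1": self.B1,
            "B2": self.B2,
            "T": self.T,
            "rp_free": self.rp_free,
            "ppi": self.ppi,
            "amp": self.amp,
        }


def rp_kinase_rate(adp: float, params: RateParameters) -> float:
    """Specific RP kinase rate Vk(ADP) = Vk0 * ADP.

    Only the ratio Vk/Vp is constrained to be proportional to ADP; the linear
    form puts all ADP dependence in the kinase and is monotone increasing, so
    high ADP (darkness) maximizes PPDK inactivation.
    """
    if adp < 0:
        raise DomainError(f"adp must be >= 0, got {adp}")
    return params.Vk0 * adp


def rp_phosphatase_rate(
    adp: float,
    ppi: float,
    params: RateParameters,
    form: str = "competitive",
) -> float:
    """Specific RP phosphatase rate under PPi product inhibition.

    competitive: Vp = Vp0 / (1 + PPi/Ki_PPi)
    general:     Vp = (Vp0 - Vp'*PPi/Ki2_PPi) / (1 + PPi/Ki_PPi), floored at 0

    ``adp`` is accepted for interface symmetry; Vp0 is taken ADP-independent
    (the ADP dependence of the ratio Vk/Vp lives entirely in the kinase).
    """
    if ppi < 0:
        raise DomainError(f"ppi must be >= 0, got {ppi}")
    if adp < 0:
        raise DomainError(f"adp must be >= 0, got {adp}")
    denom = 1.0 + ppi / params.Ki_PPi
    if form == "competitive":
        return params.Vp0 / denom
    if form == "general":
        if params.Vp_prime is None or params.Ki2_PPi is None:
            raise DomainError("general form requires Vp_prime and Ki2_PPi")
        num = params.Vp0 - params.Vp_prime * ppi / params.Ki2_PPi
        return max(num, 0.0) / denom
    raise DomainError(f"unknown inhibition form: {form!r}")


def ternary_binary_bound(
    params: RateParameters,
    p1: float,
    p2: float,
    Vk: float = 0.0,
    Vp: float = 0.0,
) -> float:
    """Lower bound on T/(B1+B2): kon2/(2 koff2 + Vk + Vp) * min(p1, p2).

    Follows from the ternary-complex balance at steady state with symmetric
    branch rates (kon2 = kon3, koff2 = koff3).  With Vk, Vp << koff2 this is
    ~ (A/2) * min(p1, p2) where A = kon2/koff2 is the avidity ratio; it breaks
    down only when one of the neighbour probabilities is of order 1/A.
    """
    if not (0.0 <= p1 <= 1.0 and 0.0 <= p2 <= 1.0):
        raise DomainError("p1, p2 must lie in [0, 1]")
    if Vk < 0 or Vp < 0:
        raise DomainError("Vk, Vp must be >= 0")
    return params.kon2 / (2.0 * params.koff2 + Vk + Vp) * min(p1, p2)


def complex_steady_state(
    ppdk1: float,
    ppdk2: float,
    rp_total: float,
    params: RateParameters,
    Vk: Optional[float] = None,
    Vp: Optional[float] = None,
    ppdk_total: Optional[float] = None,
    eps_binary: Optional[float] = None,
) -> PoolState:
    """Solve the binary/ternary complex balance for given free subunit pools.

    The three steady-state balance equations (with mean-field neighbour
    probabilities p1 = PPDK2/PPDK_T, p2 = PPDK1/PPDK_T) are linear in
    (B1, B2, T) once free RP is eliminated through RP conservation:

        kon1*PPDK1*RPf - (koff1 + eps*Vk + kon2*p1)*B1 + koff2*T = 0
        kon4*PPDK2*RPf - (koff4 + eps*Vp + kon3*p2)*B2 + koff3*T = 0
        kon2*p1*B1 + kon3*p2*B2 - (koff2 + koff3 + Vk + Vp)*T    = 0

    Ternary catalysis always destroys the complex at Vk + Vp; binary-complex
    catalysis is scaled by ``eps_binary`` (``params.eps_binary`` when None;
    pass 1.0 for the plain mass-action scheme).

    Returns a :class:`PoolState` with the free pools echoed back and
    ``ppdk0``/``ppi``/``amp`` zero (they do not enter the binding problem).
    """
    if min(ppdk1, ppdk2, rp_total) < 0:
        raise DomainError("ppdk1, ppdk2, rp_total must be >= 0")
    Vk = params.Vk0 if Vk is None else Vk
    Vp = params.Vp0 if Vp is None else Vp
    eps = params.eps_binary if eps_binary is None else eps_binary
    if ppdk_total is None:
        ppdk_total = ppdk1 + ppdk2
    if ppdk_total <= 0:
        # No PPDK at all: RP stays free.
        return PoolState(rp_free=rp_total)
    p1 = ppdk2 / ppdk_total
    p2 = ppdk1 / ppdk_total

    a1 = params.kon1 * ppdk1
    a4 = params.kon4 * ppdk2
    c1 = params.koff1 + eps * Vk + params.kon2 * p1
    c2 = params.koff4 + eps * Vp + params.kon3 * p2
    cT = params.koff2 + params.koff3 + Vk + Vp

    # Rows: B1-, B2-, T-balance; RPf = rp_total - B1 - B2 - T substituted.
    A = np.array(
        [
            [-a1 - c1, -a1, -a1 + params.koff2],
            [-a4, -a4 - c2, -a4 + params.koff3],
            [params.kon2 * p1, params.kon3 * p2, -cT],
        ]
    )
    b = np.array([-a1 * rp_total, -a4 * rp_total, 0.0])
    try:
        B1, B2, T = np.linalg.solve(A, b)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise SolverError(f"complex balance solve failed: {exc}")

    resid = A @ np.array([B1, B2, T]) - b
    if np.max(np.abs(resid)) > 1e-8 * max(1.0, rp_total):
        raise SolverError("complex balance residual too large", residual=resid)
    tiny = -1e-12 * max(1.0, rp_total)
    if min(B1, B2, T) < tiny:
        raise SolverError(
            f"negative complex concentration: B1={B1}, B2={B2}, T={T}"
        )
    B1, B2, T = (v if v > 0.0 else 0.0 for v in (B1, B2, T))
    return PoolState(
        ppdk1=ppdk1,
        ppdk2=ppdk2,
        B1=B1,
        B2=B2,
        T=T,
        rp_free=rp_total - B1 - B2 - T,
    )
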