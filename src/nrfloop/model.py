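"""Delayed negative-feedback model of stress-induced autophagy.

Oxidative stress (a sustained step input ``s(t) = dose``) activates AMPK
both by enhancing its synthesis and by driving Thr172 phosphorylation.
Active AMPK phosphorylates ULK1 on Ser555, which drives autophagosome
formation (LC3-II / LGG-1 proxy ``L``). AMPK-P and stress both activate
NRF2, which — after the lag imposed by the mRNA -> protein -> active-TF
cascade — represses AMPK transcription through a decreasing Hill term.
That delayed negative feedback makes AMPK, NRF2 and autophagy
*transient* under sustained stress: a rapid rise followed by a decline,
so that autophagy is not hyperactivated during prolonged exposure.
Removing NRF2 (siRNA / skn-1 RNAi) breaks the loop and leaves AMPK and
autophagy persistently elevated.

State variables (arbitrary units, WT stress-free mA = A = 1):

========  =====================================================
``mA``    AMPK mRNA
``A``     total AMPK protein
``Ap``    phospho-AMPK (Thr172), a sub-pool of ``A``
``mN``    NRF2 mRNA
``N``     active NRF2 protein
``U``     ULK1 phosphorylated at Ser555 (bounded by pool U_T)
``L``     autophagosome abundance (LC3-II / GFP::LGG-1 proxy)
``P``     p62/SQSTM1 (NRF2 target, autophagy substrate)
========  =====================================================

Equations (time in hours)::

    mA' = k_mA / (1 + (N/K_N)^h) - d_mA*mA
    A'  = k_A*(1 + e_A*s)*mA - d_A*A
    Ap' = (k_p0 + k_p*s)*(A - Ap) - (k_dp + d_A)*Ap
    mN' = k_mN*(1 + c_N*s) - d_mN*mN
    N'  = k_N*mN*(k_N0 + k_N1*s + k_N2*Ap) - d_N*N
    U'  = (k_U0 + k_U*Ap)*(U_T - U) - d_U*U
    L'  = k_L*U - d_L*(1 + g_L*s)*L
    P'  = k_P*(1 + b_P*N) - d_P0*P - d_P1*L*P

``k_p0`` and ``k_U0`` are small basal activities: untreated cells and
worms have nonzero basal autophagy, so the basal operating point must
have Ap, U, L > 0. ``g_L`` is a stress-enhanced autophagosome clearance
used by the worm parameter set, where LGG-1 puncta fall under stress
even in aak-2 null animals (an AMPK-independent route); the human set
keeps it near zero so the human transient is purely feedback-shaped.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields, replace
from importlib import resources
from pathlib import Path
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import root

__all__ = [
    "PARAM_NAMES",
    "STATE_NAMES",
    "CONDITIONS",
    "SYSTEMS",
    "ParameterSet",
    "Condition",
    "Trajectory",
    "default_parameters",
    "apply_condition",
    "rhs",
    "steady_state",
    "simulate",
    "readout",
]

STATE_NAMES = ("mA", "A", "Ap", "mN", "N", "U", "L", "P")
SYSTEMS = ("human_cell", "worm")

#: default knockdown factor for siRNA / RNAi conditions
KNOCKDOWN_FACTOR = 0.05
#: default NRF2-synthesis amplification for skn-1 gain-of-function
GOF_FACTOR = 3.0


@dataclass(frozen=True)
class ParameterSet:
    """Rate constants and basal levels of the feedback model (h^-1 or a.u.)."""

    k_mA: float = 1.0  # AMPK transcription, maximal
    d_mA: float = 0.5  # AMPK mRNA turnover
    k_A: float = 1.0  # AMPK translation
    e_A: float = 6.0  # stress enhancement of AMPK synthesis
    d_A: float = 1.0  # AMPK protein turnover
    k_p0: float = 0.02  # basal Thr172 phosphorylation
    k_p: float = 3.0  # stress-driven Thr172 phosphorylation
    k_dp: float = 1.0  # Thr172 dephosphorylation
    k_mN: float = 1.0  # NRF2 transcription, basal
    c_N: float = 1.0  # stress induction of NRF2 transcription
    d_mN: float = 0.8  # NRF2 mRNA turnover
    k_N: float = 1.0  # NRF2 translation/maturation
    k_N0: float = 0.2  # basal NRF2 activation (KEAP1 leak)
    k_N1: float = 1.0  # KEAP1 release by stress
    k_N2: float = 1.0  # AMPK-P-driven NRF2 activation
    d_N: float = 1.0  # active-NRF2 turnover
    K_N: float = 0.2  # repression threshold on AMPK transcription
    h: float = 2.0  # Hill exponent of the repression
    k_U0: float = 0.05  # basal ULK1-S555 phosphorylation drive
    k_U: float = 1.0  # AMPK-P-driven ULK1 phosphorylation
    U_T: float = 1.0  # ULK1 pool size
    d_U: float = 1.0  # ULK1-S555 dephosphorylation
    k_L: float = 1.0  # ULK1-driven autophagosome production
    g_L: float = 0.0  # stress enhancement of autophagosome clearance
    d_L: float = 1.0  # autophagosome clearance
    k_P: float = 1.0  # p62 synthesis, basal
    b_P: float = 0.5  # NRF2 induction of p62
    d_P0: float = 0.2  # basal p62 decay
    d_P1: float = 0.5  # autophagy-mediated p62 degradation

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"parameter {f.name} must be finite and >= 0, got {v}")
        if self.K_N <= 0:
            raise ValueError("K_N must be > 0")
        if self.h < 1:
            raise ValueError("Hill exponent h must be >= 1")
        if self.U_T <= 0:
            raise ValueError("U_T must be > 0")
        for name in ("d_mA", "d_A", "d_mN", "d_N", "d_U", "d_L", "d_P0", "k_dp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"degradation rate {name} must be > 0")

    def to_dict(self) -> dict[str, float]:
        return {f.name: float(getattr(self, f.name)) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: Mapping[str, float]) -> "ParameterSet":
        return cls(**{k: float(v) for k, v in d.items()})

    @classmethod
    def from_json(cls, path: str | Path) -> "ParameterSet":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


PARAM_NAMES = tuple(f.name for f in fields(ParameterSet))


@dataclass(frozen=True)
class Condition:
    """A genotype/treatment expressed as multipliers on parameters.

    ``multipliers`` maps parameter names to nonnegative factors; the
    wild type is the empty map (identity).
    """

    name: str
    multipliers: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for k, v in self.multipliers.items():
            if k not in PARAM_NAMES:
                raise ValueError(f"unknown parameter {k!r} in condition {self.name!r}")
            if v < 0:
                raise ValueError(f"multiplier for {k} must be >= 0, got {v}")


CONDITIONS: dict[str, Condition] = {
    "WT": Condition("WT"),
    # siRNA / RNAi deplete the NRF2/SKN-1 transcript and, with it, the
    # protein made from it; scaling both synthesis steps abolishes the
    # feedback rather than merely weakening it
    "siNRF2": Condition(
        "siNRF2", {"k_mN": KNOCKDOWN_FACTOR, "k_N": KNOCKDOWN_FACTOR}
    ),
    "skn1_RNAi": Condition(
        "skn1_RNAi", {"k_mN": KNOCKDOWN_FACTOR, "k_N": KNOCKDOWN_FACTOR}
    ),
    # skn-1(lax120) constitutively elevated SKN-1 activity
    "skn1_GOF": Condition("skn1_GOF", {"k_N": GOF_FACTOR}),
    # aak-2(gt33) deletion: no AMPK protein made
    "aak2_null": Condition("aak2_null", {"k_A": 0.0}),
    # atg-11(tm2508): autophagosome formation initiation lost
    "atg11_null": Condition("atg11_null", {"k_L": 0.0}),
    # compound genotypes used in the paralysis assay
    "aak2_skn1_RNAi": Condition(
        "aak2_skn1_RNAi",
        {"k_A": 0.0, "k_mN": KNOCKDOWN_FACTOR, "k_N": KNOCKDOWN_FACTOR},
    ),
    "skn1_GOF_RNAi": Condition(
        "skn1_GOF_RNAi",
        {"k_mN": KNOCKDOWN_FACTOR, "k_N": GOF_FACTOR * KNOCKDOWN_FACTOR},
    ),
}


def default_parameters(system: str) -> ParameterSet:
    """Return the shipped calibrated parameter set for a system."""
    if system not in SYSTEMS:
        raise ValueError(f"unknown system {system!r}; valid systems: {list(SYSTEMS)}")
    with resources.files("nrfloop.params").joinpath(f"{system}.json").open() as fh:
        return ParameterSet.from_dict(json.load(fh))


def apply_condition(params: ParameterSet, condition: str | Condition) -> ParameterSet:
    """Apply a genotype/treatment's multipliers to a parameter set."""
    if isinstance(condition, str):
        try:
            condition = CONDITIONS[condition]
        except KeyError:
            raise ValueError(
                f"unknown condition {condition!r}; valid: {list(CONDITIONS)}"
            ) from None
    changes = {
        k: getattr(params, k) * v for k, v in condition.multipliers.items()
    }
    return replace(params, **changes) if changes else params


def rhs(
    state: np.ndarray,
    t: float,
    p: ParameterSet,
    stress: Callable[[float], float] | float,
) -> np.ndarray:
    """Time derivative of the 8-dimensional model state."""
    mA, A, Ap, mN, N, U, L, P = state
    s = stress(t) if callable(stress) else float(stress)
    rep = p.k_mA / (1.0 + (max(N, 0.0) / p.K_N) ** p.h)
    return np.array(
        [
            rep - p.d_mA * mA,
            p.k_A * (1.0 + p.e_A * s) * mA - p.d_A * A,
            (p.k_p0 + p.k_p * s) * (A - Ap) - (p.k_dp + p.d_A) * Ap,
            p.k_mN * (1.0 + p.c_N * s) - p.d_mN * mN,
            p.k_N * mN * (p.k_N0 + p.k_N1 * s + p.k_N2 * Ap) - p.d_N * N,
            (p.k_U0 + p.k_U * Ap) * (p.U_T - U) - p.d_U * U,
            p.k_L * U - p.d_L * (1.0 + p.g_L * s) * L,
            p.k_P * (1.0 + p.b_P * N) - p.d_P0 * P - p.d_P1 * L * P,
        ]
    )


def steady_state(p: ParameterSet, s: float = 0.0) -> np.ndarray:
    """Steady state at constant stress ``s``.

    The basal operating point is nearly closed-form: given total AMPK
    ``A`` all other variables follow, and the repression loop closes on
    ``A`` alone, so a scalar fixed-point iteration converges before a
    full Newton refinement on the complete right-hand side.
    """
    mN = p.k_mN * (1.0 + p.c_N * s) / p.d_mN
    phos = p.k_p0 + p.k_p * s

    def from_A(A: float) -> tuple[float, ...]:
        Ap = phos * A / (phos + p.k_dp + p.d_A)
        N = p.k_N * mN * (p.k_N0 + p.k_N1 * s + p.k_N2 * Ap) / p.d_N
        mA = p.k_mA / (1.0 + (N / p.K_N) ** p.h) / p.d_mA
        return Ap, N, mA

    A = p.k_A * (1.0 + p.e_A * s) * (p.k_mA / p.d_mA) / p.d_A  # repression-free cap
    for _ in range(500):
        Ap, N, mA = from_A(A)
        A_new = p.k_A * (1.0 + p.e_A * s) * mA / p.d_A
        if abs(A_new - A) <= 1e-13 * max(1.0, A):
            A = A_new
            break
        A = 0.5 * (A + A_new)  # damped; repression makes the map monotone down
    Ap, N, mA = from_A(A)
    drive = p.k_U0 + p.k_U * Ap
    U = drive * p.U_T / (drive + p.d_U)
    dL = p.d_L * (1.0 + p.g_L * s)
    L = p.k_L * U / dL
    P = p.k_P * (1.0 + p.b_P * N) / (p.d_P0 + p.d_P1 * L)
    guess = np.array([mA, A, Ap, mN, N, U, L, P])

    sol = root(lambda y: rhs(y, 0.0, p, s), guess, method="hybr", tol=1e-12)
    y = sol.x if sol.success and np.all(sol.x >= -1e-9) else guess
    return np.clip(y, 0.0, None)


@dataclass(frozen=True)
class Trajectory:
    """A simulated time course for one condition."""

    t: np.ndarray  # hours, strictly increasing
    y: np.ndarray  # shape (len(t), 8), columns in STATE_NAMES order
    condition: str = "WT"
    system: str = "human_cell"

    def state(self, name: str) -> np.ndarray:
        return self.y[:, STATE_NAMES.index(name)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.y, columns=list(STATE_NAMES))
        df.insert(0, "t", self.t)
        return df


def simulate(
    params: ParameterSet,
    condition: str | Condition = "WT",
    dose: float = 1.0,
    t_grid: np.ndarray | None = None,
    init: np.ndarray | None = None,
    system: str = "human_cell",
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Trajectory:
    """Integrate the model under a sustained stress step of amplitude ``dose``.

    The initial condition defaults to the condition-specific stress-free
    steady state, so every trajectory starts at its own basal operating
    point. Integration is stiff-capable (LSODA) and deterministic; a
    trajectory that leaves the nonnegative orthant beyond integrator
    tolerance raises.
    """
    cname = condition if isinstance(condition, str) else condition.name
    p = apply_condition(params, condition)
    if t_grid is None:
        t_grid = np.linspace(0.0, 8.0, 161)
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or len(t_grid) < 2 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be a strictly increasing 1-D array")
    if init is None:
        init = steady_state(p, s=0.0)
    init = np.asarray(init, dtype=float)
    if np.any(init < 0):
        raise ValueError("initial state must be nonnegative")

    sol = solve_ivp(
        lambda t, y: rhs(y, t, p, dose),
        (t_grid[0], t_grid[-1]),
        init,
        method="LSODA",
        t_eval=t_grid,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"integration failed at t = {sol.t[-1]:.4g} h: {sol.message}")
    y = sol.y.T
    if np.any(y < -1e-6):
        raise RuntimeError(
            f"state went negative beyond tolerance (min {y.min():.3g})"
        )
    return Trajectory(t=t_grid, y=np.clip(y, 0.0, None), condition=cname, system=system)


def _interp(traj: Trajectory, name: str, t: float) -> float:
    if t < traj.t[0] - 1e-12 or t > traj.t[-1] + 1e-12:
        raise ValueError(f"t = {t} outside trajectory grid [{traj.t[0]}, {traj.t[-1]}]")
    return float(np.interp(t, traj.t, traj.state(name)))


def readout(traj: Trajectory, name: str) -> float:
    """Evaluate a named scalar readout on a trajectory.

    Supported names: ``rel_<X>(<t>)`` — state ``X`` at time ``t`` (h)
    divided by its own t=0 value; ``peak_rel_<X>`` — max over the grid
    of the same ratio; ``basal_<X>`` — the t=0 value itself (used for
    cross-condition ratios such as the siNRF2/WT basal AMPK fold).
    Linear interpolation between grid points.
    """
    name = name.strip()
    if name.startswith("rel_") and name.endswith(")") and "(" in name:
        state, t_str = name[4:-1].split("(")
        base = _interp(traj, state, traj.t[0])
        if base <= 0:
            raise ZeroDivisionError(f"basal {state} is zero; rel_{state} undefined")
        return _interp(traj, state, float(t_str)) / base
    if name.startswith("peak_rel_"):
        state = name[len("peak_rel_") :]
        series = traj.state(state)
        if series[0] <= 0:
            raise ZeroDivisionError(f"basal {state} is zero; {name} undefined")
        return float(series.max() / series[0])
    if name.startswith("basal_"):
        return float(traj.state(name[len("basal_") :])[0])
    raise ValueError(f"unknown readout {name!r}")
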