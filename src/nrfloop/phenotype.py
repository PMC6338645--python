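"""Organism-level readouts: GFP::LGG-1 puncta fractions and paralysis.

The worm assays score (a) the GFP::LGG-1-positive area fraction per
cell, a proxy for autophagosome abundance, and (b) the fraction of
worms paralyzed under high-dose TBHP, observed hourly. The model links
the simulated autophagosome variable ``L(t)`` to paralysis through the
simplest monotone law consistent with the finding that autophagy
hyperactivation is harmful under prolonged stress: an affine hazard

    h(t) = (h0 + gamma * L(t)) * 1{dose > 0},    F(t) = 1 - exp(-∫ h)

with one (h0, gamma) pair shared by all genotypes, so that genotype
differences in paralysis are a genuine prediction of the dynamics
model, flowing exclusively through L(t).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from nrfloop.model import Trajectory

__all__ = [
    "HazardParams",
    "ParalysisCurve",
    "PRINTED_FRACTIONS",
    "PRINTED_WEIGHTS",
    "puncta_fraction",
    "paralysis_curve",
    "fit_phenotype",
]

#: printed paralyzed fractions at 7 h of 10 mM TBHP, by genotype
PRINTED_FRACTIONS: dict[str, float] = {
    "WT": 0.76,
    "skn1_RNAi": 0.85,
    "aak2_null": 0.11,
    "aak2_skn1_RNAi": 0.23,
    "atg11_null": 0.16,
    "skn1_GOF": 0.04,
    "skn1_GOF_RNAi": 0.30,
}

#: fit weights; the gain-of-function entries carry reduced weight: the
#: skn-1(gf) fraction is qualified in the source data, and the
#: skn-1(gf)+RNAi fraction reflects incomplete neuronal gene silencing,
#: a per-tissue effect the whole-animal model cannot represent
PRINTED_WEIGHTS: dict[str, float] = {
    "skn1_GOF": 0.5,
    "skn1_GOF_RNAi": 0.0,
}


@dataclass(frozen=True)
class HazardParams:
    """Shared hazard law linking autophagosome load to paralysis."""

    h0: float  # baseline stress hazard, h^-1
    gamma: float  # autophagy-coupled hazard, h^-1 per unit L

    def __post_init__(self) -> None:
        if self.h0 < 0 or self.gamma < 0:
            raise ValueError("h0 and gamma must be >= 0")


@dataclass(frozen=True)
class ParalysisCurve:
    """Expected paralyzed fraction over time for one genotype."""

    genotype: str
    t: np.ndarray
    F: np.ndarray

    def __post_init__(self) -> None:
        if abs(float(self.F[0])) > 1e-12:
            raise ValueError("F(0) must be 0")
        if np.any(np.diff(self.F) < -1e-12) or np.any(self.F > 1 + 1e-12):
            raise ValueError("F must be non-decreasing and <= 1")

    def at(self, t: float) -> float:
        return float(np.interp(t, self.t, self.F))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"genotype": self.genotype, "t_h": self.t, "F": self.F}
        )


def puncta_fraction(traj: Trajectory, scale: float = 0.2) -> pd.DataFrame:
    """GFP::LGG-1 positive area fraction over time, and its relative change.

    The area fraction is ``clamp(scale * L, 0, 1)``; the relative column
    normalizes to the same genotype's own untreated (t = 0) value.
    """
    if scale <= 0:
        raise ValueError("scale must be > 0")
    frac = np.clip(scale * traj.state("L"), 0.0, 1.0)
    rel = frac / frac[0] if frac[0] > 0 else np.full_like(frac, np.nan)
    return pd.DataFrame(
        {
            "genotype": traj.condition,
            "t_h": traj.t,
            "puncta_fraction": frac,
            "relative": rel,
        }
    )


def paralysis_curve(
    traj: Trajectory, hp: HazardParams, dose: float
) -> ParalysisCurve:
    """Cumulative paralysis from the affine-in-L hazard (trapezoidal ∫h)."""
    if dose > 0:
        haz = hp.h0 + hp.gamma * traj.state("L")
    else:
        haz = np.zeros_like(traj.t)
    cum = np.concatenate(
        [[0.0], np.cumsum(0.5 * (haz[1:] + haz[:-1]) * np.diff(traj.t))]
    )
    return ParalysisCurve(traj.condition, traj.t, 1.0 - np.exp(-cum))


def fit_phenotype(
    genotype_trajs: Mapping[str, Trajectory] | Callable[[float], Mapping[str, Trajectory]],
    printed_fractions: Mapping[str, float] | None = None,
    seed: int = 0,
    t_obs: float = 7.0,
    weights: Mapping[str, float] | None = None,
    dose_bounds: tuple[float, float] = (1.0, 30.0),
    dose_init: float = 10.0,
) -> tuple[HazardParams, float, dict[str, float], bool]:
    """Fit shared (h0, gamma) — and, when trajectories are dose-dependent,
    the paralysis-assay dose multiplier — to printed fractions.

    ``genotype_trajs`` is either a fixed genotype -> trajectory map, or
    a callable ``dose -> map`` in which case the dose multiplier is a
    third fitted parameter (the puncta assay defines dose 1; the
    paralysis assay used a 10-fold higher TBHP concentration).

    Returns ``(HazardParams, fitted_dose, predicted_fractions,
    converged)``; ``converged`` means the named residuals are finite and
    the optimizer terminated successfully. Deterministic given ``seed``
    (used only to jitter multistart initials).
    """
    if printed_fractions is None:
        printed_fractions = PRINTED_FRACTIONS
    if weights is None:
        weights = {g: PRINTED_WEIGHTS.get(g, 1.0) for g in printed_fractions}
    genos = list(printed_fractions)
    if len(genos) < 3:
        raise ValueError("need >= 3 genotypes with distinct trajectories")
    dynamic = callable(genotype_trajs)

    def predict(log_x: np.ndarray) -> dict[str, float]:
        h0, gamma = 10.0 ** log_x[0], 10.0 ** log_x[1]
        dose = 10.0 ** log_x[2] if dynamic else dose_init
        trajs = genotype_trajs(dose) if dynamic else genotype_trajs
        hp = HazardParams(h0, gamma)
        return {
            g: paralysis_curve(trajs[g], hp, dose).at(t_obs) for g in genos
        }

    def resfun(log_x: np.ndarray) -> np.ndarray:
        pred = predict(log_x)
        return np.array(
            [
                np.sqrt(weights[g]) * (pred[g] - printed_fractions[g])
                for g in genos
            ]
        )

    lo = [-4.0, -4.0] + ([np.log10(dose_bounds[0])] if dynamic else [])
    hi = [0.5, 2.0] + ([np.log10(dose_bounds[1])] if dynamic else [])
    rng = np.random.default_rng(seed)
    starts = [np.array([-1.5, -0.5] + ([np.log10(dose_init)] if dynamic else []))]
    for _ in range(4):
        starts.append(rng.uniform(lo, hi))

    best = None
    for x0 in starts:
        sol = least_squares(
            resfun, x0, bounds=(lo, hi), method="trf", xtol=1e-14, ftol=1e-14
        )
        cost = float(np.sum(sol.fun**2))
        if best is None or cost < best[0]:
            best = (cost, sol)
    _, sol = best
    hp = HazardParams(10.0 ** sol.x[0], 10.0 ** sol.x[1])
    dose = 10.0 ** sol.x[2] if dynamic else dose_init
    pred = predict(sol.x)
    converged = bool(sol.status > 0 and np.all(np.isfinite(list(pred.values()))))
    return hp, float(dose), pred, converged
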