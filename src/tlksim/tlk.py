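"""Two-lesion kinetic (TLK) model of DSB repair and cell killing.

Simple DSBs L1 and complex DSBs L2 are removed by first-order repair
(rates λ_i = ln 2 / τ_i) and by second-order pairwise interaction of break
ends (rate η per hour):

    dL1/dt = -λ1 L1 - η L1 (L1 + L2)
    dL2/dt = -λ2 L2 - η L2 (L1 + L2)

Lethal chromosome aberrations accumulate from the infidelity of linear
(mis-)repair, with lethality probabilities β1 and β2, and from pairwise
interactions, a fraction of which (default 0.25, the dicentric channel)
are lethal:

    dL_lethal/dt = β1 λ1 L1 + β2 λ2 L2 + f_pair η (L1 + L2)²

A cell with L lethal aberrations at the end of the repair interval survives
with Poisson zero-event probability p = exp(-L).

Integration uses fixed-step classical Runge-Kutta (RK4); all state
functions broadcast over numpy arrays so a whole nucleus population (with
per-nucleus repair half-times) is advanced in one pass.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass

import numpy as np
import yaml

from .errors import ValidationError

LN2 = math.log(2.0)


@dataclass(frozen=True)
class TLKParams:
    """Repair/mis-repair parameters.

    tau1/tau2 are the fast (sDSB) and slow (cDSB) repair half-times in
    hours; beta1/beta2 the lethal mis-repair probabilities; eta the
    second-order pairwise interaction rate (h^-1); lethal_pair_frac the
    probability that a pairwise interaction forms a lethal aberration.
    """

    tau1_h: float = 0.25
    tau2_h: float = 8.0
    beta1: float = 0.00026
    beta2: float = 0.011
    eta_per_h: float = 1.6e-5
    lethal_pair_frac: float = 0.25

    def __post_init__(self) -> None:
        if self.tau1_h <= 0 or self.tau2_h <= 0:
            raise ValidationError("repair half-times must be positive")
        if not (0 <= self.beta1 <= 1 and 0 <= self.beta2 <= 1):
            raise ValidationError("beta1/beta2 are probabilities in [0, 1]")
        if self.eta_per_h < 0:
            raise ValidationError("eta must be non-negative")
        if not 0 <= self.lethal_pair_frac <= 1:
            raise ValidationError("lethal_pair_frac is a probability in [0, 1]")

    @property
    def lambda1_per_h(self) -> float:
        return LN2 / self.tau1_h

    @property
    def lambda2_per_h(self) -> float:
        return LN2 / self.tau2_h

    def replace(self, **kw) -> "TLKParams":
        d = asdict(self)
        d.update(kw)
        return TLKParams(**d)

    def to_file(self, path) -> None:
        path = str(path)
        with open(path, "w") as fh:
            if path.endswith((".yml", ".yaml")):
                yaml.safe_dump(asdict(self), fh)
            else:
                json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_file(cls, path) -> "TLKParams":
        path = str(path)
        with open(path) as fh:
            d = yaml.safe_load(fh) if path.endswith((".yml", ".yaml")) else json.load(fh)
        known = {k: d[k] for k in cls.__dataclass_fields__ if k in d}
        return cls(**known)


def tlk_rhs(l1, l2, params: TLKParams, lam1=None, lam2=None):
    """Time derivatives (dL1/dt, dL2/dt, dL_lethal/dt).

    ``lam1``/``lam2`` override the repair rates derived from the params'
    half-times (used for per-nucleus heterogeneous repair).  Broadcasts
    over arrays.
    """
    l1 = np.asarray(l1, dtype=float)
    l2 = np.asarray(l2, dtype=float)
    if np.any(l1 < 0) or np.any(l2 < 0):
        raise ValidationError("lesion counts must be non-negative")
    lam1 = params.lambda1_per_h if lam1 is None else lam1
    lam2 = params.lambda2_per_h if lam2 is None else lam2
    return _rhs(l1, l2, lam1, lam2, params.eta_per_h, params.beta1, params.beta2,
                params.lethal_pair_frac)


def _rhs(l1, l2, lam1, lam2, eta, beta1, beta2, fpair):
    tot = l1 + l2
    dl1 = -lam1 * l1 - eta * l1 * tot
    dl2 = -lam2 * l2 - eta * l2 * tot
    dlet = beta1 * lam1 * l1 + beta2 * lam2 * l2 + fpair * eta * tot * tot
    return dl1, dl2, dlet


@dataclass(frozen=True)
class TLKTrajectory:
    times_h: np.ndarray
    l1: np.ndarray
    l2: np.ndarray
    l_lethal: np.ndarray

    @property
    def final(self) -> tuple[float, float, float]:
        return float(self.l1[-1]), float(self.l2[-1]), float(self.l_lethal[-1])


def _rk4_step(l1, l2, let, dt, lam1, lam2, eta, beta1, beta2, fpair):
    a1, b1, c1 = _rhs(l1, l2, lam1, lam2, eta, beta1, beta2, fpair)
    a2, b2, c2 = _rhs(l1 + 0.5 * dt * a1, l2 + 0.5 * dt * b1, lam1, lam2, eta, beta1, beta2, fpair)
    a3, b3, c3 = _rhs(l1 + 0.5 * dt * a2, l2 + 0.5 * dt * b2, lam1, lam2, eta, beta1, beta2, fpair)
    a4, b4, c4 = _rhs(l1 + dt * a3, l2 + dt * b3, lam1, lam2, eta, beta1, beta2, fpair)
    l1n = l1 + dt / 6.0 * (a1 + 2 * a2 + 2 * a3 + a4)
    l2n = l2 + dt / 6.0 * (b1 + 2 * b2 + 2 * b3 + b4)
    letn = let + dt / 6.0 * (c1 + 2 * c2 + 2 * c3 + c4)
    return l1n, l2n, letn


_NEG_TOL = -1e-9


def _time_grid(t_end_h: float, dt_h: float) -> np.ndarray:
    if t_end_h <= 0 or dt_h <= 0 or dt_h > t_end_h:
        raise ValidationError("need 0 < dt <= T")
    n = int(round(t_end_h / dt_h))
    # last step may be shorter when T is not a multiple of dt
    grid = np.arange(n + 1) * dt_h
    if grid[-1] < t_end_h - 1e-12 * t_end_h:
        grid = np.append(grid, t_end_h)
    else:
        grid[-1] = t_end_h
    return grid


def solve_final(l1_0, l2_0, t_end_h, dt_h, params: TLKParams, lam1=None, lam2=None):
    """Integrate to t = T and return final (L1, L2, L_lethal).

    Accepts scalars or arrays of initial conditions / repair rates and
    advances all trajectories simultaneously (vectorised RK4).
    """
    l1 = np.asarray(l1_0, dtype=float)
    l2 = np.asarray(l2_0, dtype=float)
    if np.any(l1 < 0) or np.any(l2 < 0):
        raise ValidationError("initial lesion counts must be non-negative")
    lam1 = params.lambda1_per_h if lam1 is None else np.asarray(lam1, dtype=float)
    lam2 = params.lambda2_per_h if lam2 is None else np.asarray(lam2, dtype=float)
    grid = _time_grid(t_end_h, dt_h)
    let = np.zeros(np.broadcast(l1, l2).shape)
    l1, l2 = np.broadcast_arrays(l1, l2)
    l1, l2 = l1.astype(float).copy(), l2.astype(float).copy()
    args = (params.eta_per_h, params.beta1, params.beta2, params.lethal_pair_frac)
    for i in range(grid.size - 1):
        dt = grid[i + 1] - grid[i]
        l1, l2, let = _rk4_step(l1, l2, let, dt, lam1, lam2, *args)
        m = min(np.min(l1), np.min(l2)) if l1.size else 0.0
        if m < _NEG_TOL:
            raise ValidationError(
                f"state went negative ({m:.3e}) at t={grid[i + 1]:g} h; reduce dt"
            )
        l1 = np.maximum(l1, 0.0)
        l2 = np.maximum(l2, 0.0)
    return l1, l2, let


def tlk_solve(state, params: TLKParams, t_end_h: float, dt_h: float,
              tau1_h: float | None = None, tau2_h: float | None = None) -> TLKTrajectory:
    """Solve the TLK system for one nucleus, recording the full trajectory.

    ``state`` is a :class:`~tlksim.accumulation.DamageState` or an
    ``(L1_0, L2_0)`` pair; optional tau overrides give this nucleus its own
    repair half-times.
    """
    if hasattr(state, "l1_0"):
        l1, l2 = float(state.l1_0), float(state.l2_0)
    else:
        l1, l2 = map(float, state)
    if l1 < 0 or l2 < 0:
        raise ValidationError("initial lesion counts must be non-negative")
    lam1 = LN2 / tau1_h if tau1_h else params.lambda1_per_h
    lam2 = LN2 / tau2_h if tau2_h else params.lambda2_per_h
    grid = _time_grid(t_end_h, dt_h)
    out1 = np.empty(grid.size)
    out2 = np.empty(grid.size)
    outl = np.empty(grid.size)
    out1[0], out2[0], outl[0] = l1, l2, 0.0
    let = 0.0
    args = (params.eta_per_h, params.beta1, params.beta2, params.lethal_pair_frac)
    for i in range(grid.size - 1):
        dt = grid[i + 1] - grid[i]
        l1, l2, let = _rk4_step(l1, l2, let, dt, lam1, lam2, *args)
        if min(l1, l2) < _NEG_TOL:
            raise ValidationError(
                f"state went negative at t={grid[i + 1]:g} h; reduce dt"
            )
        l1, l2 = max(l1, 0.0), max(l2, 0.0)
        out1[i + 1], out2[i + 1], outl[i + 1] = l1, l2, let
    return TLKTrajectory(times_h=grid, l1=out1, l2=out2, l_lethal=outl)


def survival_probability(l_lethal):
    """Poisson zero-lethal-aberration survival probability exp(-L)."""
    l = np.asarray(l_lethal, dtype=float)
    if np.any(l < 0):
        raise ValidationError("lethal damage count must be non-negative")
    p = np.exp(-l)
    return float(p) if p.ndim == 0 else p
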