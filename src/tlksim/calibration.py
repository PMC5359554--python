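"""TLK parameter calibration against measured clonogenic survival curves.

The objective is least squares on log10 survival,

    OBJ(β1, β2, η) = Σ_d [log10 SF_sim(d) - log10 SF_meas(d)]²,

with SF_sim computed in deterministic expected mode so the objective is
smooth.  (A plain-survival option exists behind ``scale="linear"``.)

Fitting follows the sensitivity-ordered strategy: each parameter is scanned
one-at-a-time over a multiplicative grid, parameters are then optimised by
coordinate descent in log10 space in order of decreasing sensitivity
(most sensitive first), and finally a derivative-free Nelder-Mead polish
runs over all three parameters jointly, still in log10 space.  Everything
is deterministic given the simulation configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .errors import ValidationError
from .population import CellPopulation, expected_survival
from .tlk import TLKParams

FIT_PARAM_NAMES = ("beta1", "beta2", "eta_per_h")

#: plausible search decades for the fitted parameters
DEFAULT_BOUNDS = {
    "beta1": (1e-5, 0.5),
    "beta2": (1e-5, 0.5),
    "eta_per_h": (1e-7, 1e-3),
}

#: hard validity limits (probabilities cannot exceed 1; rates must be > 0)
_VALIDITY = {"beta1": (0.0, 1.0), "beta2": (0.0, 1.0),
             "eta_per_h": (0.0, np.inf), "lethal_pair_frac": (0.0, 1.0)}


@dataclass(frozen=True)
class SurvivalCurveData:
    """Measured dose / survival-fraction pairs (optionally with uncertainty)."""

    doses_gy: np.ndarray
    sf: np.ndarray
    sf_err: np.ndarray | None = None

    def __post_init__(self) -> None:
        d = np.asarray(self.doses_gy, dtype=float)
        s = np.asarray(self.sf, dtype=float)
        if d.shape != s.shape or d.ndim != 1 or d.size == 0:
            raise ValidationError("doses and sf must be matching nonempty 1-D arrays")
        if np.any(d < 0):
            raise ValidationError("doses must be non-negative")
        if np.any(s <= 0) or np.any(s > 1):
            raise ValidationError("survival fractions must lie in (0, 1]")
        object.__setattr__(self, "doses_gy", d)
        object.__setattr__(self, "sf", s)
        if self.sf_err is not None:
            e = np.asarray(self.sf_err, dtype=float)
            if e.shape != d.shape:
                raise ValidationError("sf_err must match doses in length")
            object.__setattr__(self, "sf_err", e)


def read_survival_curve(path) -> SurvivalCurveData:
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("dose_gy", "sf"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing column {col}")
    err = df["sf_err"].to_numpy() if "sf_err" in df.columns else None
    return SurvivalCurveData(df["dose_gy"].to_numpy(), df["sf"].to_numpy(), err)


def write_survival_curve(data: SurvivalCurveData, path) -> None:
    cols = {"dose_gy": data.doses_gy, "sf": data.sf}
    if data.sf_err is not None:
        cols["sf_err"] = data.sf_err
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")


@dataclass(frozen=True)
class SimConfig:
    """Deterministic simulation configuration used inside the objective."""

    population: CellPopulation
    t_end_h: float = 96.0
    dt_h: float = 0.001

    def simulated_sf(self, params: TLKParams, doses_gy) -> np.ndarray:
        return expected_survival(self.population, params, doses_gy,
                                 self.t_end_h, self.dt_h)


def objective(
    params: TLKParams, data: SurvivalCurveData, config: SimConfig,
    scale: str = "log10",
) -> float:
    """Sum of squared survival-curve residuals (log10 scale by default)."""
    if scale not in ("log10", "linear"):
        raise ValidationError(f"unknown objective scale {scale!r}")
    sf_sim = np.asarray(config.simulated_sf(params, data.doses_gy))
    if np.any(sf_sim <= 0):
        raise ValidationError(
            "simulated survival underflowed to zero; restrict parameter bounds"
        )
    if scale == "log10":
        res = np.log10(sf_sim) - np.log10(data.sf)
    else:
        res = sf_sim - data.sf
    return float(np.sum(res * res))


@dataclass(frozen=True)
class SensitivityResult:
    name: str
    values: np.ndarray
    obj: np.ndarray
    range: float  # max - min of OBJ over the scanned grid


def sensitivity_scan(
    data: SurvivalCurveData,
    config: SimConfig,
    base_params: TLKParams,
    name: str,
    factors=None,
    scale: str = "log10",
) -> SensitivityResult:
    """One-at-a-time scan of a parameter over multiplicative factors.

    The default grid spans four decades (10^-2 .. 10^2 around the base
    value); grid points outside the parameter's validity range (e.g. a
    mis-repair probability above 1) are dropped.
    """
    if name not in TLKParams.__dataclass_fields__:
        raise ValidationError(f"unknown TLK parameter {name!r}")
    factors = np.asarray(
        np.logspace(-2, 2, 9) if factors is None else factors, dtype=float
    )
    if factors.size < 2 or np.any(factors <= 0):
        raise ValidationError("scan grid needs >= 2 positive factors")
    base = getattr(base_params, name)
    values = base * factors
    lo, hi = _VALIDITY.get(name, (0.0, np.inf))
    values = values[(values >= lo) & (values <= hi)]
    if values.size < 2:
        raise ValidationError(f"scan grid degenerate for {name}")
    obj = np.array(
        [objective(base_params.replace(**{name: v}), data, config, scale) for v in values]
    )
    return SensitivityResult(name=name, values=values, obj=obj,
                             range=float(obj.max() - obj.min()))


@dataclass(frozen=True)
class CalibrationResult:
    params: TLKParams
    obj_value: float
    sensitivity: list[SensitivityResult]
    order: tuple[str, ...]  # parameters in decreasing-sensitivity order
    trace: list[tuple[str, float]] = field(compare=False, default_factory=list)

    def to_dict(self) -> dict:
        return {
            "beta1": self.params.beta1,
            "beta2": self.params.beta2,
            "eta_per_h": self.params.eta_per_h,
            "obj_value": self.obj_value,
            "sensitivity_order": list(self.order),
            "sensitivity_ranges": {s.name: s.range for s in self.sensitivity},
        }


def _clip_log_bounds(name: str, bounds) -> tuple[float, float]:
    lo, hi = bounds[name]
    vlo, vhi = _VALIDITY.get(name, (0.0, np.inf))
    lo, hi = max(lo, vlo if vlo > 0 else lo), min(hi, vhi)
    if not 0 < lo < hi:
        raise ValidationError(f"invalid bounds for {name}: {(lo, hi)}")
    return np.log10(lo), np.log10(hi)


def calibrate(
    data: SurvivalCurveData,
    config: SimConfig,
    bounds: dict | None = None,
    initial: TLKParams | None = None,
    scale: str = "log10",
    coord_sweeps: int = 2,
    xatol: float = 1e-3,
) -> CalibrationResult:
    """Fit (β1, β2, η) to a survival curve.

    Sensitivity ranks are computed at the initial guess; coordinate descent
    then minimises each parameter in turn (most sensitive first) with
    bounded scalar minimisation in log10 space, followed by a Nelder-Mead
    polish over all three log10 parameters.  The returned parameters never
    score worse than the initial guess.
    """
    bounds = {**DEFAULT_BOUNDS, **(bounds or {})}
    log_bounds = {n: _clip_log_bounds(n, bounds) for n in FIT_PARAM_NAMES}
    if initial is None:
        mid = {
            n: 10 ** ((log_bounds[n][0] + log_bounds[n][1]) / 2.0)
            for n in FIT_PARAM_NAMES
        }
        initial = TLKParams().replace(**mid)
    trace: list[tuple[str, float]] = []

    def obj_of(params: TLKParams) -> float:
        try:
            return objective(params, data, config, scale)
        except ValidationError:
            return np.inf

    current = initial
    best = (obj_of(current), current)
    if not np.isfinite(best[0]):
        raise ValidationError("objective not finite at the initial guess")
    trace.append(("initial", best[0]))

    scans = [
        sensitivity_scan(data, config, current, n, scale=scale)
        for n in FIT_PARAM_NAMES
    ]
    order = tuple(
        s.name for s in sorted(scans, key=lambda s: s.range, reverse=True)
    )

    for sweep in range(coord_sweeps):
        for name in order:
            lo, hi = log_bounds[name]

            def f1(x, _name=name):
                return obj_of(current.replace(**{_name: 10**x}))

            res = optimize.minimize_scalar(
                f1, bounds=(lo, hi), method="bounded",
                options={"xatol": xatol},
            )
            cand = current.replace(**{name: float(10**res.x)})
            val = obj_of(cand)
            if val < best[0]:
                current, best = cand, (val, cand)
            trace.append((f"sweep{sweep}:{name}", best[0]))

    x0 = np.array([np.log10(getattr(best[1], n)) for n in FIT_PARAM_NAMES])

    def fnd(x):
        for n, (lo, hi) in log_bounds.items():
            i = FIT_PARAM_NAMES.index(n)
            if not lo - 1e-9 <= x[i] <= hi + 1e-9:
                return np.inf
        return obj_of(best[1].replace(**{n: 10 ** x[i]
                                         for i, n in enumerate(FIT_PARAM_NAMES)}))

    nm = optimize.minimize(
        fnd, x0, method="Nelder-Mead",
        options={"xatol": xatol, "fatol": 1e-10, "maxiter": 400},
    )
    if np.isfinite(nm.fun) and nm.fun < best[0]:
        polished = best[1].replace(
            **{n: float(10 ** nm.x[i]) for i, n in enumerate(FIT_PARAM_NAMES)}
        )
        best = (float(nm.fun), polished)
    trace.append(("polish", best[0]))

    return CalibrationResult(
        params=best[1], obj_value=best[0], sensitivity=scans, order=order, trace=trace
    )
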