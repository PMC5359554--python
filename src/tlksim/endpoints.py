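"""Derived radiobiological endpoints.

* Linear-quadratic survival SF = exp(-αD - βD²) for comparison with the
  mechanistic pipeline;
* dose-response curves through the full expected-mode pipeline;
* hypoxia reduction factor (HRF): the dose under reduced oxygen that
  matches the cell killing of a reference dose at normoxia (21% O2),
  divided by that reference dose;
* relative biological effectiveness (RBE): iso-effect dose ratio of a
  reference beam to a test beam at equal survival.

Both HRF and RBE are solved on the smooth expected-mode survival curve by
bracketed root finding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .errors import RangeError, ValidationError
from .population import CellPopulation, RepairTimeDistribution, build_population, expected_survival
from .tlk import TLKParams
from .yield_db import YieldTable

NORMOXIC_PCT = 21.0


@dataclass(frozen=True)
class LQParams:
    """Linear-quadratic coefficients (Gy^-1 and Gy^-2)."""

    alpha: float = 0.2432
    beta: float = 0.0257

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise ValidationError("LQ coefficients must be non-negative")


def lq_survival(dose_gy, params: LQParams) -> float:
    """LQ survival fraction exp(-αD - βD²)."""
    d = np.asarray(dose_gy, dtype=float)
    if np.any(d < 0):
        raise ValidationError("dose must be non-negative")
    sf = np.exp(-params.alpha * d - params.beta * d * d)
    return float(sf) if sf.ndim == 0 else sf


@dataclass
class PipelineConfig:
    """Everything needed to evaluate expected survival as a function of dose
    and oxygen: the traversal spectrum, the z̄F callable, the yield table,
    the population settings and the TLK parameters."""

    spectrum: list
    zbar_fn: object
    table: YieldTable
    params: TLKParams = field(default_factory=TLKParams)
    n: int = 1000
    dist: RepairTimeDistribution = field(default_factory=RepairTimeDistribution)
    seed: int = 0
    t_end_h: float = 24.0
    dt_h: float = 0.005
    fluctuate_fluence: bool = True
    _cache: dict = field(default_factory=dict, repr=False)

    def population(self, oxygen_pct: float) -> CellPopulation:
        """Population at the given oxygen level (same seed at every level,
        so only the damage yields change)."""
        key = float(oxygen_pct)
        if key not in self._cache:
            self._cache[key] = build_population(
                self.spectrum, self.zbar_fn, self.table, oxygen_pct,
                self.n, self.dist, self.seed, self.fluctuate_fluence,
            )
        return self._cache[key]

    def sf(self, doses_gy, oxygen_pct: float = NORMOXIC_PCT):
        return expected_survival(
            self.population(oxygen_pct), self.params, doses_gy,
            self.t_end_h, self.dt_h,
        )


def sf_vs_dose(config: PipelineConfig, doses_gy, oxygen_pct: float = NORMOXIC_PCT):
    """Expected-mode dose-response curve over an ascending dose list."""
    doses = np.asarray(doses_gy, dtype=float)
    if doses.ndim != 1 or doses.size == 0:
        raise ValidationError("doses must be a nonempty 1-D list")
    if np.any(np.diff(doses) < 0):
        raise ValidationError("doses must be ascending")
    return config.sf(doses, oxygen_pct)


def _iso_effect_dose(sf_fn, target_sf: float, d_lo: float, d_hi: float,
                     tol: float = 1e-6) -> float:
    """Dose D with sf_fn(D) = target_sf, by bisection on a decreasing curve."""
    f_lo = sf_fn(d_lo) - target_sf
    f_hi = sf_fn(d_hi) - target_sf
    if f_lo < -tol or f_hi > tol:
        raise RangeError(
            f"iso-effect dose not bracketed in [{d_lo:g}, {d_hi:g}] Gy"
        )
    if abs(f_lo) <= tol:
        return d_lo
    if abs(f_hi) <= tol:
        return d_hi
    return float(optimize.brentq(lambda d: sf_fn(d) - target_sf, d_lo, d_hi,
                                 xtol=1e-9, rtol=1e-12))


def hrf(config: PipelineConfig, oxygen_pct: float, ref_dose_gy: float,
        max_factor: float = 20.0) -> float:
    """Hypoxia reduction factor at one oxygen level.

    Solves SF(D*; oxygen) = SF(D_ref; 21%) and returns D*/D_ref.  At the
    normoxic reference level the answer is exactly 1.
    """
    if ref_dose_gy <= 0:
        raise ValidationError("reference dose must be positive")
    if oxygen_pct == NORMOXIC_PCT:
        return 1.0
    target = config.sf(ref_dose_gy, NORMOXIC_PCT)
    dstar = _iso_effect_dose(
        lambda d: config.sf(d, oxygen_pct), target, ref_dose_gy,
        max_factor * ref_dose_gy,
    )
    return dstar / ref_dose_gy


@dataclass(frozen=True)
class OxygenResponse:
    oxygen_pct: np.ndarray
    sf: np.ndarray
    hrf: np.ndarray


def oxygen_response(config: PipelineConfig, oxygen_levels, dose_gy: float) -> OxygenResponse:
    """Survival and HRF across oxygen levels at a fixed reference dose."""
    levels = np.asarray(oxygen_levels, dtype=float)
    sfs = np.array([config.sf(dose_gy, c) for c in levels])
    hrfs = np.array([hrf(config, c, dose_gy) for c in levels])
    return OxygenResponse(oxygen_pct=levels, sf=sfs, hrf=hrfs)


def rbe(test: PipelineConfig, reference: PipelineConfig, dose_gy: float,
        oxygen_pct: float = NORMOXIC_PCT, max_factor: float = 20.0) -> float:
    """Iso-effect RBE: the reference-beam dose producing the test beam's
    survival at ``dose_gy``, divided by ``dose_gy``.

    A beam compared against itself returns exactly 1.
    """
    if dose_gy <= 0:
        raise ValidationError("dose must be positive")
    if test is reference:
        return 1.0
    target = test.sf(dose_gy, oxygen_pct)
    d_ref = _iso_effect_dose(
        lambda d: reference.sf(d, oxygen_pct), target,
        dose_gy / max_factor, max_factor * dose_gy,
    )
    return d_ref / dose_gy
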