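"""Heterogeneous nucleus populations and Monte Carlo survival estimation.

Each nucleus carries its own initial damage (from its traversal spectrum)
and its own fast/slow repair half-times, drawn from truncated Gaussians to
represent cell-to-cell diversity.  The TLK system is solved per nucleus;
the per-cell survival probability p_i = exp(-L_lethal,i(T)) is either
averaged (expected survival, deterministic) or Bernoulli-sampled to give a
clonogenic-assay-like survival fraction with binomial uncertainty.

One master seed expands into independent child streams for repair-time
assignment, per-nucleus fluence fluctuation, damage sampling and the
survival draws, so every stage is reproducible on its own.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .accumulation import DamageState, spectrum_arrays
from .errors import ValidationError
from .tlk import LN2, TLKParams, solve_final, survival_probability
from .yield_db import YieldTable

#: population sizes used in the source study: voxel estimation / calibration plate
DEFAULT_VOXEL_POPULATION = 100_000
DEFAULT_CALIBRATION_POPULATION = 3_000


@dataclass(frozen=True)
class RepairTimeDistribution:
    """Gaussians for the fast and slow repair half-times (hours), truncated
    below at ``floor_h`` so that λ = ln2/τ stays finite and positive."""

    mu_fast_h: float = 0.25
    sigma_fast_h: float = 0.1
    mu_slow_h: float = 8.0
    sigma_slow_h: float = 1.0
    floor_h: float = 0.01

    def __post_init__(self) -> None:
        if min(self.mu_fast_h, self.sigma_fast_h, self.mu_slow_h,
               self.sigma_slow_h, self.floor_h) <= 0:
            raise ValidationError("all repair-time distribution parameters must be positive")


def _truncnorm(mu: float, sigma: float, floor: float, n: int, rng) -> np.ndarray:
    a = (floor - mu) / sigma
    return stats.truncnorm.rvs(a, np.inf, loc=mu, scale=sigma, size=n, random_state=rng)


def assign_repair_times(
    n: int, dist: RepairTimeDistribution | None = None, seed=None
) -> tuple[np.ndarray, np.ndarray]:
    """Draw per-nucleus (tau_fast, tau_slow) pairs; reproducible under seed."""
    if n < 1:
        raise ValidationError("population size must be >= 1")
    dist = dist or RepairTimeDistribution()
    rng = np.random.default_rng(seed)
    tau1 = _truncnorm(dist.mu_fast_h, dist.sigma_fast_h, dist.floor_h, n, rng)
    tau2 = _truncnorm(dist.mu_slow_h, dist.sigma_slow_h, dist.floor_h, n, rng)
    return tau1, tau2


@dataclass(frozen=True)
class SurvivalResult:
    n_cells: int
    n_survivors: int
    sf: float
    stderr: float
    mean_survival_prob: float
    mean_lethal: float = math.nan

    def to_dict(self) -> dict:
        return {
            "n_cells": self.n_cells,
            "n_survivors": self.n_survivors,
            "sf": self.sf,
            "stderr": self.stderr,
            "mean_survival_prob": self.mean_survival_prob,
            "mean_lethal": self.mean_lethal,
        }


@dataclass
class CellPopulation:
    """A voxel/plate worth of nuclei: per-Gy expected damage plus repair times.

    ``l1_per_gy``/``l2_per_gy`` hold each nucleus's expected lesion yield per
    macroscopic Gy (heterogeneity from per-nucleus fluence fluctuation);
    scaling linearly to a prescribed dose reproduces the study's conversion
    of damage patterns to macroscopic dose levels.
    """

    l1_per_gy: np.ndarray
    l2_per_gy: np.ndarray
    tau1_h: np.ndarray
    tau2_h: np.ndarray
    oxygen_pct: float = 21.0
    nucleus_dose_per_gy: np.ndarray | None = None  # microscopic dose per macro Gy

    def __post_init__(self) -> None:
        n = len(self.l1_per_gy)
        for name in ("l2_per_gy", "tau1_h", "tau2_h"):
            if len(getattr(self, name)) != n:
                raise ValidationError("population arrays must have equal length")
        if n == 0:
            raise ValidationError("population must contain at least one nucleus")

    @property
    def n(self) -> int:
        return len(self.l1_per_gy)

    def initial_damage(self, dose_gy: float) -> tuple[np.ndarray, np.ndarray]:
        if dose_gy < 0:
            raise ValidationError("dose must be non-negative")
        return self.l1_per_gy * dose_gy, self.l2_per_gy * dose_gy


def build_population(
    spectrum,
    zbar_fn,
    table: YieldTable,
    oxygen_pct: float,
    n: int,
    dist: RepairTimeDistribution | None = None,
    seed=None,
    fluctuate_fluence: bool = True,
) -> CellPopulation:
    """Build a nucleus population from a shared voxel spectrum.

    Expected per-bin traversal counts are Poisson-fluctuated per nucleus
    (unless ``fluctuate_fluence=False``), the expected damage of each
    nucleus is accumulated, and everything is normalised to the population
    mean microscopic dose so that damage scales linearly with prescribed
    macroscopic dose.
    """
    if n < 1:
        raise ValidationError("population size must be >= 1")
    ss = np.random.SeedSequence(seed)
    seed_tau, seed_flu = ss.spawn(2)
    e, counts = spectrum_arrays(spectrum)
    if e.size == 0:
        raise ValidationError("cannot build a population from an empty spectrum")
    z = np.asarray(zbar_fn(e), dtype=float)
    s_yield, c_yield = table.interpolate(e, np.full_like(e, oxygen_pct))
    if fluctuate_fluence:
        rng = np.random.default_rng(seed_flu)
        phi = rng.poisson(np.broadcast_to(counts, (n, e.size))).astype(float)
    else:
        phi = np.broadcast_to(counts, (n, e.size)).astype(float)
    dose = phi @ z  # (n,)
    l1 = phi @ (z * s_yield)
    l2 = phi @ (z * c_yield)
    mean_dose = float(dose.mean())
    if mean_dose <= 0:
        raise ValidationError("spectrum deposits no dose")
    tau1, tau2 = assign_repair_times(n, dist, seed_tau)
    return CellPopulation(
        l1_per_gy=l1 / mean_dose,
        l2_per_gy=l2 / mean_dose,
        tau1_h=tau1,
        tau2_h=tau2,
        oxygen_pct=oxygen_pct,
        nucleus_dose_per_gy=dose / mean_dose,
    )


def expected_survival(
    pop: CellPopulation, params: TLKParams, doses_gy, t_end_h: float, dt_h: float
):
    """Deterministic population survival fraction at one or many doses.

    Returns the population mean of p_i = exp(-L_lethal,i(T)); scalar dose in
    gives scalar out.  All (nucleus, dose) trajectories are advanced in one
    vectorised RK4 pass.
    """
    doses = np.asarray(doses_gy, dtype=float)
    scalar = doses.ndim == 0
    doses = np.atleast_1d(doses)
    if np.any(doses < 0):
        raise ValidationError("doses must be non-negative")
    l1_0 = pop.l1_per_gy[:, None] * doses[None, :]
    l2_0 = pop.l2_per_gy[:, None] * doses[None, :]
    lam1 = (LN2 / pop.tau1_h)[:, None]
    lam2 = (LN2 / pop.tau2_h)[:, None]
    _, _, lethal = solve_final(l1_0, l2_0, t_end_h, dt_h, params, lam1, lam2)
    sf = survival_probability(lethal).mean(axis=0)
    return float(sf[0]) if scalar else sf


def population_survival(
    states: list[DamageState],
    taus: tuple[np.ndarray, np.ndarray],
    params: TLKParams,
    t_end_h: float,
    dt_h: float,
    seed=None,
) -> SurvivalResult:
    """Monte Carlo survival fraction of an explicit damage-state population.

    Solves the TLK system per nucleus with its own repair half-times, then
    draws one Bernoulli survival trial per cell.
    """
    if len(states) == 0:
        raise ValidationError("population must contain at least one nucleus")
    tau1, tau2 = (np.asarray(t, dtype=float) for t in taus)
    if tau1.size != len(states) or tau2.size != len(states):
        raise ValidationError("repair-time arrays must match the number of states")
    l1_0 = np.array([s.l1_0 for s in states], dtype=float)
    l2_0 = np.array([s.l2_0 for s in states], dtype=float)
    _, _, lethal = solve_final(l1_0, l2_0, t_end_h, dt_h, params, LN2 / tau1, LN2 / tau2)
    p = survival_probability(lethal)
    rng = np.random.default_rng(seed)
    survived = rng.random(p.size) < p
    n = p.size
    sf = float(survived.mean())
    return SurvivalResult(
        n_cells=n,
        n_survivors=int(survived.sum()),
        sf=sf,
        stderr=float(math.sqrt(sf * (1.0 - sf) / n)),
        mean_survival_prob=float(p.mean()),
        mean_lethal=float(lethal.mean()),
    )


def sampled_survival(
    pop: CellPopulation,
    params: TLKParams,
    dose_gy: float,
    t_end_h: float,
    dt_h: float,
    seed=None,
) -> SurvivalResult:
    """Bernoulli-sampled survival of a :class:`CellPopulation` at one dose."""
    l1_0, l2_0 = pop.initial_damage(dose_gy)
    _, _, lethal = solve_final(
        l1_0, l2_0, t_end_h, dt_h, params, LN2 / pop.tau1_h, LN2 / pop.tau2_h
    )
    p = survival_probability(lethal)
    rng = np.random.default_rng(seed)
    survived = rng.random(p.size) < p
    sf = float(survived.mean())
    return SurvivalResult(
        n_cells=p.size,
        n_survivors=int(survived.sum()),
        sf=sf,
        stderr=float(math.sqrt(sf * (1.0 - sf) / p.size)),
        mean_survival_prob=float(p.mean()),
        mean_lethal=float(lethal.mean()),
    )


@dataclass(frozen=True)
class ReplicateSummary:
    sfs: np.ndarray
    mean_sf: float
    sd_sf: float
    results: list[SurvivalResult] = field(compare=False, default_factory=list)


def replicate_runs(
    k: int,
    states: list[DamageState],
    taus,
    params: TLKParams,
    t_end_h: float,
    dt_h: float,
    seeds,
) -> ReplicateSummary:
    """Repeat the Bernoulli survival stage k times (mirrors repeating the
    voxel Monte Carlo and reporting mean ± sd)."""
    if k < 2:
        raise ValidationError("need at least 2 replicates")
    seeds = list(seeds)
    if len(seeds) < k:
        raise ValidationError(f"need at least {k} seeds, got {len(seeds)}")
    results = [
        population_survival(states, taus, params, t_end_h, dt_h, seed=s)
        for s in seeds[:k]
    ]
    sfs = np.array([r.sf for r in results])
    return ReplicateSummary(
        sfs=sfs, mean_sf=float(sfs.mean()), sd_sf=float(sfs.std(ddof=1)), results=results
    )


def per_nucleus_table(
    states: list[DamageState], taus, lethal: np.ndarray, p: np.ndarray, survived
) -> pd.DataFrame:
    tau1, tau2 = taus
    return pd.DataFrame(
        {
            "nucleus_id": [s.nucleus_id for s in states],
            "dose_gy": [s.dose_gy for s in states],
            "l1_0": [s.l1_0 for s in states],
            "l2_0": [s.l2_0 for s in states],
            "tau1_h": tau1,
            "tau2_h": tau2,
            "l_lethal_T": lethal,
            "p_survival": p,
            "survived": np.asarray(survived, dtype=int),
        }
    )
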