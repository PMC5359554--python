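"""Synthetic stand-ins for the external simulation stages.

The full estimation chain consumes outputs of particle-transport and
damage-simulation codes that are deliberately outside this package: linac
phase-space transport (per-nucleus electron spectra), nucleus-scale
microdosimetry (z̄F curves) and the tabulated damage database.  This module
generates analytic substitutes in exactly the formats the pipeline reads,
so every stage is exercisable and testable self-contained.  None of them
claims physical fidelity to a specific beam; shapes and magnitudes are
parameterised conventions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .accumulation import SpectrumBin
from .calibration import SimConfig, SurvivalCurveData
from .errors import ValidationError
from .microdosimetry import SpecificEnergyModel
from .tlk import TLKParams
from .yield_db import ENERGY_MAX_EV, ENERGY_MIN_EV

#: Approximate electron collision stopping power of liquid water (keV/μm)
#: on a coarse energy grid, 50 eV - 6 MeV.  Synthetic fixture digitised by
#: hand from standard tabulations at ~10% accuracy — adequate for the
#: chord-length z̄F approximation, not for dosimetry.
_WATER_LET_EV = np.array(
    [5.0e1, 1.0e2, 2.0e2, 5.0e2, 1.0e3, 3.0e3, 1.0e4, 3.0e4,
     1.0e5, 3.0e5, 1.0e6, 3.0e6, 6.0e6]
)
_WATER_LET_KEV_UM = np.array(
    [18.0, 22.0, 25.0, 20.0, 12.9, 5.5, 2.3, 1.0,
     0.42, 0.25, 0.19, 0.185, 0.19]
)


def water_let_fixture() -> SpecificEnergyModel:
    """Chord-LET specific-energy model backed by the synthetic water
    stopping-power curve."""
    return SpecificEnergyModel(
        mode="chord-LET", energies_ev=_WATER_LET_EV, values=_WATER_LET_KEV_UM
    )


@dataclass(frozen=True)
class SpectrumGeneratorConfig:
    """Parameters of the analytic spectrum families.

    ``low_energy_fraction`` is the target share of traversals below
    100 keV (the quantity reported for voxel radiation patterns);
    two-component spectra hit it exactly by construction, up to seeded
    per-bin jitter that is renormalised away.
    """

    kind: str = "two-component"  # monoenergetic | two-component | power-law-with-plateau
    energy_ev: float = 1.0e6  # monoenergetic line
    low_energy_fraction: float = 0.20
    e_low_ev: tuple = (1.0e3, 1.0e5)
    e_high_ev: tuple = (1.0e5, 6.0e6)
    n_bins: int = 40
    total_count: float = 1.0
    jitter: float = 0.2
    powerlaw_index: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("monoenergetic", "two-component", "power-law-with-plateau"):
            raise ValidationError(f"unknown spectrum kind {self.kind!r}")
        if not 0.0 <= self.low_energy_fraction <= 1.0:
            raise ValidationError("low_energy_fraction must lie in [0, 1]")
        if self.n_bins < 2:
            raise ValidationError("need at least 2 bins")
        if self.total_count <= 0:
            raise ValidationError("total_count must be positive")
        for e in (self.energy_ev, *self.e_low_ev, *self.e_high_ev):
            if not ENERGY_MIN_EV <= e <= ENERGY_MAX_EV:
                raise ValidationError(
                    f"spectrum energies must lie in [{ENERGY_MIN_EV:g}, {ENERGY_MAX_EV:g}] eV"
                )


def make_spectrum(config: SpectrumGeneratorConfig | None = None, **kw) -> list[SpectrumBin]:
    """Generate an analytic electron traversal spectrum (reproducible under seed)."""
    config = config or SpectrumGeneratorConfig(**kw)
    rng = np.random.default_rng(config.seed)
    if config.kind == "monoenergetic":
        return [SpectrumBin(config.energy_ev, config.total_count)]
    if config.kind == "two-component":
        n_lo = config.n_bins // 2
        n_hi = config.n_bins - n_lo
        e_lo = np.geomspace(config.e_low_ev[0], min(config.e_low_ev[1], 0.9999e5), n_lo)
        e_hi = np.geomspace(max(config.e_high_ev[0], 1.0e5), config.e_high_ev[1], n_hi)
        w_lo = 1.0 + config.jitter * rng.random(n_lo)
        w_hi = 1.0 + config.jitter * rng.random(n_hi)
        f = config.low_energy_fraction
        w_lo *= f * config.total_count / w_lo.sum() if f > 0 else 0.0
        w_hi *= (1.0 - f) * config.total_count / w_hi.sum()
        energies = np.concatenate([e_lo, e_hi])
        weights = np.concatenate([w_lo if f > 0 else np.zeros(n_lo), w_hi])
    else:  # power-law-with-plateau
        energies = np.geomspace(config.e_low_ev[0], config.e_high_ev[1], config.n_bins)
        knee = 1.0e5
        weights = np.where(
            energies < knee, 1.0, (energies / knee) ** (-config.powerlaw_index)
        )
        weights = weights * (1.0 + config.jitter * rng.random(config.n_bins))
        weights *= config.total_count / weights.sum()
    return [SpectrumBin(e, w) for e, w in zip(energies, weights) if w > 0]


def make_survival_curve(
    config: SimConfig,
    params: TLKParams,
    doses_gy,
    noise: float = 0.0,
    seed: int | None = None,
) -> SurvivalCurveData:
    """Synthetic clonogenic survival curve from the expected-mode pipeline.

    ``noise`` is the standard deviation of multiplicative lognormal noise
    (0 for an exact curve).  Stands in for a measured survival experiment
    in calibration recovery tests.
    """
    doses = np.asarray(doses_gy, dtype=float)
    if doses.ndim != 1 or doses.size == 0 or np.any(np.diff(doses) < 0):
        raise ValidationError("doses must be a nonempty ascending 1-D list")
    if noise < 0:
        raise ValidationError("noise must be non-negative")
    sf = np.asarray(config.simulated_sf(params, doses), dtype=float)
    if noise > 0:
        rng = np.random.default_rng(seed)
        sf = sf * np.exp(rng.normal(0.0, noise, size=sf.size))
    sf = np.minimum(sf, 1.0)
    return SurvivalCurveData(doses_gy=doses, sf=sf)
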