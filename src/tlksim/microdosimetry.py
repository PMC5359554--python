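"""Microdosimetry of a spherical cell nucleus.

Specific energy z is the quotient of the energy imparted to a microscopic
volume by a single event and the volume mass — the stochastic analogue of
absorbed dose.  The frequency-mean specific energy z̄F(E) is the mean of the
single-event distribution f(z) for electrons of kinetic energy E traversing
the nucleus; multiplied by the number of traversals it yields the
microscopic dose.

Two sources for z̄F(E) are supported:

* ``tabulated`` — values imported from an external transport calculation
  (CSV ``energy_ev, zbar_gy``), interpolated linearly on log10(E);
* ``chord-LET`` — the analytic approximation z̄F = S(E)·l̄ / m with S the
  collision stopping power, l̄ = (2/3)·d the Cauchy mean chord length of a
  sphere under surface randomness, capped at E/m because a single traversal
  cannot impart more than the particle's kinetic energy.

f(z) is defined over energy-depositing events only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import RangeError, ValidationError

KEV_TO_J = 1.602176634e-16
EV_TO_KEV = 1e-3


@dataclass(frozen=True)
class NucleusModel:
    """Spherical nucleus; mass derives from diameter and density."""

    diameter_um: float = 10.0
    density_g_cm3: float = 1.0

    def __post_init__(self) -> None:
        if self.diameter_um <= 0:
            raise ValidationError("nucleus diameter must be positive")
        if self.density_g_cm3 <= 0:
            raise ValidationError("nucleus density must be positive")

    @property
    def mass_kg(self) -> float:
        d_m = self.diameter_um * 1e-6
        rho = self.density_g_cm3 * 1000.0  # kg/m^3
        return rho * (math.pi / 6.0) * d_m**3

    @property
    def mean_chord_um(self) -> float:
        """Cauchy mean chord length (2/3)·d for s-randomness on a sphere."""
        return (2.0 / 3.0) * self.diameter_um


def specific_energy(nucleus: NucleusModel, energy_imparted_kev) -> float:
    """Single-event specific energy z = ε/m in Gy (ε in keV)."""
    eps = np.asarray(energy_imparted_kev, dtype=float)
    if np.any(eps < 0):
        raise ValidationError("energy imparted must be non-negative")
    z = eps * KEV_TO_J / nucleus.mass_kg
    return float(z) if z.ndim == 0 else z


def zbar_frequency(samples) -> tuple[float, float]:
    """Frequency-mean specific energy of single-event samples.

    Returns (mean, standard error of the mean).
    """
    z = np.asarray(samples, dtype=float)
    if z.size == 0:
        raise ValidationError("zbar_frequency requires at least one sample")
    if np.any(z <= 0):
        raise ValidationError("single-event specific energies must be positive")
    mean = float(z.mean())
    stderr = float(z.std(ddof=1) / math.sqrt(z.size)) if z.size > 1 else 0.0
    return mean, stderr


@dataclass(frozen=True)
class SpecificEnergyModel:
    """Continuous z̄F(E) curve, either tabulated or chord-length × LET."""

    mode: str  # "tabulated" | "chord-LET"
    energies_ev: np.ndarray
    values: np.ndarray  # zbar_gy (tabulated) or let_kev_per_um (chord-LET)

    def __post_init__(self) -> None:
        if self.mode not in ("tabulated", "chord-LET"):
            raise ValidationError(f"unknown specific-energy mode {self.mode!r}")
        e = np.asarray(self.energies_ev, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if e.ndim != 1 or v.shape != e.shape or e.size < 2:
            raise ValidationError("need matching 1-D energy/value arrays (>= 2 points)")
        if np.any(np.diff(e) <= 0):
            raise ValidationError("tabulated energies must be strictly increasing")
        if np.any(v <= 0):
            raise ValidationError("tabulated z̄F / stopping-power values must be positive")
        object.__setattr__(self, "energies_ev", e)
        object.__setattr__(self, "values", v)

    def _check_range(self, e: np.ndarray) -> None:
        lo, hi = self.energies_ev[0], self.energies_ev[-1]
        if np.any(e < lo) or np.any(e > hi):
            raise RangeError(
                f"energy query outside z̄F model range [{lo:g}, {hi:g}] eV"
            )


def zbar_curve(model: SpecificEnergyModel, nucleus: NucleusModel, energies_ev):
    """Evaluate z̄F (Gy) at the requested electron energies.

    Tabulated mode interpolates stored values linearly on log10(E);
    chord-LET mode computes min(S(E)·l̄, E)/m.
    """
    e = np.asarray(energies_ev, dtype=float)
    scalar = e.ndim == 0
    e = np.atleast_1d(e)
    if np.any(e <= 0):
        raise RangeError("energies must be positive")
    model._check_range(e)
    loge = np.log10(e)
    interp = np.interp(loge, np.log10(model.energies_ev), model.values)
    if model.mode == "tabulated":
        z = interp
    else:  # chord-LET
        eps_kev = interp * nucleus.mean_chord_um  # keV imparted over mean chord
        eps_kev = np.minimum(eps_kev, e * EV_TO_KEV)  # cap at kinetic energy
        z = eps_kev * KEV_TO_J / nucleus.mass_kg
    return float(z[0]) if scalar else z


def make_zbar_fn(model: SpecificEnergyModel, nucleus: NucleusModel):
    """Bind model and nucleus into a callable E(eV) -> z̄F(Gy)."""
    return lambda energies_ev: zbar_curve(model, nucleus, energies_ev)


def read_zbar_table(path) -> SpecificEnergyModel:
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("energy_ev", "zbar_gy"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing column {col}")
    return SpecificEnergyModel(
        mode="tabulated",
        energies_ev=df["energy_ev"].to_numpy(),
        values=df["zbar_gy"].to_numpy(),
    )


def read_let_curve(path) -> SpecificEnergyModel:
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("energy_ev", "let_kev_per_um"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing column {col}")
    return SpecificEnergyModel(
        mode="chord-LET",
        energies_ev=df["energy_ev"].to_numpy(),
        values=df["let_kev_per_um"].to_numpy(),
    )


def write_zbar_table(model: SpecificEnergyModel, path) -> None:
    col = "zbar_gy" if model.mode == "tabulated" else "let_kev_per_um"
    pd.DataFrame({"energy_ev": model.energies_ev, col: model.values}).to_csv(
        path, index=False, float_format="%.17g"
    )
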