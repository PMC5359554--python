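"""Cellular DSB damage database: storage, I/O, interpolation, synthetic generation.

The database tabulates simple and complex double-strand-break (sDSB/cDSB)
yields per cell per Gy on a rectangular (electron kinetic energy, oxygen
concentration) grid.  A simple DSB is two opposite-strand SSBs within 10 bp;
a complex DSB is a simple DSB with at least one additional nearby strand
break.  The two categories feed the fast and slow repair channels of the
two-lesion kinetic model.

Real tables are produced by external damage-simulation codes
and imported through :func:`read_yield_table`; a phenomenological generator
(:func:`generate_fixture_table`) provides self-contained tables with the
qualitative shape of such databases: yields roughly constant above 100 keV,
rising steeply below, suppressed under hypoxia, with the complex fraction
growing at low energy and low oxygen.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator

from .errors import RangeError, ValidationError

ENERGY_MIN_EV = 50.0
ENERGY_MAX_EV = 6.0e6
#: oxygen level used to stand in for strictly anoxic (0%) conditions
OXYGEN_FLOOR_PCT = 1e-3

_CSV_COLUMNS = ["energy_ev", "oxygen_pct", "sdsb_per_cell_gy", "cdsb_per_cell_gy"]


@dataclass(frozen=True)
class YieldRecord:
    """One grid node of the damage database."""

    energy_ev: float
    oxygen_pct: float
    sdsb_per_cell_gy: float
    cdsb_per_cell_gy: float

    def __post_init__(self) -> None:
        if self.energy_ev < ENERGY_MIN_EV:
            raise ValidationError(f"energy {self.energy_ev} eV below {ENERGY_MIN_EV} eV")
        if not 0.0 <= self.oxygen_pct <= 100.0:
            raise ValidationError(f"oxygen {self.oxygen_pct}% outside [0, 100]")
        if self.sdsb_per_cell_gy < 0 or self.cdsb_per_cell_gy < 0:
            raise ValidationError("yields must be non-negative")


@dataclass(frozen=True)
class YieldTable:
    """Rectangular (energy x oxygen) grid of sDSB/cDSB yields per cell per Gy.

    Interpolation is bilinear in (log10 energy, log10 oxygen); queries
    outside the grid hull raise :class:`RangeError` rather than
    extrapolating.
    """

    energies_ev: np.ndarray
    oxygens_pct: np.ndarray
    sdsb: np.ndarray  # shape (n_energy, n_oxygen)
    cdsb: np.ndarray
    provenance: str = "imported"
    nucleus_diameter_um: float = 10.0
    _interp_s: RegularGridInterpolator = field(init=False, repr=False, compare=False)
    _interp_c: RegularGridInterpolator = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        e = np.asarray(self.energies_ev, dtype=float)
        o = np.asarray(self.oxygens_pct, dtype=float)
        s = np.asarray(self.sdsb, dtype=float)
        c = np.asarray(self.cdsb, dtype=float)
        if e.ndim != 1 or o.ndim != 1:
            raise ValidationError("energy and oxygen axes must be 1-D")
        if np.any(np.diff(e) <= 0):
            raise ValidationError("energies must be strictly increasing")
        if np.any(np.diff(o) <= 0):
            raise ValidationError("oxygen levels must be strictly increasing")
        if e[0] < ENERGY_MIN_EV:
            raise ValidationError(f"energies below {ENERGY_MIN_EV} eV are not supported")
        if o[0] <= 0:
            raise ValidationError(
                f"oxygen levels must be > 0 (store anoxia as {OXYGEN_FLOOR_PCT}%)"
            )
        if s.shape != (e.size, o.size) or c.shape != (e.size, o.size):
            raise ValidationError("yield arrays must have shape (n_energy, n_oxygen)")
        if np.any(s < 0) or np.any(c < 0):
            raise ValidationError("yields must be non-negative")
        object.__setattr__(self, "energies_ev", e)
        object.__setattr__(self, "oxygens_pct", o)
        object.__setattr__(self, "sdsb", s)
        object.__setattr__(self, "cdsb", c)
        pts = (np.log10(e), np.log10(o))
        object.__setattr__(
            self, "_interp_s", RegularGridInterpolator(pts, s, bounds_error=True)
        )
        object.__setattr__(
            self, "_interp_c", RegularGridInterpolator(pts, c, bounds_error=True)
        )

    @property
    def records(self) -> list[YieldRecord]:
        out = []
        for i, e in enumerate(self.energies_ev):
            for j, o in enumerate(self.oxygens_pct):
                out.append(YieldRecord(e, o, self.sdsb[i, j], self.cdsb[i, j]))
        return out

    def interpolate(self, energy_ev, oxygen_pct):
        """Bilinear (log-log) interpolation; returns (sdsb, cdsb) per cell per Gy.

        Scalar queries return floats; array queries return arrays.
        """
        e = np.asarray(energy_ev, dtype=float)
        o = np.asarray(oxygen_pct, dtype=float)
        scalar = e.ndim == 0 and o.ndim == 0
        e, o = np.broadcast_arrays(np.atleast_1d(e), np.atleast_1d(o))
        if np.any(e <= 0) or np.any(o <= 0):
            raise RangeError("energy and oxygen queries must be positive")
        pts = np.column_stack([np.log10(e), np.log10(o)])
        try:
            s = self._interp_s(pts)
            c = self._interp_c(pts)
        except ValueError as exc:
            raise RangeError(
                f"query outside yield-table hull "
                f"(E in [{self.energies_ev[0]:g}, {self.energies_ev[-1]:g}] eV, "
                f"O2 in [{self.oxygens_pct[0]:g}, {self.oxygens_pct[-1]:g}]%): {exc}"
            ) from exc
        if scalar:
            return float(s[0]), float(c[0])
        return s, c


def interpolate_yield(table: YieldTable, energy_ev, oxygen_pct):
    """Functional wrapper over :meth:`YieldTable.interpolate`."""
    return table.interpolate(energy_ev, oxygen_pct)


def read_yield_table(path) -> YieldTable:
    """Read a damage database from CSV (columns energy_ev, oxygen_pct,
    sdsb_per_cell_gy, cdsb_per_cell_gy); the rows must form a complete
    rectangular grid."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    if df[_CSV_COLUMNS].isna().any().any():
        bad = int(df[_CSV_COLUMNS].isna().any(axis=1).idxmax())
        raise ValidationError(f"{path}: non-numeric or missing value at row {bad}")
    dup = df.duplicated(subset=["energy_ev", "oxygen_pct"])
    if dup.any():
        raise ValidationError(
            f"{path}: duplicate grid point at row {int(dup.idxmax())}"
        )
    energies = np.sort(df["energy_ev"].unique())
    oxygens = np.sort(df["oxygen_pct"].unique())
    if len(df) != energies.size * oxygens.size:
        raise ValidationError(
            f"{path}: grid not rectangular "
            f"({len(df)} rows != {energies.size} energies x {oxygens.size} oxygen levels)"
        )
    neg = (df["sdsb_per_cell_gy"] < 0) | (df["cdsb_per_cell_gy"] < 0)
    if neg.any():
        raise ValidationError(f"{path}: negative yield at row {int(neg.idxmax())}")
    piv_s = df.pivot(index="energy_ev", columns="oxygen_pct", values="sdsb_per_cell_gy")
    piv_c = df.pivot(index="energy_ev", columns="oxygen_pct", values="cdsb_per_cell_gy")
    return YieldTable(
        energies_ev=energies,
        oxygens_pct=oxygens,
        sdsb=piv_s.loc[energies, oxygens].to_numpy(),
        cdsb=piv_c.loc[energies, oxygens].to_numpy(),
        provenance="imported",
    )


def write_yield_table(table: YieldTable, path) -> None:
    """Write the database in the CSV exchange format (full float precision)."""
    ee, oo = np.meshgrid(table.energies_ev, table.oxygens_pct, indexing="ij")
    df = pd.DataFrame(
        {
            "energy_ev": ee.ravel(),
            "oxygen_pct": oo.ravel(),
            "sdsb_per_cell_gy": table.sdsb.ravel(),
            "cdsb_per_cell_gy": table.cdsb.ravel(),
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")


@dataclass(frozen=True)
class FixtureParams:
    """Shape parameters of the phenomenological yield generator.

    ``y_inf`` is the high-energy plateau of the total DSB yield (per cell per
    Gy, fully oxygenated); ``amp``/``slope`` control the low-energy rise
    below the 100 keV knee; ``m_oxygen``/``k_oxygen`` set the hypoxic
    suppression g(c) = (1 + (m-1) c/(c+K))/m, so yields fall by a factor m
    under full anoxia; the two ``cdsb_*_gain`` terms grow the complex-DSB
    share at low energy and low oxygen.  Magnitudes are conventions chosen
    to mimic published damage-database shapes, not measured values.
    """

    y_inf: float = 8.0
    sdsb_frac_high_e: float = 0.6
    amp: float = 2.5
    slope: float = 0.5
    knee_ev: float = 1.0e5
    plateau_eps: float = 0.01
    m_oxygen: float = 3.0
    k_oxygen_pct: float = 0.3
    cdsb_energy_gain: float = 0.20
    cdsb_oxygen_gain: float = 0.10

    def __post_init__(self) -> None:
        for name in ("y_inf", "amp", "slope", "knee_ev", "m_oxygen", "k_oxygen_pct"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"fixture parameter {name} must be positive")
        if not 0 < self.sdsb_frac_high_e < 1:
            raise ValidationError("sdsb_frac_high_e must lie in (0, 1)")

    def oxygen_factor(self, oxygen_pct):
        """Saturating oxygen-enhancement factor g(c); g(0)=1/m, g(100%)~1."""
        c = np.asarray(oxygen_pct, dtype=float)
        m, k = self.m_oxygen, self.k_oxygen_pct
        return (1.0 + (m - 1.0) * c / (c + k)) / m

    def total_yield(self, energy_ev, oxygen_pct):
        """Total DSB yield per cell per Gy: plateau above the knee, power-law
        rise below, scaled by the oxygen factor."""
        e = np.asarray(energy_ev, dtype=float)
        rise = np.maximum((e / self.knee_ev) ** (-self.slope) - 1.0, 0.0)
        base = self.y_inf * (1.0 + self.amp * (self.plateau_eps + rise))
        return base * self.oxygen_factor(oxygen_pct)

    def cdsb_fraction(self, energy_ev, oxygen_pct):
        e = np.asarray(energy_ev, dtype=float)
        c = np.asarray(oxygen_pct, dtype=float)
        frac = (
            (1.0 - self.sdsb_frac_high_e)
            + self.cdsb_energy_gain / (1.0 + e / self.knee_ev)
            + self.cdsb_oxygen_gain * self.k_oxygen_pct / (c + self.k_oxygen_pct)
        )
        return np.clip(frac, 0.0, 1.0)


DEFAULT_ENERGIES_EV = np.geomspace(ENERGY_MIN_EV, ENERGY_MAX_EV, 25)
DEFAULT_OXYGENS_PCT = np.array([0.001, 0.01, 0.1, 1.0, 10.0, 21.0, 100.0])


def generate_fixture_table(
    params: FixtureParams | None = None,
    energies_ev=None,
    oxygens_pct=None,
    nucleus_diameter_um: float = 10.0,
) -> YieldTable:
    """Generate a self-contained phenomenological damage database.

    Oxygen level 0 in ``oxygens_pct`` is stored as the anoxic floor
    (0.001%) so that log-axis interpolation remains defined.
    """
    params = params or FixtureParams()
    e = np.asarray(
        DEFAULT_ENERGIES_EV if energies_ev is None else energies_ev, dtype=float
    )
    o = np.asarray(
        DEFAULT_OXYGENS_PCT if oxygens_pct is None else oxygens_pct, dtype=float
    )
    o = np.where(o <= 0, OXYGEN_FLOOR_PCT, o)
    ee, oo = np.meshgrid(e, o, indexing="ij")
    total = params.total_yield(ee, oo)
    fc = params.cdsb_fraction(ee, oo)
    return YieldTable(
        energies_ev=e,
        oxygens_pct=o,
        sdsb=total * (1.0 - fc),
        cdsb=total * fc,
        provenance="fixture",
        nucleus_diameter_um=nucleus_diameter_um,
    )
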