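"""Spectrum-based damage accumulation.

Given the spectrum of electrons traversing a nucleus, the microscopic dose
is D = Σ_E Φ(E)·z̄F(E) and the accumulated lesion yields are

    Y_s = Σ_E Φ(E)·z̄F(E)·Σ_sdsb(E, c),    Y_c likewise,

where Φ(E) is the number of traversals in a spectrum bin, z̄F the
frequency-mean specific energy, and Σ the database yield per cell per Gy at
oxygen concentration c.  ``expected`` mode stores the real-valued means;
``sampled`` mode draws independent Poisson counts with those means, which is
what the per-cell stochastic survival stage consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import RangeError, ValidationError
from .yield_db import YieldTable


@dataclass(frozen=True)
class SpectrumBin:
    energy_ev: float
    count: float  # electrons traversing the nucleus; fractional allowed

    def __post_init__(self) -> None:
        if self.energy_ev <= 0:
            raise ValidationError("bin energy must be positive")
        if self.count < 0:
            raise ValidationError("bin count must be non-negative")


@dataclass(frozen=True)
class DamageState:
    """Per-nucleus initial conditions for the repair kinetics."""

    nucleus_id: int
    dose_gy: float
    l1_0: float  # initial simple-DSB count
    l2_0: float  # initial complex-DSB count
    oxygen_pct: float

    def __post_init__(self) -> None:
        if self.dose_gy < 0 or self.l1_0 < 0 or self.l2_0 < 0:
            raise ValidationError("dose and initial lesion counts must be non-negative")


def spectrum_arrays(spectrum) -> tuple[np.ndarray, np.ndarray]:
    bins = list(spectrum)
    e = np.array([b.energy_ev for b in bins], dtype=float)
    n = np.array([b.count for b in bins], dtype=float)
    return e, n


def accumulate(
    spectrum,
    zbar_fn,
    table: YieldTable,
    oxygen_pct: float,
    mode: str = "expected",
    seed: int | None = None,
    nucleus_id: int = 0,
) -> DamageState:
    """Convert a traversal spectrum into microscopic dose and lesion counts.

    ``zbar_fn`` maps energies (eV) to z̄F (Gy).  Out-of-range bin energies
    raise :class:`RangeError` identifying the bin.
    """
    if mode not in ("expected", "sampled"):
        raise ValidationError(f"unknown accumulation mode {mode!r}")
    e, n = spectrum_arrays(spectrum)
    if e.size == 0:
        return DamageState(nucleus_id, 0.0, 0.0, 0.0, oxygen_pct)
    try:
        z = np.asarray(zbar_fn(e), dtype=float)
        s_yield, c_yield = table.interpolate(e, np.full_like(e, oxygen_pct))
    except RangeError as exc:
        raise RangeError(f"spectrum bin outside model range: {exc}") from exc
    dose_terms = n * z
    dose = float(dose_terms.sum())
    y_s = float((dose_terms * s_yield).sum())
    y_c = float((dose_terms * c_yield).sum())
    if mode == "sampled":
        rng = np.random.default_rng(seed)
        y_s = float(rng.poisson(y_s))
        y_c = float(rng.poisson(y_c))
    return DamageState(nucleus_id, dose, y_s, y_c, oxygen_pct)


def rescale_to_dose(state: DamageState, target_dose_gy: float) -> DamageState:
    """Linearly rescale a damage state to a target macroscopic dose."""
    if target_dose_gy < 0:
        raise ValidationError("target dose must be non-negative")
    if state.dose_gy <= 0:
        raise ValidationError("cannot rescale a zero-dose damage state")
    f = target_dose_gy / state.dose_gy
    return replace(
        state, dose_gy=state.dose_gy * f, l1_0=state.l1_0 * f, l2_0=state.l2_0 * f
    )


@dataclass(frozen=True)
class SpectrumSummary:
    total_count: float
    mean_energy_ev: float
    fraction_below_100kev: float


def spectrum_summary(spectrum) -> SpectrumSummary:
    """Count-weighted mean energy and the low-energy (<100 keV) fraction."""
    e, n = spectrum_arrays(spectrum)
    if e.size == 0 or n.sum() <= 0:
        raise ValidationError("spectrum summary requires a nonempty spectrum")
    total = float(n.sum())
    return SpectrumSummary(
        total_count=total,
        mean_energy_ev=float((n * e).sum() / total),
        fraction_below_100kev=float(n[e < 1e5].sum() / total),
    )


def read_spectrum(path):
    """Read a radiation-pattern CSV (energy_ev, count[, nucleus_id]).

    Returns a list of bins for a shared voxel spectrum, or a dict
    nucleus_id -> list of bins when a nucleus_id column is present.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("energy_ev", "count"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing column {col}")
    if "nucleus_id" in df.columns:
        return {
            int(nid): [SpectrumBin(r.energy_ev, r.count) for r in grp.itertuples()]
            for nid, grp in df.groupby("nucleus_id")
        }
    return [SpectrumBin(r.energy_ev, r.count) for r in df.itertuples()]


def write_spectrum(spectrum, path) -> None:
    e, n = spectrum_arrays(spectrum)
    pd.DataFrame({"energy_ev": e, "count": n}).to_csv(
        path, index=False, float_format="%.17g"
    )
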