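"""Quantification math for PET-hydrolysis activity assays.

Workflow: fit linear calibration curves for the product standards (TPA,
MHET, or pNp), convert signals to concentrations, estimate initial rates
from absorbance-vs-time traces by OLS over an early window, and split a
combined A260 rate into TPA and MHET rates using the endpoint molar
ratio, assumed constant through the reaction:

    A260_rate = eps_T * tpa_rate + eps_M * mhet_rate,   tpa_rate = r * mhet_rate
    =>  mhet_rate = A260_rate / (eps_T * r + eps_M)

where ``eps_T``/``eps_M`` are the molar responses (calibration slopes)
and ``r`` the endpoint TPA:MHET molar ratio.  Units: concentrations in
µM, rates in µM/min or A260/min, enzyme in nM, NaCl in M, temperature
in °C.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

ANALYTES = ("TPA", "MHET", "pNp")

__all__ = [
    "CalibrationCurve",
    "AssayTimeSeries",
    "ProductQuant",
    "Condition",
    "fit_calibration",
    "quantify",
    "initial_rate",
    "convert_rate",
    "fold_change",
    "optimum_map",
]


@dataclass(frozen=True)
class Condition:
    """One assay condition (temperature °C, NaCl M, pH, enzyme nM)."""

    temperature: float
    nacl: float = 0.0
    pH: float = 7.0
    enzyme_nm: float = 0.0


@dataclass(frozen=True)
class CalibrationCurve:
    """OLS line relating signal to analyte concentration (µM)."""

    analyte: str
    slope: float
    intercept: float
    r2: float
    n_points: int

    def __post_init__(self) -> None:
        if self.analyte not in ANALYTES:
            raise ValueError(f"analyte must be one of {ANALYTES}")
        if self.n_points < 2:
            raise ValueError("calibration needs >= 2 points")
        if self.slope <= 0:
            raise ValueError("calibration slope must be positive")

    def predict(self, concentration: float) -> float:
        return self.slope * concentration + self.intercept


@dataclass(frozen=True)
class AssayTimeSeries:
    """Absorbance trace (A260 or A405) for one condition."""

    condition: Condition
    times: tuple[float, ...]  # minutes
    signal: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.times) != len(self.signal):
            raise ValueError("times and signal differ in length")
        if any(b <= a for a, b in zip(self.times, self.times[1:])):
            raise ValueError("times must be strictly increasing")


@dataclass(frozen=True)
class ProductQuant:
    """Calibrated product amounts (µM) at one condition."""

    condition: Condition
    mhet: float
    tpa: float
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.mhet < 0 or self.tpa < 0:
            raise ValueError("concentrations must be >= 0")

    @property
    def total(self) -> float:
        return self.mhet + self.tpa

    @property
    def ratio_tpa_mhet(self) -> float:
        if self.mhet <= 0:
            return float("nan")
        return self.tpa / self.mhet


def fit_calibration(
    standards: Sequence[tuple[float, float]], analyte: str = "TPA"
) -> CalibrationCurve:
    """Ordinary least squares line through (concentration, signal) standards."""
    if len(standards) < 2:
        raise ValueError("need >= 2 standards")
    conc = np.array([c for c, _ in standards], dtype=float)
    sig = np.array([s for _, s in standards], dtype=float)
    if np.ptp(conc) == 0:
        raise ValueError("standards have zero concentration variance")
    res = stats.linregress(conc, sig)
    return CalibrationCurve(
        analyte=analyte,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        n_points=len(standards),
    )


def quantify(signal: float, curve: CalibrationCurve) -> tuple[float, bool]:
    """Invert the calibration; negative values floored at 0 and flagged."""
    conc = (signal - curve.intercept) / curve.slope
    if conc < 0:
        return 0.0, True
    return float(conc), False


def initial_rate(
    series: AssayTimeSeries, window: float | None = None
) -> tuple[float, float]:
    """OLS slope (signal/min) of the initial linear phase and its r².

    ``window`` is a time cutoff in minutes; by default the first 25% of
    time points are used.  Gross outliers are not removed — the reported
    r² lets the caller judge the fit.
    """
    times = np.asarray(series.times)
    sig = np.asarray(series.signal)
    if window is None:
        k = max(3, int(np.ceil(len(times) * 0.25)))
        times, sig = times[:k], sig[:k]
    else:
        mask = times <= window
        times, sig = times[mask], sig[mask]
    if len(times) < 3:
        raise ValueError("initial-rate window must contain >= 3 points")
    if np.ptp(sig) == 0:
        return 0.0, 1.0
    res = stats.linregress(times, sig)
    return float(res.slope), float(res.rvalue**2)


def convert_rate(
    a260_rate: float,
    endpoint_ratio: float,
    tpa_curve: CalibrationCurve,
    mhet_curve: CalibrationCurve,
) -> tuple[float, float]:
    """Split a combined A260 rate into (tpa_rate, mhet_rate) in µM/min.

    Uses the constant endpoint TPA:MHET molar ratio ``r``; the identity
    ``eps_T * tpa_rate + eps_M * mhet_rate == a260_rate`` holds exactly.
    ``r = 0`` assigns the whole signal to MHET.
    """
    if endpoint_ratio < 0:
        raise ValueError("endpoint ratio must be >= 0")
    eps_t, eps_m = tpa_curve.slope, mhet_curve.slope
    mhet_rate = a260_rate / (eps_t * endpoint_ratio + eps_m)
    tpa_rate = endpoint_ratio * mhet_rate
    return float(tpa_rate), float(mhet_rate)


def fold_change(test: float, reference: float) -> tuple[float, bool]:
    """test/reference; a zero reference yields (nan, flagged)."""
    if reference < 0 or test < 0:
        raise ValueError("quantities must be >= 0")
    if reference == 0:
        return float("nan"), True
    return test / reference, False


def optimum_map(grid: Mapping[Condition, float]) -> tuple[Condition, pd.DataFrame]:
    """Argmax condition of a condition -> quantity grid, plus the full table.

    NaN cells are excluded with a warning.  Ties break deterministically
    toward the lowest temperature, then lowest NaCl, then lowest pH.
    """
    if not grid:
        raise ValueError("empty condition grid")
    rows = [
        {
            "temperature_C": c.temperature,
            "nacl_M": c.nacl,
            "pH": c.pH,
            "enzyme_nM": c.enzyme_nm,
            "quantity": q,
        }
        for c, q in grid.items()
    ]
    table = pd.DataFrame(rows).sort_values(
        ["temperature_C", "nacl_M", "pH", "enzyme_nM"], ignore_index=True
    )
    valid = {c: q for c, q in grid.items() if not np.isnan(q)}
    if len(valid) < len(grid):
        warnings.warn(f"{len(grid) - len(valid)} NaN cells excluded from optimum search")
    if not valid:
        raise ValueError("all cells are NaN")
    best_q = max(valid.values())
    ties = [c for c, q in valid.items() if q == best_q]
    ties.sort(key=lambda c: (c.temperature, c.nacl, c.pH, c.enzyme_nm))
    return ties[0], table
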