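"""Luminescence-based secretion flux: calibration, rates, pool turnover,
compartment partitioning, and the flow-vs-static washout model.

A nanoluciferase tag on procollagen makes the secreted amount in the
culture medium luminometrically countable: a recombinant-standard curve
maps RLU to moles, the accumulation slope gives the secretion rate (per
cell, via Avogadro's number), and a single well-mixed compartment (CSTR)
model predicts how constant medium flow depletes the extracellular pool
relative to static culture.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "AVOGADRO",
    "CalibrationCurve",
    "SecretionEstimate",
    "FlowConfig",
    "FlowModelResult",
    "CompartmentPartition",
    "calibrate_nluc",
    "secretion_rate",
    "pool_turnover_time",
    "flow_reduction_model",
    "partition_fractions",
]

AVOGADRO = 6.02214076e23


@dataclass
class CalibrationCurve:
    """Linear RLU-vs-amount standard curve (slope in RLU per mol)."""

    slope: float
    intercept: float
    residual_sd: float
    n_standards: int

    def rlu_to_mol(self, rlu) -> np.ndarray | float:
        return (np.asarray(rlu, dtype=float) - self.intercept) / self.slope

    def mol_to_rlu(self, mol) -> np.ndarray | float:
        return self.slope * np.asarray(mol, dtype=float) + self.intercept


@dataclass
class SecretionEstimate:
    rate_molecules_per_cell_h: float
    rate_mol_per_h: float
    n_cells: int
    window_h: tuple[float, float]
    r_squared: float


@dataclass(frozen=True)
class FlowConfig:
    """Bioreactor geometry: medium volume V (mL), flow Q, duration."""

    volume_mL: float
    flow_mL_per_min: float
    duration_h: float

    def __post_init__(self) -> None:
        if self.volume_mL <= 0:
            raise ValueError("volume_mL must be positive")
        if self.flow_mL_per_min < 0:
            raise ValueError("flow must be >= 0")

    @property
    def flow_mL_per_h(self) -> float:
        return self.flow_mL_per_min * 60.0


@dataclass
class FlowModelResult:
    time_h: np.ndarray
    static_conc: np.ndarray  # mol/mL under no flow
    flow_conc: np.ndarray  # mol/mL under constant flow
    steady_state_conc: float
    percent_reduction: np.ndarray
    note: str = ""


@dataclass
class CompartmentPartition:
    medium_rlu: float
    cellular_rlu: float
    matrix_rlu: float
    medium_fraction: float
    cellular_fraction: float
    matrix_fraction: float


def calibrate_nluc(standards) -> CalibrationCurve:
    """Least-squares line through (mol, RLU) recombinant standards.

    Needs at least three standards spanning a >= 10-fold amount range.  A
    non-positive slope indicates saturated or invalid standards and raises.
    """
    arr = np.asarray(standards, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValueError("need >= 3 (mol, RLU) standards")
    mol, rlu = arr[:, 0], arr[:, 1]
    positive = mol[mol > 0]
    if len(positive) and positive.max() / positive.min() < 10:
        raise ValueError("standards must span at least a 10-fold range")
    slope, intercept = np.polyfit(mol, rlu, 1)
    if slope <= 0:
        raise ValueError("non-positive calibration slope: saturated or invalid standards")
    resid = rlu - (slope * mol + intercept)
    sd = float(resid.std(ddof=2)) if len(mol) > 2 else 0.0
    return CalibrationCurve(float(slope), float(intercept), sd, len(mol))


def _largest_linear_window(t: np.ndarray, y: np.ndarray, min_r2: float) -> slice:
    """Largest window starting at t[0] whose linear fit has R^2 >= min_r2."""
    best = slice(0, 3)
    for end in range(3, len(t) + 1):
        tt, yy = t[:end], y[:end]
        slope, intercept = np.polyfit(tt, yy, 1)
        pred = slope * tt + intercept
        ss_res = float(((yy - pred) ** 2).sum())
        ss_tot = float(((yy - yy.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        if r2 >= min_r2:
            best = slice(0, end)
    return best


def secretion_rate(
    series: pd.DataFrame,
    calibration: CalibrationCurve,
    n_cells: int,
    volume_mL: float,
    min_r2: float = 0.99,
) -> SecretionEstimate:
    """Secretion rate from a static-culture luminescence accumulation series.

    RLU is converted to a medium concentration via the calibration inverse
    (mol per mL of assayed medium), scaled by ``volume_mL`` to total moles,
    and the slope of mol(t) taken over the largest initial window whose
    linear fit reaches R^2 >= ``min_r2``.  The per-cell molecular rate uses
    Avogadro's number.
    """
    t = series["time_h"].to_numpy(dtype=float)
    rlu = series["RLU"].to_numpy(dtype=float)
    if len(t) < 3:
        raise ValueError("need >= 3 timepoints")
    order = np.argsort(t)
    t, rlu = t[order], rlu[order]
    mol = np.asarray(calibration.rlu_to_mol(rlu)) * volume_mL

    win = _largest_linear_window(t, mol, min_r2)
    tt, mm = t[win], mol[win]
    slope, intercept = np.polyfit(tt, mm, 1)
    if slope < 0:
        # distinguish genuine decline from float noise on a flat series
        scale = max(np.abs(mm).max(), 1e-300)
        if abs(slope) * (tt[-1] - tt[0]) > 1e-9 * scale:
            raise ValueError(
                "negative accumulation slope: declining signal, wrong assay window"
            )
        slope = 0.0
    pred = slope * tt + intercept
    ss_tot = float(((mm - mm.mean()) ** 2).sum())
    r2 = 1.0 - float(((mm - pred) ** 2).sum()) / ss_tot if ss_tot > 0 else 1.0
    return SecretionEstimate(
        rate_molecules_per_cell_h=slope * AVOGADRO / n_cells,
        rate_mol_per_h=float(slope),
        n_cells=n_cells,
        window_h=(float(tt[0]), float(tt[-1])),
        r_squared=r2,
    )


def pool_turnover_time(
    intracellular_molecules: float, rate_molecules_per_cell_h: float
) -> float:
    """Hours to secrete the entire intracellular pool at the given rate."""
    if rate_molecules_per_cell_h <= 0:
        raise ValueError("rate must be positive")
    if intracellular_molecules < 0:
        raise ValueError("pool size must be non-negative")
    return intracellular_molecules / rate_molecules_per_cell_h


def flow_reduction_model(
    rate_mol_per_h: float, flowcfg: FlowConfig, n_times: int = 145
) -> FlowModelResult:
    """CSTR washout model of the perfused bioreactor.

    Static: C_s(t) = r t / V.  Constant flow Q: dC/dt = r/V - (Q/V) C so
    C_f(t) = (r/Q)(1 - exp(-Q t / V)) with steady state r/Q.  The percent
    reduction 100 (1 - C_f/C_s) starts at 0 and increases monotonically in
    both t and Q.  With Q = 0 the flow curve degenerates to the static one
    (noted in the result).
    """
    t = np.linspace(0.0, flowcfg.duration_h, n_times)
    v = flowcfg.volume_mL
    static = rate_mol_per_h * t / v
    q = flowcfg.flow_mL_per_h
    if q == 0:
        return FlowModelResult(
            t, static, static.copy(), math.inf, np.zeros_like(t),
            note="Q = 0: flow model degenerates to static accumulation",
        )
    tau = v / q
    flow = (rate_mol_per_h / q) * (1.0 - np.exp(-t / tau))
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(static > 0, flow / static, 1.0)
    return FlowModelResult(
        t, static, flow, rate_mol_per_h / q, 100.0 * (1.0 - ratio)
    )


def partition_fractions(
    medium_rlu: float, cellular_rlu: float, matrix_rlu: float
) -> CompartmentPartition:
    """Fractional distribution of reporter activity across compartments."""
    vals = (medium_rlu, cellular_rlu, matrix_rlu)
    if any(v < 0 for v in vals):
        raise ValueError("activities must be non-negative")
    total = sum(vals)
    if total == 0:
        raise ValueError("all compartment activities are zero")
    m, c, x = (v / total for v in vals)
    return CompartmentPartition(*vals, m, c, x)
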