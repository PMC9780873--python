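"""Hepatocyte and dialysis assay analysis.

Turns raw in vitro time courses into the kinetic parameters that feed
in vitro–in vivo extrapolation:

* substrate-depletion (metabolic stability) time courses in hepatocyte
  suspension -> in vitro intrinsic metabolic clearance ``CL_int,met,vitro``;
* oil-spin uptake time courses analysed by the integration plot
  -> initial uptake clearance ``PS_inf,hep`` and initial distribution
  volume ``V_0``;
* a 37 °C / 4 °C temperature split of the uptake slope -> active vs
  passive components;
* rapid-equilibrium-dialysis donor/receiver pairs -> fractions unbound
  (``f_u,p``, ``f_u,inc,hepa``);
* cell-to-buffer partitioning on ice -> intracellular fraction unbound
  ``f_u,hepa`` and the temperature-method unbound partition coefficient
  ``Kp_uu,ss``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DepletionDataset",
    "UptakeDataset",
    "DialysisPair",
    "CellPartitionMeasurement",
    "InVitroParams",
    "DepletionFit",
    "IntegrationPlotFit",
    "UptakeSplit",
    "fit_depletion",
    "fit_integration_plot",
    "split_active_passive",
    "fu_from_dialysis",
    "fu_hepa_from_partition",
    "kpuu_ss",
    "read_assay_csv",
]

#: Default rat hepatocyte volume, µL per 10^6 cells.
DEFAULT_V_CELL = 3.68

_ASSAY_UNIT_WHITELIST = {
    "depletion": {"ratio"},
    "uptake_xhep": {"pmol/1e6cells"},
    "uptake_cbuff": {"uM"},
    "dialysis": {"uM"},
}


class AssayInputError(ValueError):
    """Raised when an assay dataset violates its structural preconditions."""


@dataclass(frozen=True)
class DepletionDataset:
    """Parent-drug depletion time course in hepatocyte suspension.

    ``response`` is the parent peak-area ratio relative to t=0
    (dimensionless); ``cell_density`` is in 10^6 cells/mL.
    """

    time_min: np.ndarray
    response: np.ndarray
    cell_density: float = 1.0
    group: str = "control"

    def __post_init__(self):
        t = np.asarray(self.time_min, dtype=float)
        r = np.asarray(self.response, dtype=float)
        object.__setattr__(self, "time_min", t)
        object.__setattr__(self, "response", r)
        if t.size < 3:
            raise AssayInputError("depletion profile needs at least 3 time points")
        if t.size != r.size:
            raise AssayInputError("time and response lengths differ")
        if np.any(t < 0) or np.any(np.diff(t) <= 0):
            raise AssayInputError("times must be non-negative and strictly increasing")
        if self.cell_density <= 0:
            raise AssayInputError("cell density must be positive")


@dataclass(frozen=True)
class UptakeDataset:
    """Oil-spin hepatocyte uptake time course.

    ``x_hep`` is the cell-associated amount (pmol per 10^6 cells) and
    ``c_buff`` the buffer concentration (µM) at each sampling time (s).
    ``c0_nominal`` is the nominal starting buffer concentration used as
    the t=0 anchor of the buffer AUC.
    """

    time_s: np.ndarray
    x_hep: np.ndarray
    c_buff: np.ndarray
    temperature_c: float
    cell_density: float = 0.5
    c0_nominal: float = 1.0

    def __post_init__(self):
        t = np.asarray(self.time_s, dtype=float)
        x = np.asarray(self.x_hep, dtype=float)
        c = np.asarray(self.c_buff, dtype=float)
        for name, arr in (("time_s", t), ("x_hep", x), ("c_buff", c)):
            object.__setattr__(self, name, arr)
        if not (t.size == x.size == c.size):
            raise AssayInputError("uptake arrays must have equal length")
        if t.size < 3:
            raise AssayInputError("uptake profile needs at least 3 time points")
        if np.any(np.diff(t) <= 0) or np.any(t <= 0):
            raise AssayInputError("sampling times must be positive and increasing")
        if np.any(x <= 0) or np.any(c <= 0):
            raise AssayInputError("amounts and concentrations must be positive")
        if self.temperature_c not in (4.0, 37.0, 4, 37):
            raise AssayInputError("uptake assay temperature must be 4 or 37 °C")


@dataclass(frozen=True)
class DialysisPair:
    """Equilibrium-dialysis donor/receiver concentration pair (µM)."""

    c_donor: float
    c_receiver: float
    matrix: str = "plasma"

    def __post_init__(self):
        if self.c_donor <= 0 or self.c_receiver <= 0:
            raise AssayInputError("dialysis concentrations must be positive")
        if self.c_receiver > self.c_donor:
            raise AssayInputError(
                "receiver concentration exceeds donor: equilibrium violated"
            )


@dataclass(frozen=True)
class CellPartitionMeasurement:
    """Hepatocyte/buffer partitioning on ice (active transport abolished)."""

    a_cell: float  # pmol per 10^6 cells
    c_buffer: float  # µM
    v_cell: float = DEFAULT_V_CELL  # µL per 10^6 cells
    temperature_c: float = 4.0

    def __post_init__(self):
        if min(self.a_cell, self.c_buffer, self.v_cell) <= 0:
            raise AssayInputError("partition measurement values must be positive")


@dataclass
class InVitroParams:
    """Collected in vitro kinetic parameters for one treatment group."""

    clint_met_vitro: float  # µL/min per 10^6 cells
    ps_inf_hep: float  # µL/min per 10^6 cells (37 °C slope)
    ps_passive_hep: float  # µL/min per 10^6 cells (4 °C slope)
    fu_p: float
    fu_inc_hepa: float
    fu_hepa: float
    v0: float = 0.0  # µL per 10^6 cells
    kp_37: float | None = None
    kp_4: float | None = None
    kpuu_ss: float | None = field(default=None)

    def __post_init__(self):
        for name in ("fu_p", "fu_inc_hepa", "fu_hepa"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise AssayInputError(f"{name}={v} outside (0, 1]")
        for name in ("clint_met_vitro", "ps_inf_hep", "ps_passive_hep"):
            if getattr(self, name) < 0:
                raise AssayInputError(f"{name} must be non-negative")
        if self.kpuu_ss is None and self.kp_37 is not None and self.kp_4 is not None:
            self.kpuu_ss = kpuu_ss(self.kp_37, self.kp_4)


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DepletionFit:
    k_dep: float  # 1/min
    t_half: float  # min (inf if stable)
    clint_met_vitro: float  # µL/min per 10^6 cells
    stable: bool  # True when no depletion was detected
    r_squared: float


def fit_depletion(data: DepletionDataset) -> DepletionFit:
    """Monophasic log-linear fit of a substrate-depletion time course.

    The depletion rate constant is the negated slope of an ordinary
    least-squares fit of ln(response) against time; the in vitro intrinsic
    metabolic clearance follows as k · (incubation volume per 10^6 cells)
    = k · 1000/cell_density.  A non-positive depletion slope is reported
    as a flagged stable result (clearance 0), not an error.
    """
    if np.any(data.response <= 0):
        raise AssayInputError("all responses must be positive for the log-linear fit")
    fit = stats.linregress(data.time_min, np.log(data.response))
    k = -fit.slope
    r2 = float(fit.rvalue**2) if np.isfinite(fit.rvalue) else 1.0
    if k <= 0:
        return DepletionFit(0.0, np.inf, 0.0, stable=True, r_squared=r2)
    clint = k * 1000.0 / data.cell_density
    return DepletionFit(float(k), float(np.log(2) / k), float(clint), False, r2)


@dataclass(frozen=True)
class IntegrationPlotFit:
    slope: float  # µL/min per 10^6 cells
    v0: float  # µL per 10^6 cells
    r_squared: float
    temperature_c: float


def _buffer_auc(data: UptakeDataset) -> np.ndarray:
    """Trapezoidal AUC of the buffer concentration, anchored at t=0.

    The t=0 concentration is the nominal dose concentration: the assay
    defines the start concentration and no sample is drawn at t=0.
    Returned in µM·s at each sampling time.
    """
    t = np.concatenate(([0.0], data.time_s))
    c = np.concatenate(([data.c0_nominal], data.c_buff))
    incr = np.diff(t) * (c[:-1] + c[1:]) / 2.0
    return np.cumsum(incr)


def fit_integration_plot(
    data: UptakeDataset, max_time_s: float | None = None
) -> IntegrationPlotFit:
    """Integration-plot regression for the initial uptake clearance.

    Regresses X_hep(t)/C_buff(t) on AUC_buff(0..t)/C_buff(t) by ordinary
    least squares; the slope is the uptake clearance PS_inf,hep (converted
    from per-second sampling to µL/min per 10^6 cells) and the intercept
    is the initial distribution volume V_0.  An optional ``max_time_s``
    restricts the fit to the early linear window.
    """
    mask = np.ones(data.time_s.size, dtype=bool)
    if max_time_s is not None:
        mask = data.time_s <= max_time_s
    if mask.sum() < 3:
        raise AssayInputError("integration plot needs at least 3 points in window")
    auc = _buffer_auc(data)[mask]
    if np.any(np.diff(auc) <= 0):
        raise AssayInputError("buffer AUC must be strictly increasing")
    x = auc / data.c_buff[mask]  # s
    y = data.x_hep[mask] / data.c_buff[mask]  # µL per 10^6 cells
    if np.ptp(x) == 0:
        raise AssayInputError("degenerate integration plot: constant covariate")
    fit = stats.linregress(x, y)
    slope = float(fit.slope) * 60.0  # µL/s -> µL/min
    v0 = float(fit.intercept)
    if v0 < 0:
        warnings.warn(
            f"negative initial distribution volume V0={v0:.3g} µL/10^6 cells "
            "from the integration plot; check the linear window",
            stacklevel=2,
        )
    r2 = float(fit.rvalue**2) if np.isfinite(fit.rvalue) else 1.0
    return IntegrationPlotFit(slope, v0, r2, float(data.temperature_c))


@dataclass(frozen=True)
class UptakeSplit:
    ps_act_vitro: float  # µL/min per 10^6 cells
    ps_diff_vitro: float  # µL/min per 10^6 cells
    clamped: bool  # True when slope_4 > slope_37 forced the active part to 0


def split_active_passive(slope_37: float, slope_4: float) -> UptakeSplit:
    """Temperature split of the uptake slope into active and passive parts.

    The 4 °C slope is the passive (diffusional) component; the active
    component is the 37 °C excess, clamped at zero (physical
    non-negativity) with the clamping recorded on the result.
    """
    if slope_37 < 0 or slope_4 < 0:
        raise AssayInputError("uptake slopes must be non-negative")
    active = slope_37 - slope_4
    clamped = active < 0
    if clamped:
        warnings.warn(
            "4 °C uptake slope exceeds the 37 °C slope; active uptake clamped to 0",
            stacklevel=2,
        )
    return UptakeSplit(max(active, 0.0), slope_4, clamped)


def fu_from_dialysis(pair: DialysisPair) -> float:
    """Fraction unbound from an equilibrium-dialysis pair: receiver/donor."""
    return pair.c_receiver / pair.c_donor


def fu_hepa_from_partition(m: CellPartitionMeasurement) -> float:
    """Intracellular fraction unbound from on-ice cell/buffer partitioning.

    f_u,hepa = 1 / (A_cell / (V_cell · C_buffer)), i.e. the reciprocal of
    the cell-to-medium concentration ratio with passive equilibrium only.
    Values above 1 (cell amount below the aqueous equilibrium amount) are
    clamped to 1 with a warning.
    """
    fu = m.v_cell * m.c_buffer / m.a_cell
    if fu > 1:
        warnings.warn(
            f"apparent f_u,hepa={fu:.3g} > 1 clamped to 1 "
            "(cell amount below aqueous equilibrium)",
            stacklevel=2,
        )
        return 1.0
    return fu


def kpuu_ss(kp_37: float, kp_4: float) -> float:
    """Unbound steady-state partition coefficient by the temperature method.

    Kp_uu,ss = Kp(37 °C)/Kp(4 °C): intracellular binding cancels between
    the two temperatures, leaving the active-transport contribution.
    """
    if kp_4 <= 0:
        raise AssayInputError("Kp at 4 °C must be positive")
    return kp_37 / kp_4


# ---------------------------------------------------------------------------
# CSV input
# ---------------------------------------------------------------------------

_REQUIRED_COLS = {"assay_type", "group", "temperature_c", "time", "value", "unit"}


def read_assay_csv(path: str | Path) -> pd.DataFrame:
    """Read the tidy assay CSV (one row per replicate × time point).

    Columns: assay_type, group, temperature_c, time, value, unit.  Units
    are validated against a fixed whitelist per assay type.
    """
    df = pd.read_csv(path)
    missing = _REQUIRED_COLS - set(df.columns)
    if missing:
        raise AssayInputError(f"assay CSV missing columns: {sorted(missing)}")
    for assay, sub in df.groupby("assay_type"):
        allowed = _ASSAY_UNIT_WHITELIST.get(str(assay))
        if allowed is None:
            raise AssayInputError(f"unknown assay_type {assay!r}")
        bad = set(sub["unit"].unique()) - allowed
        if bad:
            raise AssayInputError(
                f"assay {assay!r}: units {sorted(bad)} not in whitelist {sorted(allowed)}"
            )
    return df
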