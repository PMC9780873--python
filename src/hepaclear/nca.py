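"""Non-compartmental analysis of IV-bolus concentration–time data.

Linear-trapezoid AUC/AUMC with log-linear terminal-slope extrapolation,
systemic clearance and steady-state distribution volume, excretion
(biliary/renal) clearances from cumulative amounts, tissue-to-plasma
partition coefficients with residual-blood correction, and the
blood-to-plasma concentration ratio.

Conventions follow common NCA software defaults: linear trapezoid
(a log-down variant is available behind a flag), terminal slope fitted
by ordinary least squares on log concentrations over the candidate
terminal window (≥3 points, C_max excluded) with the best adjusted R²,
ties resolved toward the longer window.  Below-quantification values
are dropped before analysis, not zero-imputed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ConcentrationTimeProfile",
    "CumulativeExcretion",
    "NcaResult",
    "auc_trapezoid",
    "iv_bolus_params",
    "excretion_clearance",
    "tissue_kp",
    "blood_plasma_ratio",
]


class ProfileInputError(ValueError):
    """Raised when a concentration–time input violates its preconditions."""


@dataclass(frozen=True)
class ConcentrationTimeProfile:
    """One subject's concentration–time series in one matrix.

    times in h; concentrations in the declared unit (µg/mL by default);
    dose in mg/kg.
    """

    times: np.ndarray
    concentrations: np.ndarray
    dose: float
    subject_id: str = "subject"
    group: str = "control"
    matrix: str = "plasma"
    route: str = "iv"
    concentration_unit: str = "ug/mL"

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.concentrations, dtype=float)
        # drop BLOQ/missing values rather than zero-impute
        keep = np.isfinite(c) & (c > 0)
        object.__setattr__(self, "times", t[keep])
        object.__setattr__(self, "concentrations", c[keep])
        if self.times.size < 2:
            raise ProfileInputError("profile needs at least 2 quantifiable points")
        if np.any(np.diff(self.times) <= 0) or self.times[0] < 0:
            raise ProfileInputError("times must start >= 0 and strictly increase")
        if self.dose <= 0:
            raise ProfileInputError("dose must be positive")


@dataclass(frozen=True)
class CumulativeExcretion:
    """Cumulative amount excreted (µg per kg body weight) into bile or urine."""

    times: np.ndarray
    cumulative_amount: np.ndarray
    matrix: str = "bile"

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        a = np.asarray(self.cumulative_amount, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "cumulative_amount", a)
        if np.any(np.diff(a) < 0):
            raise ProfileInputError("cumulative excreted amount must be non-decreasing")


@dataclass(frozen=True)
class AucResult:
    auc_0_last: float
    auc_0_inf: float | None
    lambda_z: float | None
    lambda_z_points: int
    lambda_z_adj_r2: float | None


@dataclass(frozen=True)
class NcaResult:
    auc_0_last: float
    auc_0_inf: float | None
    lambda_z: float | None
    mrt: float | None  # h
    cl: float | None  # (dose unit)/(AUC unit), mL/h/kg for mg/kg & µg/mL
    vdss: float | None  # mL/kg
    clb: float | None = None
    clr: float | None = None


def _trapz_cum(t: np.ndarray, c: np.ndarray, log_down: bool) -> float:
    """Trapezoidal AUC over the observed points."""
    dt = np.diff(t)
    c0, c1 = c[:-1], c[1:]
    seg = dt * (c0 + c1) / 2.0
    if log_down:
        down = (c1 < c0) & (c1 > 0)
        with np.errstate(divide="ignore", invalid="ignore"):
            logseg = dt * (c0 - c1) / np.log(c0 / c1)
        seg = np.where(down, logseg, seg)
    return float(seg.sum())


def _lambda_z(t: np.ndarray, c: np.ndarray) -> tuple[float, int, float] | None:
    """Terminal slope by best-adjusted-R² window of >=3 points, C_max excluded."""
    imax = int(np.argmax(c))
    cand_start = range(imax + 1, t.size - 2)
    best = None
    for s in cand_start:
        n = t.size - s
        if n < 3:
            continue
        fit = stats.linregress(t[s:], np.log(c[s:]))
        if fit.slope >= 0:
            continue
        r2 = fit.rvalue**2
        adj = 1 - (1 - r2) * (n - 1) / (n - 2)
        # ties (within float fuzz) go to the longer window, i.e. earlier start
        if best is None or adj > best[0] + 1e-12:
            best = (adj, -fit.slope, n)
    if best is None:
        return None
    adj, lz, n = best
    return float(lz), int(n), float(adj)


def auc_trapezoid(
    profile: ConcentrationTimeProfile,
    extrapolate: bool = True,
    log_down: bool = False,
) -> AucResult:
    """AUC to the last observation and, optionally, extrapolated to infinity.

    The extrapolated tail is C_last/λz with λz from the terminal
    log-linear fit; when λz is not estimable the infinite AUC is
    reported as missing with a warning.
    """
    t, c = profile.times, profile.concentrations
    auc_last = _trapz_cum(t, c, log_down)
    if not extrapolate:
        return AucResult(auc_last, None, None, 0, None)
    lz = _lambda_z(t, c)
    if lz is None:
        warnings.warn(
            "terminal slope not estimable; AUC(0-inf) reported as missing",
            stacklevel=2,
        )
        return AucResult(auc_last, None, None, 0, None)
    lambda_z, npts, adj = lz
    auc_inf = auc_last + c[-1] / lambda_z
    return AucResult(auc_last, auc_inf, lambda_z, npts, adj)


def iv_bolus_params(
    profile: ConcentrationTimeProfile,
    auc: AucResult | None = None,
    log_down: bool = False,
) -> NcaResult:
    """Systemic clearance and distribution volume after an IV bolus.

    CL = dose/AUC(0-inf); MRT = AUMC(0-inf)/AUC(0-inf); Vd_ss = CL × MRT.
    The AUMC tail beyond the last observation is
    t_last·C_last/λz + C_last/λz².  With dose in mg/kg and concentrations
    in µg/mL (= mg/L), CL comes out in L/h/kg and is reported in mL/h/kg.
    """
    if profile.route != "iv":
        raise ProfileInputError("iv_bolus_params requires an IV profile")
    if auc is None:
        auc = auc_trapezoid(profile, log_down=log_down)
    if auc.auc_0_inf is None or auc.lambda_z is None:
        return NcaResult(auc.auc_0_last, None, None, None, None, None)
    t, c = profile.times, profile.concentrations
    aumc_last = _trapz_cum(t, t * c, log_down=False)
    lam = auc.lambda_z
    aumc_inf = aumc_last + t[-1] * c[-1] / lam + c[-1] / lam**2
    cl = profile.dose / auc.auc_0_inf * 1000.0  # mg/kg / (mg/L) -> L/kg -> mL/kg, per h
    mrt = aumc_inf / auc.auc_0_inf
    vdss = cl * mrt
    return NcaResult(auc.auc_0_last, auc.auc_0_inf, lam, mrt, cl, vdss)


def excretion_clearance(
    excretion: CumulativeExcretion, auc_0_t_plasma: float
) -> float:
    """Excretion clearance over a window: amount excreted / matched plasma AUC.

    With the cumulative amount in µg/kg and the plasma AUC in µg·h/mL
    over the same window, the clearance comes out in mL/h per kg.
    """
    if auc_0_t_plasma <= 0:
        raise ProfileInputError("plasma AUC over the excretion window must be positive")
    return float(excretion.cumulative_amount[-1]) / auc_0_t_plasma


def tissue_kp(
    c_tissue: float,
    c_plasma: float,
    c_blood: float = 0.0,
    vascular_fraction: float = 0.0,
) -> float:
    """Tissue-to-plasma partition coefficient with residual-blood correction.

    Kp = (C_tissue − f_v·C_blood) / ((1 − f_v)·C_plasma) where f_v is the
    residual vascular volume fraction of the tissue; with f_v = 0 this is
    the plain tissue/plasma ratio.  A negative corrected tissue
    concentration (all signal attributable to residual blood) is clamped
    to zero with a warning.
    """
    if not (0 <= vascular_fraction < 1):
        raise ProfileInputError("vascular_fraction must lie in [0, 1)")
    if c_plasma <= 0:
        raise ProfileInputError("plasma concentration must be positive")
    num = c_tissue - vascular_fraction * c_blood
    if num < 0:
        warnings.warn(
            "residual-blood correction exceeds tissue concentration; Kp clamped to 0",
            stacklevel=2,
        )
        num = 0.0
    return num / ((1.0 - vascular_fraction) * c_plasma)


def blood_plasma_ratio(
    c_blood_spiked: float | Sequence[float],
    c_plasma_after_spin: float | Sequence[float],
) -> tuple[float, float]:
    """Blood-to-plasma ratio R_b from spiked whole blood.

    Accepts scalars or replicate sequences (element-wise ratios);
    returns (mean, SD) across replicates (SD 0 for a single value).
    """
    b = np.atleast_1d(np.asarray(c_blood_spiked, dtype=float))
    p = np.atleast_1d(np.asarray(c_plasma_after_spin, dtype=float))
    if b.shape != p.shape:
        raise ProfileInputError("replicate arrays must have matching shapes")
    if np.any(b <= 0) or np.any(p <= 0):
        raise ProfileInputError("concentrations must be positive")
    r = b / p
    return float(r.mean()), float(r.std(ddof=1)) if r.size > 1 else 0.0
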