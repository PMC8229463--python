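"""Non-compartmental analysis of concentration–time curves.

Exposure metrics (Cmax, Tmax, AUC_last) use the linear trapezoidal rule.
Moment analysis estimates the terminal slope λz by log-linear regression on
the tail, extrapolates AUC and AUMC to infinity, and derives MRT and the
moment-based steady-state volume of distribution V_SS = Dose·AUMC/AUC²
(meaningful for intravenous profiles).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np


@dataclass
class NCAResult:
    cmax: float
    tmax_min: float
    auc_last: float  # ng·min/mL
    auc_inf: Optional[float] = None
    aumc_inf: Optional[float] = None
    mrt_min: Optional[float] = None
    lambda_z_per_min: Optional[float] = None
    vss_moment_ml: Optional[float] = None
    window_min: tuple[float, float] = (0.0, 0.0)


def _window(
    times: np.ndarray, conc: np.ndarray, t0: float, t_last: float
) -> tuple[np.ndarray, np.ndarray]:
    mask = (times >= t0 - 1e-9) & (times <= t_last + 1e-9)
    if mask.sum() < 2:
        raise ValueError(f"fewer than 2 points in window [{t0}, {t_last}]")
    return times[mask], conc[mask]


def auc_trapezoid(
    times_min: Sequence[float],
    conc_ng_ml: Sequence[float],
    t0: float = 0.0,
    t_last: Optional[float] = None,
) -> float:
    """Linear trapezoidal AUC (ng·min/mL) over [t0, t_last]."""
    times = np.asarray(times_min, float)
    conc = np.asarray(conc_ng_ml, float)
    if t_last is None:
        t_last = float(times[-1])
    t, c = _window(times, conc, t0, t_last)
    return float(np.trapezoid(c, t))


def cmax_tmax(
    times_min: Sequence[float], conc_ng_ml: Sequence[float]
) -> tuple[float, float]:
    """Peak concentration and its first attainment time (ties → earliest)."""
    conc = np.asarray(conc_ng_ml, float)
    if conc.size == 0:
        raise ValueError("empty series")
    i = int(np.argmax(conc))  # argmax returns the first maximum
    return float(conc[i]), float(np.asarray(times_min, float)[i])


def terminal_slope(
    times_min: Sequence[float],
    conc_ng_ml: Sequence[float],
    n_tail: int = 3,
) -> float:
    """λz (1/min) from log-linear regression on the last ``n_tail`` points."""
    times = np.asarray(times_min, float)
    conc = np.asarray(conc_ng_ml, float)
    pos = conc > 0
    if pos.sum() < n_tail or n_tail < 2:
        raise ValueError(f"need at least {max(n_tail, 2)} positive tail points")
    t_tail = times[pos][-n_tail:]
    c_tail = conc[pos][-n_tail:]
    slope, _ = np.polyfit(t_tail, np.log(c_tail), 1)
    lam = -float(slope)
    if lam <= 0:
        raise ValueError("terminal phase is not declining; cannot extrapolate")
    return lam


def moment_analysis(
    times_min: Sequence[float],
    conc_ng_ml: Sequence[float],
    dose_ng: float,
    n_tail: int = 3,
) -> NCAResult:
    """Statistical-moment NCA of an intravenous profile.

    AUC_inf = AUC_last + C_last/λz;
    AUMC_inf = AUMC_last + C_last·t_last/λz + C_last/λz²;
    MRT = AUMC/AUC; V_SS = Dose·AUMC/AUC².
    """
    times = np.asarray(times_min, float)
    conc = np.asarray(conc_ng_ml, float)
    cmax, tmax = cmax_tmax(times, conc)
    auc_last = float(np.trapezoid(conc, times))
    aumc_last = float(np.trapezoid(conc * times, times))
    lam = terminal_slope(times, conc, n_tail)
    c_last = float(conc[conc > 0][-1])
    t_last = float(times[conc > 0][-1])
    auc_inf = auc_last + c_last / lam
    aumc_inf = aumc_last + c_last * t_last / lam + c_last / lam**2
    mrt = aumc_inf / auc_inf
    vss = dose_ng * aumc_inf / auc_inf**2
    return NCAResult(
        cmax=cmax, tmax_min=tmax, auc_last=auc_last, auc_inf=auc_inf,
        aumc_inf=aumc_inf, mrt_min=mrt, lambda_z_per_min=lam,
        vss_moment_ml=vss, window_min=(float(times[0]), float(times[-1])),
    )


def nca_summary(
    times_min: Sequence[float],
    conc_ng_ml: Sequence[float],
    t0: float = 0.0,
    t_last: Optional[float] = None,
) -> NCAResult:
    """Cmax/Tmax/AUC_last within a window (no extrapolation)."""
    times = np.asarray(times_min, float)
    conc = np.asarray(conc_ng_ml, float)
    if t_last is None:
        t_last = float(times[-1])
    t, c = _window(times, conc, t0, t_last)
    cmax, tmax = cmax_tmax(t, c)
    return NCAResult(
        cmax=cmax, tmax_min=tmax, auc_last=float(np.trapezoid(c, t)),
        window_min=(t0, t_last),
    )


def bioavailability_ratio(
    times_po: Sequence[float],
    conc_po: Sequence[float],
    times_iv: Sequence[float],
    conc_iv: Sequence[float],
    dose_po_ng: float,
    dose_iv_ng: float,
) -> float:
    """Absolute bioavailability F = (AUC_PO/dose_PO) / (AUC_IV/dose_IV).

    Both curves must cover the same time horizon so truncation biases
    cancel.
    """
    t_po = np.asarray(times_po, float)
    t_iv = np.asarray(times_iv, float)
    if abs(t_po[-1] - t_iv[-1]) > 1e-6 or abs(t_po[0] - t_iv[0]) > 1e-6:
        raise ValueError("oral and intravenous curves must share the horizon")
    auc_po = auc_trapezoid(t_po, conc_po)
    auc_iv = auc_trapezoid(t_iv, conc_iv)
    return (auc_po / dose_po_ng) / (auc_iv / dose_iv_ng)


def prediction_ratios(
    auc_obs: float, cmax_obs: float, auc_pred: float, cmax_pred: float
) -> tuple[float, float, bool]:
    """Predicted/observed AUC and Cmax ratios with the two-fold flag.

    The flag is true iff both ratios lie in [0.5, 2] — the conventional
    adequacy criterion for PBPK model performance.
    """
    if auc_obs <= 0 or cmax_obs <= 0:
        raise ValueError("observed values must be > 0")
    auc_ratio = auc_pred / auc_obs
    cmax_ratio = cmax_pred / cmax_obs
    ok = 0.5 <= auc_ratio <= 2.0 and 0.5 <= cmax_ratio <= 2.0
    return auc_ratio, cmax_ratio, ok
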