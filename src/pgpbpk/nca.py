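"""Non-compartmental analysis of simulated concentration-time profiles.

"Observed" clearance is defined as dose over AUC: at steady state, the dose
administered per interval divided by the plasma AUC over that final
interval.  This apparent clearance quantifies the combined effect of
hepatic saturation and renal capacity, and is the quantity the dose-scan
analysis tracks across dose levels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .engine import DoseRegimen, SimulationResult

__all__ = [
    "NcaResult",
    "auc_trapezoid",
    "observed_clearance",
    "steady_state_metrics",
    "terminal_half_life",
]


@dataclass(frozen=True)
class NcaResult:
    """Summary metrics over the final dosing interval."""

    auc_tau: float  # mg*h/L
    cl_observed: float  # L/h (= dose per interval / auc_tau)
    cmax: float  # mg/L
    tmax: float  # h (within the final interval)
    t_half: float | None  # h, terminal (needs washout data); None if absent
    at_steady_state: bool


def auc_trapezoid(
    times: np.ndarray, concs: np.ndarray, t_start: float, t_end: float
) -> float:
    """Linear trapezoidal AUC of ``concs`` over [t_start, t_end]."""
    t = np.asarray(times, dtype=float)
    c = np.asarray(concs, dtype=float)
    if t.ndim != 1 or t.shape != c.shape:
        raise ValueError("times and concs must be 1-D arrays of equal length")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if t_end <= t_start:
        raise ValueError("empty AUC window")
    if t_start < t[0] - 1e-9 or t_end > t[-1] + 1e-9:
        raise ValueError("AUC window outside the data range")
    mask = (t >= t_start) & (t <= t_end)
    tt, cc = t[mask], c[mask]
    # interpolate exact endpoints if the grid does not contain them
    if tt.size == 0 or tt[0] > t_start + 1e-12:
        tt = np.insert(tt, 0, t_start)
        cc = np.insert(cc, 0, np.interp(t_start, t, c))
    if tt[-1] < t_end - 1e-12:
        tt = np.append(tt, t_end)
        cc = np.append(cc, np.interp(t_end, t, c))
    return float(np.trapezoid(cc, tt))


def observed_clearance(dose_mg: float, auc: float) -> float:
    """CL = dose / AUC, in L/h."""
    if auc <= 0:
        raise ValueError("AUC must be positive")
    return dose_mg / auc


def terminal_half_life(
    times: np.ndarray, concs: np.ndarray, t_last_dose_end: float
) -> float | None:
    """Half-life from log-linear regression of the terminal washout phase.

    Uses the final two-thirds of the post-dose samples with positive
    concentration; returns None if fewer than 4 such points exist.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(concs, dtype=float)
    mask = (t > t_last_dose_end) & (c > 0)
    t, c = t[mask], c[mask]
    if t.size < 4:
        return None
    start = t.size // 3
    t, c = t[start:], c[start:]
    res = stats.linregress(t, np.log(c))
    if res.slope >= 0:
        return None
    return float(np.log(2.0) / -res.slope)


def steady_state_metrics(
    result: SimulationResult,
    regimen: DoseRegimen,
    dose_mg: float | None = None,
    ss_rel_tol: float = 0.01,
) -> NcaResult:
    """NCA over the final dosing interval of a multiple-dose simulation.

    Steady state is verified by requiring the interval AUC to change by
    less than ``ss_rel_tol`` between the last two intervals; if not, the
    result is flagged (``at_steady_state=False``) with a warning.  The
    half-life is estimated from washout samples after the last interval
    when the simulation extends beyond it.
    """
    if regimen.n_doses < 2:
        raise ValueError("steady-state metrics need >= 2 dosing intervals")
    tau = regimen.interval
    t_end = regimen.n_doses * tau
    t = result.times
    c = result.plasma_conc
    if t[-1] < t_end - 1e-9:
        raise ValueError("simulation shorter than the dosing schedule")
    auc_last = auc_trapezoid(t, c, t_end - tau, t_end)
    auc_prev = auc_trapezoid(t, c, t_end - 2 * tau, t_end - tau)
    at_ss = auc_prev > 0 and abs(auc_last - auc_prev) <= ss_rel_tol * auc_last
    if not at_ss:
        warnings.warn(
            "steady state not reached: final-interval AUC differs by "
            f"{abs(auc_last - auc_prev) / max(auc_last, 1e-300):.2%}",
            stacklevel=2,
        )
    if dose_mg is None:
        dose_mg = float(result.dosed[-1]) / regimen.n_doses
    window = (t >= t_end - tau) & (t <= t_end)
    cw = c[window]
    tw = t[window]
    i_max = int(np.argmax(cw))
    t_half = terminal_half_life(t, c, t_end)
    return NcaResult(
        auc_tau=auc_last,
        cl_observed=observed_clearance(dose_mg, auc_last),
        cmax=float(cw[i_max]),
        tmax=float(tw[i_max] - (t_end - tau)),
        t_half=t_half,
        at_steady_state=bool(at_ss),
    )
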