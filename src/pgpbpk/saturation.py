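"""Dose-vs-clearance scans, saturation-onset detection, and toxicity
screening.

A scan simulates a dosing regimen to steady state over a grid of per-event
doses and records the population-summary (geometric-mean) observed
clearance at each dose.  Because hepatic elimination is saturable, the
apparent clearance declines with dose; the onset detector flags where that
decline departs from the low-dose linear trend:

* the *linear phase* is the maximal low-dose prefix of the (dose,
  clearance) points whose ordinary-least-squares line achieves r² ≥ 0.98
  (constant clearance counts as perfectly linear);
* the *onset dose* is the first grid dose beyond the linear phase,
  confirmed by an absolute deviation of more than 1% from the phase
  regression's prediction (doses whose inclusion breaks the r² criterion
  are, by construction, no longer dose-linear).

Screening compares steady-state peak plasma concentration of the
population-mean profile against the plasma level associated with toxicity
(PLAT, 580 mg/L — the exposure at which an increased osmolar gap, the first
toxicity signal, has been reported).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .engine import DoseRegimen, SimulationResult, SolverConfig, simulate, subject_model
from .nca import auc_trapezoid, observed_clearance
from .population import Subject

log = logging.getLogger(__name__)

__all__ = [
    "PLAT_MG_L",
    "DOSE_GRID_MG_KG",
    "SaturationScan",
    "PlatScreen",
    "LinearPhaseFit",
    "run_dose_scan",
    "detect_saturation_onset",
    "screen_plat",
    "recommend_daily_dose",
    "steady_state_duration",
]

#: Plasma level associated with toxicity (increased osmolar gap), mg/L.
PLAT_MG_L = 580.0

#: Default per-event dose grid (mg/kg): the printed example doses, so that
#: threshold statements are evaluable on-grid, spanning 0.75-7500 mg/kg.
DOSE_GRID_MG_KG = (
    0.75, 50.0, 100.0, 200.0, 250.0, 400.0, 500.0, 600.0,
    800.0, 1000.0, 1200.0, 3200.0, 7500.0,
)

#: Days of dosing before the analysis interval, enough for >= 5 half-lives.
PRE_ANALYSIS_DAYS = {"adult": 5.0, "term_neonate": 10.0}


@dataclass(frozen=True)
class LinearPhaseFit:
    slope: float
    intercept: float
    r_squared: float
    n_points: int

    def predict(self, dose: float) -> float:
        return self.intercept + self.slope * dose


@dataclass(frozen=True)
class SaturationScan:
    group: Literal["adult", "term_neonate"]
    interval: float  # h
    dose_grid: tuple[float, ...]  # mg/kg per event
    cl_observed: tuple[float, ...]  # L/h, population geometric mean
    linear_phase_fit: LinearPhaseFit | None = None
    onset_dose: float | None = None  # mg/kg, None if no dose qualifies

    def deviations_pct(self) -> np.ndarray:
        """Percent deviation of each point below the linear-phase line."""
        if self.linear_phase_fit is None:
            raise ValueError("scan has no linear-phase fit")
        d = np.asarray(self.dose_grid)
        cl = np.asarray(self.cl_observed)
        pred = self.linear_phase_fit.predict(d)
        return (pred - cl) / pred * 100.0


@dataclass(frozen=True)
class PlatScreen:
    regimen: DoseRegimen
    plat: float  # mg/L
    max_ss_conc: float  # mg/L, peak of the mean profile in the last interval
    exceeds: bool
    time_above: float  # h above PLAT within the final interval


def steady_state_duration(group: str, interval: float) -> tuple[int, float]:
    """(n_doses, duration) reaching steady state plus one analysis interval."""
    pre_h = PRE_ANALYSIS_DAYS[group] * 24.0
    n_doses = int(np.ceil(pre_h / interval)) + 1
    return n_doses, n_doses * interval


def _geomean(x: np.ndarray) -> float:
    return float(np.exp(np.mean(np.log(x))))


def _population_cl(
    population: Sequence[Subject],
    regimen: DoseRegimen,
    solver_cfg: SolverConfig | None,
) -> float:
    """Geometric-mean observed clearance (dose/AUC_tau) over the population."""
    cls = []
    tau = regimen.interval
    t_end = regimen.n_doses * tau
    for subject in population:
        model = subject_model(subject)
        res = simulate(model, regimen, duration=t_end, solver_cfg=solver_cfg)
        auc = auc_trapezoid(res.times, res.plasma_conc, t_end - tau, t_end)
        cls.append(observed_clearance(regimen.dose_per_event * subject.weight, auc))
    return _geomean(np.asarray(cls))


def run_dose_scan(
    population: Sequence[Subject],
    interval: float,
    dose_grid: Sequence[float] = DOSE_GRID_MG_KG,
    route: str = "iv_infusion",
    solver_cfg: SolverConfig | None = None,
) -> SaturationScan:
    """Scan observed clearance across per-event doses at one frequency.

    Each dose is simulated to steady state (group-specific run-in) and the
    population geometric-mean dose/AUC clearance recorded; a failed solve
    flags the dose (NaN) and the scan continues.
    """
    doses = tuple(float(d) for d in dose_grid)
    if any(np.diff(doses) <= 0):
        raise ValueError("dose grid must be strictly increasing")
    group = population[0].group
    n_doses, duration = steady_state_duration(group, interval)
    cl = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # saturated doses never reach steady state
        for dose in doses:
            regimen = DoseRegimen(
                route=route, dose_per_event=dose, interval=interval, n_doses=n_doses
            )
            try:
                cl.append(_population_cl(population, regimen, solver_cfg))
            except RuntimeError as exc:  # solver failure: flag and continue
                log.warning("dose %.3g mg/kg failed: %s", dose, exc)
                cl.append(float("nan"))
    scan = SaturationScan(
        group=group, interval=interval, dose_grid=doses, cl_observed=tuple(cl)
    )
    return detect_saturation_onset(scan)


def _prefix_r_squared(d: np.ndarray, cl: np.ndarray) -> tuple[float, float, float]:
    """(slope, intercept, r²) of the OLS line, treating flat data as exact."""
    if np.ptp(cl) <= 1e-9 * np.abs(cl).max():
        return 0.0, float(cl.mean()), 1.0
    res = stats.linregress(d, cl)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def detect_saturation_onset(
    scan: SaturationScan,
    r2_threshold: float = 0.98,
    deviation_pct: float = 1.0,
    min_phase_points: int = 4,
) -> SaturationScan:
    """Apply the linearity criterion; returns the scan with fit and onset.

    Non-monotone clearance beyond solver noise triggers a warning but not
    an error (population summaries can wiggle).
    """
    d = np.asarray(scan.dose_grid)
    cl = np.asarray(scan.cl_observed)
    ok = np.isfinite(cl)
    d, cl = d[ok], cl[ok]
    if d.size < min_phase_points:
        raise ValueError(f"need >= {min_phase_points} usable grid points")
    if np.any(np.diff(cl) > 1e-3 * cl.max()):
        warnings.warn("observed clearance is not monotone non-increasing", stacklevel=2)

    fit = None
    for k in range(d.size, min_phase_points - 1, -1):
        slope, intercept, r2 = _prefix_r_squared(d[:k], cl[:k])
        if r2 >= r2_threshold:
            fit = LinearPhaseFit(slope=slope, intercept=intercept, r_squared=r2, n_points=k)
            break
    if fit is None:
        slope, intercept, r2 = _prefix_r_squared(d[:min_phase_points], cl[:min_phase_points])
        fit = LinearPhaseFit(
            slope=slope, intercept=intercept, r_squared=r2, n_points=min_phase_points
        )
        warnings.warn(
            "no low-dose prefix satisfies the r^2 criterion; using the "
            "smallest allowed phase",
            stacklevel=2,
        )

    onset = None
    for dose, c in zip(d[fit.n_points :], cl[fit.n_points :]):
        pred = fit.predict(float(dose))
        scale = abs(pred) if pred != 0 else abs(c)
        if scale > 0 and abs(pred - c) / scale > deviation_pct / 100.0:
            onset = float(dose)
            break
    return SaturationScan(
        group=scan.group,
        interval=scan.interval,
        dose_grid=scan.dose_grid,
        cl_observed=scan.cl_observed,
        linear_phase_fit=fit,
        onset_dose=onset,
    )


def _mean_profile(
    population: Sequence[Subject],
    regimen: DoseRegimen,
    duration: float,
    solver_cfg: SolverConfig | None,
) -> tuple[np.ndarray, np.ndarray]:
    profiles = []
    times = None
    for subject in population:
        model = subject_model(subject)
        res = simulate(model, regimen, duration=duration, solver_cfg=solver_cfg)
        times = res.times
        profiles.append(res.plasma_conc)
    return times, np.mean(profiles, axis=0)


def screen_plat(
    population: Sequence[Subject],
    regimen: DoseRegimen,
    plat: float = PLAT_MG_L,
    solver_cfg: SolverConfig | None = None,
) -> PlatScreen:
    """Compare the mean steady-state profile's peak against the PLAT."""
    if plat <= 0:
        raise ValueError("plat must be positive")
    tau = regimen.interval
    t_end = regimen.n_doses * tau
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        times, mean_conc = _mean_profile(population, regimen, t_end, solver_cfg)
    window = (times >= t_end - tau) & (times <= t_end)
    cw = mean_conc[window]
    tw = times[window]
    cmax = float(cw.max())
    above = cw >= plat
    time_above = float(np.trapezoid(above.astype(float), tw))
    return PlatScreen(
        regimen=regimen,
        plat=plat,
        max_ss_conc=cmax,
        exceeds=bool(cmax >= plat),
        time_above=time_above,
    )


STANDARD_INTERVALS_H = (6.0, 8.0, 12.0, 24.0)


def recommend_daily_dose(
    population: Sequence[Subject],
    candidate_daily_doses: Sequence[float],
    intervals: Sequence[float] = STANDARD_INTERVALS_H,
    plat: float = PLAT_MG_L,
    onset_by_interval: dict[float, float | None] | None = None,
    solver_cfg: SolverConfig | None = None,
):
    """Screen total daily doses (mg/kg/day) across standard frequencies.

    For each candidate and frequency the per-event dose is daily/(24/tau);
    a candidate is *safe* if no frequency reaches the PLAT (and, when scan
    onsets are supplied, no per-event dose reaches the saturation onset).
    Returns (report rows, largest safe candidate or None).
    """
    group = population[0].group
    n_by_tau = {tau: steady_state_duration(group, tau)[0] for tau in intervals}
    rows = []
    safe: list[float] = []
    for daily in candidate_daily_doses:
        all_ok = True
        for tau in intervals:
            per_event = daily * tau / 24.0
            regimen = DoseRegimen(
                route="iv_infusion",
                dose_per_event=per_event,
                interval=tau,
                n_doses=n_by_tau[tau],
            )
            screen = screen_plat(population, regimen, plat, solver_cfg)
            saturated = None
            if onset_by_interval is not None:
                onset = onset_by_interval.get(tau)
                saturated = onset is not None and per_event >= onset
            ok = not screen.exceeds and not bool(saturated)
            all_ok &= ok
            rows.append(
                {
                    "daily_dose_mg_kg": daily,
                    "interval_h": tau,
                    "per_event_mg_kg": per_event,
                    "max_ss_conc_mg_l": screen.max_ss_conc,
                    "reaches_plat": screen.exceeds,
                    "saturated": saturated,
                }
            )
        if all_ok:
            safe.append(daily)
    return rows, (max(safe) if safe else None)
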