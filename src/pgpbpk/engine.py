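"""Whole-body perfusion-limited PBPK model and its ODE integration.

Topology: venous blood -> lung -> arterial blood -> parallel tissues ->
venous blood.  Gut and spleen drain into the portal vein, so the liver
receives hepatic-arterial plus portal inflow; hepatic metabolism
(saturable, Michaelis-Menten) is subtracted in the liver compartment and
renal elimination in the kidney compartment.  Oral doses enter a gut-lumen
depot and are absorbed first-order (rate ka, fraction fa) directly into the
portal inflow; intravenous doses enter the venous pool, by default as a
0.5-h zero-order infusion (the clinical regimens the model screens are
short IV infusions; a bolus route is available).

All amounts are mg, volumes L, flows L/h (whole-blood basis), times h.
State = [arterial, venous, tissues..., gut-lumen depot, cumulative
metabolized, cumulative excreted, cumulative unabsorbed], so mass balance
can be asserted at every output time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from pydantic import BaseModel, model_validator
from scipy.integrate import solve_ivp

from .clearance import (
    HepaticClearanceParams,
    RenalClearanceParams,
    km_mass_mg_l,
    whole_liver_vmax,
)
from .distribution import KpSet
from .population import Subject
from .units import CompoundParams

__all__ = [
    "DoseRegimen",
    "PbpkModel",
    "SimulationResult",
    "SolverConfig",
    "build_model",
    "simulate",
]

DEFAULT_INFUSION_H = 0.5


class DoseRegimen(BaseModel):
    """A repeated-dose regimen; doses are per kg body weight."""

    route: Literal["iv_infusion", "iv_bolus", "oral"] = "iv_infusion"
    dose_per_event: float  # mg/kg
    interval: float = 24.0  # h
    n_doses: int = 1
    infusion_duration: float = DEFAULT_INFUSION_H  # h, iv_infusion only

    model_config = {"frozen": True}

    @model_validator(mode="after")
    def _check(self) -> "DoseRegimen":
        if self.dose_per_event < 0:
            raise ValueError("dose must be non-negative")
        if self.interval <= 0:
            raise ValueError("interval must be positive")
        if self.n_doses < 1:
            raise ValueError("n_doses must be >= 1")
        if self.route == "iv_infusion" and not (
            0 < self.infusion_duration <= self.interval
        ):
            raise ValueError("infusion_duration must lie in (0, interval]")
        return self

    @property
    def daily_dose(self) -> float:
        """Total mg/kg per 24 h implied by the regimen."""
        return self.dose_per_event * 24.0 / self.interval


@dataclass(frozen=True)
class SolverConfig:
    rtol: float = 1e-8
    atol: float = 1e-10  # mg
    method: str = "LSODA"
    output_dt: float = 0.1  # h


@dataclass(frozen=True)
class PbpkModel:
    """Assembled per-subject model: arrays aligned with ``tissues``."""

    tissues: tuple[str, ...]
    volumes: np.ndarray  # L, per tissue
    flows: np.ndarray  # L/h inflow per tissue (liver = total, lung = CO)
    v_arterial: float
    v_venous: float
    cardiac_output: float
    kp_scaled: np.ndarray  # Kp * kp_scalar per tissue
    compound: CompoundParams
    vmax_total: float  # mg/h
    km_mass: float  # mg/L
    renal: RenalClearanceParams
    weight: float  # kg
    subject: Subject | None = field(default=None, repr=False)

    @property
    def n_states(self) -> int:
        return 2 + len(self.tissues) + 4

    def state_labels(self) -> list[str]:
        return (
            ["arterial", "venous"]
            + list(self.tissues)
            + ["gut_lumen", "metabolized", "excreted", "unabsorbed"]
        )


@dataclass(frozen=True)
class SimulationResult:
    """Time grids and per-compartment trajectories from one regimen."""

    times: np.ndarray  # h
    plasma_conc: np.ndarray  # mg/L (venous blood / B:P)
    labels: tuple[str, ...]
    amounts: np.ndarray  # n_times x n_states, mg
    dosed: np.ndarray  # cumulative administered mg

    def column(self, label: str) -> np.ndarray:
        return self.amounts[:, self.labels.index(label)]

    @property
    def cumulative_metabolized(self) -> np.ndarray:
        return self.column("metabolized")

    @property
    def cumulative_excreted(self) -> np.ndarray:
        return self.column("excreted")

    def mass_balance_error(self) -> np.ndarray:
        """|dosed - (in body + eliminated + unabsorbed)| at each time, mg."""
        return np.abs(self.dosed - self.amounts.sum(axis=1))


def build_model(
    subject: Subject,
    compound: CompoundParams,
    kps: KpSet,
    hep: HepaticClearanceParams,
    ren: RenalClearanceParams,
) -> PbpkModel:
    """Assemble the ODE model for one subject.

    Raises on flow imbalance: the arterial draws of all tissues (hepatic
    artery instead of total liver inflow) must sum to cardiac output.
    """
    tissues = tuple(t for t in subject.organ_volumes if t not in ("venous", "arterial"))
    vols = np.array([subject.organ_volumes[t] for t in tissues])
    flows = np.array([subject.blood_flows[t] for t in tissues])
    co = subject.cardiac_output

    names = list(tissues)
    q_arterial = 0.0
    for t, q in zip(names, flows):
        if t == "lung":
            continue
        if t == "liver":
            q_ha = q - subject.blood_flows.get("gut", 0.0) - subject.blood_flows.get(
                "spleen", 0.0
            )
            if q_ha <= 0:
                raise ValueError("hepatic arterial flow must be positive")
            q_arterial += q_ha
        else:
            q_arterial += q
    if abs(q_arterial - co) > 1e-6 * co:
        raise ValueError(
            f"flow imbalance: arterial draws {q_arterial:.6g} != cardiac output {co:.6g}"
        )

    kp = np.array([kps.scaled(t) for t in tissues])
    return PbpkModel(
        tissues=tissues,
        volumes=vols,
        flows=flows,
        v_arterial=subject.organ_volumes["arterial"],
        v_venous=subject.organ_volumes["venous"],
        cardiac_output=co,
        kp_scaled=kp,
        compound=compound,
        vmax_total=whole_liver_vmax(hep, compound.molecular_weight),
        km_mass=km_mass_mg_l(hep.km, compound.molecular_weight),
        renal=ren,
        weight=subject.weight,
        subject=subject,
    )


def subject_model(
    subject: Subject,
    compound: CompoundParams | None = None,
    vmax_invitro: float = 1.57,
    km_mm: float = 25.1,
    kp_scalar: float | None = None,
) -> PbpkModel:
    """Assemble the default PG model for one subject.

    The Kp scalar defaults by group: 1.0 for adults, 0.44 for term neonates
    (the uniform scalar recovering the smaller neonatal distribution
    volume).
    """
    from .clearance import hepatic_params_for, renal_params_for
    from .distribution import predict_kp_set
    from .units import PG_DEFAULTS

    compound = compound or PG_DEFAULTS
    if kp_scalar is None:
        kp_scalar = 0.44 if subject.group == "term_neonate" else 1.0
    kps = predict_kp_set(compound, kp_scalar=kp_scalar)
    hep = hepatic_params_for(subject, vmax_invitro, km_mm)
    ren = renal_params_for(subject, compound)
    return build_model(subject, compound, kps, hep, ren)


def _make_rhs(model: PbpkModel):
    """Closure computing dy/dt; infusion rate is passed per segment."""
    nt = len(model.tissues)
    V = model.volumes
    Q = model.flows
    bp = model.compound.blood_to_plasma
    fu_p = model.compound.fu_plasma
    conv = bp / model.kp_scaled  # tissue conc -> outflow blood conc
    co = model.cardiac_output
    idx = {t: i for i, t in enumerate(model.tissues)}
    i_lung = idx.get("lung", -1)
    i_liver = idx.get("liver", -1)
    i_kidney = idx.get("kidney", -1)
    i_gut = idx.get("gut", -1)
    i_spleen = idx.get("spleen", -1)
    q_gut = Q[i_gut] if i_gut >= 0 else 0.0
    q_spleen = Q[i_spleen] if i_spleen >= 0 else 0.0
    q_liver = Q[i_liver] if i_liver >= 0 else 0.0
    q_ha = q_liver - q_gut - q_spleen
    # venous collectors: every tissue except lung and the portal organs
    collect = np.array(
        [i for i, t in enumerate(model.tissues) if t not in ("lung", "gut", "spleen")]
    )
    vmax = model.vmax_total
    km = model.km_mass
    kp_liver = model.kp_scaled[i_liver] if i_liver >= 0 else 1.0
    renal = model.renal
    renal_adult = renal.mode == "fixed_adult"
    cl_renal = renal.cl_fixed if renal_adult else renal.gfr * 60.0 / 1000.0 * renal.fu_b
    ka = model.compound.ka
    fa = model.compound.fa
    i_depot = 2 + nt
    v_art = model.v_arterial
    v_ven = model.v_venous

    def rhs(t, y, infusion_rate):
        c_art = y[0] / v_art
        c_ven = y[1] / v_ven
        ct = y[2 : 2 + nt] / V
        cout = ct * conv
        dy = np.empty_like(y)
        d_t = Q * (c_art - cout)
        # lung sits in series between the venous and arterial pools
        if i_lung >= 0:
            d_t[i_lung] = co * (c_ven - cout[i_lung])
            dy[0] = co * (cout[i_lung] - c_art)
        else:
            dy[0] = co * (c_ven - c_art)

        absorbed = fa * ka * y[i_depot]
        met = 0.0
        if i_liver >= 0:
            cu = fu_p * ct[i_liver] / kp_liver
            if cu < 0.0:
                cu = 0.0
            met = vmax * cu / (km + cu)
            inflow = q_ha * c_art + absorbed
            if i_gut >= 0:
                inflow += q_gut * cout[i_gut]
            if i_spleen >= 0:
                inflow += q_spleen * cout[i_spleen]
            d_t[i_liver] = inflow - q_liver * cout[i_liver] - met

        excr = 0.0
        if i_kidney >= 0:
            c_drive = (c_art / bp) if renal_adult else c_art
            if c_drive < 0.0:
                c_drive = 0.0
            excr = cl_renal * c_drive
            d_t[i_kidney] -= excr

        dy[2 : 2 + nt] = d_t
        dy[1] = float(Q[collect] @ cout[collect]) - co * c_ven + infusion_rate
        dy[i_depot] = -ka * y[i_depot]
        dy[i_depot + 1] = met
        dy[i_depot + 2] = excr
        dy[i_depot + 3] = (1.0 - fa) * ka * y[i_depot]
        return dy

    return rhs


def _dose_schedule(model: PbpkModel, regimen: DoseRegimen, duration: float):
    """Segment boundaries, per-segment infusion rates, and state jumps."""
    dose_mg = regimen.dose_per_event * model.weight
    starts = [k * regimen.interval for k in range(regimen.n_doses)]
    bounds = {0.0, duration}
    jumps: dict[float, tuple[str, float]] = {}
    infusions: list[tuple[float, float, float]] = []  # start, end, rate
    for t0 in starts:
        if t0 >= duration:
            continue
        if regimen.route == "iv_infusion":
            t1 = min(t0 + regimen.infusion_duration, duration)
            infusions.append((t0, t1, dose_mg / regimen.infusion_duration))
            bounds |= {t0, t1}
        else:
            bounds.add(t0)
            target = "venous" if regimen.route == "iv_bolus" else "gut_lumen"
            jumps[t0] = (target, jumps.get(t0, ("", 0.0))[1] + dose_mg)
    return sorted(bounds), infusions, jumps, dose_mg


def simulate(
    model: PbpkModel,
    regimen: DoseRegimen,
    duration: float,
    solver_cfg: SolverConfig | None = None,
) -> SimulationResult:
    """Integrate the model under a dosing regimen over [0, duration] h."""
    cfg = solver_cfg or SolverConfig()
    if duration <= 0:
        raise ValueError("duration must be positive")
    rhs = _make_rhs(model)
    bounds, infusions, jumps, dose_mg = _dose_schedule(model, regimen, duration)
    labels = model.state_labels()
    i_depot = labels.index("gut_lumen")
    y = np.zeros(model.n_states)

    grid = np.round(np.arange(0.0, duration + cfg.output_dt / 2, cfg.output_dt), 10)
    grid = grid[grid <= duration + 1e-9]
    times_out: list[np.ndarray] = []
    states_out: list[np.ndarray] = []
    dosed_out: list[np.ndarray] = []

    def infusion_rate_at(t0: float, t1: float) -> float:
        mid = 0.5 * (t0 + t1)
        return sum(r for (a, b, r) in infusions if a <= mid < b)

    def cumulative_dosed(ts: np.ndarray) -> np.ndarray:
        out = np.zeros_like(ts)
        for a, b, r in infusions:
            out += r * np.clip(ts - a, 0.0, b - a)
        for tj, (_, amt) in jumps.items():
            out += np.where(ts >= tj, amt, 0.0)
        return out

    for t0, t1 in zip(bounds[:-1], bounds[1:]):
        if t0 in jumps:
            target, amt = jumps[t0]
            y[1 if target == "venous" else i_depot] += amt
        rate = infusion_rate_at(t0, t1)
        mask = (grid >= t0) & (grid < t1)
        t_eval = np.concatenate([grid[mask], [t1]])
        if dose_mg == 0.0 and not np.any(y):
            sol_y = np.zeros((model.n_states, len(t_eval)))
        else:
            sol = solve_ivp(
                rhs,
                (t0, t1),
                y,
                method=cfg.method,
                rtol=cfg.rtol,
                atol=cfg.atol,
                t_eval=t_eval,
                args=(rate,),
            )
            if not sol.success:  # pragma: no cover
                raise RuntimeError(
                    f"ODE solver failed in [{t0}, {t1}] h: {sol.message}; "
                    f"last state norm {np.abs(y).max():.3g} mg"
                )
            sol_y = sol.y
        y = sol_y[:, -1].copy()
        keep = len(t_eval) - (0 if t1 == bounds[-1] else 1)
        times_out.append(t_eval[:keep])
        states_out.append(sol_y[:, :keep].T)
        dosed_out.append(cumulative_dosed(t_eval[:keep]))

    times = np.concatenate(times_out)
    amounts = np.vstack(states_out)
    dosed = np.concatenate(dosed_out)
    # de-duplicate identical consecutive times from segment stitching
    uniq = np.concatenate([[True], np.diff(times) > 1e-12])
    times, amounts, dosed = times[uniq], amounts[uniq], dosed[uniq]
    plasma = amounts[:, 1] / model.v_venous / model.compound.blood_to_plasma
    return SimulationResult(
        times=times,
        plasma_conc=plasma,
        labels=tuple(labels),
        amounts=amounts,
        dosed=dosed,
    )
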