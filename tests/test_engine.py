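"""ODE engine: conservation, closed-form oracles, linearity, convergence."""

import numpy as np
import pytest

from pgpbpk.clearance import (
    HepaticClearanceParams,
    RenalClearanceParams,
    unbound_blood_fraction,
    well_stirred_hepatic_blood_cl,
)
from pgpbpk.distribution import KpSet, predict_kp_set
from pgpbpk.engine import (
    DoseRegimen,
    PbpkModel,
    SolverConfig,
    build_model,
    simulate,
    subject_model,
)
from pgpbpk.nca import auc_trapezoid
from pgpbpk.population import TISSUES
from pgpbpk.units import PG_DEFAULTS


def _zero_clearance_model(subject):
    kps = predict_kp_set(PG_DEFAULTS, kp_scalar=1.0)
    hep = HepaticClearanceParams(
        vmax_invitro=1.57, km=25.1, cppgl=80.7,
        liver_mass=subject.liver_mass, adh_fraction=0.0,
    )
    ren = RenalClearanceParams(mode="gfr_neonate", gfr=0.0)
    return build_model(subject, PG_DEFAULTS, kps, hep, ren)


def _one_compartment_model(v_total=10.0, cl=1.0):
    """Degenerate configuration behaving as one well-mixed compartment.

    A single 'liver' tissue with an enormous perfusion flow equilibrates
    instantaneously with the blood pools; an effectively linear elimination
    (Km far above any concentration) gives CL = Vmax/Km.
    """
    km_mass = 1e9
    compound = PG_DEFAULTS.model_copy(
        update={"blood_to_plasma": 1.0, "fu_plasma": 1.0, "log_p": 0.0}
    )
    return PbpkModel(
        tissues=("liver",),
        volumes=np.array([v_total - 2.0]),
        flows=np.array([1e5]),
        v_arterial=1.0,
        v_venous=1.0,
        cardiac_output=1e5,
        kp_scaled=np.array([1.0]),
        compound=compound,
        vmax_total=cl * km_mass,
        km_mass=km_mass,
        renal=RenalClearanceParams(mode="gfr_neonate", gfr=0.0),
        weight=1.0,
    )


class TestConservation:
    def test_zero_dose_all_zero(self, adult):
        model = subject_model(adult)
        reg = DoseRegimen(route="iv_infusion", dose_per_event=0.0, interval=12, n_doses=2)
        res = simulate(model, reg, duration=36.0)
        assert np.all(res.plasma_conc == 0.0)
        assert np.all(res.amounts == 0.0)

    def test_zero_clearance_mass_constant(self, neonate):
        model = _zero_clearance_model(neonate)
        reg = DoseRegimen(route="iv_infusion", dose_per_event=10.0, interval=24, n_doses=1)
        res = simulate(model, reg, duration=48.0)
        dose = 10.0 * neonate.weight
        in_body = res.amounts[:, : res.labels.index("gut_lumen")].sum(axis=1)
        after = res.times > 0.5  # infusion over
        assert np.allclose(in_body[after], dose, rtol=1e-6)
        assert float(res.cumulative_metabolized[-1]) == pytest.approx(0.0, abs=1e-9)

    def test_oral_fraction_absorbed(self, adult):
        model = _zero_clearance_model(adult)
        reg = DoseRegimen(route="oral", dose_per_event=10.0, interval=24, n_doses=1)
        res = simulate(model, reg, duration=24.0)
        dose = 10.0 * adult.weight
        depot = res.column("gut_lumen")[-1]
        unabs = res.column("unabsorbed")[-1]
        in_body = res.amounts[-1, : res.labels.index("gut_lumen")].sum()
        assert depot == pytest.approx(0.0, abs=1e-9 * dose)
        assert in_body == pytest.approx(0.99 * dose, rel=1e-6)
        assert unabs == pytest.approx(0.01 * dose, rel=1e-4)

    def test_mass_balance_reference_simulation(self, adult):
        model = subject_model(adult)
        reg = DoseRegimen(route="iv_infusion", dose_per_event=100.0, interval=12, n_doses=4)
        res = simulate(model, reg, duration=72.0)
        dose_total = 100.0 * adult.weight * 4
        assert res.mass_balance_error().max() < 1e-6 * dose_total


class TestClosedFormOracle:
    def test_iv_bolus_matches_exponential(self):
        v, cl = 10.0, 1.0
        model = _one_compartment_model(v_total=v, cl=cl)
        reg = DoseRegimen(route="iv_bolus", dose_per_event=100.0, interval=24, n_doses=1)
        res = simulate(model, reg, duration=10.0)
        t = res.times[res.times > 0.2]  # past the mixing transient
        c = res.plasma_conc[res.times > 0.2]
        expected = (100.0 / v) * np.exp(-cl * t / v)
        assert np.allclose(c, expected, rtol=1e-3)

    def test_half_life_identity(self):
        v, cl = 10.0, 1.0
        model = _one_compartment_model(v_total=v, cl=cl)
        reg = DoseRegimen(route="iv_bolus", dose_per_event=100.0, interval=24, n_doses=1)
        res = simulate(model, reg, duration=30.0)
        from pgpbpk.nca import terminal_half_life

        t_half = terminal_half_life(res.times, res.plasma_conc, 0.5)
        assert t_half == pytest.approx(v * np.log(2) / cl, rel=0.02)


class TestLinearity:
    def test_superposition_of_low_doses(self, adult):
        """In the linear range, two q24h doses obey superposition."""
        model = subject_model(adult)
        single = simulate(
            model,
            DoseRegimen(route="iv_infusion", dose_per_event=0.75, interval=24, n_doses=1),
            duration=48.0,
        )
        double = simulate(
            model,
            DoseRegimen(route="iv_infusion", dose_per_event=0.75, interval=24, n_doses=2),
            duration=48.0,
        )
        auc2 = auc_trapezoid(double.times, double.plasma_conc, 24.0, 48.0)
        shifted = auc_trapezoid(single.times, single.plasma_conc, 0.0, 24.0)
        residual = auc_trapezoid(single.times, single.plasma_conc, 24.0, 48.0)
        assert auc2 == pytest.approx(shifted + residual, rel=0.01)

    def test_dose_normalized_auc_constant_at_low_dose(self, adult):
        model = subject_model(adult)
        aucs = []
        for dose in (0.375, 0.75):
            reg = DoseRegimen(route="iv_infusion", dose_per_event=dose, interval=24, n_doses=1)
            res = simulate(model, reg, duration=48.0)
            aucs.append(auc_trapezoid(res.times, res.plasma_conc, 0, 48) / dose)
        assert aucs[0] == pytest.approx(aucs[1], rel=0.005)


class TestWellStirredCrossCheck:
    def test_ode_hepatic_extraction_matches_closed_form(self, adult):
        """Low-dose steady state: ODE hepatic clearance vs analytic value."""
        model = subject_model(adult)
        reg = DoseRegimen(
            route="iv_infusion", dose_per_event=0.75, interval=24,
            n_doses=7, infusion_duration=24.0,  # continuous infusion
        )
        res = simulate(model, reg, duration=7 * 24.0)
        # steady state over the final day
        mask = res.times >= 6 * 24.0
        c_ss = float(np.mean(res.plasma_conc[mask]))
        rate_met = np.gradient(res.cumulative_metabolized[mask], res.times[mask])
        cl_h_plasma_ode = float(np.mean(rate_met)) / c_ss
        clu_int = model.vmax_total / model.km_mass
        fu_b = unbound_blood_fraction(model.compound)
        q_h = adult.blood_flows["liver"]
        cl_h_blood = well_stirred_hepatic_blood_cl(q_h, fu_b, clu_int)
        cl_h_plasma = cl_h_blood * model.compound.blood_to_plasma
        assert cl_h_plasma_ode == pytest.approx(cl_h_plasma, rel=0.05)


class TestSolverRobustness:
    def test_tolerance_convergence(self, neonate):
        """Halving tolerances changes the AUC by far less than 0.1%."""
        model = subject_model(neonate)
        reg = DoseRegimen(route="iv_infusion", dose_per_event=100.0, interval=24, n_doses=2)
        aucs = []
        for rtol, atol in ((1e-8, 1e-10), (5e-9, 5e-11)):
            res = simulate(
                model, reg, duration=48.0, solver_cfg=SolverConfig(rtol=rtol, atol=atol)
            )
            aucs.append(auc_trapezoid(res.times, res.plasma_conc, 0, 48))
        assert abs(aucs[0] - aucs[1]) / aucs[1] < 1e-3

    def test_flow_imbalance_rejected(self, adult):
        bad_flows = dict(adult.blood_flows)
        bad_flows["muscle"] *= 2
        broken = adult.model_copy(update={"blood_flows": bad_flows})
        kps = predict_kp_set(PG_DEFAULTS)
        hep = HepaticClearanceParams(
            vmax_invitro=1.57, km=25.1, liver_mass=adult.liver_mass
        )
        ren = RenalClearanceParams(mode="fixed_adult", cl_fixed=3.3)
        with pytest.raises(ValueError, match="flow imbalance"):
            build_model(broken, PG_DEFAULTS, kps, hep, ren)


def test_lung_in_series_and_compartment_set(adult):
    model = subject_model(adult)
    assert set(model.tissues) == set(TISSUES)
    assert model.state_labels()[:2] == ["arterial", "venous"]
    assert "gut_lumen" in model.state_labels()
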