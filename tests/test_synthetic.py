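"""Synthetic plates and pseudo-clinical observation sets."""

from dataclasses import replace

import numpy as np
import pytest

from pgpbpk.engine import DoseRegimen
from pgpbpk.invitro import PG_KINETICS, absorbance_to_rate, fit_michaelis_menten
from pgpbpk.nca import terminal_half_life
from pgpbpk.population import generate_population, population_spec
from pgpbpk.synthetic import (
    DEFAULT_STANDARD_CURVE,
    generate_observations,
    generate_plate,
    twofold_and_vpc,
)


class TestGeneratePlate:
    def test_noiseless_round_trip_recovers_kinetics(self):
        plate = generate_plate(PG_KINETICS, noise_cv=0.0, seed=0)
        points = absorbance_to_rate(plate, DEFAULT_STANDARD_CURVE)
        fit = fit_michaelis_menten(points)
        assert fit.vmax == pytest.approx(PG_KINETICS.vmax, rel=1e-6)
        assert fit.km == pytest.approx(PG_KINETICS.km, rel=1e-6)

    def test_blank_wells_have_blank_absorbance_only(self):
        plate = generate_plate(PG_KINETICS, noise_cv=0.0, seed=0)
        assert plate.substrate_conc[0] == 0.0
        a0 = np.asarray(plate.absorbance_t0[0])
        a20 = np.asarray(plate.absorbance_t20[0])
        assert np.allclose(a20 - a0, 0.0, atol=1e-12)

    def test_same_seed_identical_plate(self):
        assert generate_plate(PG_KINETICS, 0.05, seed=9) == generate_plate(
            PG_KINETICS, 0.05, seed=9
        )

    def test_published_design(self):
        plate = generate_plate(PG_KINETICS, 0.0, seed=0)
        assert plate.substrate_conc == (0.0, 1.0, 3.0, 10.0, 30.0, 100.0, 300.0, 1000.0)
        assert plate.replicates == 3
        assert plate.protein_conc == 0.5
        assert plate.incubation_time == 20.0


def _spec(group, n=5, seed=0, zero_var=True):
    return population_spec(group, n_subjects=n, seed=seed, zero_variability=zero_var)


def _reg(dose=0.75, tau=24.0, n=3):
    return DoseRegimen(route="iv_infusion", dose_per_event=dose, interval=tau, n_doses=n)


class TestGenerateObservations:
    def test_zero_residual_dense_schedule_equals_simulation(self):
        spec = _spec("adult", n=1)
        reg = _reg()
        sched = np.arange(0.5, 24.01, 0.5)
        obs = generate_observations(spec, reg, sparse_schedule=sched, residual_cv=0.0, seed=0)
        from pgpbpk.engine import simulate, subject_model

        (subject,) = generate_population(spec)
        res = simulate(subject_model(subject), reg, 72.0)
        t, c = obs.for_subject(0)
        assert np.allclose(c, np.interp(t, res.times, res.plasma_conc), rtol=1e-9)

    def test_residual_cv_moment_recovery(self):
        spec = _spec("adult", n=20, zero_var=True)
        obs = generate_observations(spec, _reg(), residual_cv=0.2, seed=4)
        noiseless = generate_observations(spec, _reg(), residual_cv=0.0, seed=4)
        ratio = obs.observed_conc / noiseless.observed_conc
        cv = ratio.std(ddof=1) / ratio.mean()
        assert abs(cv - 0.2) / 0.2 < 0.30

    def test_seed_reproducibility(self):
        a = generate_observations(_spec("adult"), _reg(), residual_cv=0.1, seed=5)
        b = generate_observations(_spec("adult"), _reg(), residual_cv=0.1, seed=5)
        assert np.array_equal(a.observed_conc, b.observed_conc)

    def test_neonatal_half_life_elevated_vs_adult(self):
        """NCA on generated sets shows the slower neonatal elimination."""
        halves = {}
        for group, n_doses in (("adult", 3), ("term_neonate", 6)):
            spec = _spec(group, n=1)
            tau = 24.0
            reg = _reg(dose=10.0, tau=tau, n=n_doses)
            from pgpbpk.engine import simulate, subject_model

            (subject,) = generate_population(spec)
            res = simulate(subject_model(subject), reg, n_doses * tau + 72.0)
            halves[group] = terminal_half_life(res.times, res.plasma_conc, n_doses * tau)
        assert halves["term_neonate"] > 2 * halves["adult"]
        assert 2.0 < halves["adult"] < 5.0
        assert 10.0 < halves["term_neonate"] < 31.0


class TestTwofoldAndVpc:
    def test_self_consistency_is_perfect(self):
        spec = _spec("adult", n=3)
        obs = generate_observations(spec, _reg(), residual_cv=0.0, seed=0)
        report = twofold_and_vpc(generate_population(spec), obs)
        assert report.frac_auc_within_2fold == 1.0
        assert report.frac_cl_within_2fold == 1.0
        assert report.frac_points_in_band == 1.0
        assert report.pass_2fold and report.pass_vpc

    def test_threefold_clearance_mismatch_fails(self):
        spec = _spec("adult", n=3)
        obs = generate_observations(spec, _reg(), residual_cv=0.0, seed=0)
        shifted = replace(obs, observed_conc=obs.observed_conc / 3.0)
        report = twofold_and_vpc(generate_population(spec), shifted)
        assert not report.pass_2fold

    def test_empty_observation_set_rejected(self):
        spec = _spec("adult", n=1)
        obs = generate_observations(spec, _reg(), residual_cv=0.0, seed=0)
        empty = replace(
            obs,
            subject_id=np.array([], dtype=int),
            times=np.array([]),
            observed_conc=np.array([]),
        )
        with pytest.raises(ValueError, match="empty"):
            twofold_and_vpc(generate_population(spec), empty)

    def test_group_mismatch_rejected(self):
        obs = generate_observations(_spec("term_neonate", n=1), _reg(n=6), residual_cv=0.0)
        with pytest.raises(ValueError, match="group"):
            twofold_and_vpc(generate_population(_spec("adult", n=1)), obs)
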