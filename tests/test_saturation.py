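"""Saturation-onset detection and PLAT screening."""

import numpy as np
import pytest
from scipy import stats

from pgpbpk.engine import DoseRegimen
from pgpbpk.saturation import (
    DOSE_GRID_MG_KG,
    PLAT_MG_L,
    SaturationScan,
    detect_saturation_onset,
    recommend_daily_dose,
    screen_plat,
    steady_state_duration,
)


def _scan(doses, cl, group="adult", interval=24.0):
    return SaturationScan(
        group=group, interval=interval,
        dose_grid=tuple(doses), cl_observed=tuple(cl),
    )


def brute_force_onset(doses, cl, r2=0.98, dev=1.0, min_pts=4):
    """Independent straight-loop implementation of the detector rule."""
    d = np.asarray(doses, float)
    c = np.asarray(cl, float)
    phase = None
    for k in range(len(d), min_pts - 1, -1):
        if np.ptp(c[:k]) <= 1e-9 * np.abs(c[:k]).max():
            slope, intercept, r_sq = 0.0, float(c[:k].mean()), 1.0
        else:
            res = stats.linregress(d[:k], c[:k])
            slope, intercept, r_sq = res.slope, res.intercept, res.rvalue**2
        if r_sq >= r2:
            phase = (k, slope, intercept)
            break
    if phase is None:
        res = stats.linregress(d[:min_pts], c[:min_pts])
        phase = (min_pts, res.slope, res.intercept)
    k, slope, intercept = phase
    for i in range(k, len(d)):
        pred = intercept + slope * d[i]
        scale = abs(pred) if pred != 0 else abs(c[i])
        if scale > 0 and abs(pred - c[i]) / scale > dev / 100.0:
            return float(d[i])
    return None


class TestOnsetDetector:
    doses = np.array(DOSE_GRID_MG_KG)

    def test_constant_clearance_gives_no_onset(self):
        scan = detect_saturation_onset(_scan(self.doses, np.full(13, 8.5)))
        assert scan.onset_dose is None
        assert scan.linear_phase_fit.r_squared == pytest.approx(1.0)

    @pytest.mark.parametrize("d50", [500.0, 2000.0, 10000.0])
    def test_matches_brute_force_on_hyperbolic_curves(self, d50):
        cl = 8.5 / (1.0 + self.doses / d50)
        scan = detect_saturation_onset(_scan(self.doses, cl))
        assert scan.onset_dose == brute_force_onset(self.doses, cl)

    def test_matches_brute_force_on_noisy_curves(self, rng):
        for _ in range(20):
            d50 = rng.uniform(200, 20000)
            noise = rng.lognormal(0, 0.002, self.doses.size)
            cl = 8.5 / (1.0 + self.doses / d50) * noise
            scan = detect_saturation_onset(_scan(self.doses, cl))
            assert scan.onset_dose == brute_force_onset(self.doses, cl)

    def test_grid_refinement_never_delays_onset(self):
        cl_fn = lambda d: 8.5 / (1.0 + d / 800.0)
        coarse = np.array(DOSE_GRID_MG_KG)
        scan_c = detect_saturation_onset(_scan(coarse, cl_fn(coarse)))
        assert scan_c.onset_dose is not None
        refined = np.unique(
            np.concatenate([coarse, np.linspace(coarse[0], scan_c.onset_dose, 15)])
        )
        scan_r = detect_saturation_onset(_scan(refined, cl_fn(refined)))
        assert scan_r.onset_dose is not None
        assert scan_r.onset_dose <= scan_c.onset_dose

    def test_low_dose_clearance_near_linear_phase(self):
        """A detected onset implies the 10x-lower dose is still linear."""
        cl = 8.5 / (1.0 + self.doses / 800.0)
        scan = detect_saturation_onset(_scan(self.doses, cl))
        onset = scan.onset_dose
        assert onset is not None
        low = onset / 10.0
        pred = scan.linear_phase_fit.predict(low)
        assert abs(pred - 8.5 / (1 + low / 800.0)) / pred < 0.05

    def test_non_monotone_curve_warns(self):
        cl = np.full(13, 8.5)
        cl[5] = 9.5
        with pytest.warns(UserWarning, match="monotone"):
            detect_saturation_onset(_scan(self.doses, cl))

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            detect_saturation_onset(_scan([1, 2, 3], [1.0, 1.0, 1.0]))


class TestPlatScreen:
    def test_zero_dose_never_exceeds(self, neonate):
        reg = DoseRegimen(route="iv_infusion", dose_per_event=0.0, interval=24, n_doses=2)
        screen = screen_plat([neonate], reg)
        assert not screen.exceeds
        assert screen.max_ss_conc == 0.0

    def test_monotone_in_dose(self, neonate):
        n, _ = steady_state_duration("term_neonate", 12.0)
        results = []
        for dose in (50.0, 100.0, 200.0):
            reg = DoseRegimen(route="iv_infusion", dose_per_event=dose, interval=12, n_doses=n)
            results.append(screen_plat([neonate], reg))
        assert results[0].max_ss_conc < results[1].max_ss_conc < results[2].max_ss_conc
        exceeded = [r.exceeds for r in results]
        assert exceeded == sorted(exceeded)  # once above PLAT, stays above

    def test_infinite_plat_always_safe(self, adult):
        reg = DoseRegimen(route="iv_infusion", dose_per_event=7500.0, interval=24, n_doses=6)
        screen = screen_plat([adult], reg, plat=1e12)
        assert not screen.exceeds

    def test_time_above_positive_when_exceeding(self, neonate):
        n, _ = steady_state_duration("term_neonate", 6.0)
        reg = DoseRegimen(route="iv_infusion", dose_per_event=200.0, interval=6, n_doses=n)
        screen = screen_plat([neonate], reg)
        assert screen.exceeds
        assert screen.time_above > 0


class TestRecommendDailyDose:
    def test_adult_candidates(self, adult):
        rows, largest = recommend_daily_dose(
            [adult], [100.0, 200.0, 500.0], intervals=(24.0, 6.0)
        )
        by_daily = {}
        for r in rows:
            by_daily.setdefault(r["daily_dose_mg_kg"], []).append(r["reaches_plat"])
        assert not any(by_daily[100.0])
        assert not any(by_daily[200.0])
        assert any(by_daily[500.0])
        assert largest == 200.0

    def test_neonate_window_safe(self, neonate):
        rows, _ = recommend_daily_dose(
            [neonate], [25.0, 50.0], intervals=(24.0, 12.0, 8.0, 6.0)
        )
        assert not any(r["reaches_plat"] for r in rows)

    def test_infinite_plat_all_safe(self, adult):
        rows, largest = recommend_daily_dose(
            [adult], [100.0, 7500.0], intervals=(24.0,), plat=1e12
        )
        assert largest == 7500.0
        assert not any(r["reaches_plat"] for r in rows)
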