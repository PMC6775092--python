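"""CPMG dispersion: conversions, engines, error model, and global fit."""

import math

import numpy as np
import pytest

from spindyn.cpmg_dispersion import (
    CPMGSchedule,
    DispersionProfile,
    ScheduleError,
    carver_richards,
    dw_rad_per_ppm,
    estimate_sigma,
    fit_global_two_state,
    luz_meiboom_rex,
    nu_delta_convert,
    r2eff_from_intensity,
    rmsd_vs_random_coil,
    screen_significant,
    simulate_bm,
)
from spindyn.io_tables import ResidueID
from spindyn.synthetic_data import (
    cpmg_schedule_600,
    cpmg_schedule_800,
    default_exchange_truth,
    gen_dispersion_dataset,
)

RID = ResidueID(30, "A")


class TestConversions:
    def test_delta_to_nu(self):
        assert nu_delta_convert(0.012) == pytest.approx(41.67, abs=0.01)

    def test_nu_to_delta_inverse(self):
        assert nu_delta_convert(2000.0) == pytest.approx(0.25e-3)
        assert nu_delta_convert(nu_delta_convert(137.0)) == pytest.approx(137.0)

    def test_zero_rejected(self):
        with pytest.raises(ValueError):
            nu_delta_convert(0.0)

    @pytest.mark.parametrize(
        "i, i0, t, expected",
        [(5.0, 5.0, 0.048, 0.0),
         (5.0 * math.exp(-1.0), 5.0, 0.040, 25.0),
         (5.0 * math.exp(-0.48), 5.0, 0.048, 10.0)],
    )
    def test_r2eff_closed_form(self, i, i0, t, expected):
        assert r2eff_from_intensity(i, i0, t) == pytest.approx(expected)

    def test_nonpositive_intensity_rejected(self):
        with pytest.raises(ValueError):
            r2eff_from_intensity(-1.0, 5.0, 0.04)


class TestSchedule:
    def test_whole_block_invariant_enforced(self):
        with pytest.raises(ScheduleError):
            CPMGSchedule(600.0, 0.048, [41.7, 100.0])  # 100*0.048 = 4.8

    def test_odd_block_count_rejected(self):
        with pytest.raises(ScheduleError):
            CPMGSchedule(600.0, 0.048, [62.5])  # T*nu = 3

    def test_default_schedules_match_acquisition_scheme(self):
        s6, s8 = cpmg_schedule_600(), cpmg_schedule_800()
        assert s6.nu_hz.size == 17 and s6.t_cpmg == 0.048
        assert s8.nu_hz.size == 14 and s8.t_cpmg == 0.040
        assert s6.nu_hz[0] == pytest.approx(41.7, abs=0.1)
        assert s6.nu_hz[-1] == pytest.approx(2000.0)
        assert s8.nu_hz[0] == pytest.approx(50.0)
        assert s8.nu_hz[-1] == pytest.approx(1000.0)
        for s in (s6, s8):
            n = s.t_cpmg * s.nu_hz
            assert np.allclose(n, np.round(n)) and np.all(np.round(n) % 2 == 0)


class TestSigmaEstimation:
    def _profile(self, r2eff, nu=None, sched=None):
        sched = sched or cpmg_schedule_800()
        nu = nu if nu is not None else sched.nu_hz
        return DispersionProfile(RID, sched, nu, np.asarray(r2eff, float))

    def test_identical_duplicates_floor_everywhere(self):
        sched = cpmg_schedule_800()
        nu = np.concatenate([sched.nu_hz, sched.nu_hz[[0, 7, 13]]])
        r2 = np.full(nu.size, 15.0)
        sigma = estimate_sigma(self._profile(r2, nu))
        np.testing.assert_allclose(sigma, 0.02 * 15.0)

    def test_duplicate_spread_dominates_floor(self):
        sched = cpmg_schedule_800()
        nu = np.concatenate([sched.nu_hz, [sched.nu_hz[0]]])
        r2 = np.full(nu.size, 20.0)
        r2[-1] = 30.0   # duplicate pair differs by 10/s
        sigma = estimate_sigma(self._profile(r2, nu))
        assert sigma[0] == pytest.approx(math.sqrt(50.0), rel=1e-6)
        assert np.all(sigma > 0.02 * 20.0)

    def test_nonpositive_point_gets_neighbor_median_floor(self):
        sched = cpmg_schedule_800()
        r2 = np.full(sched.nu_hz.size, 12.0)
        r2[3] = -0.5
        sigma = estimate_sigma(self._profile(r2))
        assert sigma[3] == pytest.approx(0.02 * 12.0)


class TestEngines:
    def test_no_exchange_limit_flat_at_r20(self):
        s8 = cpmg_schedule_800()
        np.testing.assert_allclose(
            simulate_bm(847.0, 1e-12, 3.0, 11.0, s8), 11.0, rtol=1e-9
        )

    def test_zero_shift_difference_flat_at_r20(self):
        s8 = cpmg_schedule_800()
        np.testing.assert_allclose(
            simulate_bm(847.0, 0.0163, 0.0, 11.0, s8), 11.0, rtol=1e-12
        )

    def test_dispersion_monotone_nonincreasing_in_nu(self):
        for sched in (cpmg_schedule_600(), cpmg_schedule_800()):
            prof = simulate_bm(847.0, 0.0163, 3.0, 10.0, sched)
            assert np.all(np.diff(prof) <= 1e-9)

    def test_bm_matches_carver_richards_at_study_regime(self):
        for sched in (cpmg_schedule_600(), cpmg_schedule_800()):
            bm = simulate_bm(847.0, 0.0163, 3.0, 12.0, sched)
            cr = carver_richards(847.0, 0.0163, 3.0, 12.0, sched)
            assert np.max(np.abs(bm - cr) / np.abs(bm)) < 0.01

    def test_carver_richards_fast_exchange_is_luz_meiboom(self):
        sched = cpmg_schedule_800()
        kex, pb, dw = 20000.0, 0.05, 1.0
        dw_rad = dw * dw_rad_per_ppm(800.0)
        lm = 10.0 + luz_meiboom_rex(sched.nu_hz, kex,
                                    (1 - pb) * pb * dw_rad**2)
        cr = carver_richards(kex, pb, dw, 10.0, sched)
        assert np.max(np.abs(lm - cr) / lm) < 0.01

    def test_refocusing_limit_approaches_baseline(self):
        sched = cpmg_schedule_800()
        prof = carver_richards(2000.0, 0.02, 2.0, 10.0, sched)
        assert prof[-1] - 10.0 < 0.2 * (prof[0] - 10.0)


class TestGlobalFit:
    def _fixture(self, n_residues, truth_seed, noise_seed, noise):
        truth = default_exchange_truth(truth_seed, n_residues=n_residues)
        profs = gen_dispersion_dataset(truth, seed=noise_seed,
                                       noise_floor=noise)
        for p in profs:
            estimate_sigma(p)
        return truth, profs

    def test_noiseless_recovery_exact(self):
        truth, profs = self._fixture(6, 5, 5, 0.0)
        model = fit_global_two_state(profs)
        assert model.kex == pytest.approx(truth.kex, rel=1e-6)
        assert model.pb == pytest.approx(truth.pb, rel=1e-6)
        for rid, dw in truth.dw_ppm.items():
            assert model.dw_ppm[rid] == pytest.approx(dw, rel=1e-6)

    def test_fit_invariant_to_profile_ordering(self):
        _, profs = self._fixture(4, 21, 22, 0.02)
        m1 = fit_global_two_state(profs)
        m2 = fit_global_two_state(profs[::-1])
        assert m1.kex == pytest.approx(m2.kex, rel=1e-6)
        assert m1.pb == pytest.approx(m2.pb, rel=1e-6)

    def test_single_flat_profile_unidentifiable(self):
        sched = cpmg_schedule_800()
        rng = np.random.default_rng(8)
        nu = np.concatenate([sched.nu_hz, sched.nu_hz[[0, 7, 13]]])
        r2 = 12.0 + rng.normal(0, 0.24, nu.size)
        prof = DispersionProfile(RID, sched, nu, r2)
        estimate_sigma(prof)
        model = fit_global_two_state([prof])
        assert "pB-unidentifiable" in model.flags

    def test_sigma_required(self):
        sched = cpmg_schedule_800()
        prof = DispersionProfile(RID, sched, sched.nu_hz,
                                 np.full(sched.nu_hz.size, 12.0))
        with pytest.raises(ValueError, match="sigma"):
            fit_global_two_state([prof])


class TestScreen:
    def test_flat_profile_excluded_dispersing_kept(self):
        truth, profs = TestGlobalFit()._fixture(3, 21, 22, 0.02)
        sched = cpmg_schedule_800()
        rng = np.random.default_rng(3)
        nu = np.concatenate([sched.nu_hz, sched.nu_hz[[0, 7, 13]]])
        flat = DispersionProfile(
            ResidueID(99, "A"), sched, nu, 12.0 + rng.normal(0, 0.24, nu.size)
        )
        kept, log = screen_significant(profs + [flat])
        kept_res = {p.residue.number for p in kept}
        assert kept_res == {r.number for r in truth.dw_ppm}
        assert any(r.number == 99 for r, _ in log)

    def test_amplitude_boundary_is_inclusive(self):
        # construct a two-point-step profile with amplitude exactly
        # 3x the median sigma: must not be excluded by the amplitude rule
        sched = cpmg_schedule_800()
        base = np.full(sched.nu_hz.size, 10.0)
        base[: sched.nu_hz.size // 2] += 0.75   # amplitude exactly 3 sigma
        prof = DispersionProfile(RID, sched, sched.nu_hz, base,
                                 sigma=np.full(base.size, 0.25))
        kept, log = screen_significant([prof], alpha=1.0 - 1e-12)
        assert not any("amplitude" in msg for _, msg in log)


class TestRandomCoilRMSD:
    def test_identical_sets_zero(self):
        dw = {ResidueID(i, "A"): 2.0 for i in range(5)}
        assert rmsd_vs_random_coil(dw, dict(dw)) == 0.0

    def test_constant_offset(self):
        dw = {ResidueID(i, "A"): 2.0 for i in range(8)}
        rc = {ResidueID(i, "A"): 1.0 for i in range(8)}
        assert rmsd_vs_random_coil(dw, rc) == pytest.approx(1.0)

    def test_empty_intersection_raises(self):
        with pytest.raises(ValueError):
            rmsd_vs_random_coil({ResidueID(1, "A"): 1.0},
                                {ResidueID(2, "A"): 1.0})
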