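"""Diffusion tensor and Lipari-Szabo model-free analysis."""

import numpy as np
import pytest

from spindyn.diffusion_modelfree import (
    DiffusionTensor,
    TensorFitError,
    correlation_times,
    filter_rigid_residues,
    fit_diffusion_tensor,
    fit_modelfree,
    predict_rates,
    spectral_density,
)
from spindyn.io_tables import ResidueID
from spindyn.relaxation import RelaxationRecord, SpinLockSetup, extract_rates
from spindyn.synthetic_data import (
    TENSOR_DEFAULT,
    default_relaxation_truth,
    gen_relaxation_dataset,
)

Z = np.array([0.0, 0.0, 1.0])


def make_records(n, r1=0.8, r2=20.0, noe=0.8):
    return [
        RelaxationRecord(ResidueID(i, "A"), 800.0, r1=r1, r1_err=0.01,
                         r2=r2, r2_err=0.4, noe=noe, noe_err=0.02)
        for i in range(1, n + 1)
    ]


class TestCorrelationTimes:
    def test_oblate_tensor_autocorrelation_times(self):
        ct = correlation_times(TENSOR_DEFAULT)
        assert ct["tau_a"] * 1e9 == pytest.approx(12.0, abs=0.05)
        assert ct["tau_b"] * 1e9 == pytest.approx(12.1, abs=0.05)
        assert ct["tau_iso"] * 1e9 == pytest.approx(12.3, abs=0.05)

    def test_isotropic_inverse_identity(self):
        t = DiffusionTensor.isotropic(1.0 / (6.0 * 10e-9))
        ct = correlation_times(t)
        for v in ct.values():
            assert v == pytest.approx(10e-9, rel=1e-14)

    def test_axial_reduces_to_isotropic_when_degenerate(self):
        d = 1.5e7
        ct = correlation_times(DiffusionTensor.axial(d, d))
        assert ct["tau_a"] == ct["tau_iso"]
        assert ct["tau_b"] == pytest.approx(ct["tau_iso"], rel=1e-14)
        assert ct["tau_c"] == pytest.approx(ct["tau_iso"], rel=1e-14)

    def test_oblate_flag(self):
        assert TENSOR_DEFAULT.is_oblate
        assert not DiffusionTensor.axial(2e7, 1.5e7).is_oblate


class TestRigidFilter:
    def test_low_noe_excluded_with_reason(self):
        recs = make_records(12)
        recs[0].noe = 0.5
        kept, log = filter_rigid_residues(recs)
        reasons = dict((r.number, msg) for r, msg in log)
        assert 1 in reasons and "NOE" in reasons[1]
        assert all(r.residue.number != 1 for r in kept)

    def test_identical_ratios_none_excluded_by_ratio_rule(self):
        kept, log = filter_rigid_residues(make_records(12))
        assert len(kept) == 12 and log == []

    def test_ratio_outlier_excluded(self):
        recs = make_records(12)
        recs[3].r2 = 20.0 * 1.2   # ratio 1.2x the mean
        kept, log = filter_rigid_residues(recs)
        assert any(r.number == 4 and "R2/R1" in msg for r, msg in log)

    def test_mean_recomputed_after_noe_exclusion(self):
        # a mobile residue with an extreme ratio must not drag the mean
        recs = make_records(12)
        recs[0].noe = 0.3
        recs[0].r2 = 60.0
        kept, _ = filter_rigid_residues(recs)
        assert len(kept) == 11

    def test_too_few_survivors_refused(self):
        with pytest.raises(TensorFitError):
            filter_rigid_residues(make_records(5))


class TestPredictRates:
    def test_rigid_limit_and_noe_maximal(self):
        rigid = predict_rates(TENSOR_DEFAULT, Z, 800.0)
        moving = predict_rates(TENSOR_DEFAULT, Z, 800.0, s2=0.85,
                               tau_e=50e-12)
        assert 0 < rigid["NOE"] < 1
        assert moving["NOE"] < rigid["NOE"]

    def test_rates_decrease_with_s2_at_slow_tumbling(self):
        r1 = predict_rates(TENSOR_DEFAULT, Z, 800.0, s2=1.0)
        r085 = predict_rates(TENSOR_DEFAULT, Z, 800.0, s2=0.85)
        assert r085["R1"] < r1["R1"]
        assert r085["R2"] < r1["R2"]

    def test_rex_adds_to_r2_only(self):
        base = predict_rates(TENSOR_DEFAULT, Z, 800.0, s2=0.9)
        with_rex = predict_rates(TENSOR_DEFAULT, Z, 800.0, s2=0.9, rex=5.0)
        assert with_rex["R2"] == pytest.approx(base["R2"] + 5.0)
        assert with_rex["R1"] == base["R1"]

    def test_isotropic_collapse_matches_single_correlation_time(self):
        tau = 12.3e-9
        t = DiffusionTensor.isotropic(1.0 / (6.0 * tau))
        omega = np.array([0.0, 1e8, 5e8])
        j = spectral_density(omega, t, Z, s2=0.85, tau_e=50e-12)
        tau_pp = 1.0 / (1.0 / tau + 1.0 / 50e-12)
        expected = 0.4 * (
            0.85 * tau / (1 + (omega * tau) ** 2)
            + 0.15 * tau_pp / (1 + (omega * tau_pp) ** 2)
        )
        np.testing.assert_allclose(j, expected, rtol=1e-12)

    def test_orientation_matters_for_axial_tensor(self):
        par = predict_rates(TENSOR_DEFAULT, Z, 800.0)
        perp = predict_rates(TENSOR_DEFAULT, np.array([1.0, 0, 0]), 800.0)
        assert par["R2"] != pytest.approx(perp["R2"], rel=1e-4)


class TestTensorFit:
    def _ratios(self, tensor, rng, n=30, noise=0.0):
        nh, ratios = {}, {}
        for i in range(n):
            rid = ResidueID(10 + i, "A")
            v = rng.normal(size=3)
            v /= np.linalg.norm(v)
            nh[rid] = v
            r = predict_rates(tensor, v, 800.0)
            ratio = r["R2"] / r["R1"]
            ratios[rid] = (ratio * (1 + rng.normal(0, noise)),
                           max(ratio * noise, 1e-3))
        return ratios, nh

    def test_isotropic_truth_gives_unit_anisotropy(self):
        rng = np.random.default_rng(2)
        ratios, nh = self._ratios(DiffusionTensor.isotropic(1.36e7), rng)
        fit = fit_diffusion_tensor(ratios, nh, 800.0)
        assert fit.axial.d_par / fit.axial.d_perp == pytest.approx(1.0,
                                                                   abs=0.01)

    def test_oblate_recovery_within_two_percent_at_two_percent_noise(self):
        rng = np.random.default_rng(11)
        truth = DiffusionTensor.axial(1.30e7, 1.39e7, (0.9, 2.3))
        ratios, nh = self._ratios(truth, rng, n=40, noise=0.02)
        fit = fit_diffusion_tensor(ratios, nh, 800.0)
        assert fit.axial.d_par == pytest.approx(1.30e7, rel=0.02)
        assert fit.axial.d_perp == pytest.approx(1.39e7, rel=0.02)
        assert fit.chi2_axial < fit.chi2_isotropic

    def test_two_residues_refused(self):
        rng = np.random.default_rng(3)
        ratios, nh = self._ratios(TENSOR_DEFAULT, rng, n=2)
        with pytest.raises(TensorFitError):
            fit_diffusion_tensor(ratios, nh, 800.0)


class TestModelFree:
    def test_noiseless_closed_loop_recovers_parameters(self):
        """predict_rates -> fit_modelfree round trip on noiseless data."""
        truth = default_relaxation_truth(3, n_residues=12)
        ir, sl, noe, _ = gen_relaxation_dataset(truth, noise_pct=0.0)
        recs = extract_rates(ir, sl, noe, 800.0, SpinLockSetup(2020.0),
                             offsets_hz={})
        params = fit_modelfree(recs, truth.tensor, truth.nh_vectors, n_mc=0)
        assert len(params) == 12
        for p in params:
            s2_t, tau_t, rex_t = truth.params[p.residue]
            assert p.s2 == pytest.approx(s2_t, rel=1e-3)
            assert p.tau_e == pytest.approx(tau_t, rel=1e-3)
            assert p.rex == pytest.approx(rex_t, rel=1e-3, abs=1e-3)

    def test_rex_recovered_within_twenty_percent_at_two_percent_noise(self):
        truth = default_relaxation_truth(5, n_residues=12)
        # residues 24..27 of this truth carry Rex in 3-8/s
        ir, sl, noe, _ = gen_relaxation_dataset(truth, noise_pct=2.0, seed=5)
        recs = extract_rates(ir, sl, noe, 800.0, SpinLockSetup(2020.0),
                             offsets_hz={})
        params = {p.residue: p for p in
                  fit_modelfree(recs, truth.tensor, truth.nh_vectors, n_mc=0)}
        rex_residues = [r for r, (s, t, x) in truth.params.items() if x > 0]
        hits = 0
        for rid in rex_residues:
            p = params[rid]
            if p.rex > 0 and abs(p.rex - truth.params[rid][2]) \
                    <= 0.2 * truth.params[rid][2]:
                hits += 1
        assert hits >= len(rex_residues) - 1

    def test_noiseless_rigid_residue_hits_s2_boundary(self):
        rid = ResidueID(30, "A")
        r = predict_rates(TENSOR_DEFAULT, Z, 800.0)   # S2 = 1 exactly
        rec = RelaxationRecord(rid, 800.0, r1=r["R1"], r1_err=1e-3,
                               r2=r["R2"], r2_err=1e-2, noe=r["NOE"],
                               noe_err=1e-3)
        (p,) = fit_modelfree([rec], TENSOR_DEFAULT, {rid: Z}, n_mc=0)
        assert p.s2 == pytest.approx(1.0, abs=1e-4)
        assert "boundary" in p.flags

    def test_monte_carlo_errors_are_seed_deterministic(self):
        rid = ResidueID(30, "A")
        r = predict_rates(TENSOR_DEFAULT, Z, 800.0, s2=0.85, tau_e=30e-12)
        rec = RelaxationRecord(rid, 800.0, r1=r["R1"], r1_err=0.02,
                               r2=r["R2"], r2_err=0.4, noe=r["NOE"],
                               noe_err=0.02)
        p1 = fit_modelfree([rec], TENSOR_DEFAULT, {rid: Z}, n_mc=25, seed=9)
        p2 = fit_modelfree([rec], TENSOR_DEFAULT, {rid: Z}, n_mc=25, seed=9)
        assert p1[0].s2_err == p2[0].s2_err > 0
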