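import numpy as np
import pytest

from renalivive import simulate
from renalivive.binding import predict_fu
from renalivive.domain import PhysiologyConstants
from renalivive.fdmodel import fd_predict_R
from renalivive.ivive import ScalerSet


class TestDeterminism:
    def test_same_seed_same_panel(self):
        a = simulate.generate_panel(simulate.paper_like_truth(seed=5))
        b = simulate.generate_panel(simulate.paper_like_truth(seed=5))
        for ta, tb in zip(a.timecourses, b.timecourses):
            assert ta.points == tb.points
        for ba, bb in zip(a.binding, b.binding):
            assert ba.fu_replicates == bb.fu_replicates

    def test_different_seeds_differ(self):
        a = simulate.generate_panel(simulate.paper_like_truth(seed=5))
        b = simulate.generate_panel(simulate.paper_like_truth(seed=6))
        assert a.timecourses[0].points != b.timecourses[0].points


class TestNoiseFreeConsistency:
    def test_prenoise_outputs_satisfy_models_exactly(self, noiseless_panel):
        truth = noiseless_panel.truth
        for bm in noiseless_panel.binding:
            expected = predict_fu(truth.kd[bm.substrate],
                                  bm.condition.molar_conc)
            assert abs(bm.fu_mean - expected) < 1e-12
        for tc in noiseless_panel.timecourses:
            if tc.condition == "probenecid":
                slope = truth.clint_passive[tc.substrate] * tc.unbound_conc
            else:
                pct = {"control": 0.0, "hsa_1pct": 1.0, "hsa_4pct": 4.0}[tc.condition]
                from renalivive.domain import albumin_molar
                slope = truth.clint_total(tc.substrate,
                                          albumin_molar(pct)) * tc.unbound_conc
            for t, amt in tc.points:
                assert abs(amt - slope * t) < 1e-9

    def test_ratio_structure_matches_reduced_model(self, noiseless_panel):
        truth = noiseless_panel.truth
        from renalivive.domain import albumin_molar
        for sub in truth.substrates:
            r = (truth.clint_total(sub, albumin_molar(4.0))
                 - truth.clint_passive[sub]) / truth.clint_active_free[sub]
            expected = fd_predict_R(truth.efd, truth.kdm, truth.kd[sub],
                                    albumin_molar(4.0))
            assert r == pytest.approx(expected, rel=1e-12)


class TestValidation:
    def test_bad_replicate_count(self):
        truth = simulate.paper_like_truth(seed=1)
        with pytest.raises(ValueError):
            simulate.generate_panel(truth, n_replicates=0)

    def test_no_albumin_levels(self):
        truth = simulate.paper_like_truth(seed=1)
        with pytest.raises(ValueError):
            simulate.generate_panel(truth, albumin_levels_pct=())

    def test_non_positive_truth_rejected(self):
        with pytest.raises(ValueError):
            simulate.TruthRecord("OAT3", ["a"], {"a": 0.0}, {"a": 1.0},
                                 {"a": 0.1}, efd=500.0, kdm=500.0)


class TestClinicalRefs:
    def test_zero_noise_round_trip_gives_unity_fold_errors(self):
        from renalivive.ivive import predict_renal_clearance
        from renalivive.domain import albumin_molar
        truth = simulate.paper_like_truth(seed=9, uptake_cv=0.0,
                                          fu_noise_sd=0.0)
        phys = PhysiologyConstants()
        scaler = ScalerSet("OAT3", 10.0, 1.0, 10.0, 1.0)
        observed = simulate.generate_clinical_refs(truth, phys, scaler)
        for sub in truth.substrates:
            fu_p = predict_fu(truth.kd[sub], albumin_molar(4.0))
            clint = truth.clint_active_free[sub] * fd_predict_R(
                truth.efd, truth.kdm, truth.kd[sub], albumin_molar(4.0))
            pred = predict_renal_clearance(sub, {"OAT3": clint},
                                           {"OAT3": scaler}, fu_p, phys,
                                           fu_b=fu_p)
            assert pred.cl_r == pytest.approx(observed[sub], rel=1e-12)

    def test_gmfe_approaches_noise_magnitude(self):
        """Lognormal noise of SD log10(2) drives GMFE toward 2 for large n."""
        from renalivive.metrics import fold_errors, gmfe
        truth = simulate.paper_like_truth(seed=3, n_substrates=5,
                                          uptake_cv=0.0, fu_noise_sd=0.0)
        clean = simulate.generate_clinical_refs(truth, noise_sd_log10=0.0)
        rng = np.random.default_rng(77)
        sigma = np.log10(2.0)
        n = 1000
        fes = []
        for _ in range(n):
            for sub, clr in clean.items():
                noisy = clr * 10 ** rng.normal(0, sigma)
                fes.append(clr / noisy)
        g = gmfe(np.array(fes))
        # E|log10 FE| = sigma * sqrt(2/pi); GMFE -> 10^that ~ 1.74 for sigma=log10(2)
        expected = 10 ** (sigma * np.sqrt(2 / np.pi))
        assert g == pytest.approx(expected, rel=0.05)


class TestRecoveryStudySmoke:
    def test_small_recovery_study_runs_and_is_unbiased(self):
        res = simulate.fd_recovery_study(n_sim=20, seed=100)
        assert res["median_rel_err_efd"] < 0.35
        assert res["median_rel_err_kdm"] < 0.5
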