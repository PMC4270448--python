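"""Parameter estimation: recovery, identifiability, comparison, bootstrap."""

import numpy as np
import pytest

from junctionfit import (
    BindingModel,
    BindingTitration,
    CleavageModel,
    CruciformModel,
    DomainError,
    NoSignalError,
    ProgressCurve,
    UnidentifiableError,
    compare_models,
    fit_binding,
    fit_cruciform,
    fit_exponential,
    simulate_cleavage_course,
    simulate_cruciform_course,
    simulate_titration,
)


class TestFitExponential:
    @pytest.mark.parametrize("kc_true", [0.008, 0.01])
    def test_noiseless_recovery(self, kc_true):
        curve = simulate_cleavage_course(Ff=1.0, kc=kc_true, noise_sd=0)
        res = fit_exponential(curve)
        assert res.kc == pytest.approx(kc_true, rel=1e-3)
        assert res.Ff == pytest.approx(1.0, rel=1e-3)
        assert res.converged

    def test_partial_amplitude_recovery(self):
        curve = simulate_cleavage_course(Ff=0.85, kc=0.01, noise_sd=0)
        res = fit_exponential(curve)
        assert res.Ff == pytest.approx(0.85, rel=1e-3)
        assert res.kc == pytest.approx(0.01, rel=1e-3)

    def test_amplitude_rate_separability(self):
        base = simulate_cleavage_course(Ff=1.0, kc=0.008, noise_sd=0)
        res0 = fit_exponential(base)
        halved = ProgressCurve(times=base.times, F=0.5 * base.F, time_unit="s")
        res1 = fit_exponential(halved)
        assert res1.Ff == pytest.approx(0.5 * res0.Ff, rel=1e-6)
        assert res1.kc == pytest.approx(res0.kc, rel=1e-6)

    def test_flat_data_rejected(self):
        with pytest.raises(NoSignalError):
            fit_exponential(ProgressCurve(times=[0, 1, 2, 3, 4], F=[0, 0, 0, 0, 0]))
        with pytest.raises(NoSignalError):
            fit_exponential(
                ProgressCurve(times=[0, 1, 2, 3, 4], F=[0.4, 0.4, 0.4, 0.4, 0.4])
            )

    def test_too_few_points_rejected(self):
        with pytest.raises(DomainError):
            CleavageModel(ProgressCurve(times=[0, 1, 2], F=[0, 0.1, 0.2]))


class TestFitCruciform:
    def test_noiseless_recovery_at_reported_rates(self):
        traj = simulate_cruciform_course(k1=0.019, k2=0.20, noise_sd=0)
        res = fit_cruciform(traj)
        assert res.k1 == pytest.approx(0.019, rel=1e-3)
        assert res.k2 == pytest.approx(0.20, rel=1e-3)
        assert round(res.acceleration) == 11

    def test_degenerate_rates_recovered_via_limit_branch(self):
        traj = simulate_cruciform_course(k1=0.05, k2=0.05, noise_sd=0)
        res = fit_cruciform(traj)
        assert res.k1 == pytest.approx(0.05, rel=1e-3)
        assert res.k2 == pytest.approx(0.05, rel=1e-3)

    def test_label_swap_start_converges_to_same_rates(self):
        traj = simulate_cruciform_course(noise_sd=0)
        res = fit_cruciform(traj, start=(0.20, 0.019))
        assert res.k1 == pytest.approx(0.019, rel=1e-6)
        assert res.k2 == pytest.approx(0.20, rel=1e-6)

    def test_sequential_mode_matches_joint_on_noiseless_data(self):
        traj = simulate_cruciform_course(noise_sd=0)
        joint = fit_cruciform(traj, mode="joint")
        seq = fit_cruciform(traj, mode="sequential")
        assert seq.k1 == pytest.approx(joint.k1, rel=1e-6)
        assert seq.k2 == pytest.approx(joint.k2, rel=1e-6)
        assert seq.method == "sequential"

    def test_rss_reproducible_from_estimates(self):
        traj = simulate_cruciform_course(noise_sd=0.03, seed=11)
        res = fit_cruciform(traj)
        recomputed = float(np.sum(res.resid() ** 2))
        assert recomputed == pytest.approx(res.rss, rel=1e-10)

    def test_too_few_points_rejected(self):
        traj = simulate_cruciform_course(times=[0, 10, 30, 60], noise_sd=0)
        with pytest.raises(DomainError):
            CruciformModel(traj)


class TestFitBinding:
    def test_noiseless_kd_recovery_on_study_design(self):
        titr = simulate_titration(Kd=10.0, noise_sd=0)
        res = fit_binding(titr, model="two_state")
        assert res.Kd == pytest.approx(10.0, rel=1e-3)

    def test_hill_recovery(self):
        titr = simulate_titration(model="hill", K_app=100.0, n=2.0, noise_sd=0)
        res = fit_binding(titr, model="hill")
        assert res.K_app == pytest.approx(100.0, rel=1e-3)
        assert res.n == pytest.approx(2.0, rel=1e-3)
        assert res.half_saturation == pytest.approx(10.0, rel=1e-3)

    def test_two_state_misfit_of_cooperative_data_has_larger_rss(self):
        titr = simulate_titration(model="hill", K_app=100.0, n=2.0, noise_sd=0)
        rss_ts = fit_binding(titr, model="two_state").rss
        rss_h = fit_binding(titr, model="hill").rss
        assert rss_ts > rss_h

    @pytest.mark.parametrize("fb_value", [0.0, 1.0])
    def test_flat_titrations_unidentifiable(self, fb_value):
        titr = BindingTitration(
            Pt=np.geomspace(0.043, 44, 11), fb=np.full(11, fb_value), Dt=0.082
        )
        with pytest.raises(UnidentifiableError):
            fit_binding(titr)

    def test_stoichiometry_convention_is_preserved(self):
        titr = simulate_titration(Kd=10.0, noise_sd=0, stoichiometry="monomer")
        assert titr.stoichiometry == "monomer"
        with pytest.raises(DomainError):
            BindingTitration(Pt=[1, 2, 3], fb=[0.1, 0.2, 0.3], Dt=0.082,
                             stoichiometry="trimer")


class TestCompareModels:
    def test_identical_models_tie(self):
        titr = simulate_titration(Kd=10.0, noise_sd=0.03, seed=4)
        a = fit_binding(titr, model="two_state")
        b = fit_binding(titr, model="two_state")
        cmp = compare_models(a, b)
        assert cmp.preferred == "tie"
        assert cmp.delta_rss == pytest.approx(0.0, abs=1e-12)

    def test_mismatched_data_rejected(self):
        a = fit_binding(simulate_titration(Kd=10.0, noise_sd=0.03, seed=1))
        b = fit_binding(simulate_titration(Kd=10.0, noise_sd=0.03, seed=2))
        with pytest.raises(DomainError):
            compare_models(a, b)

    def test_cooperative_data_prefer_hill(self):
        # 200 seeded replicates of strongly cooperative (n=2) titrations
        wins = 0
        for seed in range(200):
            titr = simulate_titration(
                model="hill", K_app=100.0, n=2.0, noise_sd=0.03, seed=seed
            )
            ts = fit_binding(titr, model="two_state")
            hill = fit_binding(titr, model="hill")
            if compare_models(ts, hill).preferred == "B":
                wins += 1
        assert wins >= 190  # >= 95% of replicates

    def test_noncooperative_data_prefer_two_state(self):
        wins = 0
        for seed in range(200):
            titr = simulate_titration(Kd=10.0, noise_sd=0.03, seed=10_000 + seed)
            ts = fit_binding(titr, model="two_state")
            hill = fit_binding(titr, model="hill")
            if compare_models(ts, hill).preferred == "A":
                wins += 1
        assert wins > 100  # parsimony penalty favors the 1-parameter model


class TestBootstrap:
    def test_deterministic_under_seed(self):
        res = fit_binding(simulate_titration(Kd=10.0, noise_sd=0.03, seed=42))
        ci1 = res.bootstrap_ci(n_boot=200, seed=9)
        ci2 = res.bootstrap_ci(n_boot=200, seed=9)
        assert ci1 == ci2
        assert res.boot_seed == 9

    def test_intervals_contain_point_estimate(self):
        res = fit_binding(simulate_titration(Kd=10.0, noise_sd=0.03, seed=7))
        ci = res.bootstrap_ci(n_boot=200, seed=3)
        lo, hi = ci["Kd"]
        assert lo - 1e-9 <= res.Kd <= hi + 1e-9

    def test_noiseless_intervals_collapse(self):
        res = fit_exponential(simulate_cleavage_course(kc=0.008, noise_sd=0))
        ci = res.bootstrap_ci(n_boot=100, seed=0)
        for lo, hi in ci.values():
            assert hi - lo < 1e-4

    def test_minimum_replicates_enforced(self):
        res = fit_binding(simulate_titration(Kd=10.0, noise_sd=0.03, seed=1))
        with pytest.raises(DomainError):
            res.bootstrap_ci(n_boot=50)

    def test_coverage_near_nominal(self):
        # Residual-resampling percentile intervals on the 11-point study
        # design: coverage is close to the nominal 95% but a few percent
        # low, as expected when clipped, mildly heteroscedastic noise at
        # n=11 violates the i.i.d.-residual assumption.
        hits = 0
        for i in range(200):
            titr = simulate_titration(Kd=10.0, noise_sd=0.03, seed=5000 + i)
            res = fit_binding(titr)
            lo, hi = res.bootstrap_ci(n_boot=200, seed=77)["Kd"]
            if lo <= 10.0 <= hi:
                hits += 1
        assert 0.85 <= hits / 200 <= 1.0


class TestSummaryAndDiagnostics:
    def test_summary_lists_parameters_and_diagnostics(self):
        res = fit_cruciform(simulate_cruciform_course(noise_sd=0.03, seed=2))
        text = res.summary()
        for token in ("k1", "k2", "RSS", "AICc", "converged"):
            assert token in text

    def test_to_dict_round_trips_through_json(self):
        import json

        res = fit_binding(simulate_titration(Kd=10.0, noise_sd=0.03, seed=5))
        res.bootstrap_ci(n_boot=100, seed=1)
        rec = json.loads(json.dumps(res.to_dict()))
        assert rec["params"]["Kd"] == pytest.approx(res.Kd)
        assert "conf_int" in rec

    def test_standard_errors_positive_on_noisy_fit(self):
        res = fit_cruciform(simulate_cruciform_course(noise_sd=0.03, seed=3))
        assert res.bse["k1"] > 0
        assert res.bse["k2"] > 0
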