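"""Model qualification: CWRES calibration, VPC self-consistency, bootstrap
summaries and individual profile curves."""
import math

import numpy as np
import pytest

import clozapk as cz

from _oracles import fit_result_at


class TestGof:
    def test_cwres_calibrated_on_self_simulated_data(self, final_pop):
        ds = cz.simulate_dataset(
            final_pop, cz.enriched_design(n_subjects=150, p_zop=0.25, seed=31)
        )
        fr = fit_result_at(ds, final_pop)
        tab = cz.gof(ds, fr)
        n = len(tab)
        assert n == ds.n_obs
        assert abs(tab["cwres"].mean()) < 3.0 / math.sqrt(n)
        assert abs(tab["cwres"].std() - 1.0) < 3.0 / math.sqrt(2 * n)
        assert np.isfinite(tab["cwres"]).all()

    def test_noise_free_data_has_zero_residuals(self, final_pop):
        pop = final_pop.with_(omega_cl=0.0, sigma_prop=1e-10)
        ds = cz.simulate_dataset(pop, cz.enriched_design(n_subjects=4, seed=2))
        fr = fit_result_at(ds, pop)
        tab = cz.gof(ds, fr)
        assert tab["pred"].to_numpy() == pytest.approx(tab["dv"].to_numpy(), rel=1e-6)
        assert tab["ipred"].to_numpy() == pytest.approx(tab["dv"].to_numpy(), rel=1e-6)

    def test_single_observation_without_iiv_reduces_to_z_score(self, final_pop):
        pop = final_pop.with_(omega_cl=1e-13)
        ds = cz.simulate_dataset(pop, cz.DesignSpec(n_subjects=1, n_trough_obs=1, seed=6))
        fr = fit_result_at(ds, pop)
        tab = cz.gof(ds, fr)
        row = tab.iloc[0]
        expected = (row["dv"] - row["pred"]) / (pop.sigma_prop * row["pred"])
        assert row["cwres"] == pytest.approx(expected, rel=1e-4)


class TestVpc:
    def test_self_consistency_calibration(self, final_pop):
        # observed percentiles of data simulated from the same model should
        # sit inside their simulated 95% bands in nearly all bins
        inside = total = 0
        for seed in range(10):
            ds = cz.simulate_dataset(
                final_pop, cz.enriched_design(n_subjects=60, p_zop=0.2, seed=200 + seed)
            )
            fr = fit_result_at(ds, final_pop)
            summary = cz.vpc(ds, fr, n_sim=200, seed=seed)
            for _, row in summary.table.iterrows():
                for p in summary.percentiles:
                    total += 1
                    if row[f"sim_lo_p{p:g}"] <= row[f"obs_p{p:g}"] <= row[f"sim_hi_p{p:g}"]:
                        inside += 1
        assert inside / total >= 0.90

    def test_single_simulation_degenerates_to_point_bands(self, small_dataset, final_pop):
        fr = fit_result_at(small_dataset, final_pop)
        summary = cz.vpc(small_dataset, fr, n_sim=1, seed=3)
        for p in summary.percentiles:
            assert (
                summary.table[f"sim_lo_p{p:g}"].to_numpy()
                == pytest.approx(summary.table[f"sim_hi_p{p:g}"].to_numpy())
            )

    def test_seed_determinism(self, small_dataset, final_pop):
        fr = fit_result_at(small_dataset, final_pop)
        a = cz.vpc(small_dataset, fr, n_sim=50, seed=9).table
        b = cz.vpc(small_dataset, fr, n_sim=50, seed=9).table
        assert a.equals(b)

    def test_small_bins_flagged(self, final_pop):
        ds = cz.simulate_dataset(final_pop, cz.DesignSpec(n_subjects=2, n_trough_obs=2, seed=1))
        fr = fit_result_at(ds, final_pop)
        summary = cz.vpc(ds, fr, n_sim=20, seed=0)
        assert summary.flagged_bins  # 2 observations per time point


class TestBootstrap:
    @pytest.mark.parametrize(
        "estimate, median, expected",
        [
            (29.6, 29.4, -0.68),
            (308.0, 309.0, 0.32),
            (-0.254, -0.241, -5.12),
            (0.348, 0.342, -1.72),
            (0.257, 0.254, -1.17),
        ],
    )
    def test_bias_formula_reproduces_published_cells(self, estimate, median, expected):
        assert round(cz.bias_pct(estimate, median), 2) == expected

    def test_cloned_subjects_give_degenerate_intervals(self, final_pop):
        base = cz.simulate_dataset(final_pop, cz.DesignSpec(n_subjects=1, n_trough_obs=3, seed=44))
        s = base.subjects[0]
        clones = cz.Dataset(
            [cz.SubjectRecord(f"C{k}", s.cov, list(s.doses), list(s.obs)) for k in range(4)]
        )
        init = final_pop.with_(cl_std=20.0, theta_zop=0.0)
        fixed = ("ka", "theta_zop", "v_std")
        orig = cz.fit(clones, init=init, fixed=fixed, compute_se=False)
        bs = cz.bootstrap(clones, n_rep=200, seed=1, fixed=fixed, original=orig)
        # every resample contains the same information, so the refits
        # coincide with the original and the CIs collapse
        for _, row in bs.table.iterrows():
            assert row["ci_hi"] - row["ci_lo"] == pytest.approx(0.0, abs=1e-4 * abs(row["estimate"]))
            assert row["median"] == pytest.approx(row["estimate"], rel=1e-4)

    def test_minimum_replicates_enforced(self, small_dataset, final_pop):
        with pytest.raises(ValueError):
            cz.bootstrap(small_dataset, init=final_pop, n_rep=50)

    def test_ci_covers_truth_across_recovery_studies(self, final_pop):
        # 20 small seeded recovery studies; the percentile CI for the
        # reference clearance should cover the generating value ~95% of the
        # time (loose 85-100% band)
        truth = final_pop.cl_std
        fixed = ("ka", "theta_zop", "v_std")
        init = final_pop.with_(cl_std=22.0, theta_zop=0.0, omega_cl=0.3, sigma_prop=0.2)
        covered = 0
        for k in range(20):
            ds = cz.simulate_dataset(
                final_pop, cz.DesignSpec(n_subjects=30, n_trough_obs=2, p_zop=0.0, seed=500 + k)
            )
            orig = cz.fit(ds, init=init, fixed=fixed, compute_se=False)
            assert orig.converged
            bs = cz.bootstrap(ds, n_rep=200, seed=k, fixed=fixed, original=orig)
            row = bs.table.set_index("parameter").loc["cl_std"]
            if row["ci_lo"] <= truth <= row["ci_hi"]:
                covered += 1
        assert 17 <= covered <= 20


class TestIndividualProfiles:
    def test_noise_free_curve_passes_through_observations(self, final_pop):
        pop = final_pop.with_(omega_cl=0.0, sigma_prop=1e-10)
        ds = cz.simulate_dataset(pop, cz.enriched_design(n_subjects=2, seed=2))
        fr = fit_result_at(ds, pop)
        prof = cz.individual_profiles(ds, fr, n_points=100)
        for s in ds.subjects:
            curve = prof[prof["id"] == s.id].set_index("time")
            for o in s.obs:
                assert curve.loc[o.time, "ipred"] == pytest.approx(o.conc, rel=1e-6)

    def test_grid_extends_one_interval_past_last_observation(self, small_dataset, final_pop):
        fr = fit_result_at(small_dataset, final_pop)
        prof = cz.individual_profiles(small_dataset, fr)
        for s in small_dataset.subjects:
            t_end = prof[prof["id"] == s.id]["time"].max()
            assert t_end == pytest.approx(max(o.time for o in s.obs) + 12.0)

    def test_high_clearance_subject_sits_below_population_curve_at_trough(self, final_pop):
        ds = cz.simulate_dataset(final_pop, cz.DesignSpec(n_subjects=20, seed=77))
        fr = fit_result_at(ds, final_pop)
        prof = cz.individual_profiles(ds, fr)
        idx = int(np.argmax(fr.ebes))
        assert fr.ebes[idx] > 0  # at least one clearly fast eliminator
        s = ds.subjects[idx]
        curve = prof[prof["id"] == s.id]
        t_tr = max(o.time for o in s.obs)
        ipred = np.interp(t_tr, curve["time"], curve["ipred"])
        pred = np.interp(t_tr, curve["time"], curve["pred"])
        assert ipred < pred
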