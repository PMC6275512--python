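"""Division likelihood and Bayesian coupling-function inference."""

import numpy as np
import pandas as pd
import pytest

from circadiv import (
    CouplingModel,
    DivisionTimeModel,
    ElongationModel,
    LightProfile,
    SizeControlParams,
    bump_coupling,
    cycle_log_likelihood,
    flat_coupling,
)
from circadiv.finestep import first_division_times


def _exp_trace(L0=3.0, rate=0.06, t0=0.0, t1=10.0, dt=0.5, cell_id=0):
    t = np.arange(t0, t1 + 1e-9, dt)
    return pd.DataFrame({"cell_id": cell_id, "time_h": t, "length_um": L0 * np.exp(rate * (t - t0))})


class TestCycleLogLikelihood:
    def test_closed_form_constant_hazard(self):
        """k=1, G=1, constant alpha: int Gamma dt = (L_div - L_birth)/lam."""
        params = SizeControlParams(a=-0.2, k=1.0, lam=4.5, sigma_zeta=0.0)
        trace = _exp_trace()
        rec = pd.Series({"cell_id": 0, "censored": 0})
        ll = cycle_log_likelihood(trace, rec, flat_coupling(1.0), params)
        L = trace["length_um"].to_numpy()
        closed = np.log((1 / 4.5) * 0.06 * L[-1]) - (L[-1] - L[0]) / 4.5
        assert ll == pytest.approx(closed, abs=1e-6)

    def test_scaling_of_coupling(self):
        """Doubling G adds log 2 to the division term and doubles the integral."""
        params = SizeControlParams(a=-0.2, k=2.0, lam=4.5, sigma_zeta=0.0)
        trace = _exp_trace()
        rec = pd.Series({"cell_id": 0, "censored": 0})
        ll1 = cycle_log_likelihood(trace, rec, flat_coupling(1.0), params)
        ll2 = cycle_log_likelihood(trace, rec, flat_coupling(2.0), params)
        L = trace["length_um"].to_numpy()
        from scipy.integrate import quad

        integral, _ = quad(
            lambda L_: (2.0 / 4.5) * max(L_ - 0.8 * L[0], 0) / 4.5, L[0], L[-1], limit=200
        )
        assert ll2 - ll1 == pytest.approx(np.log(2.0) - integral, rel=1e-3)

    def test_censored_dark_interval_contributes_zero(self):
        """A censored cell that never grows (dark) has zero hazard mass."""
        t = np.arange(0.0, 5.1, 0.5)
        trace = pd.DataFrame({"cell_id": 0, "time_h": t, "length_um": np.full(t.size, 3.0)})
        rec = pd.Series({"cell_id": 0, "censored": 1})
        params = SizeControlParams(a=0.0, k=2.0, lam=4.5)
        assert cycle_log_likelihood(trace, rec, bump_coupling(), params) == 0.0

    def test_mismatched_trace_raises(self):
        rec = pd.Series({"cell_id": 0, "censored": 0})
        with pytest.raises(ValueError):
            cycle_log_likelihood(pd.DataFrame({"cell_id": [], "time_h": [], "length_um": []}),
                                 rec, flat_coupling(1.0), SizeControlParams())

    def test_matches_fine_step_division_density(self):
        """exp(log-lik) equals the empirical division-time density of the
        brute-force simulator for a single deterministic cell."""
        params = SizeControlParams(a=-0.2, k=2.0, lam=3.0, sigma_zeta=0.0)
        profile = LightProfile(mode="constant", A=15.0)
        model = ElongationModel(alpha_bar=0.06, epsilon=0.0)
        G = bump_coupling()
        rng = np.random.default_rng(0)
        tdiv = first_division_times(
            100_000, 3.0, 1.0, 0.0, 60.0, G, model, profile, params, rng, h=2e-3
        )
        edges = np.arange(4.0, 30.0, 2.0)
        hist, _ = np.histogram(tdiv, bins=edges)
        emp_density = hist / 100_000 / 2.0
        rec = pd.Series({"cell_id": 0, "censored": 0})

        def density_at(t_div):
            t = np.arange(0.0, t_div + 1e-9, 0.01)
            trace = pd.DataFrame(
                {"cell_id": 0, "time_h": t, "length_um": 3.0 * np.exp(0.06 * t)}
            )
            return np.exp(cycle_log_likelihood(trace, rec, G, params))

        for lo, hi, d_emp in zip(edges[:-1], edges[1:], emp_density):
            if d_emp < 5e-3:
                continue
            # bin-averaged model density (the density is strongly curved
            # within a 2-h bin, so a midpoint value would not be comparable)
            pts = np.linspace(lo + 0.2, hi - 0.2, 5)
            d_model = np.mean([density_at(p) for p in pts])
            mc_sd = np.sqrt(d_emp / (100_000 * 2.0))
            assert d_model == pytest.approx(d_emp, abs=4 * mc_sd + 0.06 * d_emp)


class TestCouplingModel:
    def test_binned_loglik_consistent_with_per_cell(self, clockdel_constant, default_params):
        cells, traces = clockdel_constant
        sub = cells[cells["censored"] == 0].head(40)
        tr = traces[traces["cell_id"].isin(sub["cell_id"])]
        m = CouplingModel(sub, tr, default_params, dt_acq=0.75, time_correction="none")
        G1, G2 = flat_coupling(1.0), bump_coupling()
        binned_diff = m.log_likelihood(G2.log_values) - m.log_likelihood(np.zeros(8))
        per_cell = 0.0
        for _, rec in sub.iterrows():
            t = tr[tr["cell_id"] == rec["cell_id"]]
            per_cell += cycle_log_likelihood(t, rec, G2, default_params) - cycle_log_likelihood(
                t, rec, G1, default_params
            )
        assert binned_diff == pytest.approx(per_cell, rel=0.02, abs=0.5)

    def test_scale_identified_with_fixed_size_control(self, clockdel_constant, default_params):
        """Profile log-likelihood over a global G-scale is strictly concave."""
        cells, traces = clockdel_constant
        m = CouplingModel(cells, traces, default_params, dt_acq=0.75)
        scales = np.array([0.5, 0.8, 1.0, 1.25, 2.0])
        ll = np.array([m.log_likelihood(np.full(8, np.log(c))) for c in scales])
        i_max = np.argmax(ll)
        assert 0 < i_max < len(scales) - 1
        d2 = np.diff(np.diff(ll))
        assert np.all(d2 < 0)

    def test_null_band_contains_one(self, clockdel_constant, default_params):
        cells, traces = clockdel_constant
        post = CouplingModel(cells, traces, default_params, dt_acq=0.75).fit(
            seed=3, nwalkers=20, nsteps=600
        )
        assert post.contains(1.0).sum() >= 7

    def test_wt_recovery_single_replicate(self, wt_constant, default_params):
        cells, traces = wt_constant
        post = CouplingModel(cells, traces, default_params, dt_acq=0.75).fit(
            seed=3, nwalkers=20, nsteps=600
        )
        truth = bump_coupling()
        assert abs(post.peak_time - truth.argmax()) <= 1.0
        gt = truth(post.knot_times)
        gmap = post.map_estimate(post.knot_times)
        # shape recovered: log-coupling profiles strongly correlated, and the
        # night-time repression vs end-of-day peak contrast reproduced
        assert np.corrcoef(np.log(gmap), np.log(gt))[0, 1] > 0.95
        assert gmap[post.knot_times == 21.0][0] > 3.0 * gmap[post.knot_times == 9.0][0]
        cover = (post.ci_low <= gt) & (gt <= post.ci_high)
        assert cover.sum() >= 4
        assert post.sampler_diagnostics["acceptance_fraction"] > 0.1

    def test_no_data_returns_prior(self, default_params):
        """With zero cells the posterior equals the (proper) prior."""
        empty_cells = pd.DataFrame(
            columns=["cell_id", "censored", "birth_time_h", "division_time_h"]
        )
        empty_traces = pd.DataFrame(columns=["cell_id", "time_h", "length_um"])
        m = CouplingModel(empty_cells, empty_traces, default_params, dt_acq=0.75)
        post = m.fit(seed=1, nwalkers=20, nsteps=800)
        # prior: second differences ~ N(0, 1), mean log-level ~ N(0, 3)
        d2 = (m._D @ post.samples.T).ravel()
        assert np.std(d2) == pytest.approx(1.0, rel=0.25)
        assert abs(np.mean(post.samples)) < 1.5
        assert np.std(post.samples.mean(axis=1)) > 1.0

    def test_periodicity_by_construction(self, clockdel_constant, default_params):
        cells, traces = clockdel_constant
        post = CouplingModel(cells, traces, default_params, dt_acq=0.75).fit(
            seed=0, nwalkers=20, nsteps=200
        )
        assert post.map_estimate(0.0) == pytest.approx(post.map_estimate(24.0))


class TestDivisionTimeModel:
    @pytest.fixture(scope="class")
    def time_only_dataset(self):
        """Data generated from the division-time model itself:
        hazard h(age) * G(tau) with Weibull h."""
        rng = np.random.default_rng(8)
        G = bump_coupling()
        k_age, theta = 4.0, 14.0
        rows = []
        h_grid = 0.02
        for i in range(900):
            tb = rng.uniform(0, 72)
            age = 0.0
            while True:
                age += h_grid
                if age > 60:
                    break
                h = (k_age / theta) * (age / theta) ** (k_age - 1.0)
                lam_t = h * G((tb + age + 12.0) % 24.0)
                if rng.random() < lam_t * h_grid:
                    rows.append(
                        {
                            "cell_id": i, "lineage_id": i, "parent_id": -1,
                            "condition": "custom", "birth_time_h": tb,
                            "division_time_h": tb + age, "birth_length_um": 3.0,
                            "division_length_um": 6.0, "censored": 0,
                        }
                    )
                    break
        return pd.DataFrame(rows), G

    def test_recovers_coupling_shape(self, time_only_dataset):
        cells, G_true = time_only_dataset
        post = DivisionTimeModel(cells, time_correction="none").fit(seed=2, nwalkers=28, nsteps=900)
        # compare shapes: the division-time G is normalized to geometric mean 1
        gt = G_true(post.knot_times)
        gt_norm = gt / np.exp(np.mean(np.log(gt)))
        assert abs(post.peak_time - G_true.argmax()) <= 1.5
        cover = (post.ci_low <= gt_norm) & (gt_norm <= post.ci_high)
        assert cover.sum() >= 6

    def test_null_contains_one(self, clockdel_constant):
        cells, _ = clockdel_constant
        post = DivisionTimeModel(cells, dt_acq=0.75).fit(seed=1, nwalkers=28, nsteps=700)
        assert post.contains(1.0).sum() >= 7

    def test_wider_than_size_control_at_peak(self, wt_constant, default_params):
        """Length information narrows the posterior at the coupling peak."""
        cells, traces = wt_constant
        post_dt = DivisionTimeModel(cells, dt_acq=0.75).fit(seed=1, nwalkers=28, nsteps=700)
        post_sc = CouplingModel(cells, traces, default_params, dt_acq=0.75).fit(
            seed=1, nwalkers=20, nsteps=600
        )
        # compare relative credible widths at the knot nearest the peak
        i_peak = int(np.argmax(post_sc.map_estimate(post_sc.knot_times)))
        rel_w_dt = (post_dt.ci_high[i_peak] - post_dt.ci_low[i_peak]) / np.maximum(
            post_dt.map_estimate(post_dt.knot_times)[i_peak], 1e-9
        )
        rel_w_sc = (post_sc.ci_high[i_peak] - post_sc.ci_low[i_peak]) / np.maximum(
            post_sc.map_estimate(post_sc.knot_times)[i_peak], 1e-9
        )
        assert rel_w_dt > rel_w_sc

    def test_age_hazard_matches_marginal_durations(self):
        """With a flat coupling the fitted Weibull age hazard reproduces the
        marginal cycle-duration distribution."""
        from scipy import stats as sps

        rng = np.random.default_rng(4)
        n = 800
        ages = sps.weibull_min(3.0, scale=13.0).rvs(n, random_state=rng)
        cells = pd.DataFrame(
            {
                "cell_id": np.arange(n), "lineage_id": np.arange(n), "parent_id": -1,
                "condition": "custom", "birth_time_h": rng.uniform(0, 72, n),
                "division_time_h": 0.0, "birth_length_um": 3.0,
                "division_length_um": 6.0, "censored": 0,
            }
        )
        cells["division_time_h"] = cells["birth_time_h"] + ages
        post = DivisionTimeModel(cells, time_correction="none").fit(seed=1, nwalkers=28, nsteps=700)
        log_k, log_th = post.extra_samples.mean(axis=0)
        ks = sps.kstest(ages, sps.weibull_min(np.exp(log_k), scale=np.exp(log_th)).cdf)
        assert ks.statistic < 0.05
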