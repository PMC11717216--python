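import json

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import livertwin as lt
from livertwin.estimate import PRED_NONPOSITIVE_PENALTY, cost_function, predict_kpuu


class TestCostFunction:
    def test_perfect_fit_is_zero(self):
        assert cost_function([1.0, 0.5, 0.2], [1.0, 0.5, 0.2]) == 0.0

    def test_single_point_relative_residual(self):
        assert cost_function([1.1], [1.0]) == pytest.approx(0.01)

    @given(
        st.lists(st.floats(0.01, 10), min_size=1, max_size=20),
        st.integers(0, 2**31 - 1),
    )
    def test_matches_brute_force_sum(self, pred, seed):
        """Oracle: element-by-element python summation of squared relative residuals."""
        rng = np.random.default_rng(seed)
        pred = np.array(pred)
        obs = pred * rng.lognormal(0, 0.2, size=pred.size)
        expected = sum(((o - p) / p) ** 2 for o, p in zip(obs, pred))
        assert cost_function(obs, pred) == pytest.approx(expected, rel=1e-12)

    def test_anchor_term_added(self):
        base = cost_function([1.0], [1.0])
        with_anchor = cost_function([1.0], [1.0], kpuu_obs=2.0, kpuu_pred=1.0)
        assert base == 0.0
        assert with_anchor == pytest.approx(((2.0 - 1.0) / 1.0) ** 2)

    def test_nonpositive_prediction_penalised_finite(self, caplog):
        cost = cost_function([1.0, 1.0], [1.0, -0.1])
        assert cost == PRED_NONPOSITIVE_PENALTY
        assert np.isfinite(cost)


class TestKpuu:
    def make_traj(self, c_m, c_i, c_c, times=None):
        times = np.linspace(0, 10, len(c_m)) if times is None else times
        return lt.Trajectory(
            times=times,
            c_m=np.asarray(c_m, float),
            c_i=np.asarray(c_i, float),
            c_c=np.asarray(c_c, float),
            solver_tag="analytic",
        )

    def test_identity_case(self):
        c = np.linspace(1, 0.1, 11)
        traj = self.make_traj(c, 0.25 * c, 0.75 * c)
        assert predict_kpuu(traj, fu_cell=0.3, fu_media=0.3) == pytest.approx(1.0)

    def test_fu_ratio_scales(self):
        c = np.linspace(1, 0.1, 11)
        traj = self.make_traj(c, 0.5 * c, 0.5 * c)
        assert predict_kpuu(traj, fu_cell=0.5, fu_media=1.0) == pytest.approx(0.5)

    def test_matches_fine_grid_oracle(self, probe_params):
        """Oracle: trapezoidal AUC on a ~50x finer boundary-layer-resolving
        grid; the default simulation grid agrees to < 0.1%."""
        coarse = lt.simulation_grid(360.0)
        fine = np.unique(np.concatenate([[0.0], np.geomspace(1e-5, 360.0, 10001)]))
        kp_coarse = predict_kpuu(lt.solve_analytic(probe_params, 1e-3, coarse), 0.9, 0.5)
        kp_fine = predict_kpuu(lt.solve_analytic(probe_params, 1e-3, fine), 0.9, 0.5)
        assert kp_coarse == pytest.approx(kp_fine, rel=1e-3)

    def test_zero_media_auc_errors(self):
        traj = self.make_traj([0.0, 0.0], [1.0, 1.0], [1.0, 1.0])
        with pytest.raises(ValueError, match="media AUC"):
            predict_kpuu(traj, 1.0, 1.0)


class TestScalingFactor:
    def test_identity_and_arithmetic(self):
        assert lt.scaling_factor(1.0, 1.0) == 1.0
        assert lt.scaling_factor(2.0, 0.5) == pytest.approx(4.0)

    def test_two_d_to_human_hepatocyte_factor(self):
        """A 4.9-fold higher observed Kp_uu yields SF = 4.9."""
        assert lt.scaling_factor(4.9 * 0.37, 0.37) == pytest.approx(4.9)

    def test_rejects_non_positive(self):
        with pytest.raises(ValueError):
            lt.scaling_factor(0.0, 1.0)
        with pytest.raises(ValueError):
            lt.scaling_factor(1.0, -2.0)


@pytest.fixture(scope="module")
def noiseless_experiment(cnbio, probe_compound):
    return lt.generate_depletion(cnbio, probe_compound, cl_c=0.05, noise="none", seed=0)


@pytest.fixture(scope="module")
def anchored_fit(noiseless_experiment, cnbio, probe_compound):
    exp = noiseless_experiment
    pp = lt.compound_parameters(probe_compound, cnbio)
    kpuu = predict_kpuu(
        lt.solve_analytic(exp.params, exp.c0, lt.simulation_grid(360.0)),
        pp.fu_cell,
        probe_compound.fu_media,
    )
    return lt.fit_twin(
        exp.design.times_min,
        exp.observed_mean,
        cnbio,
        probe_compound,
        kpuu_obs=kpuu,
        c0=exp.c0,
    )


class TestFitTwin:
    def test_noiseless_recovery_within_one_percent(self, anchored_fit):
        assert anchored_fit.cl_c_hat == pytest.approx(0.05, rel=1e-2)
        assert anchored_fit.converged

    def test_trace_monotone_endpoints(self, anchored_fit):
        assert anchored_fit.trace[-1] <= anchored_fit.trace[0]
        assert anchored_fit.ssq == pytest.approx(min(anchored_fit.trace), abs=1e-12)

    def test_sf_consistent(self, anchored_fit):
        assert anchored_fit.sf == pytest.approx(
            anchored_fit.kpuu_obs / anchored_fit.kpuu_pred, rel=1e-9
        )

    def test_reproducible_for_same_seed(self, noiseless_experiment, cnbio, probe_compound):
        exp = noiseless_experiment
        opts = lt.FitOptions(seed=11, n_starts=3, kpuu_mode="none")
        fits = [
            lt.fit_twin(
                exp.design.times_min, exp.observed_mean, cnbio, probe_compound,
                c0=exp.c0, options=opts,
            )
            for _ in range(2)
        ]
        assert fits[0].cl_c_hat == fits[1].cl_c_hat
        assert fits[0].multistart_cl_c == fits[1].multistart_cl_c

    def test_kpuu_grid_mode_reports_grid(self, noiseless_experiment, cnbio, probe_compound):
        exp = noiseless_experiment
        fit = lt.fit_twin(
            exp.design.times_min, exp.observed_mean, cnbio, probe_compound,
            c0=exp.c0, options=lt.FitOptions(n_starts=2, maxiter=400),
        )
        assert fit.kpuu_grid is not None and len(fit.kpuu_grid) == 5
        assert fit.ssq == pytest.approx(min(fit.kpuu_grid.values()), abs=1e-15)
        assert fit.kpuu_obs in fit.kpuu_grid

    def test_validation_errors(self, cnbio, probe_compound):
        with pytest.raises(ValueError, match="at least 3"):
            lt.fit_twin([0, 60], [1.0, 0.5], cnbio, probe_compound)
        with pytest.raises(ValueError, match="cl_c"):
            lt.fit_twin([0, 60, 120], [1, 0.5, 0.2], cnbio, probe_compound, free_params=("sa",))
        with pytest.raises(ValueError, match="unknown free parameter"):
            lt.fit_twin([0, 60, 120], [1, 0.5, 0.2], cnbio, probe_compound, free_params=("cl_c", "x"))

    def test_low_information_fit_flags_identifiability(self, cnbio):
        """With a nearly impermeable compound the media curve carries almost no
        clearance information; the multi-start spread must trip the flag."""
        sluggish = lt.CompoundRecord(
            name="sluggish", logp=-2.0, mw=700.0, fu_media=0.05, ionisation=-1, rbp=1.0
        )
        exp = lt.generate_depletion(cnbio, sluggish, cl_c=0.01, noise="lognormal", seed=3)
        fit = lt.fit_twin(
            exp.design.times_min, exp.observed_mean, cnbio, sluggish,
            c0=exp.c0, options=lt.FitOptions(kpuu_mode="none", n_starts=5, maxiter=300),
        )
        assert fit.cv_across_starts > 0.20
        assert fit.identifiability_flagged

    def test_report_serialises(self, anchored_fit, tmp_path):
        path = tmp_path / "fit.json"
        anchored_fit.to_json(path)
        payload = json.loads(path.read_text())
        assert payload["cl_c_hat"] == anchored_fit.cl_c_hat
        assert payload["options"]["n_starts"] == 5
        assert payload["seed"] == anchored_fit.seed
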