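"""ML engine: implied covariance, exact and iterative fits, SE calibration."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import usem
from usem.fit import RamSystem, implied_covariance
from usem.model import PathParam, build_usem
from usem.prep import CohortCovariances
from usem.simulate import SimConfig

from conftest import white_config


def _covs_from_config(cfg, censor=False):
    panel = usem.simulate_panel(cfg)
    if censor:
        panel = usem.censor_spikes(panel)
    return usem.cohort_covariances(usem.build_lagged(usem.standardize(panel)))


@pytest.fixture(scope="module")
def chain3_config():
    return SimConfig(
        node_names=["A", "B", "C"],
        contemporaneous=[[0, 0, 0], [0.5, 0, 0], [0, 0.4, 0]],
        auto=[0.4, 0.4, 0.4],
        subjects_per_cohort=4,
        timepoints_per_subject=1250,
        seed=42,
    )


@pytest.fixture(scope="module")
def chain3_covs(chain3_config):
    return _covs_from_config(chain3_config)


class TestImpliedCovariance:
    def test_zero_paths_identity_residuals(self):
        m = build_usem(["A"], [])
        sys = RamSystem(m)
        sigma = implied_covariance(sys, np.array([0.0, 1.0, 1.0]))
        np.testing.assert_allclose(sigma, np.eye(2), atol=1e-14)

    def test_single_auto_path_hand_algebra(self):
        # one node, auto coefficient a, unit residuals:
        # Sigma = [[1, a], [a, 1 + a^2]]
        m = build_usem(["A"], [])
        sys = RamSystem(m)
        a = 0.7
        sigma = implied_covariance(sys, np.array([a, 1.0, 1.0]))
        np.testing.assert_allclose(sigma, [[1, a], [a, 1 + a * a]], atol=1e-14)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_symmetric_for_random_parameters(self, seed):
        rng = np.random.default_rng(seed)
        m = build_usem(["A", "B", "C"], [("A", "B"), ("B", "C"), ("A", "C")])
        sys = RamSystem(m)
        theta = np.concatenate([
            rng.uniform(-0.6, 0.6, sys.n_paths), rng.uniform(0.3, 2.0, sys.n_var)
        ])
        sigma = implied_covariance(sys, theta)
        assert np.abs(sigma - sigma.T).max() < 1e-12

    def test_unit_gain_feedback_loop_named(self):
        m = usem.UsemModel(["A", "B"], [usem.Edge("A", "B", bidirectional=True)])
        sys = RamSystem(m)
        theta = np.zeros(sys.n_params)
        for k, p in enumerate(m.paths):
            if p.kind == "contemporaneous":
                theta[k] = 1.0
        theta[sys.n_paths:] = 1.0
        with pytest.raises(ValueError, match="feedback loop"):
            implied_covariance(sys, theta)


class TestFitMl:
    def test_saturated_model_perfect_fit(self):
        covs = _covs_from_config(white_config(n_nodes=1, subjects=2, timepoints=400, seed=1))
        res = usem.fit_ml(build_usem(["R0"], []), covs)
        assert res.df == 0
        assert res.chi_square == pytest.approx(0.0, abs=1e-8)

    def test_gradient_matches_finite_differences(self, chain3_covs):
        m = build_usem(["A", "B", "C"], [("A", "B"), ("B", "C")])
        sys = RamSystem(m)
        S = chain3_covs.matrices["c1"]
        rng = np.random.default_rng(0)
        theta = np.concatenate([rng.uniform(-0.3, 0.3, sys.n_paths),
                                rng.uniform(0.5, 1.5, sys.n_var)])
        from scipy.optimize import approx_fprime
        num = approx_fprime(theta, lambda t: sys.discrepancy(t, S), 1e-7)
        assert np.abs(sys.gradient(theta, S) - num).max() < 1e-5

    def test_closed_form_equals_optimizer(self, chain3_covs):
        m = build_usem(["A", "B", "C"], [("A", "B"), ("B", "C")])
        exact = usem.fit_ml(m, chain3_covs, method="closed")
        iterated = usem.fit_ml(m, chain3_covs, method="optimize")
        assert exact.chi_square == pytest.approx(iterated.chi_square, abs=1e-6)
        np.testing.assert_allclose(exact.theta["c1"], iterated.theta["c1"], atol=1e-4)

    def test_gradient_norm_small_at_optimum(self, chain3_covs):
        m = build_usem(["A", "B", "C"], [("A", "B"), ("B", "C")])
        res = usem.fit_ml(m, chain3_covs)
        assert res.grad_norm < 1e-5

    def test_parameter_recovery_within_3_se(self, chain3_config, chain3_covs):
        """Estimates on data generated from the model itself converge to
        the generating values (consistency at large N)."""
        m = build_usem(["A", "B", "C"], [("A", "B"), ("B", "C")])
        res = usem.fit_ml(m, chain3_covs)
        Cs, Ls, a = usem.standardized_coefficients(chain3_config, 0)
        idx = {"A": 0, "B": 1, "C": 2}
        for s_, t_ in [("A", "B"), ("B", "C")]:
            p = PathParam("lagged", s_, t_)
            est = res.estimate("c1", p)
            se = res.standard_error("c1", p)
            assert abs(est - Cs[idx[t_], idx[s_]]) < 3 * se
        for node in "ABC":
            p = PathParam("auto", node, node)
            assert abs(res.estimate("c1", p) - 0.4) < 3 * res.standard_error("c1", p)

    def test_chi2_df_calibration_under_true_model(self):
        """Null-model fit to white noise: chi^2/df averages ~1 over replicates."""
        ratios = []
        m = build_usem(["R0", "R1", "R2"], [])
        for rep in range(200):
            covs = _covs_from_config(
                white_config(n_nodes=3, subjects=1, timepoints=121, seed=1000 + rep)
            )
            res = usem.fit_ml(m, covs, compute_se=False, compute_indices=False)
            ratios.append(res.chi_square / res.df)
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.1)

    def test_adding_free_path_never_increases_chi2(self, chain3_covs):
        base = build_usem(["A", "B", "C"], [("A", "B")])
        res0 = usem.fit_ml(base, chain3_covs, compute_indices=False)
        for extra in [("B", "C"), ("C", "B"), ("A", "C")]:
            res1 = usem.fit_ml(base.with_edge(usem.Edge(*extra)), chain3_covs,
                               compute_indices=False)
            assert res1.chi_square <= res0.chi_square + 1e-8
            assert res0.df - res1.df == 3

    def test_equality_constraint_nested_in_free(self):
        cfg = SimConfig(
            node_names=["A", "B"], contemporaneous=[[0, 0], [0.5, 0]],
            auto=[0.3, 0.3], n_cohorts=2, subjects_per_cohort=3,
            timepoints_per_subject=400, seed=5,
        )
        covs = _covs_from_config(cfg)
        m = build_usem(["A", "B"], [("A", "B")])
        free = usem.fit_ml(m, covs)
        equal = usem.fit_ml(m, covs, grouping="equal")
        assert equal.chi_square >= free.chi_square - 1e-8
        assert free.q - equal.q == equal.df - free.df

    def test_standard_errors_calibrated(self):
        """Reported SEs match the sampling spread of the estimator."""
        m = build_usem(["A", "B"], [("A", "B")])
        p = PathParam("lagged", "A", "B")
        ests, ses = [], []
        for rep in range(60):
            cfg = SimConfig(
                node_names=["A", "B"], contemporaneous=[[0, 0], [0.5, 0]],
                auto=[0.3, 0.3], subjects_per_cohort=1,
                timepoints_per_subject=501, seed=3000 + rep,
            )
            res = usem.fit_ml(m, _covs_from_config(cfg), compute_indices=False)
            ests.append(res.estimate("c1", p))
            ses.append(res.standard_error("c1", p))
        ratio = np.std(ests) / np.mean(ses)
        assert 0.7 < ratio < 1.4

    def test_non_pd_covariance_rejected(self):
        S = np.array([[1.0, 2.0], [2.0, 1.0]])
        covs = CohortCovariances(["A", "A_lag"], {"c1": S}, {"c1": 100})
        with pytest.raises(ValueError, match="positive definite"):
            usem.fit_ml(build_usem(["A"], []), covs)


@pytest.fixture(scope="module")
def directional_covs():
    # A -> B strong one-directional coupling, plus B -> C so the
    # feedback variant keeps positive df
    cfg = SimConfig(
        node_names=["A", "B", "C"],
        contemporaneous=[[0, 0, 0], [0.6, 0, 0], [0, 0.4, 0]],
        auto=[0.4, 0.4, 0.4], subjects_per_cohort=4,
        timepoints_per_subject=1000, seed=7,
    )
    return _covs_from_config(cfg)


@pytest.fixture(scope="module")
def directional_model():
    return build_usem(["A", "B", "C"], [("A", "B"), ("B", "C")])


class TestBidirectionalVariants:
    def test_feedback_no_worse_in_chi2(self, directional_model, directional_covs):
        out = usem.fit_bidirectional_variants(
            directional_model, directional_covs, [("A", "B")]
        )
        by_label = {v["variant"]: v for v in out["variants"]}
        fb = by_label["feedback:A->B"]
        for label, v in by_label.items():
            if label != fb["variant"]:
                assert fb["chi_square"] <= v["chi_square"] + 1e-4

    def test_true_orientation_wins_bcc(self, directional_model, directional_covs):
        out = usem.fit_bidirectional_variants(
            directional_model, directional_covs, [("A", "B")]
        )
        by_label = {v["variant"]: v for v in out["variants"]}
        assert by_label["A->B"]["bcc"] < by_label["B->A"]["bcc"]

    def test_ranking_deterministic(self, directional_model, directional_covs):
        r1 = usem.fit_bidirectional_variants(directional_model, directional_covs, [("A", "B")])
        r2 = usem.fit_bidirectional_variants(directional_model, directional_covs, [("A", "B")])
        assert [v["variant"] for v in r1["variants"]] == [v["variant"] for v in r2["variants"]]
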