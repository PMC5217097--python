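import numpy as np
import pytest

from wcep import (
    ComponentSet,
    MultistateTree,
    SubjectHistory,
    aalen_johansen_arm,
    analytic_event_probs,
    difference,
    estimate_binary_arm,
    integrated_difference,
    simulate_arm,
    transform_estimate,
)
from wcep.datasets import enteric_fever_records, enteric_fever_scheme


class TestMultistateTree:
    def test_two_parents_rejected(self):
        with pytest.raises(ValueError, match="parent"):
            MultistateTree(
                states=("initial", "a", "b"),
                edges=(("initial", "a"), ("initial", "b"), ("a", "b")),
                state_components={"initial": frozenset(), "a": frozenset("a"), "b": frozenset("b")},
            )

    def test_negative_hazard_rejected(self, illness_tree):
        with pytest.raises(ValueError, match="hazard"):
            MultistateTree(
                states=illness_tree.states,
                edges=illness_tree.edges,
                state_components=illness_tree.state_components,
                hazards={e: -1.0 for e in illness_tree.edges},
            )


class TestBinaryEstimate:
    def test_enteric_fever_proportions(self):
        scheme = enteric_fever_scheme()
        arms = enteric_fever_records()
        est = estimate_binary_arm(arms["Cefixime"], scheme, 1.0)
        np.testing.assert_allclose(est.probs, [20 / 77, 6 / 77])
        expected_cov = (np.diag(est.probs) - np.outer(est.probs, est.probs)) / 77
        np.testing.assert_allclose(est.cov, expected_cov)

    def test_single_subject_unit_vector(self, exhaustive_scheme):
        rec = SubjectHistory("1", "A", ((1.0, "N"),), 5.0)
        est = estimate_binary_arm([rec], exhaustive_scheme, 5.0)
        np.testing.assert_array_equal(est.probs, [1, 0, 0])
        np.testing.assert_array_equal(est.cov, np.zeros((3, 3)))

    def test_incomplete_followup_directs_to_aj(self, exhaustive_scheme):
        rec = SubjectHistory("1", "A", (), 3.0)
        with pytest.raises(ValueError, match="Aalen-Johansen"):
            estimate_binary_arm([rec], exhaustive_scheme, 5.0)

    def test_empty_arm_rejected(self, exhaustive_scheme):
        with pytest.raises(ValueError):
            estimate_binary_arm([], exhaustive_scheme, 5.0)

    def test_marginal_covariance_two_routes_agree(
        self, illness_tree, nf_components, exhaustive_scheme, marginal_scheme
    ):
        # transform of the exhaustive multinomial covariance equals the
        # covariance of the marginal indicators computed directly
        recs = simulate_arm(illness_tree, 400, 5.0, 0.0, seed=9)
        via_L = estimate_binary_arm(recs, marginal_scheme, 5.0)
        from wcep import classify_subject

        ind = np.array([classify_subject(r, marginal_scheme, 5.0) for r in recs])
        p = ind.mean(axis=0)
        direct_cov = np.cov(ind.T, bias=True) / len(recs)
        np.testing.assert_allclose(via_L.probs, p, atol=1e-12)
        np.testing.assert_allclose(via_L.cov, direct_cov, atol=1e-12)


class TestAalenJohansen:
    def test_reduces_to_proportions_without_censoring(
        self, illness_tree, exhaustive_scheme
    ):
        recs = simulate_arm(illness_tree, 250, 5.0, 0.0, seed=21)
        aj = aalen_johansen_arm(recs, illness_tree, 5.0, exhaustive_scheme)
        binom = estimate_binary_arm(recs, exhaustive_scheme, 5.0)
        np.testing.assert_allclose(aj.probs, binom.probs, atol=1e-12)

    def test_hand_computed_product_limit(self, illness_tree, exhaustive_scheme):
        # four subjects: N@1 then F@2; censored@1.5; F@3; censored@5.
        # At t=1: 4 at risk in root, one moves to N -> p = (3/4, 1/4, 0, 0).
        # At t=2: the single N-state subject dies -> N+F+ = 1/4.
        # At t=3 only 2 remain in root (censoring at 1.5) -> dA = 1/2,
        # root 3/4 * 1/2 = 3/8 and N-F+ = 3/8.
        recs = [
            SubjectHistory("1", "A", ((1.0, "N"), (2.0, "F")), None),
            SubjectHistory("2", "A", (), 1.5),
            SubjectHistory("3", "A", ((3.0, "F"),), None),
            SubjectHistory("4", "A", (), 5.0),
        ]
        est = aalen_johansen_arm(recs, illness_tree, 5.0, exhaustive_scheme)
        np.testing.assert_allclose(est.probs, [0.0, 0.375, 0.25], atol=1e-12)

    def test_converges_to_analytic_under_censoring(
        self, illness_tree, exhaustive_scheme
    ):
        n = 20_000
        recs = simulate_arm(illness_tree, n, 5.0, 0.05, seed=33)
        est = aalen_johansen_arm(recs, illness_tree, 5.0, exhaustive_scheme)
        truth = analytic_event_probs(illness_tree, 5.0, exhaustive_scheme)
        se = np.sqrt(np.diag(est.cov))
        np.testing.assert_array_less(np.abs(est.probs - truth), 3.5 * se)

    def test_matches_lifelines_competing_risks(self):
        # independent oracle on the initial-state competing-risks reduction
        lifelines = pytest.importorskip("lifelines")
        comps = ComponentSet(("A", "B"), (True, True))
        tree = MultistateTree(
            states=("initial", "A", "B"),
            edges=(("initial", "A"), ("initial", "B")),
            state_components={
                "initial": frozenset(),
                "A": frozenset({"A"}),
                "B": frozenset({"B"}),
            },
            hazards={("initial", "A"): 0.3, ("initial", "B"): 0.2},
        )
        scheme = tree.scheme(comps, "exhaustive")
        recs = simulate_arm(tree, 400, 4.0, 0.25, seed=5)
        est = aalen_johansen_arm(recs, tree, 4.0, scheme)
        durations, labels = [], []
        for r in recs:
            if r.events:
                durations.append(r.events[0][0])
                labels.append(1 if r.events[0][1] == "A" else 2)
            else:
                durations.append(r.censor_time)
                labels.append(0)
        fitter = lifelines.AalenJohansenFitter(calculate_variance=False)
        for cause, k in ((1, 0), (2, 1)):
            fitter.fit(np.array(durations), np.array(labels), event_of_interest=cause)
            cif = float(fitter.cumulative_density_.iloc[-1, 0])
            assert est.probs[k] == pytest.approx(cif, abs=1e-10)

    def test_greenwood_close_to_jackknife(self, illness_tree, exhaustive_scheme):
        n = 500
        recs = simulate_arm(illness_tree, n, 5.0, 0.05, seed=12)
        est = aalen_johansen_arm(recs, illness_tree, 5.0, exhaustive_scheme)
        thetas = np.array(
            [
                aalen_johansen_arm(
                    recs[:i] + recs[i + 1 :], illness_tree, 5.0, exhaustive_scheme
                ).probs
                for i in range(n)
            ]
        )
        centered = thetas - thetas.mean(axis=0)
        jack = (n - 1) / n * centered.T @ centered
        rel = np.linalg.norm(est.cov - jack) / np.linalg.norm(jack)
        assert rel < 0.15

    def test_unknown_transition_rejected(self, illness_tree, exhaustive_scheme):
        rec = SubjectHistory("1", "A", ((1.0, "F"), (2.0, "N")), 5.0)
        with pytest.raises(ValueError, match="not an edge"):
            aalen_johansen_arm([rec], illness_tree, 5.0, exhaustive_scheme)

    def test_exhausted_risk_set_flags_extrapolation(
        self, illness_tree, exhaustive_scheme
    ):
        recs = [
            SubjectHistory("1", "A", ((1.0, "N"),), 2.0),
            SubjectHistory("2", "A", (), 2.5),
        ]
        with pytest.warns(RuntimeWarning, match="exhausted"):
            est = aalen_johansen_arm(recs, illness_tree, 5.0, exhaustive_scheme)
        assert est.extrapolated


class TestTransformAndDifference:
    def test_identity_transform_is_noop(self, illness_tree, exhaustive_scheme):
        recs = simulate_arm(illness_tree, 100, 5.0, 0.0, seed=1)
        est = estimate_binary_arm(recs, exhaustive_scheme, 5.0)
        out = transform_estimate(est, np.eye(3))
        np.testing.assert_array_equal(out.probs, est.probs)
        np.testing.assert_array_equal(out.cov, est.cov)

    def test_any_event_row_gives_binomial_variance(
        self, illness_tree, exhaustive_scheme
    ):
        recs = simulate_arm(illness_tree, 200, 5.0, 0.0, seed=2)
        est = estimate_binary_arm(recs, exhaustive_scheme, 5.0)
        out = transform_estimate(
            est, np.ones((1, 3)), event_types=("any",), setting="worst_event"
        )
        p = out.probs[0]
        assert out.cov[0, 0] == pytest.approx(p * (1 - p) / 200, rel=1e-10)

    def test_identical_arms_zero_difference(self, illness_tree, exhaustive_scheme):
        recs = simulate_arm(illness_tree, 50, 5.0, 0.0, seed=3)
        est = estimate_binary_arm(recs, exhaustive_scheme, 5.0)
        d = difference(est, est)
        np.testing.assert_array_equal(d.D, np.zeros(3))

    def test_enteric_fever_difference(self):
        scheme = enteric_fever_scheme()
        arms = enteric_fever_records()
        estC = estimate_binary_arm(arms["Cefixime"], scheme, 1.0)
        estG = estimate_binary_arm(arms["Gatifloxacin"], scheme, 1.0)
        d = difference(estC, estG)
        np.testing.assert_allclose(d.D, [20 / 77 - 1 / 92, 6 / 77 - 2 / 92])
        np.testing.assert_allclose(d.V, estC.cov + estG.cov)

    def test_mismatched_horizons_rejected(self, illness_tree, exhaustive_scheme):
        recs = simulate_arm(illness_tree, 50, 5.0, 0.0, seed=3)
        est5 = estimate_binary_arm(recs, exhaustive_scheme, 5.0)
        est4 = estimate_binary_arm(recs, exhaustive_scheme, 4.0)
        with pytest.raises(ValueError, match="horizon"):
            difference(est5, est4)


class TestIntegratedDifference:
    def single_event_tree(self, rate=0.3):
        return MultistateTree(
            states=("initial", "E"),
            edges=(("initial", "E"),),
            state_components={"initial": frozenset(), "E": frozenset({"E"})},
            hazards={("initial", "E"): rate},
        )

    def test_identical_arms_zero(self, illness_tree, exhaustive_scheme):
        recs = simulate_arm(illness_tree, 40, 5.0, 0.0, seed=8)
        res = integrated_difference(
            recs, recs, illness_tree, 5.0, exhaustive_scheme, grid_step=0.05
        )
        np.testing.assert_allclose(res.Dprime, np.zeros(3), atol=1e-12)

    def test_restricted_mean_interpretation(self):
        # with a single absorbing event, no censoring and h == 1 the
        # integrated statistic is the difference of mean event-time lost
        # up to tau: integral of F equals tau - mean(min(T, tau))
        tree = self.single_event_tree()
        comps = ComponentSet(("E",), (True,))
        scheme = tree.scheme(comps, "exhaustive")
        tau = 4.0
        ra = simulate_arm(tree, 150, tau, 0.0, seed=31, arm="A")
        rb = simulate_arm(self.single_event_tree(0.15), 150, tau, 0.0, seed=32, arm="B")
        res = integrated_difference(ra, rb, tree, tau, scheme, grid_step=tau / 400)

        def lost(recs):
            t = np.array([r.events[0][0] if r.events else tau for r in recs])
            return np.mean(tau - np.minimum(t, tau))

        expected = lost(ra) - lost(rb)
        assert res.Dprime[0] == pytest.approx(expected, abs=0.02)

    def test_riemann_sum_converges(self, illness_tree, exhaustive_scheme):
        ra = simulate_arm(illness_tree, 150, 5.0, 0.0, seed=41, arm="A")
        rb = simulate_arm(illness_tree, 150, 5.0, 0.0, seed=42, arm="B")
        coarse = integrated_difference(
            ra, rb, illness_tree, 5.0, exhaustive_scheme, grid_step=5.0 / 250
        )
        fine = integrated_difference(
            ra, rb, illness_tree, 5.0, exhaustive_scheme, grid_step=5.0 / 500
        )
        denom = np.maximum(np.abs(fine.Dprime), 0.05)
        assert np.all(np.abs(coarse.Dprime - fine.Dprime) / denom < 0.01)

    def test_negative_h_rejected(self, illness_tree, exhaustive_scheme):
        recs = simulate_arm(illness_tree, 30, 5.0, 0.0, seed=1)
        with pytest.raises(ValueError, match="non-negative"):
            integrated_difference(
                recs, recs, illness_tree, 5.0, exhaustive_scheme,
                h=lambda t: -1.0, grid_step=0.5,
            )

    def test_bad_grid_step_rejected(self, illness_tree, exhaustive_scheme):
        recs = simulate_arm(illness_tree, 30, 5.0, 0.0, seed=1)
        with pytest.raises(ValueError, match="grid_step"):
            integrated_difference(
                recs, recs, illness_tree, 5.0, exhaustive_scheme, grid_step=6.0
            )


class TestCovariancePSD:
    def test_all_covariances_are_psd(self, illness_tree, exhaustive_scheme):
        for seed in range(5):
            recs = simulate_arm(illness_tree, 150, 5.0, 0.05, seed=seed)
            est = aalen_johansen_arm(recs, illness_tree, 5.0, exhaustive_scheme)
            assert np.linalg.eigvalsh(est.cov).min() >= -1e-10
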