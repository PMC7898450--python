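"""Loss pieces, gradients, and the multi-start projected-gradient fit."""

import numpy as np
import pytest

import logicfit as lf
from logicfit.fitting import _Objective, _Parameterization, _project_simplex
from logicfit.simulate import CompiledNetwork

from conftest import random_params


def _chain_data(noise=0.0, seed=0, contexts=("c1",), n_diffs=0):
    net = lf.chain_network()
    truth = lf.generate_ground_truth(net, n_diffs, list(contexts), seed=seed, noise_scale=noise)
    design = lf.chain_design()
    datasets = [lf.simulate_dataset(truth, design, c) for c in contexts]
    return net, truth, datasets


class TestLossPieces:
    def test_mse_hand_example(self):
        sim = np.array([[0.0, 0.5], [1.0, 0.5]])
        meas = np.array([[0.1, 0.5], [0.8, 0.1]])
        # squares: 0.01, 0, 0.04, 0.16 -> mean 0.0525
        assert lf.mse(sim, meas) == pytest.approx(0.0525)

    def test_mse_identical_matrices_is_zero(self):
        m = np.random.default_rng(0).random((3, 4))
        assert lf.mse(m, m) == 0.0

    def test_mse_opposite_unit_vectors(self):
        assert lf.mse(np.array([1.0, 0.0]), np.array([0.0, 1.0])) == 1.0

    def test_mse_random_pair_matches_hand_summation(self):
        rng = np.random.default_rng(1)
        sim, meas = rng.random((4, 4)), rng.random((4, 4))
        oracle = sum(
            (sim[i, j] - meas[i, j]) ** 2 for i in range(4) for j in range(4)
        ) / 16
        assert lf.mse(sim, meas) == pytest.approx(oracle, abs=1e-15)

    def test_mse_ignores_missing_cells(self):
        sim = np.array([[0.0, 0.5]])
        meas = np.array([[0.1, np.nan]])
        assert lf.mse(sim, meas) == pytest.approx(0.01)

    def test_mse_pools_contexts(self):
        a = (np.array([[0.0]]), np.array([[0.2]]))
        b = (np.array([[0.0]]), np.array([[0.4]]))
        pooled = lf.mse([a[0], b[0]], [a[1], b[1]])
        assert pooled == pytest.approx((0.04 + 0.16) / 2)

    def test_mse_all_missing_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            lf.mse(np.array([[0.0]]), np.array([[np.nan]]))

    def test_pruning_penalty_hand_example(self, chain_net):
        # only M (k_S1_M + k_S2_M) and O2/O3 have >= 2 activators
        values = {}
        w = {
            "k_S1_M": 0.6, "k_S2_M": 0.4, "k_D1_M": 0.5, "k_M_O1": 1.0,
            "k_S1_O2": 0.3, "k_M_O2": 0.7, "k_D2_O2": 0.8,
            "k_S2_O3": 0.2, "k_M_O3": 0.8,
        }
        for l, v in w.items():
            values[(l, "c")] = v
        p = lf.ParameterSet(values=values)
        # (1.0 - 0.6) + (1.0 - 0.7) + (1.0 - 0.8)
        assert lf.pruning_penalty(chain_net, p) == pytest.approx(0.9)

    def test_pruning_penalty_zero_for_dominant_single_activator(self, chain_net):
        values = {}
        for l in chain_net.param_labels:
            values[(l, "c")] = 0.0
        for l in ("k_S1_M", "k_M_O1", "k_M_O2", "k_M_O3"):
            values[(l, "c")] = 1.0
        p = lf.ParameterSet(values=values)
        assert lf.pruning_penalty(chain_net, p) == 0.0

    def test_pruning_penalty_random_weights_match_brute_force(self):
        # 5 activators into one node, 3 contexts
        doc = "\n".join(f"A{i}\t->\tZ\tk{i}" for i in range(5))
        net = lf.parse_network(doc, outputs=["Z"])
        rng = np.random.default_rng(3)
        values = {}
        for ctx in ("a", "b", "c"):
            w = rng.dirichlet(np.ones(5))
            for i in range(5):
                values[(f"k{i}", ctx)] = float(w[i])
        p = lf.ParameterSet(values=values)
        oracle = sum(
            sum(values[(f"k{i}", ctx)] for i in range(5))
            - max(values[(f"k{i}", ctx)] for i in range(5))
            for ctx in ("a", "b", "c")
        )
        assert lf.pruning_penalty(net, p) == pytest.approx(oracle, abs=1e-12)

    def test_uniformity_penalty_hand_example(self):
        p = lf.ParameterSet(values={("k", "a"): 0.2, ("k", "b"): 0.5, ("k", "c"): 0.9})
        # median 0.5 -> |0.2-0.5| + 0 + |0.9-0.5|
        assert lf.uniformity_penalty(p) == pytest.approx(0.7)

    def test_uniformity_penalty_zero_when_tied(self):
        p = lf.ParameterSet(values={("k", "a"): 0.37, ("k", "b"): 0.37})
        assert lf.uniformity_penalty(p) == 0.0

    def test_uniformity_four_context_example(self):
        p = lf.ParameterSet(
            values={("k", c): v for c, v in zip("wxyz", (0.2, 0.2, 0.2, 0.6))}
        )
        assert lf.uniformity_penalty(p) == pytest.approx(0.4)

    def test_uniformity_random_values_match_brute_force(self):
        rng = np.random.default_rng(4)
        contexts = ("a", "b", "c", "d")
        labels = [f"k{i}" for i in range(6)]
        values = {(l, c): float(rng.random()) for l in labels for c in contexts}
        p = lf.ParameterSet(values=values)
        oracle = sum(
            abs(values[(l, c)] - np.median([values[(l, cc)] for cc in contexts]))
            for l in labels
            for c in contexts
        )
        assert lf.uniformity_penalty(p) == pytest.approx(oracle, abs=1e-12)

    def test_uniformity_single_context_warns_and_returns_zero(self):
        p = lf.ParameterSet(values={("k", "a"): 0.4})
        with pytest.warns(UserWarning, match="contexts"):
            assert lf.uniformity_penalty(p) == 0.0


class TestSimplexProjection:
    def test_already_feasible_unchanged(self):
        v = np.array([0.2, 0.3, 0.5])
        assert np.allclose(_project_simplex(v), v)

    def test_hand_example(self):
        # projection of (1, 1) onto the simplex is (0.5, 0.5)
        assert np.allclose(_project_simplex(np.array([1.0, 1.0])), [0.5, 0.5])

    def test_matches_brute_force_qp(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            v = rng.normal(size=rng.integers(2, 6)) * 2
            p = _project_simplex(v)
            assert p.min() >= 0 and p.sum() == pytest.approx(1.0)
            # optimality: no feasible direction improves the distance
            for _ in range(20):
                q = rng.dirichlet(np.ones(v.size))
                assert ((p - v) ** 2).sum() <= ((q - v) ** 2).sum() + 1e-12


class TestGradients:
    def _finite_diff_check(self, net, datasets, lp, lu, seed):
        compiled = CompiledNetwork(net)
        contexts = [ds.context for ds in datasets]
        par = _Parameterization(compiled, contexts, None)
        obj = _Objective(compiled, datasets, par, lp, lu)
        rng = np.random.default_rng(seed)
        theta = par.project(rng.random(par.n_theta))
        f0, g, _ = obj(theta)
        eps = 1e-7
        for i in range(par.n_theta):
            d = np.zeros(par.n_theta)
            d[i] = eps
            f_plus = obj(theta + d)[0]
            f_minus = obj(theta - d)[0]
            num = (f_plus - f_minus) / (2 * eps)
            assert num == pytest.approx(g[i], abs=1e-5), f"coordinate {i}"

    def test_mse_gradient_matches_finite_differences(self):
        net, _t, datasets = _chain_data(noise=0.05, seed=11)
        self._finite_diff_check(net, datasets, 0.0, 0.0, seed=1)

    def test_regularized_gradient_matches_finite_differences(self):
        # smooth region: random theta has distinct weights, so neither the
        # max nor the median ties, and the penalty terms are differentiable
        net, _t, datasets = _chain_data(noise=0.05, seed=12, contexts=("c1", "c2"))
        self._finite_diff_check(net, datasets, 0.01, 0.01, seed=2)


class TestFit:
    def test_noise_free_self_consistency(self):
        net, truth, datasets = _chain_data(noise=0.0, seed=3)
        res = lf.fit(net, datasets, lf.FitConfig(n_starts=8, seed=0))
        assert res.converged
        assert res.mse <= 1e-8
        for key, v in truth.params.values.items():
            assert res.params.values[key] == pytest.approx(v, abs=0.01)

    def test_deterministic_given_config(self):
        net, _t, datasets = _chain_data(noise=0.02, seed=4)
        cfg = lf.FitConfig(n_starts=3, seed=7)
        a = lf.fit(net, datasets, cfg)
        b = lf.fit(net, datasets, cfg)
        assert a.params.values == b.params.values
        assert a.total_loss == b.total_loss
        assert a.best_start == b.best_start

    def test_result_parts_are_consistent(self):
        net, _t, datasets = _chain_data(noise=0.02, seed=5, contexts=("c1", "c2"))
        cfg = lf.FitConfig(lambda_pruning=0.01, lambda_uniformity=0.01, n_starts=2, seed=0)
        res = lf.fit(net, datasets, cfg)
        res.params.validate(net)
        assert res.total_loss == pytest.approx(
            res.mse + 0.01 * res.penalty_pruning + 0.01 * res.penalty_uniformity
        )
        assert res.penalty_pruning == pytest.approx(lf.pruning_penalty(net, res.params))
        assert res.penalty_uniformity == pytest.approx(
            lf.uniformity_penalty(res.params), abs=1e-9
        )

    def test_loss_trace_is_monotone_nonincreasing(self):
        net, _t, datasets = _chain_data(noise=0.02, seed=6)
        res = lf.fit(net, datasets, lf.FitConfig(n_starts=1, seed=0))
        trace = np.array(res.loss_trace)
        assert (np.diff(trace) <= 1e-15).all()

    def test_large_lambda_pruning_concentrates_activator_mass(self):
        net, _t, datasets = _chain_data(noise=0.02, seed=8)
        res = lf.fit(net, datasets, lf.FitConfig(lambda_pruning=100.0, n_starts=4, seed=0))
        # each multi-activator node ends with all mass on one activator
        assert res.penalty_pruning <= 1e-8

    def test_large_lambda_uniformity_matches_hard_tied_fit(self):
        net, _t, datasets = _chain_data(noise=0.02, seed=9, contexts=("c1", "c2"), n_diffs=1)
        contexts = [ds.context for ds in datasets]
        tied = lf.fit(
            net, datasets, lf.FitConfig(n_starts=6, seed=0),
            sharing=lf.tie_all_contexts(net, contexts),
        )
        soft = lf.fit(net, datasets, lf.FitConfig(lambda_uniformity=100.0, n_starts=6, seed=0))
        for key in tied.params.values:
            assert soft.params.values[key] == pytest.approx(tied.params.values[key], abs=1e-3)

    def test_sharing_groups_are_exactly_tied(self):
        net, _t, datasets = _chain_data(noise=0.02, seed=10, contexts=("c1", "c2"))
        contexts = [ds.context for ds in datasets]
        res = lf.fit(
            net, datasets, lf.FitConfig(n_starts=2, seed=0),
            sharing=lf.tie_all_contexts(net, contexts),
        )
        for lab in net.param_labels:
            assert res.params.values[(lab, "c1")] == res.params.values[(lab, "c2")]

    def test_missing_cells_are_ignored(self):
        net, _t, datasets = _chain_data(noise=0.0, seed=13)
        ds = datasets[0]
        corrupted = ds.values.copy()
        corrupted.iloc[0, 0] = np.nan
        holed = lf.MeasurementSet(
            context=ds.context, conditions=list(ds.conditions), values=corrupted
        )
        res = lf.fit(net, [holed], lf.FitConfig(n_starts=6, seed=0))
        assert res.mse <= 1e-8

    def test_duplicate_contexts_rejected(self):
        net, _t, datasets = _chain_data(noise=0.0, seed=14)
        with pytest.raises(ValueError, match="duplicate"):
            lf.fit(net, [datasets[0], datasets[0]], lf.FitConfig(n_starts=1))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            lf.FitConfig(lambda_pruning=-1.0)
        with pytest.raises(ValueError):
            lf.FitConfig(n_starts=0)
        with pytest.raises(ValueError):
            lf.FitConfig(tol=0.0)
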