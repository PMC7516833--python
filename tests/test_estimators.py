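"""kNN information estimators against Gaussian closed forms."""

import numpy as np
import pytest
from scipy.spatial import cKDTree

import bundleflow as bf
from bundleflow.estimators import (
    EstimatorError,
    _count_strictly_within,
    _kth_neighbor_distance,
)


def gaussian_mi(rho):
    return -0.5 * np.log(1 - rho**2)


def corr_pair(rho, n, rng):
    x = rng.normal(size=n)
    y = rho * x + np.sqrt(1 - rho**2) * rng.normal(size=n)
    return x, y


class TestKnnMi:
    def test_independent_uniforms_near_zero(self, est_cfg):
        rng = np.random.default_rng(0)
        mi = bf.knn_mi(rng.uniform(size=5000), rng.uniform(size=5000), est_cfg)
        assert abs(mi) < 0.02

    def test_bivariate_gaussian_closed_form(self, est_cfg):
        rng = np.random.default_rng(1)
        x, y = corr_pair(0.6, 10000, rng)
        assert bf.knn_mi(x, y, est_cfg) == pytest.approx(gaussian_mi(0.6), abs=0.02)

    def test_self_dependence_grows_with_n(self, est_cfg):
        rng = np.random.default_rng(2)
        vals = []
        for n in (500, 2000, 8000):
            x = rng.normal(size=n)
            vals.append(bf.knn_mi(x, x, est_cfg))
        assert vals[0] > 1.0 and vals[0] < vals[1] < vals[2]

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(3)
        x, y = corr_pair(0.5, 2000, rng)
        cfg = bf.EstimatorConfig(k=5, seed=99)
        assert bf.knn_mi(x, y, cfg) == bf.knn_mi(x, y, cfg)

    def test_degenerate_inputs_rejected(self):
        cfg = bf.EstimatorConfig(k=5, seed=0)
        with pytest.raises(EstimatorError):
            bf.knn_mi(np.arange(4.0), np.arange(4.0), cfg)
        no_jitter = bf.EstimatorConfig(k=2, jitter_scale=0.0, seed=0)
        with pytest.raises(EstimatorError):
            bf.knn_mi(np.ones(50), np.random.default_rng(0).normal(size=50), no_jitter)

    def test_monotone_rescaling_invariance(self, est_cfg):
        """Column z-scoring makes affine rescaling a near no-op."""
        rng = np.random.default_rng(4)
        x, y = corr_pair(0.5, 10000, rng)
        base = bf.knn_mi(x, y, est_cfg)
        scaled = bf.knn_mi(7.0 * x + 3.0, y / 40.0, est_cfg)
        assert abs(base - scaled) < 0.02

    def test_convergence_to_closed_form(self):
        truth = gaussian_mi(0.6)
        maes = []
        for n in (1000, 10000):
            errs = []
            for seed in range(3):
                rng = np.random.default_rng(100 + seed)
                x, y = corr_pair(0.6, n, rng)
                cfg = bf.EstimatorConfig(k=5, seed=seed)
                errs.append(abs(bf.knn_mi(x, y, cfg) - truth))
            maes.append(np.mean(errs))
        assert maes[1] < maes[0]


class TestKnnCmi:
    def test_conditioning_on_source_kills_information(self, est_cfg):
        # duplicated-coordinate conditioning carries a small negative bias in
        # the max-norm FP estimator; the estimate collapses to ~0 regardless
        rng = np.random.default_rng(5)
        x, y = corr_pair(0.7, 5000, rng)
        mi = bf.knn_mi(x, y, est_cfg)
        cmi = bf.knn_cmi(x, y, x, est_cfg)
        assert abs(cmi) < 0.06
        assert abs(cmi) < 0.25 * mi

    def test_markov_chain_screens_off(self, est_cfg):
        rng = np.random.default_rng(6)
        n = 5000
        x = rng.normal(size=n)
        z = 0.8 * x + 0.6 * rng.normal(size=n)
        y = 0.7 * z + np.sqrt(1 - 0.49) * rng.normal(size=n)
        assert bf.knn_mi(x, y, est_cfg) > 0.1
        assert abs(bf.knn_cmi(x, y, z, est_cfg)) < 0.03

    def test_four_dim_gaussian_determinant_formula(self, est_cfg):
        rng = np.random.default_rng(7)
        A = rng.normal(size=(4, 4))
        S = A @ A.T + 4 * np.eye(4)
        data = rng.multivariate_normal(np.zeros(4), S, size=10000)
        x, y, z = data[:, [0]], data[:, [1]], data[:, 2:]

        def ld(idx):
            return np.linalg.slogdet(S[np.ix_(idx, idx)])[1]

        truth = 0.5 * (ld([0, 2, 3]) + ld([1, 2, 3]) - ld([2, 3]) - ld([0, 1, 2, 3]))
        assert bf.knn_cmi(x, y, z, est_cfg) == pytest.approx(truth, abs=0.05)

    def test_empty_condition_equals_mi_bitwise(self, est_cfg):
        rng = np.random.default_rng(8)
        x, y = corr_pair(0.4, 1500, rng)
        assert bf.knn_cmi(x, y, None, est_cfg) == bf.knn_mi(x, y, est_cfg)
        empty = np.empty((1500, 0))
        assert bf.knn_cmi(x, y, empty, est_cfg) == bf.knn_mi(x, y, est_cfg)


class TestNeighborKernels:
    """The numba counting kernels against an independent spatial-tree route."""

    def test_kth_distance_matches_ckdtree(self):
        rng = np.random.default_rng(9)
        for d in (1, 3, 6):
            pts = rng.normal(size=(400, d))
            ours = _kth_neighbor_distance(pts, 5)
            ref = cKDTree(pts).query(pts, k=6, p=np.inf)[0][:, -1]
            np.testing.assert_allclose(ours, ref, rtol=1e-12)

    def test_counts_match_ckdtree(self):
        rng = np.random.default_rng(10)
        for d in (1, 4):
            pts = rng.normal(size=(400, d))
            radii = rng.uniform(0.1, 1.0, size=400)
            ours = _count_strictly_within(pts, radii)
            tree = cKDTree(pts)
            ref = (
                np.asarray(
                    tree.query_ball_point(
                        pts, np.nextafter(radii, 0), p=np.inf, return_length=True
                    )
                )
                - 1
            )
            np.testing.assert_array_equal(ours, ref)


class TestMitEdgeWeight:
    def test_two_variable_closed_form(self, est_cfg):
        a = 0.6
        dag = bf.TimeSeriesDAG.from_edges(["X", "Y"], [("X", "Y", 1)])
        spec = bf.VARSpec(
            dag=dag,
            coeff={bf.EdgeTemplate("X", "Y", 1): a},
            noise_sd={"X": 1.0, "Y": 1.0},
            n=10000,
            seed=1,
        )
        series = bf.generate_var(spec)
        w = bf.mit_edge_weight(dag, bf.EdgeTemplate("X", "Y", 1), series, est_cfg)
        truth = 0.5 * np.log(1 + a**2)  # I(X_{t-1}; Y_t), unit noise variances
        assert w == pytest.approx(truth, abs=0.03)

    def test_spurious_edge_has_near_zero_weight(self, est_cfg):
        var_spec, _ = bf.fixture_disconnected(n=8000, seed=2)
        series = bf.generate_var(var_spec)
        w = bf.mit_edge_weight(
            var_spec.dag, bf.EdgeTemplate("m1", "tar", 1), series, est_cfg
        )
        assert abs(w) < 0.03

    def test_stationarity_of_weights(self, est_cfg):
        vs, _ = bf.fixture_miwtr(n=6000, seed=3)
        full = bf.generate_var(vs)
        early = bf.SeriesMatrix(full.values[:5000], full.names)
        late = bf.SeriesMatrix(full.values[1000:], full.names)
        e = bf.EdgeTemplate("p", "q", 2)
        w1 = bf.mit_edge_weight(vs.dag, e, early, est_cfg)
        w2 = bf.mit_edge_weight(vs.dag, e, late, est_cfg)
        assert w1 == pytest.approx(w2, abs=0.05)
        assert w1 > 0.05

    def test_non_edge_rejected(self, seven_var, est_cfg):
        var_spec, _, series = seven_var
        with pytest.raises(ValueError):
            bf.mit_edge_weight(
                var_spec.dag, bf.EdgeTemplate("m1", "m2", 1), series, est_cfg
            )
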