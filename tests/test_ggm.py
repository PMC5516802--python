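"""Graphical lasso correctness, penalty selection and network comparison."""

import warnings

import numpy as np
import pytest
from scipy.optimize import minimize

from mirscreen.ggm import (
    compare_networks,
    constrained_mle,
    default_lambda_grid,
    ebic,
    graphical_lasso,
    infer_network,
    kkt_violation,
    penalized_objective,
    select_lambda,
)
from mirscreen.simulate import (
    partial_correlations,
    random_sparse_precision,
    sample_ggm,
)

from conftest import make_screen

TRIDIAG = np.array([[2.0, -1.0, 0.0], [-1.0, 2.0, -1.0], [0.0, -1.0, 2.0]])


def corr_from_precision(theta):
    cov = np.linalg.inv(theta)
    d = np.sqrt(np.diag(cov))
    return cov / np.outer(d, d)


def brute_force_objective(S, lam):
    """Numerically maximize the penalized likelihood over Cholesky factors."""
    p = S.shape[0]
    tril = np.tril_indices(p)

    def negobj(x):
        L = np.zeros((p, p))
        L[tril] = x
        theta = L @ L.T + 1e-12 * np.eye(p)
        val = penalized_objective(S, theta, lam)
        return np.inf if not np.isfinite(val) else -val

    best = np.inf
    for scale in (0.5, 1.0, 2.0):
        x0 = np.linalg.cholesky(np.linalg.inv(S) * scale)[tril]
        r = minimize(negobj, x0, method="Nelder-Mead",
                     options={"maxiter": 20000, "xatol": 1e-10, "fatol": 1e-12})
        r2 = minimize(negobj, r.x, method="BFGS",
                      options={"gtol": 1e-12, "maxiter": 10000})
        best = min(best, r.fun, r2.fun)
    return -best


class TestGraphicalLasso:
    def test_unpenalized_limit_equals_inverse(self):
        S = corr_from_precision(TRIDIAG)
        res = graphical_lasso(S, 0.0)
        assert np.abs(res.theta - np.linalg.inv(S)).max() < 1e-6

    def test_large_penalty_gives_diagonal_model(self):
        S = corr_from_precision(TRIDIAG)
        lam = np.abs(S - np.diag(np.diag(S))).max() + 1e-6
        res = graphical_lasso(S, lam)
        off = res.theta - np.diag(np.diag(res.theta))
        assert np.abs(off).max() == 0.0
        assert np.allclose(np.diag(res.theta), 1.0 / np.diag(S))

    @pytest.mark.parametrize("lam", [0.02, 0.1, 0.3])
    def test_objective_matches_brute_force_and_kkt(self, lam):
        S = corr_from_precision(TRIDIAG)
        res = graphical_lasso(S, lam, tol=1e-9)
        assert kkt_violation(S, res.theta, lam) < 1e-6
        mine = penalized_objective(S, res.theta, lam)
        brute = brute_force_objective(S, lam)
        assert mine >= brute - 1e-6
        assert abs(mine - brute) < 1e-6

    def test_monotone_ascent_every_sweep(self, rng):
        g = random_sparse_precision(10, 9, 0.4, seed=0)
        S = np.corrcoef(sample_ggm(g, 80, seed=1), rowvar=False)
        for lam in (0.05, 0.15):
            res = graphical_lasso(S, lam)
            assert np.all(np.diff(res.primal_path) > -1e-7)
            assert np.all(np.diff(res.dual_path) > -1e-9)

    def test_precision_positive_definite(self, rng):
        g = random_sparse_precision(8, 6, 0.4, seed=2)
        S = np.corrcoef(sample_ggm(g, 60, seed=2), rowvar=False)
        res = graphical_lasso(S, 0.1)
        assert np.linalg.eigvalsh(res.theta).min() > 0

    def test_edge_set_monotone_along_path(self, rng):
        # edges of material size persist as the penalty decreases; machine-
        # scale edges (|theta| ~ 1e-3) may flicker on the exact path
        g = random_sparse_precision(10, 10, 0.4, seed=3)
        S = np.corrcoef(sample_ggm(g, 200, seed=3), rowvar=False)
        iu = np.triu_indices(10, 1)
        prev_res, prev_strong = None, None
        for lam in sorted(default_lambda_grid(S, 10))[::-1]:
            res = graphical_lasso(S, lam, warm=prev_res)
            edges = {(i, j) for i, j in zip(*iu) if abs(res.theta[i, j]) > 1e-8}
            strong = {(i, j) for i, j in zip(*iu) if abs(res.theta[i, j]) > 1e-2}
            if prev_strong is not None:
                assert prev_strong <= edges
            prev_res, prev_strong = res, strong

    def test_partial_correlations_match_classical_at_zero_penalty(self, rng):
        x = rng.normal(size=(200, 6))
        x[:, 1] += 0.5 * x[:, 0]
        S = np.corrcoef(x, rowvar=False)
        res = graphical_lasso(S, 0.0)
        assert np.abs(partial_correlations(res.theta)
                      - partial_correlations(np.linalg.inv(S))).max() < 1e-6

    def test_agrees_with_independent_solver(self):
        from sklearn.covariance import GraphicalLasso as SkGlasso

        g = random_sparse_precision(6, 5, 0.35, seed=3)
        S = np.corrcoef(sample_ggm(g, 2000, seed=4), rowvar=False)
        mine = graphical_lasso(S, 0.2, tol=1e-9).theta
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sk = SkGlasso(alpha=0.2, covariance="precomputed", tol=1e-10,
                          max_iter=2000).fit(S)
        assert np.abs(mine - sk.precision_).max() < 1e-3

    def test_asymmetric_input_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            graphical_lasso(np.array([[1.0, 0.5], [0.2, 1.0]]), 0.1)


class TestSelectLambda:
    def test_empty_grid_rejected(self, rng):
        with pytest.raises(ValueError, match="empty"):
            select_lambda(rng.normal(size=(50, 4)), lambda_grid=np.array([]))

    def test_ebic_of_empty_model_is_diagonal_loglik(self):
        S = corr_from_precision(TRIDIAG)
        n = 100
        theta = constrained_mle(S, set())
        assert np.allclose(theta, np.diag(1.0 / np.diag(S)))
        ll = 0.5 * n * (np.linalg.slogdet(theta)[1] - np.trace(S @ theta))
        assert ebic(S, theta, n) == pytest.approx(-2.0 * ll)

    def test_consistent_support_selection_at_large_n(self):
        g = random_sparse_precision(8, 7, 0.4, seed=5)
        x = sample_ggm(g, 4000, seed=6)
        S = np.corrcoef(x, rowvar=False)
        lam, path = select_lambda(x, return_path=True)
        res = graphical_lasso(S, lam)
        iu = np.triu_indices(8, 1)
        est = {(i, j) for i, j in zip(*iu) if abs(res.theta[i, j]) > 1e-8}
        assert est == set(g.support)

    def test_null_data_yields_near_empty_network(self):
        false_edges = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            x = rng.normal(size=(154, 20))
            lam = select_lambda(x)
            S = np.corrcoef(x, rowvar=False)
            res = graphical_lasso(S, lam)
            iu = np.triu_indices(20, 1)
            false_edges.append(int((np.abs(res.theta[iu]) > 1e-8).sum()))
        assert sorted(false_edges)[-2] <= 2  # <=2 false edges in >=90% of seeds


class TestInferNetwork:
    def test_tridiagonal_chain_recovered_at_large_n(self):
        from mirscreen.simulate import PlantedGGM

        g = PlantedGGM(TRIDIAG, frozenset({(0, 1), (1, 2)}),
                       proteins=["A_pS1", "B_pS1", "C_pS1"])
        x = sample_ggm(g, 5000, seed=7)
        s = make_screen(x)
        s.protein_ids = g.proteins
        net = infer_network(s)
        assert net.edge_set() == {("A_pS1", "B_pS1"), ("B_pS1", "C_pS1")}
        rhos = dict(zip(zip(net.edges.protein_a, net.edges.protein_b),
                        net.edges.rho))
        assert rhos[("A_pS1", "B_pS1")] == pytest.approx(0.5, abs=0.03)
        assert rhos[("B_pS1", "C_pS1")] == pytest.approx(0.5, abs=0.03)

    def test_chain_without_shortcut_at_screen_scale(self):
        # MEK -> ERK -> GSK3-like chain: both links present, shortcut absent
        from mirscreen.simulate import PlantedGGM

        chain = np.eye(20)
        chain[0, 1] = chain[1, 0] = -0.45
        chain[1, 2] = chain[2, 1] = -0.45
        proteins = [f"P{j:02d}_pS1" for j in range(20)]
        g = PlantedGGM(chain, frozenset({(0, 1), (1, 2)}), proteins=proteins)
        ok = 0
        for seed in range(10):
            x = sample_ggm(g, 154, seed=100 + seed)
            s = make_screen(x)
            s.protein_ids = proteins
            net = infer_network(s)
            edges = net.edge_set()
            chain_found = {("P00_pS1", "P01_pS1"), ("P01_pS1", "P02_pS1")} <= edges
            shortcut = ("P00_pS1", "P02_pS1") in edges
            ok += chain_found and not shortcut
        assert ok >= 9

    def test_constant_column_dropped_with_warning(self, rng):
        x = rng.normal(size=(60, 4))
        x[:, 2] = 1.0
        s = make_screen(x)
        s.protein_ids = ["A_pS1", "B_pS1", "C_pS1", "D_pS1"]
        with pytest.warns(UserWarning, match="constant"):
            net = infer_network(s)
        assert "C_pS1" not in net.proteins

    def test_support_recovery_f1_at_screen_scale(self):
        f1s = []
        for seed in range(5):
            g = random_sparse_precision(20, 22, 0.35, seed=seed)
            x = sample_ggm(g, 154, seed=seed + 100)
            s = make_screen(x)
            s.protein_ids = [f"P{j:02d}_pS1" for j in range(20)]
            net = infer_network(s)
            idx = {p: i for i, p in enumerate(s.protein_ids)}
            est = {tuple(sorted((idx[a], idx[b]))) for a, b in net.edge_set()}
            tp = len(est & g.support)
            prec = tp / max(len(est), 1)
            rec = tp / len(g.support)
            f1s.append(0.0 if prec + rec == 0 else 2 * prec * rec / (prec + rec))
        assert np.mean(f1s) >= 0.8


class TestCompareNetworks:
    @staticmethod
    def run_nets(seed):
        from mirscreen.simulate import (
            SimulationConfig,
            planted_cell_line_ggms,
            simulate_secondary_screens,
        )

        ggms, classes = planted_cell_line_ggms(seed=seed)
        sec = simulate_secondary_screens(SimulationConfig(seed=seed), ggms,
                                         seed=seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return [infer_network(s) for s in sec.screens], classes

    def test_identical_networks_all_common(self):
        import copy

        nets, _ = self.run_nets(0)
        clones = []
        for name in ("X", "Y", "Z"):
            c = copy.deepcopy(nets[0])
            c.cell_line = name
            clones.append(c)
        comp = compare_networks(clones)
        total = len(nets[0].edge_set())
        assert comp.count("X", "Y", "Z") == total
        assert comp.count("X", "Y") == 0 and comp.count("X") == 0
        assert len(comp.common_core) == total

    def test_disjoint_networks_empty_intersection(self):
        nets, _ = self.run_nets(0)
        a, b, c = nets
        # relabel b's proteins so edge sets are disjoint
        b.edges["protein_a"] = "X" + b.edges["protein_a"]
        b.edges["protein_b"] = "X" + b.edges["protein_b"]
        comp = compare_networks([a, b])
        assert comp.count("A", "B") == 0

    def test_inclusion_exclusion_consistency(self):
        nets, _ = self.run_nets(1)
        comp = compare_networks(nets)
        for line in "ABC":
            total = sum(v for k, v in comp.region_counts.items() if line in k)
            assert total == len(comp.edge_sets[line])

    def test_planted_region_counts_recovered(self):
        # single-seed sanity check; the multi-seed version is an
        # acceptance-level test
        nets, classes = self.run_nets(4)
        comp = compare_networks(nets)
        assert abs(comp.count("A", "B", "C") - len(classes["core"])) <= 2
        assert abs(comp.count("A", "B") - len(classes["mutant_shared"])) <= 2
        assert abs(comp.count("B", "C") - len(classes["lineage_shared"])) <= 2
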