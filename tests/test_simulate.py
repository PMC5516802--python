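"""Ground-truth structure of the synthetic screen generator."""

import numpy as np
import pytest

from mirscreen.simulate import (
    DEFAULT_ACTIVATORS,
    DEFAULT_REPRESSORS,
    PlantedGGM,
    SimulationConfig,
    partial_correlations,
    planted_cell_line_ggms,
    random_sparse_precision,
    sample_ggm,
    simulate_primary_screen,
    simulate_proliferation,
    simulate_secondary_screens,
)


class TestPrimaryScreen:
    def test_default_shape_and_label_values(self):
        screen, labels = simulate_primary_screen(SimulationConfig(seed=0))
        assert screen.shape == (879 + 8, 127)  # 879 miRNAs + control rows
        assert set(labels[:879]) == {1, 2, 3, 4, 5}
        assert set(labels[879:]) == {0}  # controls
        sizes = {c: int((labels == c).sum()) for c in (1, 2, 3, 4, 5)}
        assert sizes == {1: 79, 2: 153, 3: 382, 4: 115, 5: 150}

    def test_zero_noise_gives_identical_rows_within_cluster(self):
        cfg = SimulationConfig(n_mirna=60, n_protein=30,
                               cluster_sizes=(20, 20), noise_sd=0.0,
                               n_controls=0, seed=1)
        screen, labels = simulate_primary_screen(cfg)
        for c in (1, 2):
            rows = screen.values[labels == c]
            assert np.ptp(rows, axis=0).max() == 0.0

    def test_signature_mean_matches_effect_size(self, small_sim_config, small_primary):
        from mirscreen.simulate import cluster_signatures, default_protein_panel

        screen, labels = small_primary
        panel = default_protein_panel(small_sim_config.n_protein)
        sigs = cluster_signatures(small_sim_config, panel)
        for cid, sig in sigs.items():
            rows = screen.values[labels == cid]
            for prot, eff in sig.items():
                col = screen.protein_ids.index(prot)
                se = small_sim_config.noise_sd / np.sqrt(len(rows))
                # 4 SE: ~24 signature cells are checked simultaneously
                assert abs(rows[:, col].mean() - eff) < 4 * se + 1e-9

    def test_inconsistent_cluster_sizes_rejected(self):
        with pytest.raises(ValueError, match="cluster_sizes"):
            SimulationConfig(n_mirna=100, cluster_sizes=(60, 60))

    def test_seed_reproducibility(self):
        cfg = SimulationConfig(n_mirna=50, n_protein=20, cluster_sizes=(15, 15),
                               seed=5, n_controls=2)
        a, la = simulate_primary_screen(cfg)
        b, lb = simulate_primary_screen(cfg)
        assert np.array_equal(a.values, b.values) and np.array_equal(la, lb)


class TestProliferation:
    def test_zero_coupling_zero_noise_gives_zeros(self, small_primary):
        screen, _ = small_primary
        t = simulate_proliferation(screen, beta=0.0, noise_sd=0.0)
        assert np.all(t.rel_change == 0.0)

    def test_single_activator_identity(self, small_primary):
        screen, _ = small_primary
        t = simulate_proliferation(screen, activator_ids=["CCNB1"],
                                   repressor_ids=[], beta=1.0, noise_sd=0.0)
        col = screen.protein_ids.index("CCNB1")
        assert np.allclose(t.rel_change, screen.values[:, col])

    def test_overlapping_sets_rejected(self, small_primary):
        screen, _ = small_primary
        with pytest.raises(ValueError, match="overlap"):
            simulate_proliferation(screen, ["CCNB1"], ["CCNB1", "PTEN"])

    def test_correlates_with_activator_signal_at_default_noise(self, small_primary):
        screen, _ = small_primary
        t = simulate_proliferation(screen, seed=3)
        df = screen.to_frame()
        signal = (df[list(DEFAULT_ACTIVATORS)].mean(axis=1)
                  - df[list(DEFAULT_REPRESSORS)].mean(axis=1))
        r = np.corrcoef(t.rel_change, signal)[0, 1]
        assert r >= 0.9


class TestPlantedGGM:
    def test_hand_computed_partial_correlations(self):
        theta = np.array([[2.0, -1.0, 0.0], [-1.0, 2.0, -1.0], [0.0, -1.0, 2.0]])
        rho = partial_correlations(theta)
        assert rho[0, 1] == pytest.approx(0.5)
        assert rho[1, 2] == pytest.approx(0.5)
        assert rho[0, 2] == pytest.approx(0.0)

    def test_no_edges_gives_diagonal(self):
        g = random_sparse_precision(6, 0, seed=2)
        off = g.precision - np.diag(np.diag(g.precision))
        assert np.all(off == 0) and g.support == frozenset()

    def test_too_many_edges_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            random_sparse_precision(4, 7)

    @pytest.mark.parametrize("seed", range(20))
    def test_positive_definite_and_exact_magnitude(self, seed):
        g = random_sparse_precision(12, 10, 0.35, seed=seed)
        assert np.linalg.eigvalsh(g.precision).min() > 0
        rho = partial_correlations(g.precision)
        for i, j in g.support:
            assert abs(rho[i, j]) == pytest.approx(0.35, abs=1e-12)
        assert len(g.support) == 10

    def test_pd_required_on_explicit_edges(self):
        # a 3-edge star at |rho| = 0.6 violates the hub's correlation budget
        # (sum of squared partial correlations >= 1) for any edge signs
        with pytest.raises(ValueError, match="positive-definite"):
            random_sparse_precision(4, 3, 0.6, edges=[(0, 1), (0, 2), (0, 3)],
                                    seed=0)

    def test_sample_covariance_converges_to_inverse_precision(self):
        g = random_sparse_precision(8, 7, 0.4, seed=9)
        err = []
        for n in (500, 10_000):
            x = sample_ggm(g, n, seed=4)
            emp = np.cov(x, rowvar=False)
            err.append(np.linalg.norm(emp - g.covariance))
        assert err[1] < err[0]
        assert err[1] < 0.15 * np.linalg.norm(g.covariance)


class TestCellLineDesign:
    def test_planted_shared_edge_counts(self):
        ggms, classes = planted_cell_line_ggms(seed=0)
        sup = {l: set(g.support) for l, g in ggms.items()}
        assert sup["A"] & sup["B"] & sup["C"] == set(classes["core"])
        assert len(classes["core"]) == 8
        assert (sup["A"] & sup["B"]) - sup["C"] == set(classes["mutant_shared"])
        assert len(classes["mutant_shared"]) == 9
        assert (sup["B"] & sup["C"]) - sup["A"] == set(classes["lineage_shared"])
        assert len(classes["lineage_shared"]) == 1
        assert (sup["A"] & sup["C"]) - sup["B"] == set()

    def test_secondary_screen_shapes_and_truth(self):
        cfg = SimulationConfig(seed=0)
        sec = simulate_secondary_screens(cfg, seed=0)
        assert len(sec.screens) == 3
        for s in sec.screens:
            assert s.shape == (154, 127)
        assert len(sec.shared_protein_ids) == 103
        assert len(sec.labels) == 154
        assert not sec.regulators.empty

    def test_flip_prob_validated(self):
        cfg = SimulationConfig(seed=0)
        with pytest.raises(ValueError, match="flip_prob"):
            simulate_secondary_screens(cfg, flip_prob=1.5)

    def test_signature_signs_agree_between_screens_without_flip(self):
        cfg = SimulationConfig(n_mirna=300, n_protein=127,
                               cluster_sizes=(40, 60, 50, 60), noise_sd=0.05,
                               seed=2, n_controls=0)
        primary, labels = simulate_primary_screen(cfg)
        sec = simulate_secondary_screens(cfg, flip_prob=0.0, seed=2)
        from mirscreen.simulate import cluster_signatures, default_protein_panel
        from mirscreen.screens import is_phospho

        sigs = cluster_signatures(cfg, default_protein_panel(cfg.n_protein))
        s2 = sec.screens[0]
        prim = primary.to_frame()
        for row, (mirna, cid) in enumerate(zip(s2.mirna_ids, sec.labels)):
            if cid == cfg.null_cluster_id:
                continue
            for prot, eff in sigs[cid].items():
                if prot in s2.protein_ids and not is_phospho(prot):
                    v2 = s2.values[row, s2.protein_ids.index(prot)]
                    v1 = prim.loc[mirna, prot]
                    assert np.sign(v1) == np.sign(v2) == np.sign(eff)

    def test_support_symmetry_and_no_self_edges(self):
        with pytest.raises(ValueError, match="self-edges"):
            PlantedGGM(np.eye(3), frozenset({(1, 1)}))
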