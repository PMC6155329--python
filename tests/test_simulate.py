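import numpy as np
import pandas as pd
import pytest

import chromou as co


class TestYuleTree:
    def test_minimal_tree_structure(self):
        t = co.simulate_yule_tree(3, 0)
        assert t.n_tips == 3
        assert t.n_nodes - t.n_tips == 2  # root + one internal

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_unit_height_and_ultrametric(self, seed):
        t = co.simulate_yule_tree(40, seed)
        assert t.height == pytest.approx(1.0)
        assert t.is_ultrametric()
        assert t.branch_length[: t.n_tips].min() > 0

    def test_determinism(self):
        a = co.simulate_yule_tree(25, 42)
        b = co.simulate_yule_tree(25, 42)
        assert a.to_newick() == b.to_newick()
        c = co.simulate_yule_tree(25, 43)
        assert a.to_newick() != c.to_newick()

    def test_too_few_tips_rejected(self):
        with pytest.raises(ValueError):
            co.simulate_yule_tree(2, 0)


class TestSimulateRegimes:
    def test_no_shifts_means_single_regime(self, yule):
        tree = yule(20, 1)
        paint, tips = co.simulate_regimes(tree, ("a", "b"), 0.0, 0)
        assert paint.change_count == 0
        assert set(tips.values()) == {"a"}

    def test_certain_shift_flips_every_branch(self, yule):
        tree = yule(10, 2)
        paint, _ = co.simulate_regimes(tree, ("a", "b"), 1.0, 0)
        n_branches = tree.n_nodes - 1
        assert paint.change_count == n_branches
        for v in range(tree.n_nodes):
            p = tree.parent[v]
            if p >= 0:
                assert paint.node_state[v] != paint.node_state[p]

    def test_expected_shift_count_binomial(self, yule):
        tree = yule(30, 3)
        n_branches = tree.n_nodes - 1
        prob = 0.2
        counts = [
            co.simulate_regimes(tree, ("a", "b", "c"), prob, s)[0].change_count
            for s in range(100)
        ]
        mean = np.mean(counts)
        expected = prob * n_branches
        sd = np.sqrt(n_branches * prob * (1 - prob) / 100)
        assert abs(mean - expected) < 4 * sd

    def test_empty_state_set_rejected(self, yule):
        with pytest.raises(ValueError):
            co.simulate_regimes(yule(5, 4), (), 0.1, 0)


class TestSimulateOUTrait:
    def test_stationarity_under_strong_selection(self):
        # at t_half << branch length every tip forgets the root: values are
        # draws from the stationary Normal(theta, v_y)
        tree = co.parse_newick("(A:1,B:1,C:1);")
        paint, _ = co.simulate_regimes(tree, ("a",), 0.0, 0)
        draws = np.concatenate(
            [
                co.simulate_ou_trait(tree, paint, 0.01, 0.5, {"a": 2.0}, s)
                for s in range(500)
            ]
        )
        assert np.mean(draws) == pytest.approx(2.0, abs=0.05)
        assert np.var(draws) == pytest.approx(0.5, rel=0.1)

    def test_weak_selection_recovers_bm_increments(self, yule):
        tree = yule(30, 5)
        paint, _ = co.simulate_regimes(tree, ("a",), 0.0, 0)
        t_half = 1e6
        v_y = 1e6  # sigma2 = 2 ln2 v_y / t_half = 2 ln2
        sigma2 = 2 * (np.log(2) / t_half) * v_y
        ou = co.simulate_ou_trait(tree, paint, t_half, v_y, {"a": 0.0}, 99, y0=0.0)
        bm = co.simulate_bm_trait(tree, sigma2, 99, y0=0.0)
        np.testing.assert_allclose(ou, bm, atol=1e-3)

    def test_missing_optimum_rejected(self, yule):
        tree = yule(5, 6)
        paint, _ = co.simulate_regimes(tree, ("a", "b"), 0.5, 1)
        with pytest.raises(KeyError):
            co.simulate_ou_trait(tree, paint, 0.3, 0.2, {"a": 1.0}, 0)

    def test_determinism(self, yule):
        tree = yule(15, 7)
        paint, _ = co.simulate_regimes(tree, ("a",), 0.0, 0)
        y1 = co.simulate_ou_trait(tree, paint, 0.3, 0.2, {"a": 3.0}, 5)
        y2 = co.simulate_ou_trait(tree, paint, 0.3, 0.2, {"a": 3.0}, 5)
        np.testing.assert_array_equal(y1, y2)


class TestBmPredictor:
    def test_zero_rate_is_constant(self, yule):
        tree = yule(10, 8)
        out = co.simulate_bm_predictor(tree, 1e-12, 0, mean=5.0)
        np.testing.assert_allclose(out["mean"], 5.0, atol=1e-4)
        assert (out["sd"] > 0).all()

    def test_tip_covariance_proportional_to_shared_time(self, yule):
        tree = yule(8, 9)
        tm = co.time_matrices(tree)
        reps = np.array(
            [
                co.simulate_bm_predictor(tree, 2.0, 1000 + s)["mean"].to_numpy()
                for s in range(800)
            ]
        )
        emp = np.cov(reps.T)
        theo = 2.0 * tm.shared_time
        se = np.sqrt((np.outer(np.diag(theo), np.diag(theo)) + theo**2) / 800)
        assert np.all(np.abs(emp - theo) < 4 * se + 1e-9)


class TestEmitAccessions:
    def test_zero_sd_gives_identical_counts(self):
        cfg = co.SimulationConfig(within_species_sd=0.0, accessions_min=3, accessions_max=3)
        acc = co.emit_accessions({"a": 3.0, "b": 3.5}, cfg, 0)
        for _, grp in acc.groupby("species"):
            assert grp["count_2n"].nunique() == 1

    def test_counts_even_and_at_least_four(self):
        cfg = co.SimulationConfig(within_species_sd=0.3)
        y = {f"s{i}": v for i, v in enumerate(np.linspace(1.0, 4.5, 50))}
        acc = co.emit_accessions(y, cfg, 1)
        assert (acc["count_2n"] % 2 == 0).all()
        assert (acc["count_2n"] >= 4).all()
        assert (acc["count_x"] >= 2).all()

    def test_pooled_variance_estimator_consistency(self):
        # large counts make the even-integer rounding negligible, so the
        # pooled log-scale variance should recover within_species_sd^2
        sd = 0.1
        cfg = co.SimulationConfig(
            within_species_sd=sd, accessions_min=3, accessions_max=3
        )
        rng = np.random.default_rng(2)
        y = {f"s{i}": v for i, v in enumerate(rng.normal(4.2, 0.3, 500))}
        acc = co.emit_accessions(y, cfg, 3)
        table = co.pooled_observation_variance(co.species_means(acc))
        assert table.attrs["s2_pooled"] == pytest.approx(sd**2, rel=0.10)


class TestMakeDataset:
    def test_roundtrip_through_readers(self, tmp_path):
        ds = co.make_dataset(co.SimulationConfig(n_tips=20, seed=5))
        ds.write(tmp_path)
        from chromou.traits import read_accessions

        tree = co.parse_newick((tmp_path / "tree.nwk").read_text())
        acc = read_accessions(tmp_path / "accessions.tsv")
        assert set(acc["species"]) == set(tree.tip_labels)
        pd.testing.assert_frame_equal(
            acc.reset_index(drop=True), ds.accessions.reset_index(drop=True)
        )

    def test_bit_reproducible(self):
        a = co.make_dataset(co.SimulationConfig(n_tips=15, seed=7))
        b = co.make_dataset(co.SimulationConfig(n_tips=15, seed=7))
        assert a.tree.to_newick() == b.tree.to_newick()
        pd.testing.assert_frame_equal(a.accessions, b.accessions)
        pd.testing.assert_frame_equal(a.species, b.species)
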