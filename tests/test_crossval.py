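import numpy as np
import pytest

from megp import (
    McmcConfig,
    ModelSpec,
    PartitionSet,
    SimulationSpec,
    TrialData,
    evaluate,
    fit,
    make_partitions,
    pearson_by_env,
    simulate_trial,
)


def balanced_trial(n_lines=20, n_envs=4, seed=0) -> TrialData:
    rng = np.random.default_rng(seed)
    return TrialData(
        [
            (f"L{i:03d}", f"E{j}", float(rng.normal()))
            for j in range(n_envs)
            for i in range(n_lines)
        ]
    )


class TestMakePartitions:
    def test_cv1_tests_exactly_twenty_percent_of_lines(self):
        T = balanced_trial(10, 3)
        ps = make_partitions(T, "CV1", n_partitions=5, fraction_train=0.8, seed=1)
        for train, test in ps.partitions:
            test_lines = set(T.line_index[test])
            assert len(test_lines) == 2
            # line-jointness: every record of a test line is in the test set
            for i in test_lines:
                assert set(np.where(T.line_index == i)[0]) <= set(test)

    def test_cv2_splits_some_line_across_train_and_test(self):
        T = balanced_trial(20, 4)
        ps = make_partitions(T, "CV2", n_partitions=3, seed=2)
        found = False
        for train, test in ps.partitions:
            for i in set(T.line_index[test]):
                recs = set(np.where(T.line_index == i)[0])
                if recs & set(train) and recs & set(test):
                    found = True
        assert found

    def test_disjoint_and_covering(self):
        T = balanced_trial(15, 3)
        for scheme in ("CV1", "CV2"):
            ps = make_partitions(T, scheme, n_partitions=4, seed=3)
            for train, test in ps.partitions:
                assert len(np.intersect1d(train, test)) == 0
                assert len(np.union1d(train, test)) == T.n_records

    def test_seed_determinism(self):
        T = balanced_trial(12, 3)
        a = make_partitions(T, "CV2", n_partitions=4, seed=9)
        b = make_partitions(T, "CV2", n_partitions=4, seed=9)
        for (tr1, te1), (tr2, te2) in zip(a.partitions, b.partitions):
            np.testing.assert_array_equal(te1, te2)
            np.testing.assert_array_equal(tr1, tr2)

    def test_every_env_keeps_two_test_records(self):
        T = balanced_trial(25, 5, seed=4)
        ps = make_partitions(T, "CV2", n_partitions=10, seed=5)
        for _, test in ps.partitions:
            counts = np.bincount(T.env_index[test], minlength=5)
            assert np.all(counts >= 2)

    def test_too_few_lines_fails(self):
        T = balanced_trial(3, 2)
        with pytest.raises(ValueError):
            make_partitions(T, "CV1", n_partitions=2, fraction_train=0.99, seed=0)

    def test_kfold_folds_are_disjoint_and_cover(self):
        T = balanced_trial(20, 3)
        ps = make_partitions(T, "CV2", fraction_train=0.8, seed=6, kfold=True)
        assert len(ps.partitions) == 5
        all_test = np.concatenate([te for _, te in ps.partitions])
        assert len(all_test) == T.n_records
        assert len(np.unique(all_test)) == T.n_records

    def test_stratified_cv2_balances_environments(self):
        T = balanced_trial(30, 3)
        ps = make_partitions(T, "CV2", n_partitions=3, seed=7, stratify_env=True)
        for _, test in ps.partitions:
            counts = np.bincount(T.env_index[test], minlength=3)
            assert counts.max() - counts.min() <= 1

    def test_json_round_trip(self, tmp_path):
        T = balanced_trial(12, 3)
        ps = make_partitions(T, "CV1", n_partitions=3, seed=8)
        path = tmp_path / "parts.json"
        ps.to_json(path)
        back = PartitionSet.from_json(path)
        assert back.scheme == ps.scheme
        for (tr1, te1), (tr2, te2) in zip(ps.partitions, back.partitions):
            np.testing.assert_array_equal(te1, te2)


class TestPearson:
    def test_perfect_predictions_score_one(self):
        T = balanced_trial(10, 2, seed=9)
        test = np.arange(T.n_records)
        r = pearson_by_env(T, T.y.copy(), test)
        for v in r.values():
            assert v == pytest.approx(1.0)

    def test_affine_invariance(self):
        T = balanced_trial(10, 2, seed=10)
        test = np.arange(T.n_records)
        r = pearson_by_env(T, 3.0 + 2.0 * T.y, test)
        for v in r.values():
            assert v == pytest.approx(1.0)

    def test_small_or_degenerate_test_sets_skipped(self):
        T = balanced_trial(10, 2, seed=11)
        test = np.array([0])  # single record in E0, none in E1
        r = pearson_by_env(T, T.y.copy(), test)
        assert all(v is None for v in r.values())


class TestEvaluate:
    def test_mask_integrity_no_leakage(self, mdsl_sim):
        """Replacing test phenotypes by arbitrary constants leaves the
        posterior chains bit-identical under the same seed."""
        _, T, truth = mdsl_sim
        ps = make_partitions(T, "CV2", n_partitions=1, seed=12)
        _, test = ps.partitions[0]
        cfg = McmcConfig(200, 50, 1, seed=31)
        r1 = fit(T, ModelSpec("MDs", "GB"), truth.K, cfg=cfg, mask=test)
        y2 = T.y.copy()
        y2[test] = 123.456
        T2 = TrialData(T.df.assign(y=y2))
        r2 = fit(T2, ModelSpec("MDs", "GB"), truth.K, cfg=cfg, mask=test)
        assert r1.chains.equals(r2.chains)
        np.testing.assert_array_equal(r1.predictions, r2.predictions)

    def test_accuracy_table_shape_and_format(self, mdsl_sim):
        _, T, truth = mdsl_sim
        ps = make_partitions(T, "CV2", n_partitions=2, seed=13)
        tab = evaluate(T, [ModelSpec("MM", "GB")], {"GB": truth.K}, ps,
                       cfg=McmcConfig(200, 50, 2, seed=1))
        assert list(tab.mean.index) == T.env_ids
        assert list(tab.mean.columns) == ["MM-GB"]
        cell = tab.formatted().iloc[0, 0]
        assert "(" in cell and ")" in cell

    def test_cv1_not_better_than_cv2_with_intercept_signal(self):
        """An iid line intercept helps only lines already seen somewhere, so
        CV1 accuracy cannot beat CV2 accuracy."""
        spec = SimulationSpec(n_lines=150, n_markers=300, n_envs=3, model="MDsl",
                              sigma2_g=0.2, sigma2_ge=0.2, sigma2_l=0.8,
                              sigma2=0.6, seed=14)
        T, truth = simulate_trial(spec)
        cfg = McmcConfig(500, 200, 2, seed=15)
        means = {}
        for scheme in ("CV1", "CV2"):
            ps = make_partitions(T, scheme, n_partitions=4, seed=16)
            tab = evaluate(T, [ModelSpec("MDsl", "GB")], {"GB": truth.K}, ps, cfg=cfg)
            means[scheme] = float(tab.mean.mean().mean())
        assert means["CV1"] <= means["CV2"]
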