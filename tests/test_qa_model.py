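"""SVR training, grouped cross-validation and the global-score formula."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.svm import SVR

from resqa.errors import InputError
from resqa.feature_encoding import ExampleSet
from resqa.qa_model import (
    ResidueQualityModel,
    ResidueQualityResults,
    SvrConfig,
    local_to_global,
)


def make_examples(n_models=10, per_model=20, dim=12, seed=0, target_fn=None):
    """Synthetic example set: target is a noisy function of the features."""
    rng = np.random.default_rng(seed)
    feats, targets, rids = [], [], []
    for m in range(n_models):
        x = rng.uniform(size=(per_model, dim))
        if target_fn is None:
            y = 12.0 * (1.0 - x[:, :5].mean(axis=1)) + rng.normal(
                0, 0.3, per_model
            )
        else:
            y = target_fn(x, rng)
        feats.append(x)
        targets.append(y)
        rids += [(f"m{m:02d}", i + 1) for i in range(per_model)]
    return ExampleSet(
        features=np.vstack(feats),
        targets=np.clip(np.concatenate(targets), 0, None),
        residue_ids=rids,
        feature_set="basic",
        window=15,
    )


class TestLocalToGlobal:
    def test_zero_deviations_give_one(self):
        assert local_to_global([0.0, 0.0, 0.0]) == 1.0

    def test_deviation_equal_to_c_gives_half(self):
        assert local_to_global([5.0] * 4, c=5.0) == pytest.approx(0.5)

    def test_mixed_vector(self):
        assert local_to_global([0, 5, 5, 0], c=5.0) == pytest.approx(0.75)

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(st.lists(st.floats(0, 100, allow_nan=False), min_size=1,
                    max_size=50))
    def test_bounds_and_monotonicity(self, devs):
        g = local_to_global(devs)
        assert 0.0 < g <= 1.0
        bumped = list(devs)
        bumped[0] += 1.0
        assert local_to_global(bumped) < g
        assert local_to_global(list(reversed(devs))) == pytest.approx(g)

    def test_empty_vector_rejected(self):
        with pytest.raises(InputError):
            local_to_global([])


class TestFolds:
    def test_models_never_straddle_folds(self):
        es = make_examples(n_models=11)
        model = ResidueQualityModel(es, SvrConfig(seed=3))
        folds = model.fold_assignment()
        for mid in {m for m, _ in es.residue_ids}:
            mask = np.array([m == mid for m, _ in es.residue_ids])
            assert len(set(folds[mask])) == 1

    def test_row_order_invariance(self):
        es = make_examples(n_models=8)
        perm = np.random.default_rng(1).permutation(es.n_examples)
        shuffled = ExampleSet(
            es.features[perm], es.targets[perm],
            [es.residue_ids[i] for i in perm], es.feature_set, es.window,
        )
        a = ResidueQualityModel(es, SvrConfig(seed=5)).fold_assignment()
        b = ResidueQualityModel(shuffled, SvrConfig(seed=5)).fold_assignment()
        for i, j in enumerate(perm):
            assert a[j] == b[i]

    def test_too_few_groups_rejected(self):
        es = make_examples(n_models=3)
        with pytest.raises(InputError):
            ResidueQualityModel(es, SvrConfig(folds=5)).fold_assignment()


class TestCrossValidation:
    def test_singleton_grid_returned(self):
        es = make_examples(n_models=6, per_model=10)
        cfg = SvrConfig(cost_grid=(2.0,), epsilon_grid=(0.2,),
                        gamma_grid=(0.05,), seed=0)
        table, best = ResidueQualityModel(es, cfg).cross_validate()
        assert best == (2.0, 0.2, 0.05)
        assert len(table) == 1

    def test_duplicate_grid_values_deduplicated(self):
        es = make_examples(n_models=6, per_model=10)
        a = SvrConfig(cost_grid=(1.0, 1.0), epsilon_grid=(0.2,),
                      gamma_grid=(0.05, 0.05), seed=0)
        b = SvrConfig(cost_grid=(1.0,), epsilon_grid=(0.2,),
                      gamma_grid=(0.05,), seed=0)
        ta, ba = ResidueQualityModel(es, a).cross_validate()
        tb, bb = ResidueQualityModel(es, b).cross_validate()
        assert ba == bb
        assert len(ta) == len(tb) == 1

    def test_matches_independent_fold_loop(self):
        """Grid search equals a brute-force re-evaluation over the same folds."""
        es = make_examples(n_models=6, per_model=12, seed=4)
        cfg = SvrConfig(cost_grid=(0.5, 5.0), epsilon_grid=(0.1, 0.4),
                        gamma_grid=(0.05, 0.5), folds=3, seed=9)
        qam = ResidueQualityModel(es, cfg)
        table, best = qam.cross_validate()
        folds = qam.fold_assignment()
        expected = {}
        for c, w, g in itertools.product(cfg.cost_grid, cfg.epsilon_grid,
                                         cfg.gamma_grid):
            errs = []
            for f in range(3):
                te = folds == f
                svr = SVR(kernel="rbf", C=c, epsilon=w, gamma=g)
                svr.fit(es.features[~te], es.targets[~te])
                errs.append(np.abs(svr.predict(es.features[te]) - es.targets[te]))
            expected[(c, w, g)] = float(np.mean(np.concatenate(errs)))
        for row in table.itertuples():
            assert row.cv_mae == pytest.approx(
                expected[(row.cost, row.epsilon, row.gamma)], abs=1e-12
            )
        assert best == min(expected, key=lambda k: (expected[k], k))


class TestFitPredict:
    def test_constant_targets_predicted_within_epsilon(self):
        es = make_examples(n_models=6, per_model=10,
                           target_fn=lambda x, rng: np.full(len(x), 3.0))
        cfg = SvrConfig(cost_grid=(1.0,), epsilon_grid=(0.2,),
                        gamma_grid=(0.05,))
        res = ResidueQualityModel(es, cfg).fit(params=(1.0, 0.2, 0.05))
        assert res.constant_target
        np.testing.assert_allclose(res.predict(es), 3.0, atol=0.2 + 1e-6)

    def test_recoverable_signal(self):
        """Held-out correlation >= 0.9 when the target is a clean function
        of the features (noise sigma 0.3)."""
        train = make_examples(n_models=10, per_model=30, seed=1)
        test = make_examples(n_models=4, per_model=30, seed=99)
        cfg = SvrConfig(cost_grid=(10.0,), epsilon_grid=(0.1,),
                        gamma_grid=(0.1,))
        res = ResidueQualityModel(train, cfg).fit(params=(10.0, 0.1, 0.1))
        r = np.corrcoef(res.predict(test), test.targets)[0, 1]
        assert r >= 0.9

    def test_negative_raw_outputs_clamped(self):
        res = ResidueQualityResults(
            svr=None, params={"cost": 1, "epsilon": 0.1, "gamma": 0.1},
            cv_table=None, feature_set="basic", window=15, dim=3, n_train=1,
        )

        class FakeSvr:
            def predict(self, x):
                return np.array([-0.4, 2.0])

        res.svr = FakeSvr()
        out = res.predict(np.zeros((2, 3)))
        assert out[0] == 0.0 and out[1] == 2.0

    def test_dimension_and_tag_mismatch_rejected(self):
        es = make_examples(n_models=6, per_model=10)
        res = ResidueQualityModel(es, SvrConfig()).fit(params=(1.0, 0.1, 0.1))
        with pytest.raises(InputError):
            res.predict(np.zeros((2, 99)))
        other = ExampleSet(np.zeros((2, 12)), None,
                           [("x", 1), ("x", 2)], "profile", 15)
        with pytest.raises(InputError):
            res.predict(other)

    def test_save_load_bit_identical(self, tmp_path):
        es = make_examples(n_models=6, per_model=10)
        res = ResidueQualityModel(es, SvrConfig()).fit(params=(1.0, 0.1, 0.1))
        p = tmp_path / "model.joblib"
        res.save(p)
        back = ResidueQualityResults.load(p)
        np.testing.assert_allclose(back.predict(es), res.predict(es),
                                   atol=1e-9)
        assert back.params == res.params
        assert back.feature_set == res.feature_set

    def test_predict_local_composes_global_score(self):
        es = make_examples(n_models=6, per_model=10)
        res = ResidueQualityModel(es, SvrConfig()).fit(params=(1.0, 0.1, 0.1))
        local = res.predict_local(es)
        assert local.global_score == pytest.approx(
            local_to_global(local.deviations)
        )
        assert 0.0 < local.global_score <= 1.0

    def test_summary_mentions_chosen_parameters(self):
        es = make_examples(n_models=6, per_model=10)
        res = ResidueQualityModel(es, SvrConfig()).fit(params=(2.0, 0.3, 0.05))
        text = res.summary()
        assert "2" in text and "0.3" in text and "basic" in text


def test_config_validation():
    with pytest.raises(InputError):
        SvrConfig(folds=1)
    with pytest.raises(InputError):
        SvrConfig(cost_grid=(0.0,))
    with pytest.raises(InputError):
        SvrConfig(gamma_grid=())
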