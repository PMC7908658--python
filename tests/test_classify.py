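import math

import numpy as np
import pandas as pd
import pytest

from trftarget.chimera import InteractionPair
from trftarget.classify import (
    ConfusionMatrix,
    GaConfig,
    SitePrediction,
    TargetSiteClassifier,
    aggregate_transcript,
    compare_feature_distributions,
    evaluate,
    ga_select_features,
    make_folds,
    sample_negatives,
    train_cv_svm,
)
from trftarget.seq import Interval
from trftarget.sites import SeedMatchSite


def _pair(trf, tx, start=0, tag=None):
    site = SeedMatchSite(trf, tx, Interval(tx, start, start + 6), False, False, False, start, 10)
    return InteractionPair(trf, tx, site, "background", "scan")


def _linear_data(n=120, n_features=8, n_informative=1, effect=2.0, seed=0):
    """Synthetic labels driven by the first features with a 2 SD shift."""
    rng = np.random.default_rng(seed)
    y = np.repeat([1, 0], n // 2)
    X = rng.normal(size=(n, n_features))
    for j in range(n_informative):
        X[:, j] += effect * y
    return X, y


class TestMakeFolds:
    def test_sizes_differ_by_at_most_one(self):
        y = np.array([0, 1] * 1274)[:2547]
        folds = make_folds(np.resize([0, 1, 0, 0, 1], 2547))
        sizes = sorted(np.bincount(folds)[1:], reverse=True)
        assert sizes == [510, 510, 509, 509, 509]

    def test_every_row_in_exactly_one_fold(self):
        folds = make_folds(np.resize([0, 1], 103))
        assert len(folds) == 103 and set(folds) == {1, 2, 3, 4, 5}

    def test_stratified_within_one_item(self):
        y = np.resize([0, 0, 0, 0, 1], 250)
        folds = make_folds(y)
        rates = [y[folds == k].sum() for k in range(1, 6)]
        assert max(rates) - min(rates) <= 1

    def test_deterministic_per_seed(self):
        y = np.resize([0, 1], 100)
        assert np.array_equal(make_folds(y, rng_seed=4), make_folds(y, rng_seed=4))
        assert not np.array_equal(make_folds(y, rng_seed=4), make_folds(y, rng_seed=5))


class TestSampleNegatives:
    def _background(self, n):
        return [_pair("t", f"NM_{i}", start=0) for i in range(n)]

    def test_ratio_contract(self):
        bg = self._background(5000)
        tags = {f"NM_{i}": i for i in range(5000)}
        neg = sample_negatives(bg, tags, 100)
        assert len(neg) == 500
        assert all(p.label == "negative" for p in neg)

    def test_deterministic_per_seed(self):
        bg = self._background(3000)
        tags = {f"NM_{i}": i % 97 for i in range(3000)}
        a = sample_negatives(bg, tags, 50, rng_seed=9)
        b = sample_negatives(bg, tags, 50, rng_seed=9)
        assert [p.key for p in a] == [p.key for p in b]

    def test_sample_prefers_high_tag_pool(self):
        bg = self._background(4000)
        rng = np.random.default_rng(0)
        tags = {f"NM_{i}": int(rng.integers(0, 1000)) for i in range(4000)}
        neg = sample_negatives(bg, tags, 100, rng_seed=1)
        med_sample = np.median([tags[p.transcript_id] for p in neg])
        med_bg = np.median([tags[p.transcript_id] for p in bg])
        assert med_sample >= med_bg

    def test_small_background_taken_whole(self):
        bg = self._background(30)
        neg = sample_negatives(bg, {}, 100)
        assert len(neg) == 30


class TestGaSelectFeatures:
    def test_informative_feature_recovered(self):
        hits = 0
        for seed in range(5):
            X, y = _linear_data(n=100, n_features=20, seed=seed)
            folds = make_folds(y, rng_seed=seed)
            cfg = GaConfig(iterations=20, population_size=20, rng_seed=seed)
            mask, _ = ga_select_features(X, y, folds, cfg)
            hits += bool(mask[0])
        assert hits >= 4

    def test_single_feature_input(self):
        X, y = _linear_data(n=60, n_features=1)
        folds = make_folds(y)
        mask, _ = ga_select_features(X, y, folds, GaConfig(iterations=1))
        assert mask.tolist() == [True]

    def test_elitism_beats_all_ones_mask(self):
        from trftarget.classify import _cv_auc

        X, y = _linear_data(n=80, n_features=10, seed=3)
        folds = make_folds(y, rng_seed=3)
        cfg = GaConfig(iterations=5, population_size=10, rng_seed=3)
        _, best_fit = ga_select_features(X, y, folds, cfg)
        all_ones = _cv_auc(X, y, folds, np.ones(10, dtype=bool), {"C": 1.0, "gamma": "scale"})
        assert best_fit >= all_ones - 1e-12


class TestTrainCvSvm:
    def test_separable_data_high_auc(self):
        X, y = _linear_data(n=150, n_features=5, effect=4.0)
        folds = make_folds(y)
        model, heldout = train_cv_svm(
            X, y, folds, np.ones(5, dtype=bool), [f"f{i}" for i in range(5)]
        )
        assert min(model.fold_auc_test) >= 0.95
        assert not np.isnan(heldout).any()

    def test_each_row_scored_exactly_once(self):
        X, y = _linear_data(n=60, n_features=3)
        folds = make_folds(y)
        _, heldout = train_cv_svm(X, y, folds, np.ones(3, dtype=bool), list("abc"))
        assert heldout.shape == (60,)
        assert np.all((heldout >= 0) & (heldout <= 1))

    def test_scaler_ignores_test_fold_rows(self):
        X, y = _linear_data(n=100, n_features=4, seed=2)
        folds = make_folds(y, rng_seed=2)
        model_a, _ = train_cv_svm(X, y, folds, np.ones(4, dtype=bool), list("abcd"))
        X_mut = X.copy()
        X_mut[folds == 1] += 1000.0  # corrupt fold-1 test rows only
        model_b, _ = train_cv_svm(X_mut, y, folds, np.ones(4, dtype=bool), list("abcd"))
        np.testing.assert_allclose(
            model_a.fold_models[0].scaler.mean_, model_b.fold_models[0].scaler.mean_
        )

    def test_empty_mask_rejected(self):
        X, y = _linear_data(n=40, n_features=3)
        with pytest.raises(ValueError):
            train_cv_svm(X, y, make_folds(y), np.zeros(3, dtype=bool), list("abc"))


class TestAggregateTranscript:
    def _sites(self, ps):
        return [SitePrediction("t", "x", i * 10, i * 10 + 6, p) for i, p in enumerate(ps)]

    @pytest.mark.parametrize(
        "ps,expected,is_target",
        [([0.5], 0.5, False), ([0.5, 0.5], 0.75, True), ([0.9, 0.2], 0.92, True)],
    )
    def test_noisy_or_examples(self, ps, expected, is_target):
        pred = aggregate_transcript(self._sites(ps))
        assert pred.P == pytest.approx(expected, abs=1e-12)
        assert pred.is_target is is_target
        assert pred.n_sites == len(ps)

    def test_adding_a_site_never_decreases_p(self):
        rng = np.random.default_rng(0)
        ps = list(rng.uniform(size=8))
        values = [aggregate_transcript(self._sites(ps[: k + 1])).P for k in range(8)]
        assert all(b >= a - 1e-12 for a, b in zip(values, values[1:]))
        assert all(0 <= v <= 1 for v in values)

    def test_p_at_least_max_site(self):
        sites = self._sites([0.3, 0.8, 0.1])
        assert aggregate_transcript(sites).P >= 0.8

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate_transcript([])


class TestEvaluate:
    def test_perfect_classifier(self):
        m = evaluate(ConfusionMatrix(5, 5, 0, 0))
        assert (m.sensitivity, m.specificity, m.mcc) == (1.0, 1.0, 1.0)

    def test_worked_example(self):
        m = evaluate(ConfusionMatrix(TP=2, TN=3, FP=1, FN=4))
        assert m.mcc == pytest.approx(2 / math.sqrt(504), abs=1e-9)
        assert m.sensitivity == pytest.approx(2 / 6)
        assert m.specificity == pytest.approx(3 / 4)

    def test_degenerate_all_positive_predictions(self):
        m = evaluate(ConfusionMatrix(TP=5, TN=0, FP=5, FN=0))
        assert m.specificity == 0.0
        assert math.isnan(m.mcc)


class TestCompareFeatureDistributions:
    def _frames(self, a, b, name="pos8_match"):
        return pd.DataFrame({name: a}), pd.DataFrame({name: b})

    def test_identical_groups(self):
        pos, bg = self._frames([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        table = compare_feature_distributions(pos, bg)
        row = table[table.feature == "pos8_match"].iloc[0]
        assert row.t == pytest.approx(0.0, abs=1e-12)
        assert row.p_value == pytest.approx(1.0, abs=1e-9)

    def test_pooled_variance_oracle(self):
        pos, bg = self._frames([1, 2, 3, 4], [3, 4, 5, 6])
        row = compare_feature_distributions(pos, bg).iloc[0]
        # closed form: t = -2 / sqrt(sp^2 * (1/4 + 1/4)), sp^2 = 5/3
        assert row.t == pytest.approx(-2.190890, abs=1e-5)

    def test_zero_variance_flagged(self):
        pos, bg = self._frames([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        row = compare_feature_distributions(pos, bg).iloc[0]
        assert math.isnan(row.p_value)


class TestModelResultsShape:
    def test_fit_summary_and_roundtrip(self, tmp_path):
        X, y = _linear_data(n=80, n_features=6, effect=3.0)
        Xdf = pd.DataFrame(
            X,
            columns=[f"f{i}" for i in range(6)],
            index=pd.MultiIndex.from_tuples(
                [("t", f"NM_{i}", 0, 6) for i in range(80)],
                names=["trf_id", "transcript_id", "start", "end"],
            ),
        )
        model = TargetSiteClassifier(Xdf, y, rng_seed=0)
        res = model.fit()
        assert 0.9 <= res.heldout_auc <= 1.0
        text = res.summary()
        assert "held-out AUC" in text and "fold" in text
        path = tmp_path / "model.bin"
        res.save(path)
        from trftarget.classify import TrainedModel, predict_site_matrix

        loaded = TrainedModel.load(path)
        p1 = predict_site_matrix(loaded, X)
        p2 = predict_site_matrix(res.trained, X)
        np.testing.assert_allclose(p1, p2)
        preds = res.predict_transcripts(Xdf)
        assert len(preds) == 80
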