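import numpy as np
import pytest

from epiboost.classifier import (
    ModelBundleError,
    ModelConfig,
    cross_validate,
    grid_search,
    load_model,
    predict,
    save_model,
    train,
)
from epiboost.evaluation import auroc
from epiboost.feature_encoding import EncoderConfig
from epiboost.peptide_data import EpitopeDataset, Peptide
from epiboost.synthetic_data import generate, preset_bcpreds_like

from conftest import make_dataset

SMALL = ModelConfig(n_estimators=60, max_depth=4, seed=0)
NO_EMB = EncoderConfig(embedding="off")


@pytest.fixture(scope="module")
def separable():
    """Small strongly separable synthetic set (planted effects)."""
    return generate(preset_bcpreds_like(n_pos=80, n_neg=80, seed=11))


class TestTrain:
    def test_training_auroc_on_separable_data(self, separable):
        model = train(separable, None, NO_EMB, SMALL)
        scores = predict(model, separable, None)
        assert auroc(scores, separable.labels()) >= 0.99

    def test_same_seed_identical_predictions(self, separable):
        held_out = generate(preset_bcpreds_like(n_pos=20, n_neg=20, seed=99))
        a = predict(train(separable, None, NO_EMB, SMALL), held_out, None)
        b = predict(train(separable, None, NO_EMB, SMALL), held_out, None)
        assert np.array_equal(a, b)

    def test_single_class_rejected(self):
        ds = make_dataset([("ACDKLM", 1), ("WYTTGG", 1), ("PPGTAC", 1)])
        with pytest.raises(Exception):
            train(ds, None, NO_EMB, SMALL)

    def test_training_positives_score_high(self, separable):
        model = train(separable, None, NO_EMB, SMALL)
        scores = predict(model, separable, None)
        pos_scores = scores[separable.labels() == 1]
        assert (pos_scores > 0.5).mean() > 0.9

    def test_score_vector_length_and_range(self, separable):
        model = train(separable, None, NO_EMB, SMALL)
        scores = predict(model, separable, None)
        assert len(scores) == len(separable)
        assert ((scores >= 0) & (scores <= 1)).all()


class TestPredictContracts:
    def test_mismatched_embedding_dim_rejected(self, separable):
        from epiboost.embedding_providers import MockEmbeddingProvider

        enc = EncoderConfig(embedding_dim=8)
        prov = MockEmbeddingProvider(seed=0, dim=8)
        model = train(separable, prov, enc, SMALL)
        wrong = MockEmbeddingProvider(seed=0, dim=16)
        with pytest.raises(ValueError, match="dim"):
            predict(model, separable, wrong)


class TestCrossValidate:
    def test_null_data_auroc_near_half(self, rng):
        from conftest import random_dataset

        ds = random_dataset(rng, 200, 200, min_len=20, max_len=20, name="null")
        report = cross_validate(ds, None, NO_EMB, SMALL, k=5, seed=4)
        assert 0.42 <= report.mean.auroc <= 0.58

    def test_separable_data_auroc_high(self):
        ds = generate(preset_bcpreds_like(n_pos=200, n_neg=200, seed=21))
        report = cross_validate(ds, None, NO_EMB, SMALL, k=5, seed=21)
        assert report.mean.auroc >= 0.9

    def test_k_exceeding_class_count_rejected(self):
        ds = make_dataset(
            [("ACDKLM", 1)] * 3 + [("WYTTGG", 0)] * 10
        )
        with pytest.raises(ValueError):
            cross_validate(ds, None, NO_EMB, SMALL, k=5, seed=0)

    def test_mean_is_arithmetic_mean_of_folds(self, separable):
        report = cross_validate(separable, None, NO_EMB, SMALL, k=3, seed=0)
        fold_aurocs = [r.auroc for r in report.fold_reports]
        assert report.mean.auroc == pytest.approx(np.mean(fold_aurocs), abs=1e-12)

    def test_leakage_guard_fold_scales_differ_from_full(self):
        """One fold holds every instance of a marker k-mer, so the scales
        built without that fold must differ from full-data scales."""
        from epiboost.antigen_scales import build_scale, count_kmers

        marker = [("WWWWWW", 1)] * 3  # 'WW' appears only in these positives
        filler_pos = [("ACDKLM", 1)] * 9
        filler_neg = [("GHTSNQ", 0), ("RKEDVM", 0), ("TTGGSS", 0)] * 4
        ds = make_dataset(marker + filler_pos + filler_neg)
        full = build_scale(count_kmers(ds, 2))
        report = cross_validate(ds, None, NO_EMB, SMALL, k=3, seed=2)
        differing = sum(
            fold_scale.raw != full.raw for fold_scale in report.fold_aap
        )
        assert differing == report.folds.k

    def test_effect_size_monotonicity(self):
        """Stronger planted effects never reduce mean CV AUROC beyond noise."""
        from epiboost.synthetic_data import GeneratorSpec, PositionalBias

        aurocs = []
        for strength in (0.05, 0.25, 0.50):
            spec = GeneratorSpec(
                n_pos=120,
                n_neg=120,
                min_length=12,
                max_length=12,
                positional_biases=[
                    PositionalBias(2, "P", strength, 0.02),
                    PositionalBias(5, "P", strength, 0.02),
                    PositionalBias(8, "G", strength, 0.02),
                ],
                seed=31,
            )
            report = cross_validate(generate(spec), None, NO_EMB, SMALL, k=3, seed=31)
            aurocs.append(report.mean.auroc)
        assert aurocs[2] >= aurocs[0] - 0.05
        assert aurocs[2] > 0.5


class TestGridSearch:
    def test_single_config_returned(self, separable):
        best, results = grid_search(
            separable, None, NO_EMB, grid=[SMALL], k=3, seed=0
        )
        assert best == SMALL and len(results) == 1

    def test_duplicate_configs_first_wins(self, separable):
        dup = ModelConfig(n_estimators=30, max_depth=3, seed=0)
        best, _ = grid_search(
            separable, None, NO_EMB, grid=[dup, dup], k=3, seed=0
        )
        assert best is dup or best == dup

    def test_underfit_config_loses(self, separable):
        stump = ModelConfig(n_estimators=1, max_depth=1, seed=0)
        strong = ModelConfig(n_estimators=80, max_depth=5, seed=0)
        best, _ = grid_search(
            separable, None, NO_EMB, grid=[stump, strong], k=3, seed=0
        )
        assert best == strong

    def test_empty_grid_rejected(self, separable):
        with pytest.raises(ValueError):
            grid_search(separable, None, NO_EMB, grid=[], k=3, seed=0)


class TestModelBundle:
    def test_round_trip_preserves_predictions_exactly(self, tmp_path, separable):
        model = train(separable, None, NO_EMB, SMALL)
        before = predict(model, separable, None)
        save_model(model, tmp_path / "bundle")
        loaded = load_model(tmp_path / "bundle")
        after = predict(loaded, separable, None)
        assert np.array_equal(before, after)

    def test_tampered_feature_list_rejected(self, tmp_path, separable):
        import json

        model = train(separable, None, NO_EMB, SMALL)
        save_model(model, tmp_path / "bundle")
        meta_path = tmp_path / "bundle" / "meta.json"
        meta = json.loads(meta_path.read_text())
        meta["feature_names"][0] = "AAC_HACKED"
        meta_path.write_text(json.dumps(meta))
        with pytest.raises(ModelBundleError, match="integrity"):
            load_model(tmp_path / "bundle")

    def test_missing_scale_file_rejected(self, tmp_path, separable):
        model = train(separable, None, NO_EMB, SMALL)
        save_model(model, tmp_path / "bundle")
        (tmp_path / "bundle" / "aat.tsv").unlink()
        with pytest.raises(ModelBundleError, match="aat"):
            load_model(tmp_path / "bundle")


def test_model_config_validation():
    with pytest.raises(ValueError):
        ModelConfig(learning_rate=0.0)
    with pytest.raises(ValueError):
        ModelConfig(subsample=1.5)
    with pytest.raises(ValueError):
        ModelConfig(n_estimators=0)
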