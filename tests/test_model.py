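"""End-to-end model behaviour: wiring, ablations, training loop, CLI."""

import numpy as np
import pytest
from click.testing import CliRunner

from nestner.cli import main as cli_main
from nestner.corpus import build_char_vocabulary, build_word_vocabulary, entities_to_tags
from nestner.model import ModelConfig, NestedNERModel
from nestner.synthetic import GeneratorConfig, generate_corpus
from nestner.training import (RunConfig, evaluate_corpus, load_checkpoint,
                              run_ablation, save_checkpoint, train)


@pytest.fixture(scope="module")
def tiny_corpus():
    return generate_corpus(GeneratorConfig(n_sentences=12, sentence_length=(5, 12), seed=21))


def build_model(corpus, cfg=None, seed=0):
    sentences = [s for s, _ in corpus]
    wv = build_word_vocabulary(sentences)
    cv = build_char_vocabulary(sentences)
    types = sorted({e.type for _, ents in corpus for e in ents})
    return NestedNERModel(cfg or ModelConfig.small(), wv, cv, types, seed=seed)


class TestWiring:
    def test_gradient_reaches_every_parameter_group(self, tiny_corpus):
        model = build_model(tiny_corpus)
        model.train_mode(False)  # no dropout: every parameter participates
        terms = model.loss([s for s, _ in tiny_corpus[:6]], [e for _, e in tiny_corpus[:6]])
        terms.total.backward()
        groups = {
            "word_table": model.encoder.word_table,
            "char_table": model.encoder.char_encoder.table,
            "word_lstm": model.encoder.word_lstm,
            "char_lstm": model.encoder.char_lstm,
            "ccm_mlp": model.low.mlp_c2w,
            "wem_mlp": model.low.mlp_w2c,
            "attention_w": model.attn_w,
            "attention_c": model.attn_c,
            "hbcl": model.high,
            "detector": model.heads.detector,
            "classifier": model.heads.classifier,
        }
        for name, module in groups.items():
            norms = [np.abs(p.grad).max() for p in module.parameters() if p.grad is not None]
            assert norms and max(norms) > 0, f"no gradient reached {name}"

    def test_prediction_sets_are_always_encodable(self, tiny_corpus):
        model = build_model(tiny_corpus)  # untrained: arbitrary outputs
        preds = model.predict([s for s, _ in tiny_corpus])
        for (tokens, _), pred in zip(tiny_corpus, preds):
            entities_to_tags(pred, len(tokens), n_layers=4)  # must not raise

    def test_empty_sentence_predicts_empty_set(self, tiny_corpus):
        model = build_model(tiny_corpus)
        assert model.predict([[]]) == [set()]


class TestAblationWiring:
    @pytest.mark.parametrize("flags, d_factor", [
        (dict(), 8),                                       # full: 2*(2d + 2d)
        (dict(use_ccm=False), 6),
        (dict(use_ccm=False, use_wem=False), 4),
        (dict(use_ccm=False, use_wem=False, use_hbcl=False), 2),
    ])
    def test_stream_widths_track_enabled_blocks(self, tiny_corpus, flags, d_factor):
        cfg = ModelConfig.small().ablated(**flags)
        model = build_model(tiny_corpus, cfg)
        assert model.d_model == d_factor * model.encoder.out_dim

    def test_parameter_count_strictly_increases_as_modules_enable(self, tiny_corpus):
        chain = [
            dict(use_ccm=False, use_wem=False, use_hbcl=False, use_mhsm=False),
            dict(use_ccm=False, use_wem=False, use_hbcl=False, use_mhsm=True),
            dict(use_wem=False, use_hbcl=False, use_mhsm=True),
            dict(use_hbcl=False, use_mhsm=True),
            dict(use_mhsm=True),
        ]
        counts = [build_model(tiny_corpus, ModelConfig.small().ablated(**f)).n_parameters()
                  for f in chain]
        assert all(a < b for a, b in zip(counts, counts[1:]))

    def test_each_named_variant_has_fewer_parameters_than_full(self, tiny_corpus):
        from nestner.training import ABLATION_VARIANTS

        full = build_model(tiny_corpus).n_parameters()
        for name, flags in ABLATION_VARIANTS.items():
            variant = build_model(tiny_corpus, ModelConfig.small().ablated(**flags))
            assert variant.n_parameters() < full, name


class TestTraining:
    def test_identical_seeds_give_identical_losses(self, tiny_corpus):
        cfg = RunConfig(epochs=2, batch_size=6, learning_rate=1e-3, seed=4,
                        model=ModelConfig.small())
        h1 = train(cfg, tiny_corpus).history
        h2 = train(cfg, tiny_corpus).history
        assert [e["L"] for e in h1] == [e["L"] for e in h2]

    def test_different_seeds_differ(self, tiny_corpus):
        base = dict(epochs=1, batch_size=6, learning_rate=1e-3, model=ModelConfig.small())
        h1 = train(RunConfig(seed=0, **base), tiny_corpus).history
        h2 = train(RunConfig(seed=1, **base), tiny_corpus).history
        assert h1[0]["L"] != h2[0]["L"]

    def test_loss_decreases_over_early_epochs(self):
        corpus = generate_corpus(GeneratorConfig(n_sentences=30, sentence_length=(5, 15), seed=30))
        cfg = RunConfig(epochs=6, batch_size=6, learning_rate=3e-3, seed=0,
                        model=ModelConfig.small(dropout=0.0))
        history = train(cfg, corpus).history
        losses = [e["L"] for e in history]
        assert np.mean(losses[3:]) < np.mean(losses[:3])

    def test_zero_epochs_yields_untrained_but_evaluable_model(self, tiny_corpus):
        cfg = RunConfig(epochs=0, batch_size=6, model=ModelConfig.small())
        result = train(cfg, tiny_corpus)
        report = evaluate_corpus(result.model, tiny_corpus)
        assert report.f1 <= 0.5

    def test_empty_training_corpus_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            train(RunConfig(epochs=1, model=ModelConfig.small()), [])

    def test_checkpoint_round_trip_preserves_predictions(self, tiny_corpus, tmp_path):
        cfg = RunConfig(epochs=1, batch_size=6, model=ModelConfig.small())
        model = train(cfg, tiny_corpus).model
        path = str(tmp_path / "model.npz")
        save_checkpoint(model, path)
        restored = load_checkpoint(path)
        sents = [s for s, _ in tiny_corpus]
        assert restored.predict(sents) == model.predict(sents)

    def test_unknown_ablation_flag_rejected(self, tiny_corpus):
        cfg = RunConfig(epochs=1, batch_size=6, model=ModelConfig.small())
        with pytest.raises(ValueError, match="unknown ablation flags"):
            run_ablation(cfg, tiny_corpus, tiny_corpus, tiny_corpus,
                         variants={"bad": {"use_crf": False}})

    def test_empty_variant_table(self, tiny_corpus):
        cfg = RunConfig(epochs=0, batch_size=6, model=ModelConfig.small())
        out = run_ablation(cfg, tiny_corpus, tiny_corpus, tiny_corpus,
                           variants={}, include_full=False)
        assert out == {}


class TestCli:
    def test_generate_train_predict_evaluate_pipeline(self, tmp_path):
        runner = CliRunner()
        data = tmp_path / "data"
        res = runner.invoke(cli_main, [
            "generate", "--out-dir", str(data), "--n-sentences", "40",
            "--sentence-length", "5", "12", "--seed", "3"])
        assert res.exit_code == 0, res.output
        assert (data / "train.bio").exists() and (data / "statistics.json").exists()

        ckpt = str(tmp_path / "model.npz")
        res = runner.invoke(cli_main, [
            "train", "--train-file", str(data / "train.bio"),
            "--dev-file", str(data / "dev.bio"), "--checkpoint", ckpt,
            "--epochs", "1", "--batch-size", "8"])
        assert res.exit_code == 0, res.output

        pred = str(tmp_path / "pred.bio")
        res = runner.invoke(cli_main, [
            "predict", "--checkpoint", ckpt, "--input", str(data / "test.bio"),
            "--output", pred])
        assert res.exit_code == 0, res.output

        res = runner.invoke(cli_main, [
            "evaluate", "--gold", str(data / "test.bio"), "--pred", pred])
        assert res.exit_code == 0, res.output
        assert "micro P=" in res.output
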