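"""Model structure, autoregressive causality, likelihood, and loss masking."""

import itertools

import numpy as np
import pytest

from haloehr.model import (
    HALOModel,
    ModelConfig,
    load_checkpoint,
    masked_bce_loss,
    offset_and_concat,
    save_checkpoint,
    scored_row_mask,
)
from haloehr import nn


def random_record_batch(C, L, rng, batch=2):
    R = (rng.random((batch, L, C)) < 0.4).astype(float)
    R[:, 0, :] = 0.0
    R[:, 0, 0] = 1.0  # start row
    return R


@pytest.fixture
def tiny_model():
    return HALOModel(ModelConfig(C=8, T_max=4, n_emb=12, n_blocks=2, n_heads=3,
                                 n_masked=2, seed=0))


class TestInitialization:
    def test_same_seed_bitwise_identical(self):
        cfg = ModelConfig(C=6, T_max=3, n_emb=8, n_blocks=1, n_heads=2, seed=9)
        a, b = HALOModel(cfg), HALOModel(cfg)
        for k in a.params:
            np.testing.assert_array_equal(a.params[k], b.params[k])

    def test_masks_are_triangular(self, tiny_model):
        D = tiny_model.config.n_emb + tiny_model.config.C
        for j in range(D):
            for k in range(D):
                assert tiny_model.mask_hidden[j, k] == (1.0 if j <= k else 0.0)
                assert tiny_model.mask_final[j, k] == (1.0 if j < k else 0.0)

    @pytest.mark.parametrize("coarse", [False, True])
    def test_parameter_count_closed_form(self, coarse):
        cfg = ModelConfig(C=10, T_max=5, n_emb=16, n_blocks=3, n_heads=4,
                          n_masked=2, coarse_only=coarse, seed=0)
        E, C, M, N = cfg.n_emb, cfg.C, cfg.n_blocks, cfg.n_masked
        D = E + C
        per_block = (2 * E) + (E * 3 * E + 3 * E + E * E + E) \
            + (2 * E) + (E * 4 * E + 4 * E + 4 * E * E + E)
        expect = C * E + cfg.max_rows * E + M * per_block + 2 * E
        expect += E * C + C if coarse else N * (D * D + D)
        assert HALOModel(cfg).n_parameters() == expect

    def test_config_validation(self):
        with pytest.raises(ValueError):
            ModelConfig(C=6, T_max=3, n_emb=10, n_heads=4)  # not divisible
        with pytest.raises(ValueError):
            ModelConfig(C=2, T_max=3)


class TestVisitLevelCausality:
    def test_equal_prefixes_give_equal_histories(self, tiny_model):
        rng = np.random.default_rng(1)
        R1 = random_record_batch(8, 6, rng, batch=1)
        R2 = R1.copy()
        R2[0, 4:, :] = (rng.random((2, 8)) < 0.5)  # change rows 4,5 only
        H1, _ = tiny_model.visit_level_forward(R1)
        H2, _ = tiny_model.visit_level_forward(R2)
        np.testing.assert_allclose(H1[0, :4], H2[0, :4], atol=1e-12)

    def test_output_shape(self, tiny_model):
        R = random_record_batch(8, 7, np.random.default_rng(2))
        H, _ = tiny_model.visit_level_forward(R)
        assert H.shape == (2, 7, tiny_model.config.n_emb)

    def test_perturbation_sweep_no_future_leak(self, tiny_model):
        rng = np.random.default_rng(3)
        R = random_record_batch(8, 6, rng, batch=1)
        H0, _ = tiny_model.visit_level_forward(R)
        for trial in range(10):
            t = int(rng.integers(1, 6))
            Rp = R.copy()
            Rp[0, t] = (rng.random(8) < 0.5)
            Hp, _ = tiny_model.visit_level_forward(Rp)
            np.testing.assert_allclose(H0[0, :t], Hp[0, :t], atol=1e-12)


class TestOffsetAndConcat:
    def test_definition_and_slicing_identity(self, tiny_model):
        rng = np.random.default_rng(4)
        R = random_record_batch(8, 5, rng)
        H, _ = tiny_model.visit_level_forward(R)
        Hp = offset_and_concat(H, R)
        E = tiny_model.config.n_emb
        assert Hp.shape == (2, 4, E + 8)
        np.testing.assert_array_equal(Hp[:, 0, :E], H[:, 0, :])
        np.testing.assert_array_equal(Hp[:, 0, E:], R[:, 1, :])
        # the C-suffix reconstructs R rows 1..L-1 exactly
        np.testing.assert_array_equal(Hp[:, :, E:], R[:, 1:, :])


class TestMaskedLinear:
    def test_zero_weights_give_bias_activation(self):
        D = 6
        mask = np.triu(np.ones((D, D)))
        h = np.random.default_rng(0).normal(size=(2, 3, D))
        b = np.linspace(-1, 1, D)
        y, _ = nn.masked_linear_forward(h, np.zeros((D, D)), b, mask, final=False)
        np.testing.assert_allclose(y, np.maximum(np.broadcast_to(b, y.shape), 0))

    def test_masked_columns_insensitive(self):
        rng = np.random.default_rng(5)
        D = 7
        W = rng.normal(size=(D, D))
        b = rng.normal(size=D)
        mask = np.triu(np.ones((D, D)), k=1)
        h = rng.normal(size=(1, 2, D))
        y0, _ = nn.masked_linear_forward(h, W, b, mask, final=True)
        for j in range(D):
            hp = h.copy()
            hp[..., j] += 1.7
            yp, _ = nn.masked_linear_forward(hp, W, b, mask, final=True)
            for k in range(D):
                if mask[j, k] == 0:
                    assert np.allclose(y0[..., k], yp[..., k])

    def test_relu_layer_nonnegative(self):
        rng = np.random.default_rng(6)
        D = 5
        mask = np.triu(np.ones((D, D)))
        y, _ = nn.masked_linear_forward(
            rng.normal(size=(1, 4, D)), rng.normal(size=(D, D)),
            rng.normal(size=D), mask, final=False)
        assert (y >= 0).all()


class TestCodeLevelCausality:
    """Exhaustive flip oracles at C=8: O[k,i] may depend only on input rows
    <= k and on codes j < i of row k+1 (full mode), and on no intra-visit
    code at all in coarse mode."""

    def _flip_sweep(self, model, strict_self):
        rng = np.random.default_rng(7)
        C, L = model.config.C, 5
        R = random_record_batch(C, L, rng, batch=1)
        O0 = model.code_probabilities(R)
        worst = 0.0
        for k in range(L - 1):
            for i in range(C):
                js = range(C) if not strict_self else range(i, C)
                for j in js:
                    Rf = R.copy()
                    Rf[0, k + 1, j] = 1.0 - Rf[0, k + 1, j]
                    Of = model.code_probabilities(Rf)
                    worst = max(worst, abs(Of[0, k, i] - O0[0, k, i]))
        return worst

    def test_full_mode_no_self_or_future_code_leak(self):
        model = HALOModel(ModelConfig(C=8, T_max=4, n_emb=12, n_blocks=2,
                                      n_heads=3, n_masked=2, seed=1))
        assert self._flip_sweep(model, strict_self=True) == 0.0

    def test_coarse_mode_ignores_all_intra_visit_codes(self):
        model = HALOModel(ModelConfig(C=8, T_max=4, n_emb=12, n_blocks=2,
                                      n_heads=3, coarse_only=True, seed=1))
        assert self._flip_sweep(model, strict_self=False) == 0.0

    def test_three_masked_layers_still_leak_free(self):
        model = HALOModel(ModelConfig(C=6, T_max=3, n_emb=8, n_blocks=1,
                                      n_heads=2, n_masked=3, seed=2))
        assert self._flip_sweep(model, strict_self=True) == 0.0

    def test_probabilities_in_open_interval(self, tiny_model):
        R = random_record_batch(8, 6, np.random.default_rng(8))
        O = tiny_model.code_probabilities(R)
        assert ((O > 0) & (O < 1)).all()


class TestLikelihood:
    @pytest.mark.parametrize("coarse", [False, True])
    def test_normalizes_over_all_completions(self, coarse):
        """Sum of P(R) over all 2^6 binary completions of a 2-row x 3-code
        matrix equals 1 (exhaustive enumeration)."""
        cfg = ModelConfig(C=3, T_max=1, n_emb=4, n_blocks=1, n_heads=2,
                          coarse_only=coarse, seed=3)
        model = HALOModel(cfg)
        total = 0.0
        for bits in itertools.product([0, 1], repeat=6):
            R = np.zeros((1, 3, 3))
            R[0, 0, 0] = 1.0
            R[0, 1] = bits[:3]
            R[0, 2] = bits[3:]
            total += float(np.exp(model.record_log_probability(R, [3])[0]))
        assert abs(total - 1.0) < 1e-10

    def test_matches_independent_bernoulli_oracle(self, tiny_model):
        rng = np.random.default_rng(9)
        R = random_record_batch(8, 6, rng, batch=1)
        lengths = [5]  # last row is padding
        O = tiny_model.code_probabilities(R)
        # independent oracle: plain python loop over scored cells
        expect = 0.0
        for k in range(4):  # rows 0..length-2 of O
            for i in range(8):
                p = O[0, k, i]
                expect += np.log(p) if R[0, k + 1, i] else np.log(1 - p)
        got = tiny_model.record_log_probability(R, lengths)[0]
        assert abs(got - expect) < 1e-10
        assert got <= 0

    def test_padding_does_not_change_log_probability(self, tiny_model):
        rng = np.random.default_rng(10)
        R = random_record_batch(8, 5, rng, batch=1)
        lp1 = tiny_model.record_log_probability(R, [5])[0]
        Rp = np.concatenate([R, np.zeros((1, 2, 8))], axis=1)
        lp2 = tiny_model.record_log_probability(Rp, [5])[0]
        assert abs(lp1 - lp2) < 1e-12


class TestMaskedBCE:
    def test_perfect_probabilities_give_zero_loss(self):
        R = np.zeros((1, 4, 3))
        R[0, 0, 0] = 1
        R[0, 1, 1] = 1
        R[0, 3, 2] = 1
        O = R[:, 1:, :].astype(float)
        assert masked_bce_loss(O, R, [4]) < 1e-6

    def test_padding_invariance(self, tiny_model):
        rng = np.random.default_rng(11)
        R = random_record_batch(8, 5, rng, batch=1)
        O = tiny_model.code_probabilities(R)
        l1 = masked_bce_loss(O, R, [5])
        Rp = np.concatenate([R, np.zeros((1, 2, 8))], axis=1)
        Op = tiny_model.code_probabilities(Rp)
        l2 = masked_bce_loss(Op, Rp, [5])
        assert abs(l1 - l2) < 1e-12

    def test_hand_computed_two_rows_three_codes(self):
        R = np.zeros((1, 3, 3))
        R[0, 0, 0] = 1
        R[0, 1] = [1, 0, 1]
        R[0, 2] = [0, 1, 0]
        O = np.array([[[0.9, 0.2, 0.6], [0.3, 0.7, 0.1]]])
        # independent arithmetic: mean of -log p over the 6 scored cells
        cells = [np.log(0.9), np.log(0.8), np.log(0.6),
                 np.log(0.7), np.log(0.7), np.log(0.9)]
        assert abs(masked_bce_loss(O, R, [3]) - (-np.mean(cells))) < 1e-12


class TestGradients:
    @pytest.mark.parametrize("coarse", [False, True])
    def test_finite_difference_agreement(self, coarse):
        cfg = ModelConfig(C=5, T_max=3, n_emb=8, n_blocks=2, n_heads=2,
                          n_masked=2, coarse_only=coarse, seed=4)
        model = HALOModel(cfg)
        rng = np.random.default_rng(12)
        R = random_record_batch(5, 6, rng)
        lengths = np.array([6, 5])
        _, grads = model.loss_and_grads(R, lengths)
        eps = 1e-6
        for key in sorted(model.params):
            p = model.params[key]
            for fi in rng.choice(p.size, size=min(4, p.size), replace=False):
                idx = np.unravel_index(fi, p.shape)
                orig = p[idx]
                p[idx] = orig + eps
                lp, _ = model.loss_and_grads(R, lengths)
                p[idx] = orig - eps
                lm, _ = model.loss_and_grads(R, lengths)
                p[idx] = orig
                num = (lp - lm) / (2 * eps)
                assert grads[key][idx] == pytest.approx(num, rel=2e-3, abs=1e-7)

    def test_masked_weight_entries_get_zero_gradient(self):
        cfg = ModelConfig(C=5, T_max=3, n_emb=6, n_blocks=1, n_heads=2,
                          n_masked=2, seed=5)
        model = HALOModel(cfg)
        R = random_record_batch(5, 5, np.random.default_rng(13))
        _, grads = model.loss_and_grads(R, [5, 5])
        assert np.all(grads["ml0.W"][model.mask_hidden == 0] == 0)
        assert np.all(grads["ml1.W"][model.mask_final == 0] == 0)

    def test_adam_step_preserves_masked_entries(self):
        cfg = ModelConfig(C=5, T_max=3, n_emb=6, n_blocks=1, n_heads=2, seed=6)
        model = HALOModel(cfg)
        before = model.params["ml1.W"][model.mask_final == 0].copy()
        opt = nn.Adam(model.params, lr=1e-2)
        R = random_record_batch(5, 5, np.random.default_rng(14))
        _, grads = model.loss_and_grads(R, [5, 5])
        opt.step(model.params, grads)
        np.testing.assert_array_equal(
            model.params["ml1.W"][model.mask_final == 0], before)


class TestCheckpoint:
    def test_roundtrip_and_vocab_hash_check(self, tmp_path, tiny_model):
        path = tmp_path / "ckpt.npz"
        save_checkpoint(path, tiny_model, vocab_hash="abc123")
        back = load_checkpoint(path, expect_vocab_hash="abc123")
        assert back.config == tiny_model.config
        for k in tiny_model.params:
            np.testing.assert_array_equal(back.params[k], tiny_model.params[k])
        with pytest.raises(ValueError, match="vocabulary"):
            load_checkpoint(path, expect_vocab_hash="different")
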