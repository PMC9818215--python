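"""Feature-weight gate, composite loss, permutation importance, selection."""

import numpy as np
import pytest

from specseed.cnn_fes import (
    FESConfig,
    ImportanceReport,
    build_fes_network,
    fes_kernel_spec,
    fes_loss,
    fw_forward,
    importance_score,
    permutation_importance,
    select_top,
    train_fes,
)
from specseed.nn.core import FWGate
from specseed.preprocess import zscore

from conftest import separable_dataset


class TestFWGate:
    def test_uniform_scores_divide_by_L(self, rng):
        L = 16
        gate = FWGate(L)
        x = rng.normal(0, 1, L)
        assert np.allclose(fw_forward(x, gate), x / L, atol=1e-7)

    def test_softmax_closed_form_two_bands(self):
        gate = FWGate(2)
        gate.scores.value = np.array([0.0, np.log(3.0)], dtype=np.float32)
        assert np.allclose(gate.coefficients, [0.25, 0.75], atol=1e-6)

    def test_coefficients_positive_sum_to_one(self, rng):
        gate = FWGate(50)
        gate.scores.value = rng.normal(0, 3, 50).astype(np.float32)
        c = gate.coefficients
        assert np.all(c > 0) and np.isclose(c.sum(), 1.0, atol=1e-6)

    def test_selfproduct_mode_matches_manual_softmax(self, rng):
        from specseed.cnn_fes import fw_forward_selfproduct

        x = rng.normal(0, 1, 6)
        e = np.exp(x * x)
        expected = (e / e.sum()) * x
        assert np.allclose(fw_forward_selfproduct(x), expected, atol=1e-12)


class TestFesNetwork:
    def test_forward_gives_row_stochastic_probabilities(self, rng):
        cfg = FESConfig(seed=0)
        net = build_fes_network(245, cfg, np.random.default_rng(0))
        x = rng.normal(0, 1, (4, 245)).astype(np.float32)
        probs = net.predict_proba(x)
        assert probs.shape == (4, 2)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(probs > 0)

    def test_inference_deterministic_despite_dropout(self, rng):
        net = build_fes_network(60, FESConfig(seed=0), np.random.default_rng(0))
        x = rng.normal(0, 1, (3, 60)).astype(np.float32)
        assert np.array_equal(net.forward(x, train=False),
                              net.forward(x, train=False))

    def test_layer_shapes_match_bookkeeping_oracle(self):
        """Conv/pool length arithmetic: L -> L-w1+1 -> -1 -> -w2+1 -> -1."""
        for L in (245, 128, 100):
            (n1, n2), (w1, w2) = fes_kernel_spec(L)
            len1 = L - w1 + 1 - 1
            len2 = len1 - w2 + 1 - 1
            net = build_fes_network(L, FESConfig(seed=0), np.random.default_rng(0))
            out = net.forward(np.zeros((2, L), dtype=np.float32), train=False)
            assert out.shape == (2, 2)
            flat_dense = net.layers[9]
            assert flat_dense.W.value.shape == (len2 * n2, 10)

    def test_reference_kernel_counts_at_245(self):
        (n1, n2), (w1, w2) = fes_kernel_spec(245)
        assert (n1, n2) == (127, 245) and (w1, w2) == (64, 32)

    def test_kernel_width_clipped_for_short_spectra(self):
        with pytest.warns(UserWarning, match="clipped"):
            (n1, n2), (w1, w2) = fes_kernel_spec(24)
        assert w1 <= 24


class TestFesLoss:
    def test_perfect_prediction_zero_loss(self):
        y = np.eye(2)[[0, 1, 1, 0]]
        assert fes_loss(y, y, np.full(10, 0.1), lambda_reg=0.0) == pytest.approx(0.0)

    def test_uniform_coefficient_regularizer_closed_form(self):
        L = 245
        c = np.full(L, 1.0 / L)
        y = np.eye(2)[[0]]
        loss = fes_loss(y, y, c, lambda_reg=0.15)
        assert loss == pytest.approx(0.15 / 245, rel=1e-9)

    def test_half_probability_gives_ln2(self):
        y = np.array([[1.0, 0.0]])
        p = np.array([[0.5, 0.5]])
        assert fes_loss(y, p, np.zeros(4), 0.0) == pytest.approx(np.log(2.0))


class TestImportanceScore:
    def test_equal_importances_score_near_zero(self):
        s = np.array([0.3, 0.001])
        IS = importance_score(s, s)
        assert np.allclose(IS, np.log(1.0 + 1e-10), atol=1e-12)

    def test_vanishing_true_importance_floors_at_log_eps(self):
        IS = importance_score(np.zeros(3), np.full(3, 0.5))
        assert np.allclose(IS, np.log(1e-10))

    def test_ratio_three_gives_ln3(self):
        IS = importance_score(np.array([0.3]), np.array([0.1]))
        assert IS[0] == pytest.approx(np.log(3.0), rel=1e-6)

    def test_monotone_in_s1_and_antitone_in_s2(self, rng):
        s2 = np.full(5, 0.2)
        s1 = np.linspace(0.01, 0.5, 5)
        assert np.all(np.diff(importance_score(s1, s2)) > 0)
        assert np.all(np.diff(importance_score(s2, s1)) < 0)


class TestTrainFes:
    def _train(self, epochs=15, seed=0):
        ds = separable_dataset(n_per_class=12, L=20, seed=1)
        std, _ = zscore(ds)
        return train_fes(std, FESConfig(epochs=epochs, seed=seed))

    def test_loss_decreases_on_separable_data(self):
        _, _, hist = self._train()
        assert hist["loss"][-1] < hist["loss"][0]
        assert hist["train_acc"][-1] == 1.0

    def test_if_vector_positive_and_sums_to_one(self):
        _, IF, _ = self._train()
        assert np.all(IF > 0) and np.isclose(IF.sum(), 1.0, atol=1e-6)

    def test_same_seed_identical_if(self):
        _, a, _ = self._train(seed=3)
        _, b, _ = self._train(seed=3)
        assert np.allclose(a, b, atol=1e-6)

    def test_history_length_matches_epochs(self):
        _, _, hist = self._train(epochs=5)
        assert len(hist["loss"]) == 5


class TestPermutationImportance:
    def test_null_runs_and_report_shapes(self):
        ds = separable_dataset(n_per_class=10, L=16, seed=2)
        std, _ = zscore(ds)
        cfg = FESConfig(epochs=4, seed=1, n_label_shuffles=3)
        rep = permutation_importance(std, cfg)
        assert rep.S1.shape == rep.S2.shape == rep.IS.shape == (16,)
        assert rep.IF_history.shape == (3, 16)
        assert np.all(rep.S1 > 0) and np.all(rep.S2 > 0)

    def test_quantile_modes_agree_on_identical_nulls(self):
        rep_kwargs = dict(
            S1=np.full(4, 0.25), IF_history=np.tile(np.full(4, 0.25), (5, 1)),
            wavelengths_nm=np.arange(4.0),
        )
        # identical uniform nulls: matched == perband == pooled S2
        from specseed.cnn_fes import _match_null_amplitude

        matched = _match_null_amplitude(rep_kwargs["IF_history"], rep_kwargs["S1"])
        assert np.allclose(matched, 0.25)


class TestSelectTop:
    def _report(self, IS):
        IS = np.asarray(IS, dtype=float)
        L = IS.size
        return ImportanceReport(
            S1=np.exp(IS) / L, S2=np.full(L, 1.0 / L), IS=IS,
            IF_history=np.zeros((1, L)), wavelengths_nm=np.linspace(900, 1700, L),
        )

    def test_ten_percent_of_245_is_24_bands(self, rng):
        IS = rng.uniform(0.1, 1.0, 245)
        sel = select_top(self._report(IS), top_fraction=0.10)
        assert sel.n_selected == 24
        assert sel.fraction_of() == 9.8

    def test_all_negative_scores_empty_selection(self):
        with pytest.warns(UserWarning, match="empty selection"):
            sel = select_top(self._report(-np.ones(50)), 0.10)
        assert sel.n_selected == 0

    def test_negative_scores_dropped_from_top_set(self):
        IS = np.full(20, -1.0)
        IS[[3, 9]] = 1.0  # only two positive; floor(0.2*20)=4 would keep 4
        sel = select_top(self._report(IS), top_fraction=0.20)
        assert list(sel.indices) == [3, 9]

    def test_tie_at_cut_keeps_lower_index(self):
        IS = np.zeros(10)
        IS[[7, 2]] = 1.0  # tied; fraction keeps exactly one
        sel = select_top(self._report(IS), top_fraction=0.10)
        assert list(sel.indices) == [2]
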