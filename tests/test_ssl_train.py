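"""Semi-supervised loop: schedule, splits, pseudo-labels, promotion, training."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sslvar.features import FeatureTable
from sslvar.network import ModelConfig
from sslvar.ssl_train import (
    PseudoLabelClassifier,
    SizingError,
    TrainConfig,
    alpha_schedule,
    combined_loss,
    make_split,
    promote_confident,
    pseudo_label,
)
from sslvar.synthetic_data import BENCHMARK_SPLIT_SIZES


def make_table(n_pos, n_neg, n_unlabeled=0, seed=0) -> FeatureTable:
    """Random feature table with the requested label composition."""
    n = n_pos + n_neg + n_unlabeled
    rng = np.random.default_rng(seed)
    onehot = np.zeros((n, 150, 4))
    for i in range(n):
        onehot[i, np.arange(150), rng.integers(0, 4, 150)] = 1.0
    tabular = rng.lognormal(size=(n, 43))
    labels = np.array([1] * n_pos + [0] * n_neg + [-1] * n_unlabeled)
    return FeatureTable(onehot, tabular, labels)


class TestAlphaSchedule:
    @pytest.mark.parametrize("t,expected", [
        (50, 0.0), (100, 0.0), (350, 0.5), (600, 1.0), (10_000, 1.0),
    ])
    def test_closed_form_including_boundaries(self, t, expected):
        assert alpha_schedule(t, 100, 600) == expected

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(st.integers(0, 1000), st.integers(0, 500), st.integers(1, 500))
    def test_nondecreasing_and_bounded(self, t, T1, dT):
        T2 = T1 + dT
        a = alpha_schedule(t, T1, T2)
        assert 0.0 <= a <= 1.0
        assert alpha_schedule(t + 1, T1, T2) >= a

    def test_requires_T1_before_T2(self):
        with pytest.raises(ValueError):
            alpha_schedule(5, 10, 10)


class TestPseudoLabel:
    def test_argmax_and_tie_break(self):
        probs = np.array([[0.3, 0.7], [0.5, 0.5], [0.9, 0.1]])
        assert pseudo_label(probs).tolist() == [1, 0, 0]

    def test_order_preserved(self):
        rng = np.random.default_rng(0)
        p1 = rng.random(20)
        probs = np.column_stack([1 - p1, p1])
        assert np.array_equal(pseudo_label(probs), (p1 > 0.5).astype(int))


class TestPromoteConfident:
    def test_threshold_selects_first_row_only(self):
        probs = np.array([[0.96, 0.04], [0.6, 0.4]])
        mask, labels = promote_confident(probs, 0.95)
        assert mask.tolist() == [True, False]
        assert labels[0] == 0

    def test_empty_pool(self):
        mask, labels = promote_confident(np.empty((0, 2)), 0.95)
        assert len(mask) == len(labels) == 0

    def test_all_confident_rows_promote(self):
        probs = np.array([[0.99, 0.01], [0.02, 0.98]])
        mask, labels = promote_confident(probs, 0.95)
        assert mask.all()
        assert labels.tolist() == [0, 1]


class TestTrainConfig:
    def test_invariants(self):
        with pytest.raises(ValueError):
            TrainConfig(T1=600, T2=100)
        with pytest.raises(ValueError):
            TrainConfig(confidence_threshold=0.0)
        with pytest.raises(ValueError):
            TrainConfig(learning_rate=-1)
        with pytest.raises(ValueError):
            TrainConfig(mode="magic")


class TestMakeSplit:
    def test_reference_catalogue_shape(self):
        """683 positives / 2745 negatives with sizes (550, rest, 272) give the
        balanced 275/275 labeled part, 272/2334 unlabeled, 136/136 validation."""
        table = make_table(683, 2745)
        split = make_split(table, (550, None, 272), seed=0)
        assert split.counts() == {
            "labeled": (550, 275, 275),
            "unlabeled": (2606, 272, 2334),
            "validation": (272, 136, 136),
        }

    def test_small_exhaustive_count(self):
        split = make_split(make_table(10, 10), (8, 8, 4), seed=1)
        assert split.counts() == {
            "labeled": (8, 4, 4), "unlabeled": (8, 4, 4), "validation": (4, 2, 2),
        }

    def test_infeasible_balance_reports_counts(self):
        with pytest.raises(SizingError, match="12 positives"):
            make_split(make_table(10, 30), (24, None, 0), seed=0)

    def test_parts_disjoint_and_unlabeled_pool_gets_hidden_labels(self):
        table = make_table(20, 40, n_unlabeled=15)
        split = make_split(table, (16, None, 8), seed=2)
        all_idx = np.concatenate([split.labeled_idx, split.unlabeled_idx, split.val_idx])
        assert len(np.unique(all_idx)) == len(all_idx) == 75
        assert (table.labels[split.unlabeled_idx] == -1).sum() == 15


class TestCombinedLoss:
    @pytest.fixture()
    def setup(self):
        table = make_table(20, 20, seed=3)
        split = make_split(table, (24, None, 8), seed=0)
        clf = PseudoLabelClassifier(split, ModelConfig(seed=0), TrainConfig(seed=0))
        lab = split.labeled
        tab = clf.preprocessor.transform(lab.tabular)
        from sslvar.network import Network
        return Network(ModelConfig(seed=0)), (lab.onehot, tab, lab.labels), clf

    def test_alpha_zero_before_T1(self, setup):
        net, labeled, clf = setup
        lc = combined_loss(labeled, (labeled[0], labeled[1]), net, t=50,
                           config=TrainConfig())
        assert lc.alpha == 0.0
        assert lc.L == lc.L_label

    def test_empty_unlabeled_batch_contributes_zero(self, setup):
        net, labeled, clf = setup
        lc = combined_loss(labeled, None, net, t=10_000, config=TrainConfig())
        assert lc.alpha == 1.0
        assert lc.L_unlabel == 0.0
        assert lc.L == lc.L_label

    def test_unlabeled_term_is_log_of_max_probability(self, setup):
        """The pseudo-label cross-entropy equals mean(-log max prob): the
        plug-in value of CE against the model's own argmax."""
        net, labeled, clf = setup
        oh, tab, _ = labeled
        lc = combined_loss(labeled, (oh, tab), net, t=1000, config=TrainConfig())
        probs = net.predict_proba(oh, tab)
        assert lc.L_unlabel == pytest.approx(-np.log(probs.max(axis=1)).mean())


@pytest.fixture(scope="module")
def quick_runs(tables):
    """Short paired SSL / supervised runs on the benchmark's cell A."""
    split = make_split(tables["cellA"], BENCHMARK_SPLIT_SIZES, seed=0)
    out = {}
    for mode in ("ssl", "supervised"):
        cfg = TrainConfig(seed=0, epochs=5, mode=mode)
        out[mode] = PseudoLabelClassifier(split, ModelConfig(seed=0), cfg).fit()
    return out


class TestTraining:
    def test_pool_size_non_increasing(self, quick_runs):
        pool = quick_runs["ssl"].history["pool_size"].to_numpy()
        assert np.all(np.diff(pool) <= 0)

    def test_no_promotion_below_threshold(self, quick_runs):
        audit = quick_runs["ssl"].audit
        assert len(audit) > 0
        assert (audit["max_prob"] >= 0.95).all()

    def test_modes_identical_before_ramp_and_promotion(self, quick_runs):
        """With 20 labeled batches per epoch, epoch 1 ends at t=20 < T1=100 and
        promotion happens only after its last step, so the first epoch's losses
        and validation metrics agree exactly between modes."""
        h_ssl = quick_runs["ssl"].history.iloc[0]
        h_sup = quick_runs["supervised"].history.iloc[0]
        for col in ("L_label", "L_unlabel", "val_auc", "val_acc"):
            assert h_ssl[col] == h_sup[col]

    def test_supervised_mode_never_promotes(self, quick_runs):
        h = quick_runs["supervised"].history
        assert (h["pool_size"] == h["pool_size"].iloc[0]).all()
        assert len(quick_runs["supervised"].audit) == 0
        assert (h["alpha"] == 0.0).all()

    def test_promoted_examples_counted_once(self, quick_runs):
        audit = quick_runs["ssl"].audit
        assert audit["locus_index"].is_unique

    def test_summary_mentions_key_quantities(self, quick_runs):
        text = quick_runs["ssl"].summary()
        assert "validation AUC" in text
        assert "threshold 0.95" in text

    def test_empty_labeled_split_rejected(self, tables):
        split = make_split(tables["cellA"], BENCHMARK_SPLIT_SIZES, seed=0)
        clf = PseudoLabelClassifier(split, ModelConfig(seed=0), TrainConfig(seed=0))
        clf.split.labeled_idx = np.array([], dtype=int)
        with pytest.raises(ValueError, match="labeled split is empty"):
            clf.fit()
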