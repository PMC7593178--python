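import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import sdmkit as sk
from sdmkit.metrics import (
    EvalResult,
    aicc,
    auc,
    fit_and_score,
    select_threshold,
    tss,
)
from sdmkit.models import HyperCombo


def brute_force_auc(p, c):
    wins = sum(1.0 if a > b else 0.5 if a == b else 0.0 for a in p for b in c)
    return wins / (len(p) * len(c))


def brute_force_tss(p, c):
    best = (-np.inf, -np.inf, np.inf)
    for t in np.unique(np.r_[p, c]):
        sens = np.mean(p >= t)
        spec = np.mean(c < t)
        cand = (sens + spec - 1, sens, -t)
        if cand > best:
            best = cand
    return best[0], -best[2]


class TestAUC:
    def test_four_point_toy(self):
        assert auc([0.9, 0.4], [0.5, 0.1]) == 0.75

    def test_all_ties(self):
        assert auc([0.3] * 5, [0.3] * 4) == 0.5

    def test_perfect_separation(self):
        assert auc([0.8, 0.9], [0.1, 0.2]) == 1.0

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None)
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n_p, n_c = rng.integers(1, 200, size=2)
        # quantized scores force ties through the tie-handling path
        p = np.round(rng.uniform(size=n_p), 2)
        c = np.round(rng.uniform(size=n_c), 2)
        assert abs(auc(p, c) - brute_force_auc(p, c)) < 1e-12

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            auc([], [0.1])


class TestTSS:
    def test_four_point_toy(self):
        value, threshold = tss([0.9, 0.4], [0.5, 0.1])
        assert value == 0.5 and threshold == 0.4

    def test_perfect(self):
        value, _ = tss([0.8, 0.9], [0.1, 0.2])
        assert value == 1.0

    def test_identical_distributions(self):
        value, _ = tss([0.2, 0.7], [0.2, 0.7])
        assert value == 0.0

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None)
    def test_matches_exhaustive_scan_and_bounds(self, seed):
        rng = np.random.default_rng(seed)
        p = np.round(rng.uniform(size=rng.integers(1, 60)), 2)
        c = np.round(rng.uniform(size=rng.integers(1, 60)), 2)
        value, threshold = tss(p, c)
        bf_value, bf_threshold = brute_force_tss(p, c)
        assert abs(value - bf_value) < 1e-12
        assert threshold == bf_threshold
        assert -1.0 <= value <= 1.0


class _StubMaxent:
    """Duck-typed Maxent results with prescribed raw scores."""

    method = "Maxent"

    def __init__(self, coefs, raw_by_label):
        self.coefs = np.asarray(coefs, float)
        self.raw_by_label = raw_by_label

    def predict(self, table, output="raw"):
        label = table.labels[0]
        return np.asarray(self.raw_by_label[label], float)


def _stub_table(n_pres, n_bg=2):
    import pandas as pd

    n = n_pres + n_bg
    return sk.SWDTable(
        species="s", coords=np.zeros((n, 2)),
        labels=np.r_[np.ones(n_pres, int), np.zeros(n_bg, int)],
        data=pd.DataFrame({"v": np.arange(n, dtype=float)}),
    )


class TestAICc:
    def test_hand_example(self):
        # k = 3, n = 20, lnL = -100  ->  2*3 + 200 + 24/16 = 207.5
        table = _stub_table(20)
        model = _StubMaxent(
            coefs=[1.0, -2.0, 0.5],
            raw_by_label={1: np.full(20, np.exp(-5.0)), 0: [0.5, 0.5]},
        )
        assert aicc(model, table) == pytest.approx(207.5, abs=1e-10)

    def test_undefined_when_overparameterized(self):
        table = _stub_table(20)
        model = _StubMaxent(
            coefs=np.ones(19), raw_by_label={1: np.full(20, 0.01), 0: [0.5, 0.5]}
        )
        assert np.isnan(aicc(model, table))

    def test_penalty_monotone_in_k(self):
        table = _stub_table(100)
        raw = {1: np.full(100, 0.001), 0: [0.5, 0.5]}
        a2 = aicc(_StubMaxent([1.0, 1.0], raw), table)
        a5 = aicc(_StubMaxent([1.0] * 5, raw), table)
        assert a5 > a2

    def test_scale_invariance(self):
        # multiplying every raw score by a constant cannot change AICc
        table = _stub_table(30)
        raw = np.random.default_rng(0).uniform(0.1, 1, size=30)
        bg = np.array([0.4, 0.6])
        a = aicc(_StubMaxent([1.0, 2.0], {1: raw, 0: bg}), table)
        b = aicc(_StubMaxent([1.0, 2.0], {1: raw * 7.3, 0: bg * 7.3}), table)
        assert a == pytest.approx(b, rel=1e-12)

    def test_only_for_maxent(self, species_pa):
        model = sk.train(species_pa, HyperCombo("RF", {"n_trees": 10}, 0))
        with pytest.raises(ValueError):
            aicc(model, species_pa)

    def test_real_model_matches_independent_recompute(self, maxent_pb):
        table = maxent_pb.table
        value = aicc(maxent_pb, table)
        k = int((maxent_pb.coefs != 0).sum())
        raw_p = maxent_pb.predict(table.subset(table.presence_idx), output="raw")
        raw_b = maxent_pb.predict(table.subset(table.contrast_idx), output="raw")
        n = table.n_presence
        lnl = np.log(raw_p / raw_b.sum()).sum()
        expected = 2 * k - 2 * lnl + 2 * k * (k + 1) / (n - k - 1)
        assert value == pytest.approx(expected, rel=1e-12)


class TestEvaluate:
    def test_kfold_mean(self, species_pb):
        fold = sk.random_folds(species_pb, 4, seed=0)
        result, models = fit_and_score(
            species_pb, HyperCombo("Maxent", {"fc": "l"}, 0), "auc", fold=fold
        )
        assert len(models) == 4
        assert result.validation_value == pytest.approx(
            np.mean(result.per_fold_validation)
        )

    def test_holdout_without_validation(self, maxent_pb, species_pb):
        result = sk.evaluate(maxent_pb, species_pb, "auc")
        assert result.validation_value is None

    def test_aicc_with_folds_rejected(self, species_pb):
        fold = sk.random_folds(species_pb, 2, seed=0)
        with pytest.raises(ValueError):
            fit_and_score(species_pb, HyperCombo("Maxent", {}, 0), "aicc", fold=fold)

    def test_tss_perfect_training_fit(self):
        # separable data: a fully grown forest reproduces the labels,
        # so the training TSS reaches its maximum of 1
        import pandas as pd

        x = np.r_[np.linspace(1, 2, 20), np.linspace(-2, -1, 20)]
        table = sk.SWDTable(
            species="s", coords=np.zeros((40, 2)),
            labels=np.r_[np.ones(20, int), np.zeros(20, int)],
            data=pd.DataFrame({"x": x}), contrast_kind="absence",
        )
        model = sk.train(table, HyperCombo("RF", {"n_trees": 50}, 0))
        assert sk.evaluate(model, table, "tss").train_value == 1.0


class TestThresholds:
    def test_min_training_presence(self):
        assert select_threshold([0.9, 0.4], [0.5, 0.1], "min_training_presence") == 0.4

    def test_max_tss_matches_tss(self):
        assert select_threshold([0.9, 0.4], [0.5, 0.1], "max_tss") == 0.4

    def test_equal_sens_spec_smallest_qualifying(self):
        # perfect separation: every t in the gap balances; the smallest
        # qualifying observed score is returned
        t = select_threshold([0.8, 0.9], [0.1, 0.2], "equal_sens_spec")
        assert t == 0.8

    def test_unknown_rule(self):
        with pytest.raises(ValueError):
            select_threshold([0.5], [0.4], "youden_prime")
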