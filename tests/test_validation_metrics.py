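"""Discretization, confusion metrics, and random-network generation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from t2dm_boolnet.model_io import load_t2dm_model
from t2dm_boolnet.validation_metrics import (
    compare_attractor_counts,
    confusion_and_metrics,
    discretize,
    f1_score,
    random_network_like,
    read_truth_table,
)


class TestDiscretize:
    @pytest.mark.parametrize(
        ("level", "bit"), [(0.65, 1), (0.50, 0), (0.0, 0), (1.0, 1), (0.51, 1)]
    )
    def test_strict_threshold(self, level, bit):
        assert discretize(level) == bit

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            discretize(1.2)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(a=st.floats(0, 1), b=st.floats(0, 1))
    def test_monotone(self, a, b):
        lo, hi = min(a, b), max(a, b)
        assert discretize(lo) <= discretize(hi)


class TestConfusionAndMetrics:
    def test_balanced_example(self):
        # TP=4, FP=1, FN=1, TN=4
        predicted = {f"g{i}": b for i, b in enumerate([1, 1, 1, 1, 1, 0, 0, 0, 0, 0])}
        truth = {f"g{i}": b for i, b in enumerate([1, 1, 1, 1, 0, 1, 0, 0, 0, 0])}
        rep = confusion_and_metrics(predicted, truth)
        assert (rep.tp, rep.fp, rep.fn, rep.tn) == (4, 1, 1, 4)
        assert rep.precision == pytest.approx(0.8)
        assert rep.recall == pytest.approx(0.8)
        assert rep.specificity == pytest.approx(0.8)
        assert rep.f1 == pytest.approx(0.8)

    def test_perfect_agreement(self):
        truth = {"a": 1, "b": 0, "c": 1}
        rep = confusion_and_metrics(truth, truth)
        assert rep.precision == rep.recall == rep.specificity == rep.f1 == 1.0

    def test_restricted_to_truth_subset(self):
        predicted = {"a": 1, "b": 0, "extra": 1}
        rep = confusion_and_metrics(predicted, {"a": 1, "b": 0})
        assert rep.n_evaluated == 2

    def test_zero_denominator_warns_and_reports_nan(self):
        predicted = {"a": 0, "b": 0}
        truth = {"a": 1, "b": 1}
        with pytest.warns(UserWarning, match="precision"):
            rep = confusion_and_metrics(predicted, truth)
        assert math.isnan(rep.precision)
        assert rep.recall == 0.0

    def test_empty_truth_rejected(self):
        with pytest.raises(ValueError):
            confusion_and_metrics({"a": 1}, {})

    def test_permutation_invariance(self, rng):
        genes = [f"g{i}" for i in range(12)]
        predicted = {g: int(rng.integers(0, 2)) for g in genes}
        truth = {g: int(rng.integers(0, 2)) for g in genes}
        shuffled = dict(sorted(truth.items(), reverse=True))
        assert confusion_and_metrics(predicted, truth) == confusion_and_metrics(
            predicted, shuffled
        )

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        tp=st.integers(0, 40),
        fp=st.integers(0, 40),
        fn=st.integers(0, 40),
        tn=st.integers(0, 40),
    )
    def test_f1_identity_from_counts(self, tp, fp, fn, tn):
        """F1 computed from counts equals 2pr/(p+r) whenever defined."""
        predicted, truth = {}, {}
        for i in range(tp):
            predicted[f"tp{i}"], truth[f"tp{i}"] = 1, 1
        for i in range(fp):
            predicted[f"fp{i}"], truth[f"fp{i}"] = 1, 0
        for i in range(fn):
            predicted[f"fn{i}"], truth[f"fn{i}"] = 0, 1
        for i in range(tn):
            predicted[f"tn{i}"], truth[f"tn{i}"] = 0, 0
        if not truth:
            return
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep = confusion_and_metrics(predicted, truth)
        if not (math.isnan(rep.precision) or math.isnan(rep.recall)):
            if rep.precision + rep.recall > 0:
                expected = 2 * rep.precision * rep.recall / (rep.precision + rep.recall)
                assert rep.f1 == pytest.approx(expected, abs=1e-12)

    def test_example_truth_table_loads(self):
        from importlib import resources

        path = resources.files("t2dm_boolnet.data").joinpath("truth_example.csv")
        with resources.as_file(path) as p:
            truth = read_truth_table(p)
        assert truth["Apoptosis"] == 1
        assert truth["XIAP"] == 0
        assert len(truth) >= 20


class TestRandomNetworks:
    def test_degree_sequence_preserved(self, rng):
        template = load_t2dm_model()
        rand = random_network_like(template, rng)
        for name in template.nodes:
            if name in template.input_nodes:
                assert rand.rules[name] == template.rules[name]
                continue
            t = template.rules[name]
            r = rand.rules[name]
            assert len(r.activators) + len(r.inhibitors) == len(t.activators) + len(
                t.inhibitors
            )

    def test_regulators_drawn_from_non_inputs(self, rng):
        template = load_t2dm_model()
        rand = random_network_like(template, rng)
        for name in rand.nodes:
            if name in template.input_nodes:
                continue
            assert not (rand.rules[name].referenced() & template.input_nodes)

    def test_two_seeds_differ_on_large_template(self):
        template = load_t2dm_model()
        r1 = random_network_like(template, np.random.default_rng(1))
        r2 = random_network_like(template, np.random.default_rng(2))
        assert any(
            r1.rules[n].referenced() != r2.rules[n].referenced() for n in r1.nodes
        )

    def test_toggle_template_sample_space(self, toggle, rng):
        """Each rewired toggle node has exactly one regulator drawn from
        {A, B} with a coin-flipped sign: four possible rules per node."""
        seen = set()
        for _ in range(60):
            rand = random_network_like(toggle, rng)
            for n in ("A", "B"):
                rule = rand.rules[n]
                regs = rule.referenced()
                assert len(regs) == 1 and regs <= {"A", "B"}
                seen.add((n, tuple(sorted(rule.activators)), tuple(sorted(rule.inhibitors))))
        assert len(seen) == 8  # 2 nodes x (2 regulators x 2 signs)

    def test_compare_counts_type_contract(self, toggle):
        model_count, rand_counts = compare_attractor_counts(
            toggle, 5, {}, 30, 10, seed=4
        )
        assert model_count == 2
        assert len(rand_counts) == 5
        assert all(isinstance(c, int) and c >= 1 for c in rand_counts)

    def test_compare_counts_no_randoms(self, toggle):
        model_count, rand_counts = compare_attractor_counts(
            toggle, 0, {}, 30, 10, seed=4
        )
        assert model_count == 2
        assert rand_counts == []


class TestAveraging:
    def _reports(self):
        r1 = confusion_and_metrics({"a": 1, "b": 0}, {"a": 1, "b": 0})
        r2 = confusion_and_metrics({"a": 1, "b": 1}, {"a": 1, "b": 0})
        return [r1, r2]

    def test_pooled_counts(self):
        from t2dm_boolnet.validation_metrics import pooled_metrics

        pooled = pooled_metrics(self._reports())
        assert (pooled.tp, pooled.fp, pooled.tn, pooled.fn) == (2, 1, 1, 0)
        assert pooled.precision == pytest.approx(2 / 3)
        assert pooled.recall == 1.0

    def test_macro_average(self):
        from t2dm_boolnet.validation_metrics import macro_average_metrics

        avg = macro_average_metrics(self._reports())
        assert avg["precision"] == pytest.approx((1.0 + 0.5) / 2)
        assert avg["recall"] == 1.0

    def test_empty_rejected(self):
        from t2dm_boolnet.validation_metrics import macro_average_metrics, pooled_metrics

        with pytest.raises(ValueError):
            pooled_metrics([])
        with pytest.raises(ValueError):
            macro_average_metrics([])
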