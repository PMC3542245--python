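import itertools
import math
import random
from collections import Counter

import numpy as np
import pytest

from binomen.classify import (
    LABELS,
    LabeledExample,
    label_of,
    maxent_posterior,
    maxent_train,
    nb_label,
    nb_posterior,
    nb_train,
)


def _random_examples(rng, n, feature_values=None):
    feature_values = feature_values or {"f1": ["a", "b", "c"], "f2": ["x", "y"]}
    out = []
    for _ in range(n):
        fv = {f: rng.choice(vals) for f, vals in feature_values.items()}
        label = "yes" if (fv["f1"] != "c") == (rng.random() < 0.85) else "no"
        out.append(LabeledExample(fv, label))
    return out


def _counting_oracle(examples, alpha):
    """Brute-force frequency counting with the same smoothing rule."""
    n = len(examples)
    class_counts = Counter(e.label for e in examples)
    priors = {c: (class_counts[c] + alpha) / (n + 2 * alpha) for c in LABELS}
    values = {}
    for e in examples:
        for f, v in e.features.items():
            values.setdefault(f, set()).add(v)
    tables = {}
    for f, vals in values.items():
        tables[f] = {}
        for c in LABELS:
            denom = class_counts[c] + alpha * (len(vals) + 1)
            tables[f][c] = {
                v: (sum(1 for e in examples if e.label == c and e.features[f] == v) + alpha) / denom
                for v in vals
            }
    return priors, tables


class TestNaiveBayes:
    def test_symmetric_priors(self):
        exs = [LabeledExample({"f": "a"}, "yes")] * 2 + [LabeledExample({"f": "b"}, "no")] * 2
        model = nb_train(exs, alpha=1.0)
        assert model.class_priors["yes"] == pytest.approx(0.5)
        assert model.class_priors["no"] == pytest.approx(0.5)

    @pytest.mark.parametrize("alpha", [0.5, 1.0, 2.0])
    def test_parameters_match_counting_oracle(self, rng, alpha):
        exs = _random_examples(rng, 50)
        model = nb_train(exs, alpha=alpha)
        priors, tables = _counting_oracle(exs, alpha)
        for c in LABELS:
            assert model.class_priors[c] == pytest.approx(priors[c], abs=1e-12)
        for f, per_class in tables.items():
            for c, row in per_class.items():
                for v, p in row.items():
                    assert model.conditional_tables[f][c][v] == pytest.approx(p, abs=1e-12)

    def test_six_example_binary_table(self):
        exs = [
            LabeledExample({"f1": "a", "f2": "x"}, "yes"),
            LabeledExample({"f1": "a", "f2": "y"}, "yes"),
            LabeledExample({"f1": "a", "f2": "x"}, "yes"),
            LabeledExample({"f1": "b", "f2": "y"}, "no"),
            LabeledExample({"f1": "b", "f2": "x"}, "no"),
            LabeledExample({"f1": "a", "f2": "y"}, "no"),
        ]
        model = nb_train(exs, alpha=1.0)
        # counts: f1=a|yes 3/3 -> (3+1)/(3+3); f1=a|no 1/3 -> (1+1)/(3+3)
        assert model.conditional_tables["f1"]["yes"]["a"] == pytest.approx(4 / 6)
        assert model.conditional_tables["f1"]["no"]["a"] == pytest.approx(2 / 6)
        assert model.unseen["f1"]["yes"] == pytest.approx(1 / 6)

    def test_alpha_zero_uses_floor_not_zero(self):
        exs = [
            LabeledExample({"f": "a"}, "yes"),
            LabeledExample({"f": "b"}, "no"),
        ]
        model = nb_train(exs, alpha=0.0)
        assert model.conditional_tables["f"]["yes"]["b"] > 0
        # posterior stays finite and normalized
        post = nb_posterior(model, {"f": "b"})
        assert post["yes"] + post["no"] == pytest.approx(1.0)

    def test_negative_alpha_rejected(self):
        with pytest.raises(ValueError):
            nb_train([LabeledExample({"f": "a"}, "yes")], alpha=-1)

    def test_uninformative_model_returns_priors(self):
        exs = [
            LabeledExample({"f": "a"}, "yes"),
            LabeledExample({"f": "a"}, "yes"),
            LabeledExample({"f": "a"}, "no"),
        ]
        model = nb_train(exs, alpha=1.0)
        post = nb_posterior(model, {})  # empty vector -> priors
        assert post["yes"] == pytest.approx(model.class_priors["yes"])

    def test_posterior_matches_direct_product(self, rng):
        """Direct evaluation of the joint-product form on a tiny model."""
        exs = _random_examples(rng, 30)
        model = nb_train(exs, alpha=1.0)
        for _ in range(50):
            fv = {"f1": rng.choice(["a", "b", "c"]), "f2": rng.choice(["x", "y"])}
            raw = {}
            for c in LABELS:
                p = model.class_priors[c]
                for f, v in fv.items():
                    p *= model.conditional_tables[f][c].get(v, model.unseen[f][c])
                raw[c] = p
            z = sum(raw.values())
            post = nb_posterior(model, fv)
            assert post["yes"] == pytest.approx(raw["yes"] / z, abs=1e-12)
            assert post["yes"] + post["no"] == pytest.approx(1.0, abs=1e-12)

    def test_label_is_argmax_of_posterior(self, rng):
        exs = _random_examples(rng, 60)
        model = nb_train(exs, alpha=1.0)
        for _ in range(1000):
            fv = {"f1": rng.choice(["a", "b", "c", "zz"]), "f2": rng.choice(["x", "y", "zz"])}
            post = nb_posterior(model, fv)
            expected = "yes" if post["yes"] > post["no"] else "no"
            if post["yes"] != post["no"]:
                assert nb_label(model, fv) == expected

    def test_exact_tie_breaks_to_no(self):
        exs = [
            LabeledExample({"f": "a"}, "yes"),
            LabeledExample({"f": "a"}, "no"),
        ]
        model = nb_train(exs, alpha=1.0)
        assert nb_label(model, {"f": "a"}) == "no"


def _sklearn_logistic(data, fvals):
    from sklearn.linear_model import LogisticRegression

    X, y = [], []
    for fv, label, n in data:
        row = [1.0 if fv.get(f) == v else 0.0 for f, v in fvals]
        X += [row] * n
        y += [1 if label == "yes" else 0] * n
    lr = LogisticRegression(C=np.inf, max_iter=5000, tol=1e-12)
    lr.fit(X, y)
    return lr


class TestMaxEnt:
    # overlapping two-feature data: every (feature, value) pair occurs with
    # both labels, so the likelihood has a finite maximizer
    DATA = [
        ({"f1": "a", "f2": "x"}, "yes", 12), ({"f1": "a", "f2": "x"}, "no", 4),
        ({"f1": "a", "f2": "y"}, "yes", 3), ({"f1": "a", "f2": "y"}, "no", 9),
        ({"f1": "b", "f2": "x"}, "yes", 6), ({"f1": "b", "f2": "x"}, "no", 5),
        ({"f1": "b", "f2": "y"}, "yes", 2), ({"f1": "b", "f2": "y"}, "no", 7),
    ]

    def _examples(self):
        return [LabeledExample(fv, label) for fv, label, n in self.DATA for _ in range(n)]

    def test_zero_iterations_uniform(self):
        model = maxent_train(self._examples(), "gis", max_iter=0)
        post = maxent_posterior(model, {"f1": "a", "f2": "x"})
        assert post == {"yes": 0.5, "no": 0.5}

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            maxent_train(self._examples(), "simulated-annealing")

    def test_gis_log_likelihood_non_decreasing(self):
        model = maxent_train(self._examples(), "gis", max_iter=200, tol=1e-12)
        trace = model.training_meta["log_likelihood_trace"]
        assert len(trace) > 2
        assert all(b - a >= -1e-9 for a, b in zip(trace, trace[1:]))

    def test_ll_non_decreasing_on_separable_single_feature(self):
        exs = [LabeledExample({"f": "a"}, "yes")] * 5 + [LabeledExample({"f": "b"}, "no")] * 5
        model = maxent_train(exs, "gis", max_iter=50, tol=0.0)
        trace = model.training_meta["log_likelihood_trace"]
        assert all(b - a >= -1e-9 for a, b in zip(trace, trace[1:]))

    def test_posteriors_normalize(self, rng):
        model = maxent_train(self._examples(), "gis", max_iter=100)
        for _ in range(50):
            fv = {"f1": rng.choice(["a", "b", "unseen"]), "f2": rng.choice(["x", "y"])}
            post = maxent_posterior(model, fv)
            assert post["yes"] + post["no"] == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("method", ["gis", "gradient"])
    def test_matches_unregularized_logistic_fit(self, method):
        model = maxent_train(self._examples(), method, max_iter=3000, tol=1e-12)
        fvals = [("f1", "a"), ("f1", "b"), ("f2", "x"), ("f2", "y")]
        lr = _sklearn_logistic(self.DATA, fvals)
        for f1 in ("a", "b"):
            for f2 in ("x", "y"):
                fv = {"f1": f1, "f2": f2}
                row = [[1.0 if fv.get(f) == v else 0.0 for f, v in fvals]]
                expected = lr.predict_proba(row)[0, 1]
                assert maxent_posterior(model, fv)["yes"] == pytest.approx(expected, abs=1e-3)

    def test_raising_active_weight_raises_posterior(self):
        model = maxent_train(self._examples(), "gis", max_iter=100)
        fv = {"f1": "a", "f2": "x"}
        before = maxent_posterior(model, fv)["yes"]
        idx = model.feature_functions.index(("yes", "f1", "a"))
        model.weights[idx] += 1.0
        after = maxent_posterior(model, fv)["yes"]
        assert after > before

    def test_deterministic_under_permutation(self, rng):
        exs = self._examples()
        shuffled = exs[:]
        rng.shuffle(shuffled)
        m1 = maxent_train(exs, "gis", max_iter=50)
        m2 = maxent_train(shuffled, "gis", max_iter=50)
        assert list(m1.weights) == list(m2.weights)
        assert m1.feature_functions == m2.feature_functions

    def test_tie_breaks_to_no_at_zero_weights(self):
        model = maxent_train(self._examples(), "gis", max_iter=0)
        assert label_of(model, {"f1": "a", "f2": "x"}) == "no"

    def test_empty_examples_rejected(self):
        with pytest.raises(ValueError):
            maxent_train([], "gis")
        with pytest.raises(ValueError):
            nb_train([])
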