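"""Probabilistic classifiers over nominal feature vectors.

Two models share the two-class label set ``C = {"yes", "no"}`` ("is a
scientific name" / "is not"):

* **Naive Bayes** — generative: the class posterior is proportional to
  ``P(c) * prod_k P(f_k = v_k | c)`` under conditional independence of the
  features given the class.  Conditional tables are estimated by
  additively smoothed relative frequency with one reserved cell for values
  unseen in training, so log probabilities are always finite.
* **Maximum entropy** — discriminative log-linear model
  ``P(c | s) = exp(sum_m lambda_m g_m(c, s)) / Z(s)`` with binary indicator
  feature functions ``g_m`` over observed (class, feature-name=value)
  pairs.  Weights are fitted by Generalized Iterative Scaling (with the
  standard slack function making per-example active-function totals
  constant) or, optionally, by a generic gradient optimizer on the exact
  conditional log-likelihood.

Both decision rules are pure argmax of the posterior; an exact tie yields
``"no"``.  Training is deterministic: examples are canonically sorted
before estimation and no randomness is involved.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.special import logsumexp

from binomen.features import FeatureVector

LABELS = ("yes", "no")

#: probability floor used in place of log(0) when alpha = 0
ZERO_FLOOR = 1e-12


@dataclass(frozen=True)
class LabeledExample:
    features: FeatureVector
    label: str

    def __post_init__(self):
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")


def _canonical_order(examples: list[LabeledExample]) -> list[LabeledExample]:
    return sorted(examples, key=lambda e: (e.label, sorted(e.features.items())))


# ---------------------------------------------------------------------------
# Naive Bayes
# ---------------------------------------------------------------------------

@dataclass
class NBModel:
    class_priors: dict[str, float]
    conditional_tables: dict[str, dict[str, dict[str, float]]]  # fname -> label -> value -> P
    unseen: dict[str, dict[str, float]]  # fname -> label -> P(unseen value | label)
    alpha: float
    feature_index: dict[str, list[str]]  # fname -> sorted observed values
    fingerprint: dict = field(default_factory=dict)

    def log_scores(self, fv: FeatureVector) -> dict[str, float]:
        scores = {}
        for c in LABELS:
            lp = math.log(self.class_priors[c]) if self.class_priors[c] > 0 else math.log(ZERO_FLOOR)
            for fname, table in self.conditional_tables.items():
                if fname not in fv:
                    continue
                value = fv[fname]
                prob = table[c].get(value)
                if prob is None:
                    prob = self.unseen[fname][c]
                lp += math.log(prob)
            scores[c] = lp
        return scores

    def posterior(self, fv: FeatureVector) -> dict[str, float]:
        scores = self.log_scores(fv)
        arr = np.array([scores[c] for c in LABELS])
        norm = logsumexp(arr)
        return {c: float(np.exp(scores[c] - norm)) for c in LABELS}

    def to_dict(self) -> dict:
        return {
            "kind": "nb",
            "alpha": self.alpha,
            "class_priors": self.class_priors,
            "conditional_tables": self.conditional_tables,
            "unseen": self.unseen,
            "feature_index": self.feature_index,
            "fingerprint": self.fingerprint,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NBModel":
        return cls(
            class_priors=d["class_priors"],
            conditional_tables=d["conditional_tables"],
            unseen=d["unseen"],
            alpha=d["alpha"],
            feature_index=d["feature_index"],
            fingerprint=d.get("fingerprint", {}),
        )


def nb_train(examples: list[LabeledExample], alpha: float = 1.0,
             fingerprint: dict | None = None) -> NBModel:
    """Estimate priors and conditional tables by smoothed relative
    frequency.

    ``P(f=v|c) = (count(v,c) + alpha) / (count(c) + alpha * (|V_f| + 1))``
    where ``V_f`` is the set of values of feature f observed in training
    (either class) and the ``+1`` reserves one cell whose mass is reported
    for values never seen in training.  With ``alpha = 0`` zero cells fall
    to a fixed floor instead, so logarithms stay finite.
    """
    if not examples:
        raise ValueError("cannot train on an empty example list")
    if alpha < 0:
        raise ValueError(f"alpha must be >= 0, got {alpha}")
    examples = _canonical_order(examples)
    n = len(examples)
    class_counts = {c: 0 for c in LABELS}
    value_counts: dict[str, dict[str, dict[str, int]]] = {}
    values_of: dict[str, set[str]] = {}
    for ex in examples:
        class_counts[ex.label] += 1
        for fname, value in ex.features.items():
            values_of.setdefault(fname, set()).add(value)
            value_counts.setdefault(fname, {c: {} for c in LABELS})
            row = value_counts[fname][ex.label]
            row[value] = row.get(value, 0) + 1

    priors = {c: (class_counts[c] + alpha) / (n + alpha * len(LABELS)) if (n + alpha * len(LABELS)) > 0
              else 1.0 / len(LABELS) for c in LABELS}
    if alpha == 0:
        priors = {c: (class_counts[c] / n) if class_counts[c] > 0 else ZERO_FLOOR for c in LABELS}

    tables: dict[str, dict[str, dict[str, float]]] = {}
    unseen: dict[str, dict[str, float]] = {}
    for fname, values in values_of.items():
        nvals = len(values)
        tables[fname] = {}
        unseen[fname] = {}
        for c in LABELS:
            denom = class_counts[c] + alpha * (nvals + 1)
            row = {}
            for value in values:
                count = value_counts[fname][c].get(value, 0)
                if alpha > 0:
                    row[value] = (count + alpha) / denom
                else:
                    row[value] = count / class_counts[c] if class_counts[c] > 0 and count > 0 else ZERO_FLOOR
            tables[fname][c] = row
            unseen[fname][c] = alpha / denom if alpha > 0 and denom > 0 else ZERO_FLOOR
    return NBModel(
        class_priors=priors,
        conditional_tables=tables,
        unseen=unseen,
        alpha=alpha,
        feature_index={fname: sorted(values) for fname, values in values_of.items()},
        fingerprint=fingerprint or {},
    )


def nb_posterior(model: NBModel, fv: FeatureVector) -> dict[str, float]:
    """Normalized class posterior, computed in log space.  An empty vector
    returns the priors."""
    return model.posterior(fv)


def nb_label(model: NBModel, fv: FeatureVector) -> str:
    """Argmax of log prior + summed log conditionals; exact tie -> "no"."""
    scores = model.log_scores(fv)
    if scores["yes"] > scores["no"]:
        return "yes"
    return "no"


# ---------------------------------------------------------------------------
# Maximum entropy
# ---------------------------------------------------------------------------

@dataclass
class MaxEntModel:
    weights: np.ndarray  # length M + 1; last entry is the slack function
    feature_functions: list[tuple[str, str, str]]  # (label, fname, value)
    C: float  # GIS constant: max active-function total per (example, class)
    training_meta: dict = field(default_factory=dict)
    fingerprint: dict = field(default_factory=dict)

    def __post_init__(self):
        self._index = {f: i for i, f in enumerate(self.feature_functions)}

    def _score(self, fv: FeatureVector, label: str) -> float:
        idx = self._index
        total = 0.0
        active = 0
        w = self.weights
        for fname, value in fv.items():
            i = idx.get((label, fname, value))
            if i is not None:
                total += w[i]
                active += 1
        total += w[-1] * (self.C - active)  # slack keeps totals constant
        return total

    def log_scores(self, fv: FeatureVector) -> dict[str, float]:
        return {c: self._score(fv, c) for c in LABELS}

    def posterior(self, fv: FeatureVector) -> dict[str, float]:
        scores = self.log_scores(fv)
        arr = np.array([scores[c] for c in LABELS])
        norm = logsumexp(arr)
        return {c: float(np.exp(scores[c] - norm)) for c in LABELS}

    def to_dict(self) -> dict:
        return {
            "kind": "maxent",
            "weights": [float(w) for w in self.weights],
            "feature_functions": [list(f) for f in self.feature_functions],
            "C": self.C,
            "training_meta": self.training_meta,
            "fingerprint": self.fingerprint,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MaxEntModel":
        return cls(
            weights=np.array(d["weights"], dtype=float),
            feature_functions=[tuple(f) for f in d["feature_functions"]],
            C=d["C"],
            training_meta=d.get("training_meta", {}),
            fingerprint=d.get("fingerprint", {}),
        )


def maxent_label(model: MaxEntModel, fv: FeatureVector) -> str:
    scores = model.log_scores(fv)
    if scores["yes"] > scores["no"]:
        return "yes"
    return "no"


def label_of(model, fv: FeatureVector) -> str:
    """Argmax decision for either model kind; exact tie -> "no"."""
    scores = model.log_scores(fv)
    return "yes" if scores["yes"] > scores["no"] else "no"


def _encode(examples: list[LabeledExample]):
    """Build the indicator-function index and per-class sparse design
    matrices.  Column M (the last) is the GIS slack function with value
    ``C - n_active(x, c)``."""
    functions: list[tuple[str, str, str]] = []
    index: dict[tuple[str, str, str], int] = {}
    for ex in examples:
        for fname, value in ex.features.items():
            key = (ex.label, fname, value)
            if key not in index:
                index[key] = len(functions)
                functions.append(key)
    m = len(functions)
    n = len(examples)
    actives: dict[str, list[list[int]]] = {c: [] for c in LABELS}
    cmax = 0
    for ex in examples:
        for c in LABELS:
            act = [index[(c, fname, value)] for fname, value in ex.features.items()
                   if (c, fname, value) in index]
            actives[c].append(act)
            cmax = max(cmax, len(act))
    C = float(max(cmax, 1))
    mats = {}
    for c in LABELS:
        rows, cols, vals = [], [], []
        for i, act in enumerate(actives[c]):
            for j in act:
                rows.append(i)
                cols.append(j)
                vals.append(1.0)
            slack = C - len(act)
            if slack:
                rows.append(i)
                cols.append(m)
                vals.append(slack)
        mats[c] = sparse.csr_matrix(
            (vals, (rows, cols)), shape=(n, m + 1), dtype=float
        )
    return functions, mats, C


def _posteriors_matrix(mats, weights):
    scores = np.column_stack([mats[c] @ weights for c in LABELS])
    norm = logsumexp(scores, axis=1, keepdims=True)
    return np.exp(scores - norm)  # n x 2, columns ordered like LABELS


def maxent_train(examples: list[LabeledExample], method: str = "gis",
                 max_iter: int = 100, tol: float = 1e-6,
                 fingerprint: dict | None = None) -> MaxEntModel:
    """Fit maximum-entropy weights.

    ``method="gis"`` (required): multiplicative updates
    ``lambda_m += log(E_emp[g_m] / E_model[g_m]) / C``; the training
    log-likelihood is non-decreasing and is recorded per iteration.
    Stops after ``max_iter`` iterations or when the improvement drops
    below ``tol``.

    ``method="gradient"`` (optional): L-BFGS on the exact conditional
    log-likelihood, same parametrization.
    """
    if not examples:
        raise ValueError("cannot train on an empty example list")
    if method not in ("gis", "gradient"):
        raise ValueError(f"unknown estimation method {method!r} (use 'gis' or 'gradient')")
    examples = _canonical_order(examples)
    functions, mats, C = _encode(examples)
    n = len(examples)
    label_idx = np.array([LABELS.index(ex.label) for ex in examples])
    # empirical counts: sum of the observed-label rows
    emp = np.zeros(len(functions) + 1)
    for ci, c in enumerate(LABELS):
        rows = np.where(label_idx == ci)[0]
        if rows.size:
            emp += np.asarray(mats[c][rows].sum(axis=0)).ravel()
    weights = np.zeros(len(functions) + 1)
    ll_trace: list[float] = []
    iterations = 0

    def log_likelihood(w):
        scores = np.column_stack([mats[c] @ w for c in LABELS])
        norm = logsumexp(scores, axis=1)
        return float(np.sum(scores[np.arange(n), label_idx] - norm))

    if method == "gis":
        updatable = emp > 0
        prev_ll = log_likelihood(weights)
        ll_trace.append(prev_ll)
        for it in range(max_iter):
            post = _posteriors_matrix(mats, weights)
            expected = np.zeros_like(emp)
            for ci, c in enumerate(LABELS):
                expected += mats[c].T @ post[:, ci]
            with np.errstate(divide="ignore", invalid="ignore"):
                delta = np.where(
                    updatable & (expected > 0),
                    np.log(np.maximum(emp, ZERO_FLOOR) / np.maximum(expected, ZERO_FLOOR)) / C,
                    0.0,
                )
            weights = weights + delta
            iterations = it + 1
            ll = log_likelihood(weights)
            ll_trace.append(ll)
            if ll - prev_ll < tol:
                prev_ll = ll
                break
            prev_ll = ll
    else:  # gradient
        from scipy.optimize import minimize

        if max_iter > 0:
            def objective(w):
                scores = np.column_stack([mats[c] @ w for c in LABELS])
                norm = logsumexp(scores, axis=1)
                ll = np.sum(scores[np.arange(n), label_idx] - norm)
                post = np.exp(scores - norm[:, None])
                expected = np.zeros_like(emp)
                for ci, c in enumerate(LABELS):
                    expected += mats[c].T @ post[:, ci]
                grad = emp - expected
                return -ll, -grad

            res = minimize(objective, weights, jac=True, method="L-BFGS-B",
                           options={"maxiter": max_iter, "gtol": tol})
            weights = res.x
            iterations = int(res.nit)
        ll_trace.append(log_likelihood(weights))

    return MaxEntModel(
        weights=weights,
        feature_functions=functions,
        C=C,
        training_meta={
            "method": method,
            "iterations": iterations,
            "final_log_likelihood": ll_trace[-1] if ll_trace else 0.0,
            "log_likelihood_trace": ll_trace,
        },
        fingerprint=fingerprint or {},
    )


def maxent_posterior(model: MaxEntModel, fv: FeatureVector) -> dict[str, float]:
    """Exponential-form posterior ``exp(sum lambda_m g_m(c, s)) / Z(s)``;
    feature values outside the model's index activate no function."""
    return model.posterior(fv)


def train(examples: list[LabeledExample], config) -> "NBModel | MaxEntModel":
    """Train the classifier selected by the configuration."""
    fp = config.feature_fingerprint()
    if config.classifier == "nb":
        return nb_train(examples, alpha=config.alpha, fingerprint=fp)
    if config.classifier == "maxent":
        return maxent_train(examples, method=config.maxent_method,
                            max_iter=config.max_iter, tol=config.tol, fingerprint=fp)
    raise ValueError(f"unknown classifier {config.classifier!r}")
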