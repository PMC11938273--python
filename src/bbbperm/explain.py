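"""Model interpretation: Shapley attributions and surrogate decision trees.

``shap_attributions`` computes additive feature attributions for a fitted
model.  In ``exact`` mode every feature coalition is enumerated (2^p model
evaluations per sample, limited to p <= 10) against a single-reference
baseline — by default the training-set feature means — so the classical
Shapley axioms (efficiency, symmetry, null player) hold to numerical
precision.  ``sampled`` mode estimates the same values by seeded permutation
sampling for wider feature sets.

``fit_surrogate`` distills an opaque classifier into an axis-aligned
decision tree trained on the opaque model's *predictions*; the agreement
between the two (fidelity) is attached as a :class:`~bbbperm.mlcv.MetricSet`.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.tree import DecisionTreeClassifier

from .exceptions import ConfigurationError, UndefinedMetricError
from .mlcv.pipeline import MetricSet, evaluate

__all__ = [
    "AttributionMatrix",
    "SurrogateTree",
    "shap_attributions",
    "rank_features",
    "fit_surrogate",
    "export_tree",
    "parse_tree_text",
]

EXACT_MODE_MAX_FEATURES = 10
DEFAULT_N_PERMUTATIONS = 2048


@dataclass
class AttributionMatrix:
    """Per-sample, per-feature additive attributions.

    For every sample, ``base_value + values[i].sum()`` reproduces the model
    output (exactly in ``exact`` mode, within Monte Carlo error in
    ``sampled`` mode).
    """

    values: np.ndarray  # (n_samples, n_features)
    base_value: float
    feature_names: list[str]
    model_id: str = ""
    mode: str = "exact"
    seed: int | None = None

    def check_additivity(
        self, predict: Callable[[np.ndarray], np.ndarray], X: np.ndarray, tol: float = 1e-6
    ) -> None:
        out = np.asarray(predict(np.asarray(X, dtype=float)), dtype=float)
        recon = self.base_value + self.values.sum(axis=1)
        err = np.max(np.abs(out - recon))
        if err > tol:
            raise AssertionError(f"additivity violated: max error {err:.3g} > {tol}")


def _as_output_fn(model, class_index: int | None):
    """Turn a fitted model into a scalar-output function."""
    if callable(model) and not hasattr(model, "predict_proba"):
        return model
    if class_index is None:
        class_index = 1 if len(model.classes_) == 2 else 0
    return lambda X: model.predict_proba(X)[:, class_index]


def shap_attributions(
    model,
    X: np.ndarray,
    baseline: np.ndarray | None = None,
    mode: str = "exact",
    seed: int | None = None,
    class_index: int | None = None,
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    feature_names: Sequence[str] | None = None,
    background: np.ndarray | None = None,
) -> AttributionMatrix:
    """Shapley attributions of ``model`` outputs over the rows of ``X``.

    ``model`` is either a fitted classifier (its ``predict_proba`` column
    ``class_index`` is attributed; default: positive class for binary) or a
    plain callable mapping an (n, p) array to n outputs.  The coalition
    value of a feature set S is the model output with the features in S
    taken from the sample and all others from ``baseline`` (default: the
    column means of ``background`` or of ``X`` itself).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    if feature_names is None:
        feature_names = [f"x{j}" for j in range(p)]
    if baseline is None:
        ref = X if background is None else np.atleast_2d(np.asarray(background, float))
        baseline = ref.mean(axis=0)
    baseline = np.asarray(baseline, dtype=float).reshape(p)
    f = _as_output_fn(model, class_index)
    base_value = float(np.asarray(f(baseline[None, :]))[0])

    if mode == "exact":
        if p > EXACT_MODE_MAX_FEATURES:
            raise ConfigurationError(
                f"exact mode enumerates 2^p coalitions; p={p} exceeds "
                f"{EXACT_MODE_MAX_FEATURES} (use mode='sampled')"
            )
        values = _exact_shapley(f, X, baseline, base_value)
    elif mode == "sampled":
        values = _sampled_shapley(f, X, baseline, seed, n_permutations)
    else:
        raise ConfigurationError(f"unknown mode {mode!r}")
    return AttributionMatrix(
        values=values,
        base_value=base_value,
        feature_names=list(feature_names),
        model_id=type(model).__name__,
        mode=mode,
        seed=seed,
    )


def _exact_shapley(f, X: np.ndarray, baseline: np.ndarray, base_value: float) -> np.ndarray:
    n, p = X.shape
    n_masks = 1 << p
    masks = np.arange(n_masks)
    bits = ((masks[:, None] >> np.arange(p)) & 1).astype(bool)  # (2^p, p)
    # batch-evaluate every coalition of every sample in one call
    Z = np.where(bits[None, :, :], X[:, None, :], baseline[None, None, :])
    v = np.asarray(f(Z.reshape(n * n_masks, p)), dtype=float).reshape(n, n_masks)

    sizes = bits.sum(axis=1)
    fact = np.array([math.factorial(k) for k in range(p + 1)], dtype=float)
    values = np.zeros((n, p))
    for j in range(p):
        without_j = np.nonzero(~bits[:, j])[0]
        with_j = without_j | (1 << j)
        w = fact[sizes[without_j]] * fact[p - sizes[without_j] - 1] / fact[p]
        values[:, j] = ((v[:, with_j] - v[:, without_j]) * w[None, :]).sum(axis=1)
    return values


def _sampled_shapley(
    f, X: np.ndarray, baseline: np.ndarray, seed: int | None, n_permutations: int
) -> np.ndarray:
    n, p = X.shape
    rng = np.random.default_rng(seed)
    values = np.zeros((n, p))
    for _ in range(n_permutations):
        order = rng.permutation(p)
        # walk the permutation, switching features from baseline to sample
        Z = np.tile(baseline, (n, p + 1, 1))
        for step, j in enumerate(order, start=1):
            Z[:, step:, j] = X[:, None, j]
        v = np.asarray(f(Z.reshape(n * (p + 1), p)), dtype=float).reshape(n, p + 1)
        values[np.arange(n)[:, None], order[None, :]] += np.diff(v, axis=1)
    return values / n_permutations


def rank_features(attributions: AttributionMatrix) -> list[tuple[str, float]]:
    """Features ordered by mean |attribution|, descending; ties break
    lexicographically by name."""
    if attributions.values.size == 0:
        raise ValueError("empty attribution matrix")
    importance = np.abs(attributions.values).mean(axis=0)
    order = sorted(
        zip(attributions.feature_names, importance), key=lambda t: (-t[1], t[0])
    )
    return [(name, float(v)) for name, v in order]


# ---------------------------------------------------------------------------
# Surrogate trees


@dataclass
class SurrogateTree:
    """A shallow decision tree distilled from an opaque model, with the
    fidelity of its predictions to the opaque model's own."""

    tree: DecisionTreeClassifier
    max_depth: int
    feature_names: list[str]
    fidelity: MetricSet

    @property
    def depth(self) -> int:
        return self.tree.get_depth()

    def predict(self, X):
        return self.tree.predict(X)


def fit_surrogate(
    opaque_model,
    X: np.ndarray,
    max_depth: int = 4,
    seed: int | None = 0,
    feature_names: Sequence[str] | None = None,
) -> SurrogateTree:
    """Distill ``opaque_model`` into a depth-limited decision tree.

    The tree is trained on ``(X, opaque_model.predict(X))`` and its
    fidelity — how faithfully it reproduces the opaque predictions on the
    same rows — is attached.  A degenerate opaque model that predicts a
    single class yields a trivial perfectly faithful tree (with AUC
    undefined, reported as NaN) and a warning.
    """
    X = np.asarray(X, dtype=float)
    if feature_names is None:
        feature_names = [f"x{j}" for j in range(X.shape[1])]
    opaque_pred = np.asarray(opaque_model.predict(X))
    tree = DecisionTreeClassifier(max_depth=max_depth, random_state=seed)
    tree.fit(X, opaque_pred)
    if len(np.unique(opaque_pred)) < 2:
        warnings.warn(
            "opaque model predicts a single class; surrogate is trivial", stacklevel=2
        )
        fidelity = MetricSet(acc=1.0, sns=1.0, spc=1.0, ppv=1.0, npv=1.0, auc=float("nan"))
    else:
        task = "two_class" if len(tree.classes_) == 2 else "multiclass"
        fidelity = evaluate(opaque_pred, tree.predict_proba(X), tree.classes_, task=task)
    return SurrogateTree(
        tree=tree,
        max_depth=max_depth,
        feature_names=list(feature_names),
        fidelity=fidelity,
    )


def export_tree(surrogate: SurrogateTree) -> str:
    """Indented text diagram of the surrogate.

    Internal nodes print the split feature and threshold (standardized
    feature units, 2 decimals) plus the node's class distribution; leaves
    print the majority label and distribution.  Follow the tree from the
    top: left child = condition true (feature <= threshold).
    """
    t = surrogate.tree.tree_
    classes = [str(c) for c in surrogate.tree.classes_]

    def dist(node: int) -> str:
        counts = t.value[node][0]
        frac = counts / counts.sum()
        return "[" + ", ".join(f"{v:.2f}" for v in frac) + "]"

    lines: list[str] = [f"classes: {', '.join(classes)}"]

    def walk(node: int, depth: int) -> None:
        pad = "  " * depth
        if t.children_left[node] == -1:
            label = classes[int(np.argmax(t.value[node][0]))]
            lines.append(f"{pad}leaf label={label} dist={dist(node)}")
            return
        name = surrogate.feature_names[t.feature[node]]
        lines.append(f"{pad}node {name} <= {t.threshold[node]:.2f} dist={dist(node)}")
        walk(t.children_left[node], depth + 1)
        walk(t.children_right[node], depth + 1)

    walk(0, 0)
    return "\n".join(lines) + "\n"


_NODE_RE = re.compile(r"^node (?P<name>\S+) <= (?P<thr>-?\d+\.\d{2}) dist=\[(?P<dist>[^\]]*)\]$")
_LEAF_RE = re.compile(r"^leaf label=(?P<label>\S+) dist=\[(?P<dist>[^\]]*)\]$")


def parse_tree_text(text: str) -> dict:
    """Parse an :func:`export_tree` diagram back into a nested structure
    (for round-trip checks and downstream tooling)."""
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines or not lines[0].startswith("classes:"):
        raise ValueError("missing classes header")
    classes = [c.strip() for c in lines[0][len("classes:"):].split(",")]
    entries = []
    for ln in lines[1:]:
        depth = (len(ln) - len(ln.lstrip())) // 2
        body = ln.strip()
        m = _NODE_RE.match(body)
        if m:
            entries.append(
                (depth, {
                    "kind": "node",
                    "feature": m["name"],
                    "threshold": float(m["thr"]),
                    "dist": [float(v) for v in m["dist"].split(",")],
                })
            )
            continue
        m = _LEAF_RE.match(body)
        if m:
            entries.append(
                (depth, {
                    "kind": "leaf",
                    "label": m["label"],
                    "dist": [float(v) for v in m["dist"].split(",")],
                })
            )
            continue
        raise ValueError(f"unparsable line: {ln!r}")

    pos = 0

    def build(depth: int) -> dict:
        nonlocal pos
        d, node = entries[pos]
        if d != depth:
            raise ValueError("inconsistent indentation")
        pos += 1
        if node["kind"] == "node":
            node["left"] = build(depth + 1)
            node["right"] = build(depth + 1)
        return node

    root = build(0)
    if pos != len(entries):
        raise ValueError("trailing lines after tree")
    return {"classes": classes, "root": root}
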