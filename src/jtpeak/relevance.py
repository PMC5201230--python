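"""Slur-relevance decision tree.

Whether a slur that follows the T-peak marks the terminal decay of the T-wave
(and should anchor the offset search) is decided by a small binary decision
tree over three candidate-pair features: the angle between the slur's two
limb slopes, the angle between the peak's falling and the slur's rising
slope, and the peak/slur-origin amplitude ratio.

The tree is plain data (JSON): each internal node holds a feature name and a
threshold (``value <= threshold`` goes left), each leaf a label. Training is
delegated to scikit-learn's CART implementation, after which the fitted
splits are extracted into this structure, so classification at run time has
no model-library dependency.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .errors import ClassificationError, TrainingError

#: the three features retained after pruning, in training order
SELECTED_FEATURES = ("slur_slope_angle", "peak_slur_angle", "peak_slur_origin_ratio")

RELEVANT, IRRELEVANT = "relevant", "irrelevant"


@dataclass
class RelevanceTree:
    """Binary decision tree over the selected slur features."""

    root: dict
    metadata: dict = field(default_factory=dict)

    def predict(self, features):
        """Classify one example; returns ``"relevant"`` or ``"irrelevant"``."""
        node = self.root
        while "label" not in node:
            name = node["feature"]
            try:
                value = features[name]
            except KeyError as exc:
                raise ClassificationError(f"missing feature {name!r}") from exc
            node = node["left"] if value <= node["threshold"] else node["right"]
        return node["label"]

    def to_json(self, path):
        with open(path, "w") as fh:
            json.dump({"metadata": self.metadata, "root": self.root}, fh, indent=1)

    @classmethod
    def from_json(cls, path):
        with open(path) as fh:
            obj = json.load(fh)
        return cls(obj["root"], obj.get("metadata", {}))

    @classmethod
    def load_default(cls):
        """The bundled tree, trained on the labeled synthetic slur corpus."""
        ref = resources.files("jtpeak.data") / "default_relevance_tree.json"
        with resources.as_file(ref) as p:
            return cls.from_json(p)


def classify_slur_relevance(features, tree):
    """Deterministic traversal of ``tree`` over the selected features."""
    return tree.predict(features)


def _convert_sklearn(clf, feature_names):
    tree = clf.tree_
    classes = list(clf.classes_)

    def node(i):
        if tree.children_left[i] == -1:
            counts = tree.value[i][0]
            return {"label": classes[int(np.argmax(counts))]}
        return {
            "feature": feature_names[tree.feature[i]],
            "threshold": float(tree.threshold[i]),
            "left": node(tree.children_left[i]),
            "right": node(tree.children_right[i]),
        }

    return node(0)


def train_relevance_tree(examples, labels, max_depth=4, seed=0, metadata=None):
    """Fit a pruned binary tree on labeled slur examples.

    Parameters
    ----------
    examples : sequence of SlurFeatures or mappings
    labels : sequence of {"relevant", "irrelevant"}
    max_depth : int
        Pruning depth of the fitted tree.
    seed : int
        Makes tie-breaking in the fit deterministic.
    """
    from sklearn.tree import DecisionTreeClassifier

    labels = list(labels)
    if len(examples) != len(labels):
        raise TrainingError("examples and labels must have equal length")
    if len(labels) < 50:
        raise TrainingError("at least 50 labeled examples are required")
    if len(set(labels)) < 2:
        raise TrainingError("both classes must be present")
    bad = set(labels) - {RELEVANT, IRRELEVANT}
    if bad:
        raise TrainingError(f"unknown labels: {sorted(bad)}")

    X = np.array([[ex[f] for f in SELECTED_FEATURES] for ex in examples], dtype=float)
    # balanced weights: missing a genuine terminal shoulder costs far more
    # downstream than keeping a noise slur, and shoulders are the rarer class
    clf = DecisionTreeClassifier(
        max_depth=max_depth, random_state=seed, class_weight="balanced"
    )
    clf.fit(X, labels)
    meta = {
        "features": list(SELECTED_FEATURES),
        "max_depth": max_depth,
        "seed": seed,
        "n_examples": len(labels),
        "version": 1,
    }
    if metadata:
        meta.update(metadata)
    return RelevanceTree(_convert_sklearn(clf, SELECTED_FEATURES), meta)
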