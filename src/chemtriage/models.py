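"""The two document classifiers and their feature-importance schemes.

Naive Bayes
-----------
The default NB variant is the Laplacian-corrected relative-frequency score
used for "corpus-likeness" ranking: for a feature f present in A_f positive
documents and B_f documents overall,

    weight(f) = ln[(A_f + 1) / (B_f * p + 1)],    p = prior positive fraction

and a document's score is the sum of the weights of its *present* features
(absence contributes nothing). The weight is positive when a feature is
over-represented in the positive class relative to its overall rate, negative
when under-represented, and exactly zero when A_f = B_f * p. A full Bernoulli
NB variant (Laplace alpha=1, absence terms folded into per-feature weights
plus an intercept) is available via ``variant="bernoulli"``.

Random forest
-------------
Individual trees are grown by scikit-learn's CART implementation (Gini
criterion, sqrt-of-vocabulary candidate features per split); bootstrap
sampling, out-of-bag accounting, and the serializable tree representation are
handled here. Two importance schemes are exposed: the signed NB weight, and
the split-frequency count over the first levels of every tree (the level-1
count correlates with Gini importance).
"""

from __future__ import annotations

import gzip
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.tree import DecisionTreeClassifier

from . import evaluate
from .errors import ModelFormatError, ValidationError
from .preprocess import PipelineConfig
from .vectorize import DocTermMatrix, Vocabulary

MODEL_FORMAT_VERSION = 1


def _check_alignment(model_vocab: Vocabulary, matrix: DocTermMatrix) -> None:
    if matrix.vocabulary is model_vocab:
        return
    if matrix.vocabulary.terms != model_vocab.terms:
        raise ValidationError(
            "matrix vocabulary does not match the model's vocabulary "
            f"({len(matrix.vocabulary)} vs {len(model_vocab)} terms)"
        )


def _require_both_classes(labels: np.ndarray) -> tuple[int, int]:
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("training requires both classes present")
    return n_pos, n_neg


@dataclass
class ImportanceTable:
    """Per-feature importance rows, sortable by magnitude."""

    terms: list[str]
    importance: np.ndarray
    class_association: list[str]  # "positive" | "negative"
    per_level: dict[int, np.ndarray] | None = None  # RF: level -> counts

    def sorted_by_magnitude(self) -> "ImportanceTable":
        order = sorted(
            range(len(self.terms)),
            key=lambda i: (-abs(self.importance[i]), self.terms[i]),
        )
        return ImportanceTable(
            terms=[self.terms[i] for i in order],
            importance=self.importance[np.asarray(order, dtype=int)]
            if len(order)
            else self.importance,
            class_association=[self.class_association[i] for i in order],
            per_level=None
            if self.per_level is None
            else {lv: c[np.asarray(order, dtype=int)] for lv, c in self.per_level.items()},
        )

    def top_terms(self, k: int, association: str | None = None) -> list[str]:
        rows = [
            (t, imp)
            for t, imp, assoc in zip(self.terms, self.importance, self.class_association)
            if association is None or assoc == association
        ]
        key = (lambda r: (-r[1], r[0])) if association == "positive" else (
            lambda r: (-abs(r[1]), r[0])
        )
        return [t for t, _ in sorted(rows, key=key)[:k]]

    def to_tsv(self, namespaces: Sequence[str] | None = None) -> str:
        lines = ["term\tnamespace\timportance\tclass_association"]
        ns = namespaces or ["bow" if "_" not in t else "ngram" for t in self.terms]
        for t, n, imp, assoc in zip(self.terms, ns, self.importance, self.class_association):
            lines.append(f"{t}\t{n}\t{float(imp)!r}\t{assoc}")
        return "\n".join(lines) + "\n"


@dataclass
class NBModel:
    """Additive per-feature Bayesian scorer over binary document vectors."""

    vocabulary: Vocabulary
    weights: np.ndarray  # aligned to vocabulary.terms
    prior_positive: float
    threshold: float
    n_pos: int
    n_neg: int
    intercept: float = 0.0
    variant: str = "laplace_relative"
    pipeline: PipelineConfig | None = None
    oob_scores: np.ndarray | None = None  # always None; present for a uniform API

    model_type = "nb"

    @property
    def feature_weights(self) -> dict[str, float]:
        return dict(zip(self.vocabulary.terms, self.weights.tolist()))

    def decision_scores(self, matrix: DocTermMatrix) -> np.ndarray:
        """Sum of present-feature weights (+ intercept for the Bernoulli variant)."""
        _check_alignment(self.vocabulary, matrix)
        return np.asarray(matrix.bits @ self.weights).ravel() + self.intercept

    def classify(self, matrix: DocTermMatrix) -> np.ndarray:
        return (self.decision_scores(matrix) >= self.threshold).astype(int)


def train_nb(
    matrix: DocTermMatrix,
    prior: float | None = None,
    variant: str = "laplace_relative",
    pipeline: PipelineConfig | None = None,
) -> NBModel:
    """Fit the NB scorer on a labeled binary matrix.

    ``prior`` defaults to the empirical positive fraction. The decision
    threshold is the MCC-maximizing cut on the training scores (0 when
    degenerate).
    """
    if matrix.labels is None:
        raise ValidationError("training matrix has no labels")
    y = matrix.labels
    n_pos, n_neg = _require_both_classes(y)
    p = n_pos / (n_pos + n_neg) if prior is None else float(prior)
    if not 0 < p < 1:
        raise ValidationError("prior_positive must be in (0, 1)")

    bits = matrix.bits
    b_all = np.asarray(bits.sum(axis=0)).ravel().astype(float)  # B_f
    a_pos = np.asarray(bits[y == 1].sum(axis=0)).ravel().astype(float)  # A_f

    intercept = 0.0
    if variant == "laplace_relative":
        weights = np.log((a_pos + 1.0) / (b_all * p + 1.0))
    elif variant == "bernoulli":
        theta_pos = (a_pos + 1.0) / (n_pos + 2.0)
        theta_neg = (b_all - a_pos + 1.0) / (n_neg + 2.0)
        weights = np.log(theta_pos / theta_neg) - np.log(
            (1.0 - theta_pos) / (1.0 - theta_neg)
        )
        intercept = math.log(p / (1.0 - p)) + float(
            np.sum(np.log((1.0 - theta_pos) / (1.0 - theta_neg)))
        )
    else:
        raise ValidationError(f"unknown NB variant {variant!r}")

    model = NBModel(
        vocabulary=matrix.vocabulary,
        weights=weights,
        prior_positive=p,
        threshold=0.0,
        n_pos=n_pos,
        n_neg=n_neg,
        intercept=intercept,
        variant=variant,
        pipeline=pipeline,
    )
    model.threshold = evaluate.best_mcc_threshold(model.decision_scores(matrix), y)
    return model


def nb_importance(model: NBModel) -> ImportanceTable:
    """One row per feature: importance = signed weight; ties go to negative."""
    assoc = ["positive" if w > 0 else "negative" for w in model.weights]
    return ImportanceTable(
        terms=list(model.vocabulary.terms),
        importance=model.weights.copy(),
        class_association=assoc,
    )


# --------------------------------------------------------------------------
# Random forest
# --------------------------------------------------------------------------


@dataclass
class _Tree:
    """Flat array representation of one decision tree (JSON-serializable)."""

    feature: np.ndarray  # split feature per node, -1 for leaves
    left: np.ndarray
    right: np.ndarray
    pos_fraction: np.ndarray  # positive-class vote fraction per node

    def predict_pos_fraction(self, bits) -> np.ndarray:
        dense = np.asarray(bits.todense()) if hasattr(bits, "todense") else bits
        n = dense.shape[0]
        node = np.zeros(n, dtype=np.int64)
        active = self.feature[node] >= 0
        while active.any():
            idx = np.flatnonzero(active)
            cur = node[idx]
            go_right = dense[idx, self.feature[cur]] > 0.5
            node[idx] = np.where(go_right, self.right[cur], self.left[cur])
            active[idx] = self.feature[node[idx]] >= 0
        return self.pos_fraction[node]

    def node_depths(self) -> np.ndarray:
        depth = np.zeros(len(self.feature), dtype=np.int64)
        stack = [(0, 1)]
        while stack:
            node, d = stack.pop()
            depth[node] = d
            if self.feature[node] >= 0:
                stack.append((self.left[node], d + 1))
                stack.append((self.right[node], d + 1))
        return depth

    def to_dict(self) -> dict:
        return {
            "feature": self.feature.tolist(),
            "left": self.left.tolist(),
            "right": self.right.tolist(),
            "pos_fraction": self.pos_fraction.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "_Tree":
        return cls(
            feature=np.asarray(d["feature"], dtype=np.int64),
            left=np.asarray(d["left"], dtype=np.int64),
            right=np.asarray(d["right"], dtype=np.int64),
            pos_fraction=np.asarray(d["pos_fraction"], dtype=float),
        )


@dataclass
class ForestModel:
    """Bagged ensemble of CART trees over binary features.

    The document score is the mean positive-vote fraction across trees;
    ``threshold`` (default 0.5, majority vote) turns it into a class.
    ``oob_scores`` holds, per training document, the mean vote over the trees
    whose bootstrap excluded it (NaN for documents in every bag).
    """

    vocabulary: Vocabulary
    trees: list[_Tree]
    threshold: float
    n_pos: int
    n_neg: int
    seed: int
    oob_scores: np.ndarray | None = None
    gini_importance: np.ndarray | None = None
    pipeline: PipelineConfig | None = None

    model_type = "rf"

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    def decision_scores(self, matrix: DocTermMatrix) -> np.ndarray:
        _check_alignment(self.vocabulary, matrix)
        dense = np.asarray(matrix.bits.todense())
        votes = np.zeros(dense.shape[0], dtype=float)
        for tree in self.trees:
            votes += tree.predict_pos_fraction(dense)
        return votes / self.n_trees

    def classify(self, matrix: DocTermMatrix) -> np.ndarray:
        return (self.decision_scores(matrix) >= self.threshold).astype(int)


def train_rf(
    matrix: DocTermMatrix,
    n_trees: int = 100,
    seed: int = 0,
    max_depth: int | None = None,
    pipeline: PipelineConfig | None = None,
) -> ForestModel:
    """Grow a seeded bagged forest on a labeled binary matrix.

    Each tree is fit on a bootstrap sample of the same size as the training
    set, drawing ceil(sqrt(vocabulary)) candidate features at each split and
    choosing by Gini impurity decrease. A fixed seed yields a bit-identical
    forest.
    """
    if matrix.labels is None:
        raise ValidationError("training matrix has no labels")
    if n_trees < 1:
        raise ValidationError("n_trees must be >= 1")
    y = matrix.labels
    n_pos, n_neg = _require_both_classes(y)
    n = matrix.n_docs
    dense = np.asarray(matrix.bits.todense()).astype(np.float32)
    rng = np.random.default_rng(seed)

    trees: list[_Tree] = []
    oob_sum = np.zeros(n, dtype=float)
    oob_count = np.zeros(n, dtype=np.int64)
    gini = np.zeros(len(matrix.vocabulary), dtype=float)

    for _ in range(n_trees):
        sample = rng.integers(0, n, size=n)
        tree_seed = int(rng.integers(0, 2**31 - 1))
        clf = DecisionTreeClassifier(
            criterion="gini",
            max_features="sqrt",
            max_depth=max_depth,
            random_state=tree_seed,
        )
        clf.fit(dense[sample], y[sample])
        t = clf.tree_
        if clf.n_classes_ == 2:
            value = t.value[:, 0, :]
            pos_fraction = value[:, 1] / value.sum(axis=1)
        else:  # bootstrap drew a single class (tiny corpora)
            pos_fraction = np.full(t.node_count, float(clf.classes_[0]))
        tree = _Tree(
            feature=t.feature.astype(np.int64),
            left=t.children_left.astype(np.int64),
            right=t.children_right.astype(np.int64),
            pos_fraction=np.asarray(pos_fraction, dtype=float),
        )
        trees.append(tree)
        if clf.n_classes_ == 2:
            gini += clf.feature_importances_

        oob_mask = np.ones(n, dtype=bool)
        oob_mask[sample] = False
        if oob_mask.any():
            idx = np.flatnonzero(oob_mask)
            oob_sum[idx] += tree.predict_pos_fraction(dense[idx])
            oob_count[idx] += 1

    with np.errstate(invalid="ignore"):
        oob_scores = np.where(oob_count > 0, oob_sum / np.maximum(oob_count, 1), np.nan)
    return ForestModel(
        vocabulary=matrix.vocabulary,
        trees=trees,
        threshold=0.5,
        n_pos=n_pos,
        n_neg=n_neg,
        seed=seed,
        oob_scores=oob_scores,
        gini_importance=gini / n_trees,
        pipeline=pipeline,
    )


def rf_top_level_importance(model: ForestModel, max_level: int = 3) -> ImportanceTable:
    """Split-frequency importance over the first ``max_level`` tree levels.

    importance(f) = number of internal nodes at depth <= max_level (root =
    depth 1) splitting on f, summed over all trees. The per-level breakdown is
    kept so level-1 counts (the Gini-importance correlate) stay available.
    """
    if max_level < 1:
        raise ValidationError("max_level must be >= 1")
    p = len(model.vocabulary)
    per_level = {lv: np.zeros(p, dtype=np.int64) for lv in range(1, max_level + 1)}
    for tree in model.trees:
        depths = tree.node_depths()
        for node, f in enumerate(tree.feature):
            if f >= 0 and depths[node] <= max_level:
                per_level[int(depths[node])][f] += 1
    counts = sum(per_level.values())
    # class association from vote shift: does presence raise the vote fraction?
    delta = np.zeros(p, dtype=float)
    for tree in model.trees:
        internal = tree.feature >= 0
        np.add.at(
            delta,
            tree.feature[internal],
            tree.pos_fraction[tree.right[internal]]
            - tree.pos_fraction[tree.left[internal]],
        )
    assoc = ["positive" if d > 0 else "negative" for d in delta]
    return ImportanceTable(
        terms=list(model.vocabulary.terms),
        importance=counts.astype(float),
        class_association=assoc,
        per_level=per_level,
    )


# --------------------------------------------------------------------------
# Persistence
# --------------------------------------------------------------------------


def _open_text(path: Path, mode: str):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode + "t", encoding="utf-8")
    return open(path, mode, encoding="utf-8")


def save_model(model: NBModel | ForestModel, path: str | Path) -> None:
    """Serialize a trained model to JSON (gzip when the path ends in .gz)."""
    path = Path(path)
    payload: dict = {
        "format_version": MODEL_FORMAT_VERSION,
        "model_type": model.model_type,
        "threshold": model.threshold,
        "n_pos": model.n_pos,
        "n_neg": model.n_neg,
        "vocabulary": model.vocabulary.to_dict(),
        "pipeline": None if model.pipeline is None else model.pipeline.to_dict(),
    }
    if isinstance(model, NBModel):
        payload.update(
            {
                "weights": model.weights.tolist(),
                "prior_positive": model.prior_positive,
                "intercept": model.intercept,
                "variant": model.variant,
            }
        )
    else:
        payload.update(
            {
                "seed": model.seed,
                "trees": [t.to_dict() for t in model.trees],
                "oob_scores": None
                if model.oob_scores is None
                else [None if math.isnan(v) else v for v in model.oob_scores],
                "gini_importance": None
                if model.gini_importance is None
                else model.gini_importance.tolist(),
            }
        )
    with _open_text(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path: str | Path) -> NBModel | ForestModel:
    path = Path(path)
    try:
        with _open_text(path, "r") as fh:
            payload = json.load(fh)
    except (json.JSONDecodeError, OSError, UnicodeDecodeError) as exc:
        raise ModelFormatError(f"{path}: cannot read model file: {exc}") from exc
    version = payload.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise ModelFormatError(
            f"{path}: unsupported model format version {version!r} "
            f"(expected {MODEL_FORMAT_VERSION})"
        )
    vocab = Vocabulary.from_dict(payload["vocabulary"])
    pipe = payload.get("pipeline")
    pipeline = None if pipe is None else PipelineConfig.from_dict(pipe)
    if payload["model_type"] == "nb":
        return NBModel(
            vocabulary=vocab,
            weights=np.asarray(payload["weights"], dtype=float),
            prior_positive=payload["prior_positive"],
            threshold=payload["threshold"],
            n_pos=payload["n_pos"],
            n_neg=payload["n_neg"],
            intercept=payload["intercept"],
            variant=payload["variant"],
            pipeline=pipeline,
        )
    if payload["model_type"] == "rf":
        oob = payload.get("oob_scores")
        return ForestModel(
            vocabulary=vocab,
            trees=[_Tree.from_dict(d) for d in payload["trees"]],
            threshold=payload["threshold"],
            n_pos=payload["n_pos"],
            n_neg=payload["n_neg"],
            seed=payload["seed"],
            oob_scores=None
            if oob is None
            else np.asarray([math.nan if v is None else v for v in oob], dtype=float),
            gini_importance=None
            if payload.get("gini_importance") is None
            else np.asarray(payload["gini_importance"], dtype=float),
            pipeline=pipeline,
        )
    raise ModelFormatError(f"{path}: unknown model_type {payload['model_type']!r}")
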