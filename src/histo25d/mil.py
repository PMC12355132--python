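"""Attention-based multiple-instance grading and agreement statistics.

A core is a bag of 2.5D-patch feature vectors with one weak label (the
ISUP grade group of the whole core).  Gated attention pooling learns a
relevance score per instance, normalizes the scores with a softmax, and
classifies the attention-weighted mean feature — the prediction is
invariant to instance order, and the attention weights localize the
evidence.  Grade groups binarize into clinically significant (GG >= 2)
versus not.  Model comparison and reader agreement use McNemar's test
on paired correctness and quadratic-weighted Cohen's kappa.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
import sklearn.metrics

__all__ = ["GRADE_GROUPS", "FeatureBag", "BagPrediction", "ABMIL", "abmil_pool",
           "binarize_cs", "evaluate_multiclass", "mcnemar_chi2",
           "quadratic_weighted_kappa", "make_signal_bags"]

#: ordinal grade-group classes, benign through grade group 4/5
GRADE_GROUPS = ("BN", "GG1", "GG2", "GG3", "GG4/5")


@dataclass
class FeatureBag:
    """One core's bag of patch features with its weak label."""

    instances: np.ndarray          # (K, D)
    core_id: str = ""
    label: int | str | None = None

    def __post_init__(self) -> None:
        self.instances = np.atleast_2d(np.asarray(self.instances, dtype=float))
        if len(self.instances) < 1:
            raise ValueError("a bag needs at least one instance")
        if not np.isfinite(self.instances).all():
            raise ValueError("bag features must be finite")

    def __len__(self) -> int:
        return len(self.instances)


@dataclass
class BagPrediction:
    """Class probabilities plus the per-instance attention map."""

    class_probs: np.ndarray
    attention_weights: np.ndarray
    predicted_class: int

    def __post_init__(self) -> None:
        if abs(self.class_probs.sum() - 1) > 1e-6:
            raise ValueError("class_probs must sum to 1")
        if abs(self.attention_weights.sum() - 1) > 1e-6:
            raise ValueError("attention_weights must sum to 1")


def _softmax(x, axis=-1):
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


class ABMIL:
    """Gated-attention MIL pooling with a linear bag classifier.

    Attention scores are ``w^T (tanh(V h) * sigmoid(U h))`` — the tanh
    branch captures signed evidence, the sigmoid branch gates its
    magnitude — softmax-normalized over the bag.
    """

    def __init__(self, n_features: int, n_classes: int = 5,
                 hidden_dim: int = 128, seed: int = 0):
        rng = np.random.default_rng(seed)
        s = np.sqrt(2.0 / (n_features + hidden_dim))
        self.params = {
            "V": rng.normal(0, s, size=(hidden_dim, n_features)),
            "U": rng.normal(0, s, size=(hidden_dim, n_features)),
            "w": rng.normal(0, np.sqrt(1.0 / hidden_dim), size=hidden_dim),
            "W": rng.normal(0, np.sqrt(2.0 / (n_features + n_classes)),
                            size=(n_classes, n_features)),
            "b": np.zeros(n_classes),
        }
        self.n_classes = n_classes

    # -- forward -----------------------------------------------------------
    def _forward(self, h: np.ndarray):
        p = self.params
        t = np.tanh(h @ p["V"].T)                   # (K, H)
        g = 1.0 / (1.0 + np.exp(-(h @ p["U"].T)))   # (K, H)
        scores = (t * g) @ p["w"]                   # (K,)
        a = _softmax(scores)
        z = a @ h                                   # (D,)
        logits = p["W"] @ z + p["b"]
        return t, g, scores, a, z, logits

    def predict(self, bag: FeatureBag) -> BagPrediction:
        if len(bag) == 0:
            raise ValueError("empty bag")
        _, _, _, a, _, logits = self._forward(bag.instances)
        probs = _softmax(logits)
        return BagPrediction(class_probs=probs, attention_weights=a,
                             predicted_class=int(np.argmax(probs)))

    # -- training ----------------------------------------------------------
    def _grads(self, h: np.ndarray, y: int):
        """Cross-entropy gradient for one bag (hand-derived chain rule)."""
        p = self.params
        t, g, scores, a, z, logits = self._forward(h)
        probs = _softmax(logits)
        dlogits = probs.copy()
        dlogits[y] -= 1.0
        grads = {"W": np.outer(dlogits, z), "b": dlogits}
        dz = p["W"].T @ dlogits                      # (D,)
        da = h @ dz                                  # (K,)
        dscores = a * (da - np.dot(da, a))
        dtg = np.outer(dscores, p["w"])              # (K, H)
        grads["w"] = (t * g).T @ dscores
        dt = dtg * g
        dg = dtg * t
        dpre_v = dt * (1 - t**2)
        dpre_u = dg * g * (1 - g)
        grads["V"] = dpre_v.T @ h
        grads["U"] = dpre_u.T @ h
        dh = a[:, None] * dz[None, :] + dpre_v @ p["V"] + dpre_u @ p["U"]
        loss = -np.log(probs[y] + 1e-300)
        return loss, grads, dh

    def fit(self, bags: list[FeatureBag], labels: list[int],
            n_epochs: int = 60, lr: float = 1e-3,
            val_fraction: float = 0.125, patience: int = 10,
            seed: int = 0) -> pd.DataFrame:
        """Adam training with early stopping on a held-out split.

        Returns the per-epoch loss table (train and validation).
        """
        rng = np.random.default_rng(seed)
        idx = rng.permutation(len(bags))
        n_val = max(1, int(val_fraction * len(bags)))
        val_idx, train_idx = idx[:n_val], idx[n_val:]
        m = {k: np.zeros_like(v) for k, v in self.params.items()}
        v2 = {k: np.zeros_like(v) for k, v in self.params.items()}
        t_step = 0
        best_val, best_params, since_best = np.inf, None, 0
        history = []
        for epoch in range(n_epochs):
            order = rng.permutation(train_idx)
            train_loss = 0.0
            for i in order:
                loss, grads, _ = self._grads(bags[i].instances, labels[i])
                train_loss += loss
                t_step += 1
                for k in self.params:
                    m[k] = 0.9 * m[k] + 0.1 * grads[k]
                    v2[k] = 0.999 * v2[k] + 0.001 * grads[k] ** 2
                    mhat = m[k] / (1 - 0.9 ** t_step)
                    vhat = v2[k] / (1 - 0.999 ** t_step)
                    self.params[k] -= lr * mhat / (np.sqrt(vhat) + 1e-8)
            val_loss = float(np.mean([
                -np.log(self.predict(bags[i]).class_probs[labels[i]] + 1e-300)
                for i in val_idx]))
            history.append({"epoch": epoch, "train_loss": train_loss / len(order),
                            "val_loss": val_loss})
            if val_loss < best_val - 1e-6:
                best_val, since_best = val_loss, 0
                best_params = {k: v.copy() for k, v in self.params.items()}
            else:
                since_best += 1
                if since_best >= patience:
                    break
        if best_params is not None:
            self.params = best_params
        return pd.DataFrame(history)


def abmil_pool(bag: FeatureBag, params: dict, n_classes: int | None = None
               ) -> BagPrediction:
    """Functional gated-attention pooling with explicit parameters."""
    model = ABMIL.__new__(ABMIL)
    model.params = params
    model.n_classes = n_classes or params["W"].shape[0]
    return model.predict(bag)


def binarize_cs(gg_label: int | str) -> bool:
    """Clinically significant (GG >= 2) vs not (benign or GG1)."""
    if isinstance(gg_label, str):
        if gg_label not in GRADE_GROUPS:
            raise ValueError(f"unknown grade group {gg_label!r}")
        return GRADE_GROUPS.index(gg_label) >= 2
    if gg_label not in range(len(GRADE_GROUPS)):
        raise ValueError(f"grade-group index out of range: {gg_label}")
    return int(gg_label) >= 2


def evaluate_multiclass(pred_probs: np.ndarray, labels: np.ndarray
                        ) -> tuple[pd.Series, pd.DataFrame]:
    """Weighted one-vs-rest AUC, precision/recall/F1 and confusion matrix.

    ``pred_probs`` is (n, C); the confusion matrix is row-normalized
    (rows = true class).  Raises when only one class is present (AUC is
    undefined there).
    """
    labels = np.asarray(labels)
    pred_probs = np.atleast_2d(np.asarray(pred_probs, dtype=float))
    if len(labels) != len(pred_probs):
        raise ValueError("length mismatch")
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("AUC undefined with a single observed class")
    preds = np.argmax(pred_probs, axis=1)
    auc = sklearn.metrics.roc_auc_score(
        labels, pred_probs[:, classes] if pred_probs.shape[1] != len(classes)
        else pred_probs,
        multi_class="ovr", average="weighted", labels=classes)
    prec, rec, f1, _ = sklearn.metrics.precision_recall_fscore_support(
        labels, preds, average="weighted", zero_division=0)
    acc = sklearn.metrics.accuracy_score(labels, preds)
    cm = sklearn.metrics.confusion_matrix(labels, preds, labels=classes).astype(float)
    row_sums = cm.sum(axis=1, keepdims=True)
    cm_norm = np.divide(cm, row_sums, out=np.zeros_like(cm), where=row_sums > 0)
    metrics = pd.Series({"auc": auc, "precision": prec, "recall": rec,
                         "f1": f1, "accuracy": acc})
    cm_df = pd.DataFrame(cm_norm, index=classes, columns=classes)
    return metrics, cm_df


def mcnemar_chi2(correct_a, correct_b, continuity: bool = False
                 ) -> tuple[float, float]:
    """McNemar's test on paired correctness vectors.

    ``chi2 = (b - c)^2 / (b + c)`` over the discordant counts (b: A
    right / B wrong, c: A wrong / B right), referred to chi-square with
    one degree of freedom.  Optional continuity correction subtracts 1
    from |b - c|.
    """
    a = np.asarray(correct_a, dtype=bool)
    bb = np.asarray(correct_b, dtype=bool)
    if a.shape != bb.shape:
        raise ValueError("paired vectors must have equal length")
    b = int(np.sum(a & ~bb))
    c = int(np.sum(~a & bb))
    if b + c == 0:
        raise ValueError("no discordant pairs; McNemar test undefined")
    diff = abs(b - c) - (1 if continuity else 0)
    diff = max(diff, 0)
    chi2 = diff**2 / (b + c)
    p = float(scipy.stats.chi2.sf(chi2, df=1))
    return float(chi2), p


def quadratic_weighted_kappa(ratings_a, ratings_b, categories=None) -> float:
    """Cohen's kappa with quadratic disagreement weights.

    ``kappa = 1 - sum(w * O) / sum(w * E)`` with ``w_ij = (i - j)^2 /
    (C - 1)^2``; 1 for identical ratings, ~0 for independent ones.
    """
    a = np.asarray(ratings_a)
    b = np.asarray(ratings_b)
    if len(a) == 0 or len(a) != len(b):
        raise ValueError("ratings must be equal-length and non-empty")
    labels = None if categories is None else list(categories)
    return float(sklearn.metrics.cohen_kappa_score(a, b, weights="quadratic",
                                                   labels=labels))


def make_signal_bags(n_bags: int, n_features: int = 16,
                     bag_size: tuple[int, int] = (8, 24),
                     signal_shift: float = 3.0, n_signal: int = 3,
                     seed: int = 0) -> tuple[list[FeatureBag], np.ndarray, list[np.ndarray]]:
    """Synthetic MIL task: a bag is positive iff it contains signal instances.

    Background instances are standard normal; signal instances are
    shifted by ``signal_shift`` along the first feature axis.  Returns
    (bags, labels, per-bag signal masks).
    """
    rng = np.random.default_rng(seed)
    bags, labels, masks = [], [], []
    for i in range(n_bags):
        k = int(rng.integers(*bag_size))
        h = rng.normal(size=(k, n_features))
        y = int(rng.random() < 0.5)
        mask = np.zeros(k, dtype=bool)
        if y:
            sig = rng.choice(k, size=min(n_signal, k), replace=False)
            h[sig, 0] += signal_shift
            mask[sig] = True
        bags.append(FeatureBag(instances=h, core_id=f"bag{i}", label=y))
        labels.append(y)
        masks.append(mask)
    return bags, np.asarray(labels), masks
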