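"""The two classifiers: Gaussian-kernel naive Bayes and GentleBoost.

Both are implemented from first principles. The kernel naive Bayes places
an independent Gaussian kernel density estimate over the whole real line
(unbounded support) on every (class, feature) pair; GentleBoost fits
weighted least-squares regression trees to the ±1 labels and accumulates
them into an additive score. Ties (equal posteriors, zero boosting score)
resolve to the negative class — the conservative choice for a screening
tool.
"""

from __future__ import annotations

import heapq
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np

from .data import NEGATIVE, POSITIVE

MODEL_FORMAT = "amyhex-model"
MODEL_VERSION = 1

#: floor applied to per-feature densities before taking logs
DENSITY_FLOOR = 1e-300
#: per-(class, feature) bandwidths are floored at this fraction of the
#: pooled per-feature standard deviation
BANDWIDTH_FLOOR_FRACTION = 0.05
#: fitted leaf values are clamped to this range to keep exp() finite
LEAF_CLAMP = 4.0


class ModelIOError(RuntimeError):
    """Model file cannot be read (corrupt, truncated, wrong version)."""


@dataclass(frozen=True)
class TrainConfig:
    """Training configuration; named presets exp1-exp8 ship with the package."""

    algorithm: str = "kernel_nb"  # "kernel_nb" | "gentleboost"
    max_split: int = 20
    num_learners: int = 30
    learning_rate: float = 0.1
    bandwidth_rule: str = "silverman"
    cv_k: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.algorithm not in ("kernel_nb", "gentleboost"):
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if self.algorithm == "gentleboost":
            if self.num_learners < 1 or self.max_split < 1:
                raise ValueError("gentleboost needs num_learners >= 1 and max_split >= 1")
            if not (0 < self.learning_rate <= 1):
                raise ValueError("learning_rate must be in (0, 1]")


#: Experiment presets: classifier configuration x cross-validation fold count.
#: exp3's learner count was published as "Auto"; it defaults to 30 here.
PRESETS: dict[str, TrainConfig] = {
    "exp1": TrainConfig("gentleboost", max_split=26, num_learners=67, learning_rate=0.5915, cv_k=5),
    "exp2": TrainConfig("kernel_nb", cv_k=5),
    "exp3": TrainConfig("gentleboost", max_split=22, num_learners=30, learning_rate=0.0011, cv_k=10),
    "exp4": TrainConfig("gentleboost", max_split=40, num_learners=80, learning_rate=0.1, cv_k=10),
    "exp5": TrainConfig("kernel_nb", cv_k=10),
    "exp6": TrainConfig("gentleboost", max_split=30, num_learners=30, learning_rate=0.1, cv_k=15),
    "exp7": TrainConfig("gentleboost", max_split=20, num_learners=60, learning_rate=0.1, cv_k=15),
    "exp8": TrainConfig("kernel_nb", cv_k=15),
}


def _as_matrix(X) -> np.ndarray:
    from .descriptors import FeatureMatrix

    if isinstance(X, FeatureMatrix):
        return X.values
    return np.asarray(X, dtype=float)


def _labels_of(X, y=None) -> np.ndarray:
    from .descriptors import FeatureMatrix

    if y is None and isinstance(X, FeatureMatrix):
        y = X.labels
    if y is None:
        raise ValueError("labels required: pass y or a labelled FeatureMatrix")
    y = np.asarray(y, dtype=int)
    if not set(np.unique(y)) <= {NEGATIVE, POSITIVE}:
        raise ValueError("labels must be binary 0/1")
    return y


# ---------------------------------------------------------------------------
# Weighted least-squares regression tree (GentleBoost base learner)


class RegressionTree:
    """Axis-aligned regression tree grown best-first by weighted SSE reduction.

    Stored as flat arrays; ``feature[i] < 0`` marks node ``i`` as a leaf
    with prediction ``value[i]``. Candidate thresholds are midpoints
    between consecutive distinct feature values; leaf values are weighted
    target means. Ties between equally good splits resolve to the lowest
    feature index, then the smallest threshold.
    """

    def __init__(self):
        self.feature: list[int] = [-1]
        self.threshold: list[float] = [0.0]
        self.left: list[int] = [-1]
        self.right: list[int] = [-1]
        self.value: list[float] = [0.0]

    @property
    def n_splits(self) -> int:
        return sum(1 for f in self.feature if f >= 0)

    def _new_leaf(self, value: float) -> int:
        self.feature.append(-1)
        self.threshold.append(0.0)
        self.left.append(-1)
        self.right.append(-1)
        self.value.append(value)
        return len(self.feature) - 1

    def predict(self, X) -> np.ndarray:
        X = _as_matrix(X)
        out = np.empty(len(X))
        # partition sample indices down the tree iteratively
        stack = [(0, np.arange(len(X)))]
        while stack:
            node, idx = stack.pop()
            if len(idx) == 0:
                continue
            f = self.feature[node]
            if f < 0:
                out[idx] = self.value[node]
            else:
                mask = X[idx, f] <= self.threshold[node]
                stack.append((self.left[node], idx[mask]))
                stack.append((self.right[node], idx[~mask]))
        return out

    def to_dict(self) -> dict:
        return {
            "feature": self.feature,
            "threshold": self.threshold,
            "left": self.left,
            "right": self.right,
            "value": self.value,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RegressionTree":
        t = cls()
        t.feature = [int(v) for v in d["feature"]]
        t.threshold = [float(v) for v in d["threshold"]]
        t.left = [int(v) for v in d["left"]]
        t.right = [int(v) for v in d["right"]]
        t.value = [float(v) for v in d["value"]]
        return t


def _best_split(X: np.ndarray, y: np.ndarray, w: np.ndarray):
    """Exhaustive weighted-SSE split search over all features at once.

    Returns ``(gain, feature, threshold)`` or ``None`` when no valid split
    exists. ``gain`` is the decrease in weighted SSE.
    """
    n = len(y)
    if n < 2:
        return None
    order = np.argsort(X, axis=0, kind="stable")
    Xs = np.take_along_axis(X, order, axis=0)
    ws = w[order]
    wys = (w * y)[order]
    cw = np.cumsum(ws, axis=0)
    cwy = np.cumsum(wys, axis=0)
    W, S = cw[-1], cwy[-1]
    WL, SL = cw[:-1], cwy[:-1]
    WR, SR = W - WL, S - SL
    valid = (np.diff(Xs, axis=0) > 0) & (WL > 0) & (WR > 0)
    if not valid.any():
        return None
    with np.errstate(divide="ignore", invalid="ignore"):
        score = SL**2 / WL + SR**2 / WR
    score = np.where(valid, score, -np.inf)
    # feature-major ravel: ties resolve to lowest feature, then lowest threshold
    flat = np.argmax(score.T)
    j, i = divmod(flat, score.shape[0])
    base = float(S[j] ** 2 / W[j]) if W[j] > 0 else 0.0
    gain = float(score[i, j]) - base
    if not np.isfinite(gain) or gain <= 1e-12:
        return None
    threshold = 0.5 * (Xs[i, j] + Xs[i + 1, j])
    return gain, int(j), float(threshold)


def fit_stump_tree(X, targets, weights, max_split: int) -> RegressionTree:
    """Greedy weighted least-squares regression tree with <= max_split splits."""
    X = _as_matrix(X)
    y = np.asarray(targets, dtype=float)
    w = np.asarray(weights, dtype=float)
    if (w < 0).any():
        raise ValueError("weights must be non-negative")
    if w.sum() <= 0:
        raise ValueError("total weight must be positive")

    def wmean(idx):
        wi = w[idx]
        return float((wi * y[idx]).sum() / wi.sum()) if wi.sum() > 0 else 0.0

    tree = RegressionTree()
    all_idx = np.arange(len(y))
    tree.value[0] = wmean(all_idx)
    heap: list = []
    counter = 0

    def push_candidate(node: int, idx: np.ndarray):
        nonlocal counter
        found = _best_split(X[idx], y[idx], w[idx])
        if found is not None:
            gain, j, thr = found
            heapq.heappush(heap, (-gain, counter, node, j, thr, idx))
            counter += 1

    push_candidate(0, all_idx)
    while heap and tree.n_splits < max_split:
        _, _, node, j, thr, idx = heapq.heappop(heap)
        mask = X[idx, j] <= thr
        left_idx, right_idx = idx[mask], idx[~mask]
        tree.feature[node] = j
        tree.threshold[node] = thr
        tree.left[node] = self_l = tree._new_leaf(wmean(left_idx))
        tree.right[node] = self_r = tree._new_leaf(wmean(right_idx))
        push_candidate(self_l, left_idx)
        push_candidate(self_r, right_idx)
    return tree


# ---------------------------------------------------------------------------
# Gaussian-kernel naive Bayes


class KernelNBClassifier:
    """Naive Bayes with per-(class, feature) Gaussian kernel densities.

    The density of feature j under class c is the average of Gaussian
    kernels centred at the training values, with a normal-reference
    (Silverman) bandwidth per class and feature, supported on the whole
    real line. Prediction accumulates per-feature log densities plus the
    log prior; posteriors follow by normalization.
    """

    def __init__(self, bandwidth_rule: str = "silverman"):
        if bandwidth_rule != "silverman":
            raise ValueError(f"unknown bandwidth rule {bandwidth_rule!r}")
        self.bandwidth_rule = bandwidth_rule
        self.classes_ = (NEGATIVE, POSITIVE)
        self.priors_: Optional[np.ndarray] = None
        self.train_values_: Optional[list[np.ndarray]] = None
        self.bandwidths_: Optional[list[np.ndarray]] = None

    def fit(self, X, y=None) -> "KernelNBClassifier":
        y = _labels_of(X, y)
        X = _as_matrix(X)
        if np.isnan(X).any():
            raise ValueError("missing values in feature matrix")
        # Kernels are never narrower than 5% of a feature's pooled spread:
        # spike kernels on near-constant class-feature pairs otherwise veto
        # the whole posterior through their tails.
        floor = BANDWIDTH_FLOOR_FRACTION * X.std(axis=0, ddof=1) + 1e-12
        self.priors_ = np.empty(2)
        self.train_values_, self.bandwidths_ = [], []
        for k, cls in enumerate(self.classes_):
            Xc = X[y == cls]
            if len(Xc) == 0:
                raise ValueError(f"class {cls} has no training samples")
            self.priors_[k] = len(Xc) / len(X)
            sigma = Xc.std(axis=0, ddof=1) if len(Xc) > 1 else np.zeros(X.shape[1])
            h = sigma * (4.0 / (3.0 * len(Xc))) ** 0.2
            self.train_values_.append(Xc)
            self.bandwidths_.append(np.maximum(h, floor))
        return self

    @property
    def n_features_(self) -> int:
        self._check_fitted()
        return self.train_values_[0].shape[1]

    def _check_fitted(self):
        if self.train_values_ is None:
            raise RuntimeError("model is not fitted")

    _MAX_COLLAPSE = 32  # features with <= this many distinct values use the collapsed path

    def _collapsed(self, k: int):
        """Cache per-class kernel centres.

        Most descriptor features take few distinct values (positional
        encodings <= 20, compositions <= 7), so the KDE mixture collapses
        exactly to its unique values with multiplicity weights. Features
        with many distinct values keep the direct per-sample form.
        """
        if not hasattr(self, "_collapse_cache"):
            self._collapse_cache = {}
        if k in self._collapse_cache:
            return self._collapse_cache[k]
        T = self.train_values_[k]
        m, d = T.shape
        S = np.sort(T, axis=0)
        n_unique = (S[1:] != S[:-1]).sum(axis=0) + 1 if m > 1 else np.ones(d, dtype=int)
        disc = np.flatnonzero(n_unique <= self._MAX_COLLAPSE)
        cont = np.flatnonzero(n_unique > self._MAX_COLLAPSE)
        u_max = int(n_unique[disc].max()) if len(disc) else 0
        centres = np.zeros((u_max, len(disc)), dtype=np.float32)
        weights = np.zeros((u_max, len(disc)), dtype=np.float32)
        for out_j, j in enumerate(disc):
            vals, counts = np.unique(T[:, j], return_counts=True)
            centres[: len(vals), out_j] = vals
            weights[: len(vals), out_j] = counts / m
        cache = (disc, cont, centres, weights)
        self._collapse_cache[k] = cache
        return cache

    def _log_likelihood(self, X: np.ndarray) -> np.ndarray:
        """Per-class total log density, shape (n_samples, 2)."""
        n, d = X.shape
        out = np.zeros((n, 2))
        log_floor = math.log(DENSITY_FLOOR)
        log_norm = 0.5 * math.log(2 * math.pi)
        X32 = X.astype(np.float32)
        for k in range(2):
            T = self.train_values_[k]  # (m, d)
            h = self.bandwidths_[k]
            m = len(T)
            disc, cont, centres, weights = self._collapsed(k)
            h32 = h.astype(np.float32)

            def accumulate(cols, V, W, n_centres):
                # V: (u, len(cols)) kernel centres, W matching weights.
                # float32 kernel math: per-feature log densities are O(1e2),
                # well within float32 once floored; sums accumulate in float64.
                chunk = max(1, int(3e7 / max(1, n * n_centres)))
                for start in range(0, len(cols), chunk):
                    cs = cols[start : start + chunk]
                    z = (X32[:, None, cs] - V[None, :, start : start + chunk]) / h32[cs]
                    logk = -0.5 * z * z  # (n, u, c)
                    mx = logk.max(axis=1)
                    s = (np.exp(logk - mx[:, None, :]) * W[None, :, start : start + chunk]).sum(axis=1)
                    with np.errstate(divide="ignore"):
                        lse = mx + np.log(s)
                    logf = lse.astype(float) - np.log(h[cs]) - log_norm
                    out[:, k] += np.maximum(logf, log_floor).sum(axis=1)

            if len(disc):
                accumulate(disc, centres, weights, centres.shape[0])
            if len(cont):
                V = T[:, cont].astype(np.float32)
                W = np.full((m, len(cont)), 1.0 / m, dtype=np.float32)
                accumulate(cont, V, W, m)
        return out

    def predict_proba(self, X) -> np.ndarray:
        """Posterior per class, columns ordered (negative, positive)."""
        self._check_fitted()
        X = _as_matrix(X)
        if X.shape[1] != self.n_features_:
            raise ValueError(
                f"feature count {X.shape[1]} != model's {self.n_features_}"
            )
        logp = self._log_likelihood(X) + np.log(self.priors_)
        mx = logp.max(axis=1, keepdims=True)
        p = np.exp(logp - mx)
        return p / p.sum(axis=1, keepdims=True)

    def decision_scores(self, X) -> np.ndarray:
        """Positive-class posterior (the ROC score)."""
        return self.predict_proba(X)[:, 1]

    def predict(self, X) -> np.ndarray:
        proba = self.predict_proba(X)
        # ties resolve to the negative class
        return np.where(proba[:, 1] > proba[:, 0], POSITIVE, NEGATIVE)

    def to_dict(self) -> dict:
        self._check_fitted()
        return {
            "format": MODEL_FORMAT,
            "version": MODEL_VERSION,
            "algorithm": "kernel_nb",
            "bandwidth_rule": self.bandwidth_rule,
            "priors": self.priors_.tolist(),
            "train_values": [t.tolist() for t in self.train_values_],
            "bandwidths": [h.tolist() for h in self.bandwidths_],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "KernelNBClassifier":
        model = cls(bandwidth_rule=d["bandwidth_rule"])
        model.priors_ = np.asarray(d["priors"], dtype=float)
        model.train_values_ = [np.asarray(t, dtype=float) for t in d["train_values"]]
        model.bandwidths_ = [np.asarray(h, dtype=float) for h in d["bandwidths"]]
        return model


# ---------------------------------------------------------------------------
# GentleBoost


class GentleBoostClassifier:
    """GentleBoost ensemble of shallow weighted least-squares trees.

    Each round fits a regression tree to the ±1 labels under the current
    weights, adds ``learning_rate * tree`` to the additive score F, and
    reweights ``w <- w * exp(-y * learning_rate * f(x))`` (renormalized).
    Fitted leaf values are clamped to ±4 so the weight update stays finite.
    """

    def __init__(self, max_split: int = 20, num_learners: int = 30,
                 learning_rate: float = 0.1):
        if num_learners < 1:
            raise ValueError("num_learners must be >= 1")
        if not (0 < learning_rate <= 1):
            raise ValueError("learning_rate must be in (0, 1]")
        self.max_split = max_split
        self.num_learners = num_learners
        self.learning_rate = learning_rate
        self.learners_: list[RegressionTree] = []
        self.n_features_: Optional[int] = None
        self.loss_trace_: list[float] = []

    def fit(self, X, y=None) -> "GentleBoostClassifier":
        y01 = _labels_of(X, y)
        if len(np.unique(y01)) != 2:
            raise ValueError("gentleboost requires both classes in training data")
        X = _as_matrix(X)
        ypm = np.where(y01 == POSITIVE, 1.0, -1.0)
        n = len(ypm)
        w = np.full(n, 1.0 / n)
        F = np.zeros(n)
        self.learners_ = []
        self.loss_trace_ = []
        self.n_features_ = X.shape[1]
        for _ in range(self.num_learners):
            tree = fit_stump_tree(X, ypm, w, self.max_split)
            tree.value = [
                float(np.clip(v, -LEAF_CLAMP, LEAF_CLAMP)) for v in tree.value
            ]
            f = tree.predict(X)
            F += self.learning_rate * f
            w = w * np.exp(-ypm * self.learning_rate * f)
            total = w.sum()
            if total <= 0 or not np.isfinite(total):
                break
            w /= total
            self.learners_.append(tree)
            self.loss_trace_.append(float(np.exp(-ypm * F).sum()))
        return self

    def decision_function(self, X) -> np.ndarray:
        """Additive score F(x) = sum learning_rate * f_t(x)."""
        X = _as_matrix(X)
        if self.n_features_ is not None and X.shape[1] != self.n_features_:
            raise ValueError(
                f"feature count {X.shape[1]} != model's {self.n_features_}"
            )
        F = np.zeros(len(X))
        for tree in self.learners_:
            F += self.learning_rate * tree.predict(X)
        return F

    decision_scores = decision_function

    def predict(self, X) -> np.ndarray:
        # F(x) == 0 (e.g. no learners) resolves to the negative class
        return np.where(self.decision_function(X) > 0, POSITIVE, NEGATIVE)

    def to_dict(self) -> dict:
        return {
            "format": MODEL_FORMAT,
            "version": MODEL_VERSION,
            "algorithm": "gentleboost",
            "max_split": self.max_split,
            "num_learners": self.num_learners,
            "learning_rate": self.learning_rate,
            "n_features": self.n_features_,
            "learners": [t.to_dict() for t in self.learners_],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GentleBoostClassifier":
        model = cls(
            max_split=d["max_split"],
            num_learners=d["num_learners"],
            learning_rate=d["learning_rate"],
        )
        model.n_features_ = d["n_features"]
        model.learners_ = [RegressionTree.from_dict(t) for t in d["learners"]]
        return model


# ---------------------------------------------------------------------------
# Dispatch and serialization


def fit_model(X, config: TrainConfig, y=None):
    """Train the classifier named by the configuration."""
    if config.algorithm == "kernel_nb":
        return KernelNBClassifier(bandwidth_rule=config.bandwidth_rule).fit(X, y)
    return GentleBoostClassifier(
        max_split=config.max_split,
        num_learners=config.num_learners,
        learning_rate=config.learning_rate,
    ).fit(X, y)


def save_model(model, path) -> None:
    """Serialize a fitted model to a portable JSON file."""
    Path(path).write_text(json.dumps(model.to_dict()))


def load_model(path):
    """Load a model saved by :func:`save_model`.

    Raises :class:`ModelIOError` on corrupt files or version mismatch.
    """
    try:
        d = json.loads(Path(path).read_text())
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise ModelIOError(f"{path}: not a valid model file ({exc})") from exc
    if not isinstance(d, dict) or d.get("format") != MODEL_FORMAT:
        raise ModelIOError(f"{path}: not an {MODEL_FORMAT} file")
    if d.get("version") != MODEL_VERSION:
        raise ModelIOError(
            f"{path}: model version {d.get('version')} != supported {MODEL_VERSION}"
        )
    if d["algorithm"] == "kernel_nb":
        return KernelNBClassifier.from_dict(d)
    if d["algorithm"] == "gentleboost":
        return GentleBoostClassifier.from_dict(d)
    raise ModelIOError(f"{path}: unknown algorithm {d['algorithm']!r}")
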