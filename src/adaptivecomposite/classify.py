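"""Group classifiers: a small feed-forward network plus KNN/SVM baselines.

The network maps the normalized 29-descriptor vector to group membership
probabilities through two ReLU hidden layers of 8 neurons and a softmax
output::

    prob = softmax(relu(relu(x @ W1) @ W2 + b2) @ W3 + b3)

with the numerically safe max-subtracted softmax.  A first-hidden-layer bias
``b1`` is representable but defaults to zero and is frozen during training,
so serialized models always match the five-array (W1, W2, b2, W3, b3) form.

Training is deliberately simple and fully deterministic under a seed:
fan-in-scaled uniform initialization and full-batch gradient descent on the
cross-entropy, with optional early stopping on validation mistakes.  The
KNN and SVM baselines wrap scikit-learn estimators and are selected on a
validation split by their mistake count, the same metric used to compare
classifier families.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol

import numpy as np
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

__all__ = [
    "ANNModel",
    "TrainConfig",
    "ann_forward",
    "train_ann",
    "train_knn",
    "train_svm",
    "select_knn",
    "select_svm",
    "count_mistakes",
    "probability_r2",
]

N_HIDDEN = 8


@dataclass(frozen=True)
class ANNModel:
    """Weights of the 29 -> 8 -> 8 -> k classifier."""

    W1: np.ndarray  # (n_features, 8)
    b1: np.ndarray  # (8,) zero unless explicitly set
    W2: np.ndarray  # (8, 8)
    b2: np.ndarray  # (8,)
    W3: np.ndarray  # (8, k)
    b3: np.ndarray  # (k,)

    def __post_init__(self) -> None:
        for name in ("W1", "b1", "W2", "b2", "W3", "b3"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.W1.ndim != 2 or self.W2.shape != (self.W1.shape[1], self.W3.shape[0]):
            raise ValueError("inconsistent layer shapes")
        if self.b1.shape != (self.W1.shape[1],) or self.b2.shape != (self.W2.shape[1],):
            raise ValueError("inconsistent hidden bias shapes")
        if self.b3.shape != (self.W3.shape[1],):
            raise ValueError("inconsistent output bias shape")
        for name in ("W1", "b1", "W2", "b2", "W3", "b3"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"non-finite entries in {name}")

    @property
    def n_features(self) -> int:
        return self.W1.shape[0]

    @property
    def n_groups(self) -> int:
        return self.W3.shape[1]

    def to_dict(self) -> dict:
        """Five-array serialized form (b1 omitted; it is zero by contract)."""
        if np.any(self.b1 != 0.0):
            raise ValueError("cannot serialize a model with nonzero first-layer bias")
        return {name: getattr(self, name).tolist() for name in ("W1", "W2", "b2", "W3", "b3")}

    @classmethod
    def from_dict(cls, doc: dict) -> "ANNModel":
        W1 = np.asarray(doc["W1"], dtype=float)
        return cls(
            W1=W1,
            b1=np.asarray(doc.get("b1", np.zeros(W1.shape[1])), dtype=float),
            W2=np.asarray(doc["W2"], dtype=float),
            b2=np.asarray(doc["b2"], dtype=float),
            W3=np.asarray(doc["W3"], dtype=float),
            b3=np.asarray(doc["b3"], dtype=float),
        )


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def ann_forward(model: ANNModel, normalized: np.ndarray) -> np.ndarray:
    """Forward pass; accepts one normalized vector or a (n, p) batch.

    Returns probabilities in (0, 1] summing to 1 along the last axis.
    """
    x = np.asarray(normalized, dtype=float)
    if x.shape[-1] != model.n_features:
        raise ValueError(f"input width {x.shape[-1]} != model width {model.n_features}")
    h1 = np.maximum(x @ model.W1 + model.b1, 0.0)
    h2 = np.maximum(h1 @ model.W2 + model.b2, 0.0)
    return _softmax(h2 @ model.W3 + model.b3)


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters of the deterministic gradient-descent trainer."""

    seed: int = 0
    learning_rate: float = 0.15
    epochs: int = 8000
    batch_size: int | None = None  # None = full batch
    patience: int = 2000  # early-stopping patience on validation mistakes
    l2: float = 1e-5

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.epochs <= 0 or self.patience <= 0:
            raise ValueError("hyperparameters must be positive")
        if self.l2 < 0:
            raise ValueError("l2 must be non-negative")


def _init_model(n_features: int, n_groups: int, rng: np.random.Generator) -> ANNModel:
    def layer(fan_in, fan_out):
        lim = np.sqrt(1.0 / fan_in)
        return rng.uniform(-lim, lim, size=(fan_in, fan_out))

    return ANNModel(
        W1=layer(n_features, N_HIDDEN),
        b1=np.zeros(N_HIDDEN),
        W2=layer(N_HIDDEN, N_HIDDEN),
        b2=np.zeros(N_HIDDEN),
        W3=layer(N_HIDDEN, n_groups),
        b3=np.zeros(n_groups),
    )


def train_ann(
    X: np.ndarray,
    y: np.ndarray,
    n_groups: int | None = None,
    config: TrainConfig = TrainConfig(),
    validation: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[ANNModel, dict]:
    """Train the classifier on normalized features X and integer labels y.

    Returns the model and a history dict with per-epoch loss, the train R^2
    (coefficient of determination between one-hot labels and probabilities)
    and, when a validation split is given, the validation mistake trace used
    for early stopping.  Deterministic for a fixed config seed.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if n_groups is None:
        n_groups = int(y.max()) + 1
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    rng = np.random.default_rng(config.seed)
    model = _init_model(X.shape[1], n_groups, rng)
    Y = np.eye(n_groups)[y]
    n = X.shape[0]
    batch = n if config.batch_size is None else min(config.batch_size, n)

    best: tuple[int, ANNModel] | None = None
    since_best = 0
    losses = []
    W1, W2, b2, W3, b3 = model.W1, model.W2, model.b2, model.W3, model.b3
    for epoch in range(config.epochs):
        order = rng.permutation(n) if batch < n else np.arange(n)
        for start in range(0, n, batch):
            idx = order[start:start + batch]
            Xb, Yb = X[idx], Y[idx]
            h1 = np.maximum(Xb @ W1, 0.0)
            h2 = np.maximum(h1 @ W2 + b2, 0.0)
            P = _softmax(h2 @ W3 + b3)
            m = len(idx)
            d3 = (P - Yb) / m
            gW3 = h2.T @ d3 + config.l2 * W3
            gb3 = d3.sum(axis=0)
            d2 = (d3 @ W3.T) * (h2 > 0)
            gW2 = h1.T @ d2 + config.l2 * W2
            gb2 = d2.sum(axis=0)
            d1 = (d2 @ W2.T) * (h1 > 0)
            gW1 = Xb.T @ d1 + config.l2 * W1
            lr = config.learning_rate
            W1 = W1 - lr * gW1
            W2 = W2 - lr * gW2
            b2 = b2 - lr * gb2
            W3 = W3 - lr * gW3
            b3 = b3 - lr * gb3
        P_full = ann_forward(ANNModel(W1, model.b1, W2, b2, W3, b3), X)
        loss = -np.mean(np.log(P_full[np.arange(n), y] + 1e-300))
        losses.append(loss)
        if validation is not None:
            cur = ANNModel(W1, model.b1, W2, b2, W3, b3)
            mistakes = count_mistakes(ANNClassifier(cur), validation[0], validation[1])
            if best is None or mistakes <= best[0]:
                # keep the latest among equally good snapshots: logits keep
                # sharpening after the mistake count has plateaued
                if best is None or mistakes < best[0]:
                    since_best = 0
                best = (mistakes, cur)
            else:
                since_best += 1
                if since_best >= config.patience:
                    break

    final = best[1] if best is not None else ANNModel(W1, model.b1, W2, b2, W3, b3)
    history = {
        "loss": np.array(losses),
        "r2_train": probability_r2(y, ann_forward(final, X), n_groups),
    }
    if validation is not None:
        Xv, yv = validation
        history["val_mistakes"] = count_mistakes(ANNClassifier(final), Xv, yv)
        history["r2_val"] = probability_r2(np.asarray(yv, int), ann_forward(final, Xv), n_groups)
    return final, history


def probability_r2(y: np.ndarray, probs: np.ndarray, n_groups: int) -> float:
    """Coefficient of determination between one-hot labels and probabilities.

    Computed over the flattened (n, k) arrays; a goodness-of-fit summary for
    the classifier's probability outputs.
    """
    Y = np.eye(n_groups)[np.asarray(y, int)].ravel()
    P = np.asarray(probs, dtype=float).ravel()
    ss_res = np.sum((Y - P) ** 2)
    ss_tot = np.sum((Y - Y.mean()) ** 2)
    return 1.0 - ss_res / ss_tot


# ---------------------------------------------------------------------------
# baselines and the mistake-count metric

class GroupClassifier(Protocol):
    def predict_proba(self, X: np.ndarray) -> np.ndarray: ...  # pragma: no cover


@dataclass(frozen=True)
class ANNClassifier:
    """Adapter giving the network the common predict_proba surface."""

    model: ANNModel

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return np.atleast_2d(ann_forward(self.model, X))


def train_knn(train: tuple[np.ndarray, np.ndarray], n_neighbors: int) -> KNeighborsClassifier:
    """K-nearest-neighbour vote (Euclidean metric) for one neighbour count."""
    if n_neighbors not in (3, 5, 7):
        raise ValueError("n_neighbors must be one of 3, 5, 7")
    X, y = train
    return KNeighborsClassifier(n_neighbors=n_neighbors).fit(X, y)


def select_knn(train, validation) -> tuple[KNeighborsClassifier, dict]:
    """Pick the neighbour count in {3, 5, 7} with fewest validation mistakes."""
    Xv, yv = validation
    best = None
    for k in (3, 5, 7):
        clf = train_knn(train, k)
        mistakes = count_mistakes(clf, Xv, yv)
        if best is None or mistakes < best[0]:
            best = (mistakes, k, clf)
    return best[2], {"n_neighbors": best[1], "val_mistakes": best[0]}


#: logarithmic grids over the scanned ranges, 7 points per axis
SVM_C_GRID = tuple(np.geomspace(0.1, 100.0, 7))
SVM_GAMMA_GRID = tuple(np.geomspace(0.01, 10.0, 7))
SVM_KERNELS = ("linear", "rbf", "poly")


def train_svm(train, kernel: str, C: float, gamma: float) -> SVC:
    if kernel not in SVM_KERNELS:
        raise ValueError(f"kernel must be one of {SVM_KERNELS}")
    X, y = train
    return SVC(kernel=kernel, C=C, gamma=gamma).fit(X, y)


def select_svm(train, validation) -> tuple[SVC, dict]:
    """Grid search over kernel, C and gamma by validation mistakes.

    Ties go to the smaller C (then the earlier kernel/gamma in grid order).
    """
    Xv, yv = validation
    best = None
    for kernel in SVM_KERNELS:
        for C in SVM_C_GRID:
            for gamma in SVM_GAMMA_GRID:
                clf = train_svm(train, kernel, C, gamma)
                mistakes = count_mistakes(clf, Xv, yv)
                key = (mistakes, C)
                if best is None or key < best[0]:
                    best = (key, clf, {"kernel": kernel, "C": C, "gamma": gamma,
                                       "val_mistakes": mistakes})
    return best[1], best[2]


def count_mistakes(classifier, X: np.ndarray, y: np.ndarray) -> int:
    """Number of items whose predicted group differs from the label.

    Predictions are the argmax of predict_proba when available (ties to the
    smallest index), else the estimator's predict output.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=int)
    if hasattr(classifier, "predict_proba"):
        pred = np.argmax(classifier.predict_proba(X), axis=1)
    else:
        pred = np.asarray(classifier.predict(X), dtype=int)
    return int(np.sum(pred != y))
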