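"""The four classifier back-ends behind one fit/predict contract.

Random forest, logistic regression and the plain feed-forward ANN consume the
concatenated binary clinical + variant-presence vector and delegate to
scikit-learn.  The variant-embedding network ("ANN with GE") is implemented
here from scratch: each panel variant owns a learned d-dimensional embedding
row, a patient's variant rows are aggregated (summed by default, mean
available) into one genetic vector — a permutation-invariant set function —
concatenated with the binary clinical vector and passed through a single
ReLU hidden layer to a sigmoid output.  Sum aggregation keeps the genetic
vector linear in variant presence, which lets the hidden layer represent
variant co-occurrence; mean pooling normalizes away the mutation burden but
empirically under-recovers interaction signals.
Embeddings and network weights are trained jointly by minimizing binary
cross-entropy with Adam.

Positive class is *paclitaxel-sensitive* throughout.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable, Sequence

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.neural_network import MLPClassifier

from .features import FeatureSet, VariantVocabulary, stratified_split

__all__ = [
    "MODEL_KINDS",
    "ModelSpec",
    "EmbedNetParams",
    "FittedModel",
    "embed_aggregate",
    "forward_embednet",
    "embednet_loss_and_grads",
    "train_embednet",
    "fit_classifier",
    "predict_proba",
    "save_model",
    "load_model",
]

MODEL_KINDS = ("random_forest", "logistic_regression", "ann", "ann_with_ge")


@dataclass(frozen=True)
class ModelSpec:
    """Hyperparameters for one classifier.

    The embedding dimension and hidden-layer width both default to 20 — the
    architecture sizes of the study design.
    """

    kind: str
    seed: int = 0
    embedding_dim: int = 20
    hidden_units: int = 20
    aggregation: str = "sum"           # or "mean"
    learning_rate: float = 1e-3
    max_epochs: int = 500
    batch_size: int | None = 32        # None = full batch
    early_stopping: bool = True
    early_stopping_patience: int = 20
    l2_penalty: float = 1.0            # LR only (C = 1 / l2_penalty)
    n_trees: int = 500
    max_depth: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in MODEL_KINDS:
            raise ValueError(f"unknown model kind {self.kind!r}; expected {MODEL_KINDS}")
        if self.embedding_dim <= 0 or self.hidden_units <= 0:
            raise ValueError("embedding_dim and hidden_units must be positive")
        if self.aggregation not in ("mean", "sum"):
            raise ValueError("aggregation must be 'mean' or 'sum'")


@dataclass
class EmbedNetParams:
    """Embedding table and feed-forward weights of the ANN-with-GE model."""

    E: np.ndarray    # V x d variant embeddings
    W1: np.ndarray   # (k + d) x h
    b1: np.ndarray   # h
    w2: np.ndarray   # h
    b2: float

    def copy(self) -> "EmbedNetParams":
        return EmbedNetParams(
            self.E.copy(), self.W1.copy(), self.b1.copy(), self.w2.copy(), float(self.b2)
        )

    def blocks(self) -> dict[str, np.ndarray]:
        return {"E": self.E, "W1": self.W1, "b1": self.b1, "w2": self.w2}


def embed_aggregate(
    variant_indices: Iterable[int], E: np.ndarray, aggregation: str = "mean"
) -> np.ndarray:
    """Aggregate one patient's variant embedding rows into a single vector.

    Set semantics: invariant to ordering and duplication of indices; the
    empty set maps to the zero vector.
    """
    idx = sorted(frozenset(int(v) for v in variant_indices))
    if idx and (idx[0] < 0 or idx[-1] >= E.shape[0]):
        bad = [v for v in idx if v < 0 or v >= E.shape[0]]
        raise IndexError(f"variant index out of range: {bad} (V={E.shape[0]})")
    if not idx:
        return np.zeros(E.shape[1])
    rows = E[idx]
    return rows.mean(axis=0) if aggregation == "mean" else rows.sum(axis=0)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def forward_embednet(
    clinical_vec: Sequence[float],
    variant_indices: Iterable[int],
    params: EmbedNetParams,
    aggregation: str = "mean",
) -> float:
    """Predicted probability of paclitaxel sensitivity for one patient."""
    x = np.concatenate(
        [np.asarray(clinical_vec, dtype=float),
         embed_aggregate(variant_indices, params.E, aggregation)]
    )
    if x.shape[0] != params.W1.shape[0]:
        raise ValueError(
            f"input width {x.shape[0]} does not match W1 rows {params.W1.shape[0]}"
        )
    hidden = np.maximum(x @ params.W1 + params.b1, 0.0)
    return float(_sigmoid(np.array([hidden @ params.w2 + params.b2]))[0])


def _batch_forward(
    X_clin: np.ndarray,
    variant_sets: Sequence[frozenset[int]],
    params: EmbedNetParams,
    aggregation: str,
):
    n = X_clin.shape[0]
    d = params.E.shape[1]
    G = np.zeros((n, d))
    for i, s in enumerate(variant_sets):
        if s:
            rows = params.E[sorted(s)]
            G[i] = rows.mean(axis=0) if aggregation == "mean" else rows.sum(axis=0)
    X = np.hstack([X_clin, G])
    Z1 = X @ params.W1 + params.b1
    A = np.maximum(Z1, 0.0)
    logits = A @ params.w2 + params.b2
    return X, Z1, A, _sigmoid(logits)


def embednet_loss_and_grads(
    params: EmbedNetParams,
    X_clin: np.ndarray,
    variant_sets: Sequence[frozenset[int]],
    y: np.ndarray,
    aggregation: str = "mean",
) -> tuple[float, EmbedNetParams]:
    """Mean binary cross-entropy and its analytic gradient in every block.

    The gradient object reuses the EmbedNetParams container (same shapes).
    """
    n = X_clin.shape[0]
    k = X_clin.shape[1]
    X, Z1, A, p = _batch_forward(X_clin, variant_sets, params, aggregation)
    eps = 1e-12
    loss = float(-np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)))
    dlogit = (p - y) / n
    gw2 = A.T @ dlogit
    gb2 = float(dlogit.sum())
    dA = np.outer(dlogit, params.w2)
    dZ1 = dA * (Z1 > 0)
    gW1 = X.T @ dZ1
    gb1 = dZ1.sum(axis=0)
    dX = dZ1 @ params.W1.T
    dG = dX[:, k:]
    gE = np.zeros_like(params.E)
    for i, s in enumerate(variant_sets):
        if s:
            idx = sorted(s)
            w = 1.0 / len(idx) if aggregation == "mean" else 1.0
            gE[idx] += w * dG[i]
    return loss, EmbedNetParams(gE, gW1, gb1, gw2, gb2)


def _init_params(V: int, k: int, spec: ModelSpec, rng: np.random.Generator) -> EmbedNetParams:
    d, h = spec.embedding_dim, spec.hidden_units
    # embeddings: zero-mean Gaussian sd 0.1; weights: He-scaled Gaussians
    E = rng.normal(0.0, 0.1, size=(V, d))
    W1 = rng.normal(0.0, np.sqrt(2.0 / (k + d)), size=(k + d, h))
    b1 = np.zeros(h)
    w2 = rng.normal(0.0, np.sqrt(2.0 / h), size=h)
    return EmbedNetParams(E, W1, b1, w2, 0.0)


class _Adam:
    def __init__(self, shapes: dict[str, tuple], lr: float):
        self.lr = lr
        self.t = 0
        self.m = {k: np.zeros(s) for k, s in shapes.items()}
        self.v = {k: np.zeros(s) for k, s in shapes.items()}
        self.mb2 = 0.0
        self.vb2 = 0.0

    def step(self, params: EmbedNetParams, grads: EmbedNetParams) -> None:
        b1, b2, eps = 0.9, 0.999, 1e-8
        self.t += 1
        corr1 = 1 - b1 ** self.t
        corr2 = 1 - b2 ** self.t
        for name, g in grads.blocks().items():
            self.m[name] = b1 * self.m[name] + (1 - b1) * g
            self.v[name] = b2 * self.v[name] + (1 - b2) * g * g
            update = (self.m[name] / corr1) / (np.sqrt(self.v[name] / corr2) + eps)
            getattr(params, name)[...] -= self.lr * update
        self.mb2 = b1 * self.mb2 + (1 - b1) * grads.b2
        self.vb2 = b2 * self.vb2 + (1 - b2) * grads.b2 ** 2
        params.b2 -= self.lr * (self.mb2 / corr1) / (np.sqrt(self.vb2 / corr2) + eps)


def train_embednet(
    X_clin: np.ndarray,
    variant_sets: Sequence[frozenset[int]],
    y: np.ndarray,
    n_variants: int,
    spec: ModelSpec,
) -> EmbedNetParams:
    """Train embeddings + network jointly by Adam on binary cross-entropy.

    With early stopping on, 10% of the training data is held out (outcome-
    stratified) and the parameters with the best held-out AUROC are returned
    (cross-entropy on the holdout rises with overconfidence long before
    discrimination stops improving, so the ranking metric is the better
    monitor); with early stopping off, the parameters with the best
    *training* loss are returned, so extending ``max_epochs`` can never
    worsen the final loss.  Embedding rows of variants absent from the
    training data receive no gradient and remain exactly at initialization.
    """
    y = np.asarray(y, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    rng = np.random.default_rng(spec.seed)
    k = X_clin.shape[1]
    params = _init_params(n_variants, k, spec, rng)

    from .evaluation import auroc  # local import: evaluation has no model deps

    if spec.early_stopping and len(y) >= 20:
        split = stratified_split(y.astype(int), 0.1, seed=spec.seed + 1)
        tr = np.array(split.train_indices)
        va = np.array(split.validation_indices)
        if len(np.unique(y[va])) < 2:  # tiny inner split may miss a class
            tr, va = np.arange(len(y)), None
    else:
        tr = np.arange(len(y))
        va = None

    Xtr = X_clin[tr]
    sets_tr = [variant_sets[i] for i in tr]
    ytr = y[tr]
    if va is not None:
        Xva = X_clin[va]
        sets_va = [variant_sets[i] for i in va]
        yva = y[va]

    def monitor_value(p: EmbedNetParams) -> float:
        """Higher is better: inner-val AUROC, or negated training loss."""
        if va is not None:
            proba = _batch_forward(Xva, sets_va, p, spec.aggregation)[3]
            return auroc(proba, yva.astype(int))
        loss, _ = embednet_loss_and_grads(p, Xtr, sets_tr, ytr, spec.aggregation)
        return -loss

    opt = _Adam({k_: v.shape for k_, v in params.blocks().items()}, spec.learning_rate)
    best = params.copy()
    best_monitor = monitor_value(params)
    stale = 0
    n_tr = len(ytr)
    bs = spec.batch_size if spec.batch_size else n_tr
    for _ in range(spec.max_epochs):
        order = rng.permutation(n_tr)
        for start in range(0, n_tr, bs):
            sel = order[start : start + bs]
            _, grads = embednet_loss_and_grads(
                params, Xtr[sel], [sets_tr[i] for i in sel], ytr[sel], spec.aggregation
            )
            opt.step(params, grads)
        monitor = monitor_value(params)
        if monitor > best_monitor + 1e-12:
            best_monitor = monitor
            best = params.copy()
            stale = 0
        else:
            stale += 1
            if spec.early_stopping and stale >= spec.early_stopping_patience:
                break
    return best


@dataclass
class FittedModel:
    """A trained classifier bound to its feature layout."""

    spec: ModelSpec
    vocabulary: VariantVocabulary
    clinical_names: tuple[str, ...]
    embed_params: EmbedNetParams | None = None
    estimator: object | None = None

    @property
    def kind(self) -> str:
        return self.spec.kind


def _baseline_design(features: FeatureSet, indices: Sequence[int]) -> np.ndarray:
    idx = np.asarray(indices, dtype=int)
    return np.hstack([features.clinical_matrix[idx], features.variant_matrix[idx]])


def fit_classifier(
    spec: ModelSpec, features: FeatureSet, train_indices: Sequence[int]
) -> FittedModel:
    """Fit one of the four model kinds on the given training rows.

    Baselines consume the k+V binary design; the embedding network consumes
    the clinical vector plus the raw variant index set.  All kinds are
    deterministic given ``spec.seed``.
    """
    y = features.binary_labels(train_indices)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    if spec.kind == "ann_with_ge":
        idx = list(train_indices)
        params = train_embednet(
            features.clinical_matrix[np.asarray(idx)],
            [features.variant_sets[i] for i in idx],
            y,
            len(features.vocabulary),
            spec,
        )
        return FittedModel(spec, features.vocabulary, features.clinical_names,
                           embed_params=params)
    X = _baseline_design(features, train_indices)
    if spec.kind == "random_forest":
        est = RandomForestClassifier(
            n_estimators=spec.n_trees, max_depth=spec.max_depth, random_state=spec.seed
        )
    elif spec.kind == "logistic_regression":
        est = LogisticRegression(
            C=1.0 / spec.l2_penalty, max_iter=5000, random_state=spec.seed
        )
    else:  # ann
        est = MLPClassifier(
            hidden_layer_sizes=(spec.hidden_units,),
            max_iter=2000,
            random_state=spec.seed,
        )
    est.fit(X, y)
    return FittedModel(spec, features.vocabulary, features.clinical_names, estimator=est)


def predict_proba(
    model: FittedModel, features: FeatureSet, indices: Sequence[int]
) -> np.ndarray:
    """Probability of paclitaxel sensitivity for each requested patient."""
    if features.vocabulary.variant_ids != model.vocabulary.variant_ids:
        raise ValueError("feature vocabulary does not match the fitted model")
    if features.clinical_names != model.clinical_names:
        raise ValueError("clinical feature layout does not match the fitted model")
    if model.kind == "ann_with_ge":
        assert model.embed_params is not None
        idx = list(indices)
        _, _, _, p = _batch_forward(
            features.clinical_matrix[np.asarray(idx, dtype=int)],
            [features.variant_sets[i] for i in idx],
            model.embed_params,
            model.spec.aggregation,
        )
        return p
    X = _baseline_design(features, indices)
    proba = model.estimator.predict_proba(X)
    positive = list(model.estimator.classes_).index(1.0)
    return proba[:, positive]


# ---------------------------------------------------------------------------
# On-disk bundle
# ---------------------------------------------------------------------------

def save_model(model: FittedModel, out_dir) -> None:
    """Write a reloadable bundle: spec + vocabulary as JSON, parameters as
    .npz (embedding net) or joblib (scikit-learn back-ends)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {
        "spec": asdict(model.spec),
        "vocabulary": list(model.vocabulary.variant_ids),
        "clinical_names": list(model.clinical_names),
    }
    (out / "model.json").write_text(json.dumps(meta, indent=2))
    if model.kind == "ann_with_ge":
        p = model.embed_params
        np.savez(
            out / "params.npz", E=p.E, W1=p.W1, b1=p.b1, w2=p.w2, b2=np.array([p.b2])
        )
    else:
        joblib.dump(model.estimator, out / "estimator.joblib")


def load_model(in_dir) -> FittedModel:
    src = Path(in_dir)
    meta = json.loads((src / "model.json").read_text())
    spec = ModelSpec(**meta["spec"])
    vocab = VariantVocabulary(tuple(meta["vocabulary"]))
    names = tuple(meta["clinical_names"])
    if spec.kind == "ann_with_ge":
        data = np.load(src / "params.npz")
        params = EmbedNetParams(
            data["E"], data["W1"], data["b1"], data["w2"], float(data["b2"][0])
        )
        return FittedModel(spec, vocab, names, embed_params=params)
    est = joblib.load(src / "estimator.joblib")
    return FittedModel(spec, vocab, names, estimator=est)
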