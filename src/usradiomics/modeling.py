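"""ADASYN minority oversampling and the three majority-vote ensembles.

Three ensemble kinds, each of 16 members diversified by bootstrap resampling
with per-member seeds:

* ``random_forest`` — 16 random forests with the Gini split criterion;
* ``svm_pca_fdr``  — standardize, PCA, rank components by the Fisher
  Discriminant Ratio (mu1-mu2)^2/(s1^2+s2^2), keep the top m, then 16 SVMs;
* ``knn_pca_fdr``  — same preprocessing chain, 16 k-NN classifiers.

Prediction is by majority vote; a tie goes to the positive (malignant)
class. The continuous score is the mean member positive-class probability.

ADASYN is implemented from its original definition: G = (m_l - m_s) * beta
synthetic minority samples are distributed across minority points in
proportion to r_i = (majority neighbours among the k nearest)/k, and each
synthetic point is x_i + lambda * (x_z - x_i) with x_z a random minority
neighbour and lambda ~ U(0, 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier, NearestNeighbors
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

ENSEMBLE_KINDS = ("random_forest", "svm_pca_fdr", "knn_pca_fdr")


@dataclass
class AdasynConfig:
    beta: float = 1.0  # fraction of the class imbalance to fill
    k_neighbors: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.beta <= 1):
            raise ValueError("beta must be in (0, 1]")
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")


@dataclass
class EnsembleSpec:
    kind: str = "random_forest"
    n_members: int = 16
    pca_variance_kept: float = 0.95
    fdr_top_m: int = 10
    trees_per_member: int = 50  # random-forest members only
    svm_C: float = 1.0
    knn_k: int = 5

    def __post_init__(self) -> None:
        if self.kind not in ENSEMBLE_KINDS:
            raise ValueError(f"unknown ensemble kind {self.kind!r}")
        if self.n_members < 1:
            raise ValueError("n_members must be >= 1")


def adasyn_oversample(
    X: np.ndarray, y: np.ndarray, cfg: AdasynConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """ADASYN oversampling of the minority class.

    Returns the original samples unchanged (majority class untouched)
    followed by ~G = (m_l - m_s) * beta synthetic minority samples, each a
    convex combination of a minority point and one of its k nearest
    minority neighbours. Deterministic given ``cfg.seed``.
    """
    cfg = cfg or AdasynConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("ADASYN requires exactly two classes")
    minority = classes[np.argmin(counts)]
    m_s, m_l = counts.min(), counts.max()
    G = int(round((m_l - m_s) * cfg.beta))
    if G == 0:
        return X.copy(), y.copy()
    Xmin = X[y == minority]
    k = cfg.k_neighbors
    if m_s <= k:
        k = max(1, m_s - 1)
        warnings.warn(f"minority class too small for k={cfg.k_neighbors}; reduced to {k}")

    rng = np.random.default_rng(cfg.seed)
    # r_i: fraction of majority points among the k nearest neighbours in X
    nn_all = NearestNeighbors(n_neighbors=k + 1).fit(X)
    _, idx = nn_all.kneighbors(Xmin)
    neigh_labels = y[idx[:, 1:]]  # drop self
    r = (neigh_labels != minority).mean(axis=1)
    r_hat = np.full(len(Xmin), 1.0 / len(Xmin)) if r.sum() == 0 else r / r.sum()
    g = np.rint(r_hat * G).astype(int)

    nn_min = NearestNeighbors(n_neighbors=min(k + 1, len(Xmin))).fit(Xmin)
    _, min_idx = nn_min.kneighbors(Xmin)
    synth = []
    for i, gi in enumerate(g):
        neighbours = min_idx[i, 1:]
        if len(neighbours) == 0:
            neighbours = np.array([i])
        for _ in range(gi):
            z = neighbours[rng.integers(len(neighbours))]
            lam = rng.random()
            synth.append(Xmin[i] + lam * (Xmin[z] - Xmin[i]))
    if not synth:
        return X.copy(), y.copy()
    Xs = np.vstack(synth)
    ys = np.full(len(Xs), minority, dtype=y.dtype)
    return np.vstack([X, Xs]), np.concatenate([y, ys])


def fisher_discriminant_ratio(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Per-column FDR (mu1 - mu2)^2 / (s1^2 + s2^2) for a binary label."""
    classes = np.unique(y)
    a, b = X[y == classes[0]], X[y == classes[1]]
    num = (a.mean(axis=0) - b.mean(axis=0)) ** 2
    den = a.var(axis=0) + b.var(axis=0)
    return np.where(den > 0, num / np.where(den > 0, den, 1.0), np.inf)


@dataclass
class TrainedEnsemble:
    """Fitted preprocessing chain + 16 fitted members + the vote rule."""

    spec: EnsembleSpec
    feature_names: list[str]
    positive_class: str
    scaler: StandardScaler | None = None
    pca: PCA | None = None
    component_order: np.ndarray | None = None
    members: list = field(default_factory=list)
    classes_: np.ndarray | None = None

    def _transform(self, X: np.ndarray) -> np.ndarray:
        Z = self.scaler.transform(X) if self.scaler is not None else X
        if self.pca is not None:
            Z = self.pca.transform(Z)[:, self.component_order]
        return Z

    def _check_schema(self, columns) -> None:
        missing = [c for c in self.feature_names if c not in set(columns)]
        if missing:
            raise ValueError(f"schema mismatch; missing columns: {missing}")


@dataclass
class PredictionSet:
    labels: np.ndarray  # hard majority-vote label per case
    vote_fraction: np.ndarray  # fraction of members voting positive
    score: np.ndarray  # mean member positive-class score in [0, 1]


def _make_member(spec: EnsembleSpec, seed: int):
    if spec.kind == "random_forest":
        return RandomForestClassifier(
            n_estimators=spec.trees_per_member,
            criterion="gini",
            random_state=seed,
        )
    if spec.kind == "svm_pca_fdr":
        return SVC(C=spec.svm_C, kernel="rbf", random_state=seed)
    return KNeighborsClassifier(n_neighbors=spec.knn_k)


def fit_ensemble(
    X: np.ndarray,
    y: np.ndarray,
    spec: EnsembleSpec | None = None,
    seed: int = 0,
    feature_names: list[str] | None = None,
    positive_class: str = "malignant",
) -> TrainedEnsemble:
    """Fit one 16-member ensemble on (typically ADASYN-balanced) data.

    All preprocessing (standardization, PCA, FDR ranking) is fitted on the
    supplied training data only; per-member seeds and bootstrap resamples
    derive from ``seed``.
    """
    spec = spec or EnsembleSpec()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("single-class training data")
    ens = TrainedEnsemble(
        spec=spec,
        feature_names=list(feature_names) if feature_names is not None else
        [f"f{i}" for i in range(X.shape[1])],
        positive_class=positive_class,
        classes_=np.unique(y),
    )
    Z = X
    if spec.kind in ("svm_pca_fdr", "knn_pca_fdr"):
        ens.scaler = StandardScaler().fit(X)
        Z = ens.scaler.transform(X)
        n_comp = min(X.shape[0], X.shape[1])
        ens.pca = PCA(n_components=spec.pca_variance_kept
                      if 0 < spec.pca_variance_kept < 1 else n_comp).fit(Z)
        Z = ens.pca.transform(Z)
        fdr = fisher_discriminant_ratio(Z, y)
        order = np.argsort(-fdr, kind="stable")
        m = min(spec.fdr_top_m, Z.shape[1])
        ens.component_order = order[:m]
        Z = Z[:, ens.component_order]
    rng = np.random.default_rng(seed)
    n = len(y)
    for _ in range(spec.n_members):
        member_seed = int(rng.integers(2**31 - 1))
        idx = np.random.default_rng(member_seed).integers(n, size=n)
        while len(np.unique(y[idx])) < 2:  # bootstrap must keep both classes
            member_seed += 1
            idx = np.random.default_rng(member_seed).integers(n, size=n)
        member = _make_member(spec, member_seed)
        member.fit(Z[idx], y[idx])
        ens.members.append(member)
    return ens


def _member_scores(ens: TrainedEnsemble, member, Z: np.ndarray) -> np.ndarray:
    """Positive-class score in [0, 1] for one member."""
    pos = ens.positive_class
    if hasattr(member, "predict_proba") and member.__class__ is not SVC:
        proba = member.predict_proba(Z)
        col = list(member.classes_).index(pos)
        return proba[:, col]
    dec = member.decision_function(Z)
    if member.classes_[1] != pos:
        dec = -dec
    return 1.0 / (1.0 + np.exp(-dec))  # logistic map to [0, 1]


def predict(ensemble: TrainedEnsemble, X, columns=None) -> PredictionSet:
    """Majority-vote prediction. Hard label = positive class when more than
    half the members vote positive; an exact tie also goes positive (the
    clinically conservative choice for malignancy)."""
    import pandas as pd

    if isinstance(X, pd.DataFrame):
        ensemble._check_schema(X.columns)
        X = X[ensemble.feature_names].to_numpy(dtype=float)
    elif columns is not None:
        ensemble._check_schema(columns)
        order = [list(columns).index(c) for c in ensemble.feature_names]
        X = np.asarray(X, dtype=float)[:, order]
    else:
        X = np.asarray(X, dtype=float)
    Z = ensemble._transform(X)
    pos = ensemble.positive_class
    votes = np.stack([m.predict(Z) == pos for m in ensemble.members])
    scores = np.stack([_member_scores(ensemble, m, Z) for m in ensemble.members])
    frac = votes.mean(axis=0)
    neg = [c for c in ensemble.classes_ if c != pos][0]
    labels = np.where(frac >= 0.5, pos, neg)
    return PredictionSet(labels=labels, vote_fraction=frac, score=scores.mean(axis=0))
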