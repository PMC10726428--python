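"""Sample classifiers over chromatin-accessibility signal.

Two classifiers are provided. A k-nearest-neighbor model over progenitor
identity loci assigns each leukemia sample a cell-of-origin stage by
majority vote among the k nearest training profiles (Euclidean distance on
locus-standardized stabilized signal, ties broken by the single nearest
neighbor). A stepwise PCA-LDA model classifies subtypes from
subtype-enriched sites: features are centered and scaled, projected onto
principal axes, and a regularized linear discriminant is fit in PC space;
the number of principal components is chosen by internal leave-one-out
cross-validation (PCA and LDA refit per fold on the fixed feature set),
smallest component count winning ties.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg
from scipy.spatial.distance import cdist

from .io_formats import ConfigError, ValidationError

__all__ = [
    "KnnModel",
    "PcaLdaModel",
    "ConfusionMatrix",
    "knn_fit",
    "knn_predict",
    "knn_loocv",
    "pca_lda_fit",
    "pca_lda_predict",
    "merge_classes_accuracy",
]


@dataclass
class ConfusionMatrix:
    """Truth x prediction count matrix with a fixed label order."""

    labels: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=int)
        if self.matrix.shape != (len(self.labels), len(self.labels)):
            raise ValidationError("confusion matrix shape does not match labels")

    @property
    def accuracy(self) -> float:
        total = self.matrix.sum()
        if total == 0:
            raise ValidationError("empty confusion matrix")
        return float(np.trace(self.matrix)) / float(total)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.labels, columns=self.labels)

    @classmethod
    def from_labels(cls, truth: Sequence[str], pred: Sequence[str]) -> "ConfusionMatrix":
        labels = sorted(set(truth) | set(pred))
        pos = {lb: i for i, lb in enumerate(labels)}
        m = np.zeros((len(labels), len(labels)), dtype=int)
        for t, p in zip(truth, pred):
            m[pos[t], pos[p]] += 1
        return cls(labels, m)


def merge_classes_accuracy(confusion: ConfusionMatrix, groups: Sequence[Sequence[str]]) -> float:
    """Accuracy after collapsing label groups of a confusion matrix.

    ``groups`` must partition the label set; rows and columns of each group
    are summed and accuracy recomputed as trace over total. Coarsening can
    only keep or raise the accuracy.
    """
    flat = [lb for g in groups for lb in g]
    if sorted(flat) != sorted(confusion.labels) or len(flat) != len(set(flat)):
        raise ValidationError("groups do not partition the label set")
    pos = {lb: i for i, lb in enumerate(confusion.labels)}
    k = len(groups)
    collapsed = np.zeros((k, k), dtype=int)
    for gi, gA in enumerate(groups):
        for gj, gB in enumerate(groups):
            collapsed[gi, gj] = confusion.matrix[np.ix_([pos[a] for a in gA], [pos[b] for b in gB])].sum()
    return float(np.trace(collapsed)) / float(collapsed.sum())


# ---------------------------------------------------------------------------
# k-nearest neighbors
# ---------------------------------------------------------------------------

@dataclass
class KnnModel:
    X: np.ndarray          # (n_train, n_features)
    labels: list[str]
    feature_ids: list[str]
    k: int = 5
    metric: str = "euclidean"

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if not 1 <= self.k <= self.X.shape[0]:
            raise ConfigError(f"k={self.k} outside [1, n_train={self.X.shape[0]}]")


def knn_fit(
    signal: pd.DataFrame,
    labels: Sequence[str],
    k: int = 5,
    metric: str = "euclidean",
) -> KnnModel:
    """Store the training matrix (samples x loci) and labels.

    ``signal`` rows are samples, columns identity loci; callers typically
    supply stabilized counts standardized per locus across the training
    cohort.
    """
    if len(labels) != signal.shape[0]:
        raise ValidationError("labels length does not match samples")
    return KnnModel(signal.to_numpy(dtype=float), list(map(str, labels)), list(signal.columns), k, metric)


def knn_predict(model: KnnModel, queries: pd.DataFrame) -> list[str]:
    """Majority vote among the k nearest training samples.

    Vote ties are broken by the label of the single nearest neighbor.
    Query features must match the training loci exactly (same order).
    """
    if list(queries.columns) != model.feature_ids:
        raise ValidationError("query features do not match training loci")
    D = cdist(queries.to_numpy(dtype=float), model.X, metric=model.metric)
    out: list[str] = []
    for row in D:
        order = np.argsort(row, kind="stable")[: model.k]
        votes: dict[str, int] = {}
        for idx in order:
            lb = model.labels[idx]
            votes[lb] = votes.get(lb, 0) + 1
        top = max(votes.values())
        winners = [lb for lb, v in votes.items() if v == top]
        out.append(winners[0] if len(winners) == 1 else model.labels[order[0]])
    return out


def knn_loocv(signal: pd.DataFrame, labels: Sequence[str], k: int = 5, metric: str = "euclidean") -> ConfusionMatrix:
    """Leave-one-out cross-validation of the k-NN classifier."""
    labels = list(map(str, labels))
    n = signal.shape[0]
    if n < 2:
        raise ValidationError("LOOCV needs at least 2 samples")
    counts = pd.Series(labels).value_counts()
    if (counts < 2).any():
        import logging

        logging.getLogger("ballatac").warning(
            "knn_loocv: classes with a single sample can never be predicted correctly"
        )
    preds: list[str] = []
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        model = knn_fit(signal.iloc[mask], [labels[j] for j in range(n) if mask[j]], k=min(k, n - 1), metric=metric)
        preds.append(knn_predict(model, signal.iloc[[i]])[0])
    return ConfusionMatrix.from_labels(labels, preds)


# ---------------------------------------------------------------------------
# stepwise PCA-LDA
# ---------------------------------------------------------------------------

@dataclass
class PcaLdaModel:
    """Fitted stepwise PCA-LDA subtype classifier.

    ``components`` maps standardized features to PC space (n_pc x
    n_features); ``class_means`` are per-class means in PC space;
    ``cov_reg`` is the shrinkage-regularized pooled within-class
    covariance; ``axes`` (n_pc x n_disc) are the discriminant directions
    used for plotting coordinates.
    """

    feature_ids: list[str]
    center: np.ndarray
    scale: np.ndarray
    components: np.ndarray
    n_pc: int
    class_labels: list[str]
    class_means: np.ndarray
    cov_reg: np.ndarray
    axes: np.ndarray
    gamma: float
    cv_accuracy_: float | None = None
    cv_confusion_: ConfusionMatrix | None = None
    grid_accuracies_: dict[int, float] = field(default_factory=dict)
    training_scores_: np.ndarray | None = None

    def transform(self, signal: pd.DataFrame) -> np.ndarray:
        """Discriminant coordinates for plotting (samples x n_disc)."""
        Z = self._project(signal)
        return Z @ self.axes

    def _project(self, signal: pd.DataFrame) -> np.ndarray:
        missing = [f for f in self.feature_ids if f not in signal.columns]
        if missing:
            raise ValidationError(f"query lacks {len(missing)} model features, e.g. {missing[:3]}")
        X = signal[self.feature_ids].to_numpy(dtype=float)
        Xs = (X - self.center) / self.scale
        return Xs @ self.components[: self.n_pc].T


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    center = X.mean(axis=0)
    scale = X.std(axis=0, ddof=0)
    scale = np.where(scale > 0, scale, 1.0)
    return (X - center) / scale, center, scale


def _pca(Xs: np.ndarray, n_max: int) -> np.ndarray:
    """Principal axes by SVD with a deterministic sign convention."""
    _, _, Vt = np.linalg.svd(Xs, full_matrices=False)
    V = Vt[:n_max]
    signs = np.sign(V[np.arange(V.shape[0]), np.abs(V).argmax(axis=1)])
    signs[signs == 0] = 1.0
    return V * signs[:, None]


def _lda_fit(Z: np.ndarray, y: np.ndarray, labels: list[str], gamma: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Class means, regularized pooled covariance, discriminant axes."""
    n, k = Z.shape
    C = len(labels)
    means = np.vstack([Z[y == lb].mean(axis=0) for lb in labels])
    Sw = np.zeros((k, k))
    for i, lb in enumerate(labels):
        R = Z[y == lb] - means[i]
        Sw += R.T @ R
    dof = max(n - C, 1)
    Sw /= dof
    Sreg = (1.0 - gamma) * Sw + gamma * np.diag(np.diag(Sw))
    Sreg += 1e-10 * np.eye(k)
    grand = Z.mean(axis=0)
    Sb = np.zeros((k, k))
    for i, lb in enumerate(labels):
        d = (means[i] - grand)[:, None]
        Sb += (y == lb).sum() * (d @ d.T)
    Sb /= n
    evals, evecs = linalg.eigh(Sb, Sreg)
    order = np.argsort(evals)[::-1][: C - 1]
    return means, Sreg, evecs[:, order]


def _lda_predict(Z: np.ndarray, means: np.ndarray, Sreg: np.ndarray, labels: list[str]) -> list[str]:
    """Nearest class mean under the regularized within-class metric.

    Distance ties resolve to the lexicographically first label (labels are
    kept sorted, and argmin takes the first minimum).
    """
    L = np.linalg.cholesky(Sreg)
    Zw = linalg.solve_triangular(L, Z.T, lower=True).T
    Mw = linalg.solve_triangular(L, means.T, lower=True).T
    d2 = cdist(Zw, Mw, metric="sqeuclidean")
    idx = np.argmin(np.round(d2, 10), axis=1)  # rounding makes exact ties land on the first label
    return [labels[i] for i in idx]


def _fit_core(Xs: np.ndarray, y: np.ndarray, labels: list[str], n_pc: int, gamma: float, V: np.ndarray):
    Z = Xs @ V[:n_pc].T
    means, Sreg, axes = _lda_fit(Z, y, labels, gamma)
    return Z, means, Sreg, axes


def pca_lda_fit(
    signal: pd.DataFrame,
    labels: Sequence[str],
    n_pc_grid: Sequence[int] | None = None,
    gamma: float = 0.1,
    seed: int | None = None,
) -> PcaLdaModel:
    """Fit the stepwise PCA-LDA classifier with LOOCV component selection.

    ``signal`` is samples x subtype-enriched features (stabilized counts).
    For every candidate component count, each sample is predicted by a
    model whose standardization, PCA and LDA are refit without it (the
    feature set itself stays fixed); the count maximizing LOOCV accuracy is
    selected, smallest winning ties, and the final model is refit on all
    samples. The procedure is deterministic; ``seed`` is accepted for
    interface symmetry with stochastic fitters.
    """
    y = np.asarray(list(map(str, labels)))
    class_labels = sorted(set(y))
    n, f = signal.shape
    if n <= len(class_labels):
        raise ValidationError("need more samples than classes")
    cap = min(50, n - 2, f)
    grid = sorted({g for g in (n_pc_grid if n_pc_grid is not None else range(2, cap + 1)) if 1 <= g <= cap})
    if not grid:
        raise ConfigError("empty n_pc grid after capping at n_samples - 2")
    n_max = max(grid)

    X = signal.to_numpy(dtype=float)
    # LOOCV over the grid: PCA refit once per fold at n_max, LDA per n_pc
    preds: dict[int, list[str]] = {g: [] for g in grid}
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        Xs_tr, center, scale = _standardize(X[mask])
        fold_max = min(n_max, mask.sum() - 1)
        V = _pca(Xs_tr, fold_max)
        fold_labels = sorted(set(y[mask]))
        Xq = ((X[i] - center) / scale)[None, :]
        for g in grid:
            gg = min(g, fold_max)
            Z_tr = Xs_tr @ V[:gg].T
            means, Sreg, _ = _lda_fit(Z_tr, y[mask], fold_labels, gamma)
            Zq = Xq @ V[:gg].T
            preds[g].append(_lda_predict(Zq, means, Sreg, fold_labels)[0])

    accs = {g: float(np.mean(np.asarray(preds[g]) == y)) for g in grid}
    best = max(accs.values())
    n_pc = min(g for g, a in accs.items() if a == best)

    Xs, center, scale = _standardize(X)
    V = _pca(Xs, n_max)
    Z, means, Sreg, axes = _fit_core(Xs, y, class_labels, n_pc, gamma, V)
    model = PcaLdaModel(
        feature_ids=list(signal.columns),
        center=center,
        scale=scale,
        components=V,
        n_pc=n_pc,
        class_labels=class_labels,
        class_means=means,
        cov_reg=Sreg,
        axes=axes,
        gamma=gamma,
        cv_accuracy_=best,
        cv_confusion_=ConfusionMatrix.from_labels(list(y), preds[n_pc]),
        grid_accuracies_=accs,
        training_scores_=Z @ axes,
    )
    return model


def pca_lda_predict(model: PcaLdaModel, signal: pd.DataFrame) -> tuple[list[str], np.ndarray]:
    """Classify new samples; returns (labels, discriminant coordinates)."""
    Z = model._project(signal)
    labels = _lda_predict(Z, model.class_means, model.cov_reg, model.class_labels)
    return labels, Z @ model.axes
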