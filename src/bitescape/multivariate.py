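"""Correlation-matrix PCA and Fisher linear discriminant analysis.

Both operate on the five per-strike kinematic variables (g, jp, ja,
TTPG, rs).  PCA eigen-decomposes the correlation matrix, so it is
invariant to affine rescaling of any variable; LDA uses pooled
within-class and between-class scatter and classifies by the nearest
class mean in discriminant space, so its accuracy is invariant to
invertible linear transforms of the feature space.  Rows with any
missing value are dropped listwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg

from .errors import FitError, ValidationError
from .kinematics import KINEMATIC_COLUMNS

log = logging.getLogger(__name__)


@dataclass
class PCAResult:
    loadings: pd.DataFrame  # variables x components
    variance_fraction: np.ndarray
    scores: np.ndarray  # strikes x components

    @property
    def n_components(self) -> int:
        return len(self.variance_fraction)


@dataclass
class LDAResult:
    grouping: str
    axes: pd.DataFrame  # variables x discriminants
    scores: np.ndarray
    predicted: np.ndarray
    classification_accuracy: float
    confusion: pd.DataFrame
    classes: list


def _complete_matrix(table: pd.DataFrame, columns) -> tuple[np.ndarray, np.ndarray]:
    sub = table[list(columns)]
    keep = sub.notna().all(axis=1).to_numpy()
    dropped = int((~keep).sum())
    if dropped:
        log.info("dropping %d rows with missing kinematic values", dropped)
    return sub.to_numpy(dtype=float)[keep], keep


def pca_correlation(table: pd.DataFrame, columns=KINEMATIC_COLUMNS) -> PCAResult:
    """PCA from the correlation matrix of the kinematic variables.

    Components are ordered by decreasing variance; each loading vector's
    largest-magnitude entry is made positive (sign convention).  Scores
    are the standardized variables projected on the loadings.
    """
    X, _ = _complete_matrix(table, columns)
    if X.shape[0] < 2:
        raise ValidationError("need at least 2 complete rows for PCA")
    sd = X.std(axis=0, ddof=1)
    for name, s in zip(columns, sd):
        if s == 0 or not np.isfinite(s):
            raise ValidationError(f"variable {name!r} has zero variance")
    R = np.corrcoef(X, rowvar=False)
    eigval, eigvec = np.linalg.eigh(R)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0, None)
    eigvec = eigvec[:, order]
    for j in range(eigvec.shape[1]):
        i = np.argmax(np.abs(eigvec[:, j]))
        if eigvec[i, j] < 0:
            eigvec[:, j] = -eigvec[:, j]
    Z = (X - X.mean(axis=0)) / sd
    return PCAResult(
        loadings=pd.DataFrame(
            eigvec,
            index=list(columns),
            columns=[f"PC{i + 1}" for i in range(len(columns))],
        ),
        variance_fraction=eigval / eigval.sum(),
        scores=Z @ eigvec,
    )


def _fisher_axes(X, y, classes, ridge):
    p = X.shape[1]
    grand = X.mean(axis=0)
    Sw = np.zeros((p, p))
    Sb = np.zeros((p, p))
    for c in classes:
        Xc = X[y == c]
        mu = Xc.mean(axis=0)
        d = Xc - mu
        Sw += d.T @ d
        m = (mu - grand)[:, None]
        Sb += len(Xc) * (m @ m.T)
    if ridge:
        Sw = Sw + ridge * np.trace(Sw) / p * np.eye(p)
    try:
        eigval, eigvec = scipy.linalg.eigh(Sb, Sw)
    except scipy.linalg.LinAlgError as exc:
        raise FitError(
            "singular within-class scatter; pass a positive ridge"
        ) from exc
    order = np.argsort(eigval)[::-1][: len(classes) - 1]
    return eigvec[:, order]


def lda_classify(
    table: pd.DataFrame,
    grouping: str,
    columns=KINEMATIC_COLUMNS,
    ridge: float = 0.0,
    leave_one_out: bool = False,
) -> LDAResult:
    """Fisher LDA of strikes grouped by species or strike type.

    Classification assigns each strike to the nearest class mean in the
    discriminant space; accuracy is the resubstitution fraction correct
    (or leave-one-out if requested).
    """
    X, keep = _complete_matrix(table, columns)
    y = table[grouping].astype(str).to_numpy()[keep]
    classes = sorted(pd.unique(y))
    if len(classes) < 2:
        raise ValidationError("need at least 2 classes")
    for c in classes:
        if (y == c).sum() < 2:
            raise ValidationError(f"class {c!r} has fewer than 2 rows")

    def _predict_with(train_idx, test_idx):
        W = _fisher_axes(X[train_idx], y[train_idx], classes, ridge)
        Z = X @ W
        means = {c: Z[train_idx][y[train_idx] == c].mean(axis=0) for c in classes}
        out = []
        for i in test_idx:
            d = {c: np.sum((Z[i] - means[c]) ** 2) for c in classes}
            out.append(min(d, key=d.get))
        return W, Z, np.array(out)

    n = len(y)
    every = np.arange(n)
    if leave_one_out:
        preds = []
        for i in range(n):
            _, _, p_i = _predict_with(np.delete(every, i), [i])
            preds.append(p_i[0])
        predicted = np.array(preds)
        W, Z, _ = _predict_with(every, [])
    else:
        W, Z, predicted = _predict_with(every, every)

    acc = float((predicted == y).mean())
    confusion = pd.crosstab(
        pd.Series(y, name="true"), pd.Series(predicted, name="predicted")
    ).reindex(index=classes, columns=classes, fill_value=0)
    return LDAResult(
        grouping=grouping,
        axes=pd.DataFrame(
            W,
            index=list(columns),
            columns=[f"LD{i + 1}" for i in range(W.shape[1])],
        ),
        scores=Z,
        predicted=predicted,
        classification_accuracy=acc,
        confusion=confusion,
        classes=classes,
    )
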