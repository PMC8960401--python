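"""Canonical discriminant analysis (CDA) over the nine network parameters.

CDA finds linear combinations of the input variables (canonical functions)
that maximize between-group relative to pooled within-group scatter. For
``g`` groups and ``p`` variables it yields ``min(g - 1, p)`` functions: the
eigenvectors of ``W^{-1} B``, where ``W`` is the pooled within-group and
``B`` the between-group scatter matrix. Following the convention of the
classical statistics packages, coefficients are scaled so canonical scores
have unit pooled within-group variance, scores are centered on the grand
centroid, and the *structure matrix* reports the pooled within-group
correlation of every variable with every canonical function — the quantity
used to rank which parameters drive group separation.

The analysis here is descriptive (score plots, centroids, structure
matrix); no classification step or prior probabilities are involved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg

__all__ = ["DiscriminantResult", "canonical_discriminant"]

logger = logging.getLogger(__name__)


@dataclass
class DiscriminantResult:
    """Output of :func:`canonical_discriminant`.

    Attributes
    ----------
    coefficients:
        (variables x functions) canonical weights, scaled to unit pooled
        within-group score variance.
    scores:
        (observations x functions) canonical scores, grand centroid at the
        origin; indexed like the (non-dropped) input rows.
    eigenvalues:
        Eigenvalues of ``W^{-1} B``, descending.
    canonical_correlations:
        ``sqrt(lambda / (1 + lambda))`` per function.
    structure_matrix:
        (variables x functions) pooled within-group correlations.
    centroids:
        (groups x functions) mean canonical score per group.
    """

    variables: list[str]
    groups: list
    coefficients: np.ndarray
    scores: np.ndarray
    score_labels: np.ndarray
    eigenvalues: np.ndarray
    canonical_correlations: np.ndarray
    structure_matrix: np.ndarray
    centroids: np.ndarray
    n_dropped: int

    def structure_frame(self) -> pd.DataFrame:
        cols = [f"function_{k + 1}" for k in range(self.structure_matrix.shape[1])]
        return pd.DataFrame(self.structure_matrix, index=self.variables, columns=cols)

    def scores_frame(self) -> pd.DataFrame:
        cols = [f"function_{k + 1}" for k in range(self.scores.shape[1])]
        df = pd.DataFrame(self.scores, columns=cols)
        df.insert(0, "group", self.score_labels)
        return df


def canonical_discriminant(
    feature_table: pd.DataFrame | np.ndarray,
    labels,
    variables: list[str] | None = None,
    regularization: float = 0.0,
) -> DiscriminantResult:
    """Run canonical discriminant analysis on a wells x parameters table.

    Rows containing missing values (e.g. NBD of wells without network
    bursts) are dropped; the count is logged and reported. Requires at
    least two groups with at least two rows each.

    ``regularization`` adds a ridge term ``reg * mean(diag(S_w)) * I`` to
    the pooled within-group covariance, for tables where it is singular
    (collinear variables); the error raised in that case says so.
    """
    if isinstance(feature_table, pd.DataFrame):
        if variables is None:
            variables = [
                c for c in feature_table.columns
                if pd.api.types.is_numeric_dtype(feature_table[c])
            ]
        X = feature_table[variables].to_numpy(dtype=float)
    else:
        X = np.asarray(feature_table, dtype=float)
        if variables is None:
            variables = [f"x{j}" for j in range(X.shape[1])]
    y = np.asarray(labels)
    if len(y) != len(X):
        raise ValueError("labels and feature rows must align")

    keep = ~np.isnan(X).any(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropping %d rows with missing values", n_dropped)
    X, y = X[keep], y[keep]

    group_names = list(pd.unique(y))
    g = len(group_names)
    if g < 2:
        raise ValueError("canonical discriminant analysis needs at least 2 groups")
    n, p = X.shape
    counts = {gr: int((y == gr).sum()) for gr in group_names}
    small = [gr for gr, c in counts.items() if c < 2]
    if small:
        raise ValueError(f"groups need at least 2 wells each; too small: {small}")

    grand = X.mean(axis=0)
    W = np.zeros((p, p))
    B = np.zeros((p, p))
    for gr in group_names:
        Xg = X[y == gr]
        mg = Xg.mean(axis=0)
        C = Xg - mg
        W += C.T @ C
        d = (mg - grand)[:, None]
        B += len(Xg) * (d @ d.T)

    S_w = W / (n - g)  # pooled within-group covariance
    if regularization > 0:
        S_w = S_w + regularization * np.mean(np.diag(S_w)) * np.eye(p)
        W = S_w * (n - g)

    try:
        evals, evecs = linalg.eigh(B, W)
    except linalg.LinAlgError as err:
        raise ValueError(
            "pooled within-group scatter is singular; remove collinear "
            "variables or pass regularization > 0"
        ) from err

    order = np.argsort(evals)[::-1]
    n_func = min(g - 1, p)
    evals = np.clip(evals[order][:n_func], 0.0, None)
    A = evecs[:, order][:, :n_func]

    # scale: unit pooled within-group variance of each canonical score
    for k in range(n_func):
        v = float(A[:, k] @ S_w @ A[:, k])
        if v > 0:
            A[:, k] /= np.sqrt(v)

    # structure matrix: pooled within-group correlation variable <-> score
    sd_w = np.sqrt(np.diag(S_w))
    structure = (S_w @ A) / sd_w[:, None]

    # sign convention: largest-magnitude loading of each function positive
    for k in range(n_func):
        j = int(np.argmax(np.abs(structure[:, k])))
        if structure[j, k] < 0:
            A[:, k] *= -1
            structure[:, k] *= -1

    scores = (X - grand) @ A
    centroids = np.vstack([scores[y == gr].mean(axis=0) for gr in group_names])
    canon_corr = np.sqrt(evals / (1.0 + evals))

    return DiscriminantResult(
        variables=list(variables),
        groups=group_names,
        coefficients=A,
        scores=scores,
        score_labels=y,
        eigenvalues=evals,
        canonical_correlations=canon_corr,
        structure_matrix=structure,
        centroids=centroids,
        n_dropped=n_dropped,
    )
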