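"""Principal component analysis of samples for cluster comparison.

Samples are projected onto 'super genes' — linear combinations of probe-set
expression values capturing maximal variance. Probe-set rows are centered
across samples (no unit-variance scaling by default, the common practice
for expression PCA); signs are fixed deterministically so scores are
reproducible: the largest-magnitude loading of each component is positive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .containers import ExpressionMatrix
from .errors import InputError

__all__ = ["PCAResult", "pca_samples"]

logger = logging.getLogger(__name__)


@dataclass
class PCAResult:
    scores: pd.DataFrame             # samples x components
    variance_explained: np.ndarray   # per component fraction
    loadings: pd.DataFrame           # probe sets x components
    n_rows_dropped: int = 0


def pca_samples(
    expr: ExpressionMatrix,
    n_components: int | None = None,
    scale: bool = False,
) -> PCAResult:
    """PCA of samples over probe-set expression.

    Rows with missing values are dropped (count reported on the result).
    ``n_components`` larger than min(n_samples, n_probe_sets) is clipped
    with a warning. Set ``scale=True`` to divide each centered row by its
    standard deviation before decomposition.
    """
    values = expr.values.dropna(axis=0, how="any")
    n_dropped = expr.values.shape[0] - values.shape[0]
    if values.shape[1] < 2:
        raise InputError("pca_samples needs >= 2 samples")
    X = values.to_numpy(float)
    if scale:
        sd = X.std(axis=1, ddof=1)
        keep = sd > 0
        if not keep.all():
            logger.warning("dropping %d constant rows before scaling", int((~keep).sum()))
        values = values.loc[keep]
        X = (X[keep] - X[keep].mean(axis=1, keepdims=True)) / sd[keep][:, None]

    max_k = min(X.shape)
    k = max_k if n_components is None else int(n_components)
    if k > max_k:
        logger.warning("n_components=%d clipped to %d", k, max_k)
        k = max_k

    # samples as observations, probe sets as features; PCA centers features,
    # which is exactly row-centering of the expression matrix
    pca = PCA(n_components=max_k, svd_solver="full")
    scores = pca.fit_transform(X.T)  # n_samples x max_k
    loadings = pca.components_.T     # n_probe_sets x max_k

    for c in range(loadings.shape[1]):
        j = int(np.argmax(np.abs(loadings[:, c])))
        if loadings[j, c] < 0:
            loadings[:, c] *= -1.0
            scores[:, c] *= -1.0

    cols = [f"PC{i + 1}" for i in range(k)]
    return PCAResult(
        scores=pd.DataFrame(scores[:, :k], index=values.columns, columns=cols),
        variance_explained=pca.explained_variance_ratio_[:k].copy(),
        loadings=pd.DataFrame(loadings[:, :k], index=values.index, columns=cols),
        n_rows_dropped=n_dropped,
    )
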