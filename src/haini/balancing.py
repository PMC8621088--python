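"""Minority-class oversampling for the multiclass training set.

The default method is SMOTE: each synthetic sample is a convex
combination ``x + u * (x_nn - x)``, ``u ~ U(0, 1)``, of a minority-class
row and one of its ``k`` nearest same-class neighbours, so synthetic
rows stay inside the convex hull (and hence the bounding box) of their
class.  ``duplicate`` does plain random oversampling with replacement.
Balancing must only ever see training rows — the pipeline applies it
after the train/test split and feature selection.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

logger = logging.getLogger(__name__)


def smote_balance(
    X,
    y,
    k_neighbors: int = 5,
    seed: int = 0,
    method: str = "smote",
):
    """Oversample every class up to the majority count.

    Parameters
    ----------
    X : DataFrame or 2-D array
        feature rows; original rows are preserved verbatim and come
        first in the output, in their input order.
    y : 1-D array-like
        class labels, every class with at least one sample.
    k_neighbors
        SMOTE neighbourhood size; automatically reduced to
        ``class size - 1`` for small classes.  A single-sample class
        cannot be interpolated and falls back to duplication with a
        warning.
    method
        ``"smote"`` (interpolation) or ``"duplicate"`` (random
        oversampling with replacement).

    Returns ``(X', y')`` of the same container type as ``X``.
    """
    if method not in ("smote", "duplicate"):
        raise ValueError(f"unknown oversampling method {method!r}")
    is_frame = isinstance(X, pd.DataFrame)
    columns = X.columns if is_frame else None
    Xa = X.to_numpy(dtype=float) if is_frame else np.asarray(X, dtype=float)
    ya = np.asarray(y)
    if len(Xa) != len(ya):
        raise ValueError("X and y length mismatch")
    rng = np.random.default_rng(seed)
    classes, counts = np.unique(ya, return_counts=True)
    target = counts.max()
    new_X, new_y = [], []
    for cls, count in zip(classes, counts):
        need = int(target - count)
        if need == 0:
            continue
        Xc = Xa[ya == cls]
        if method == "duplicate" or count == 1:
            if method == "smote" and count == 1:
                logger.warning(
                    "class %r has a single sample; duplicating instead of SMOTE", cls)
            idx = rng.integers(0, count, size=need)
            synth = Xc[idx]
        else:
            k = min(k_neighbors, count - 1)
            nn = NearestNeighbors(n_neighbors=k + 1).fit(Xc)
            _, neigh = nn.kneighbors(Xc)  # column 0 is the point itself
            base = rng.integers(0, count, size=need)
            pick = rng.integers(1, k + 1, size=need)
            partner = neigh[base, pick]
            u = rng.random(size=(need, 1))
            synth = Xc[base] + u * (Xc[partner] - Xc[base])
        new_X.append(synth)
        new_y.append(np.full(need, cls, dtype=ya.dtype))
    if not new_X:
        X_out, y_out = Xa.copy(), ya.copy()
    else:
        X_out = np.vstack([Xa] + new_X)
        y_out = np.concatenate([ya] + new_y)
    if is_frame:
        X_out = pd.DataFrame(X_out, columns=columns)
    return X_out, y_out
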