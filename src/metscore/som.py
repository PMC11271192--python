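"""Kohonen self-organizing map of individuals with Ward cell grouping.

A batch SOM arranges samples on a small rectangular grid of codebook
vectors so neighbouring cells hold metabolically similar individuals:
each epoch assigns every sample to its best-matching unit (BMU, nearest
codebook by Euclidean distance) and recomputes codebooks as
neighbourhood-weighted means, with a Gaussian neighbourhood whose radius
decays over epochs.  With the radius shrunk to (near) zero the update is
exactly Lloyd's k-means step, whose mean squared quantization error is
monotonically non-increasing — the property the tests check.

The trained codebooks are then agglomerated with Ward linkage (the
variance-minimising Ward.D2 criterion on Euclidean distances) and the
tree is cut into k groups (default 6), which draw the thick boundaries
on the map.  Per-cell statistics (sample count, fraction with metabolic
syndrome, mean risk score) colour the map.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted


def default_grid_shape(n_samples: int) -> tuple[int, int]:
    """Near-square grid with about ``5 * sqrt(n)`` cells."""
    cells = max(4, int(np.ceil(5.0 * np.sqrt(n_samples))))
    rows = int(np.floor(np.sqrt(cells)))
    cols = int(np.ceil(cells / rows))
    return rows, cols


class SelfOrganizingMap(BaseEstimator, TransformerMixin):
    """Batch Kohonen map on a rectangular grid with Gaussian neighbourhood.

    Parameters
    ----------
    rows, cols : grid shape; defaults to the ~5*sqrt(n)-cells heuristic.
    epochs : number of batch passes.
    sigma_start, sigma_end : neighbourhood radius schedule (grid units);
        defaults decay from half the larger grid dimension to 0.5.
    random_state : seed for the sample-based codebook initialisation.

    Attributes
    ----------
    codebook_ : (n_cells, n_features) codebook vectors
    grid_ : (n_cells, 2) integer (row, col) coordinates
    bmu_ : best-matching cell index per training sample
    quantization_errors_ : mean squared sample-to-BMU deviation per
        epoch (the quantity Lloyd's step decreases monotonically once
        the neighbourhood has shrunk)
    cell_group_ : group id per cell (after :meth:`group_cells`)
    """

    def __init__(self, rows: int | None = None, cols: int | None = None,
                 epochs: int = 20, sigma_start: float | None = None,
                 sigma_end: float = 0.5, random_state: int = 0):
        self.rows = rows
        self.cols = cols
        self.epochs = epochs
        self.sigma_start = sigma_start
        self.sigma_end = sigma_end
        self.random_state = random_state

    def _bmus(self, X: np.ndarray) -> np.ndarray:
        d2 = ((X[:, None, :] - self.codebook_[None, :, :]) ** 2).sum(axis=2)
        return d2.argmin(axis=1)

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.size == 0:
            raise ValueError("X must be a non-empty 2D array")
        n, p = X.shape
        rows, cols = self.rows, self.cols
        if rows is None or cols is None:
            rows, cols = default_grid_shape(n)
        n_cells = rows * cols
        if n < n_cells:
            raise ValueError(
                f"need at least as many samples ({n}) as cells ({n_cells})")
        rng = np.random.default_rng(self.random_state)
        self.rows_, self.cols_ = rows, cols
        self.grid_ = np.array([(r, c) for r in range(rows) for c in range(cols)])
        init_idx = rng.choice(n, size=n_cells, replace=False)
        self.codebook_ = X[init_idx].copy()

        sigma0 = self.sigma_start
        if sigma0 is None:
            sigma0 = max(rows, cols) / 2.0
        sigma1 = self.sigma_end
        grid_d2 = ((self.grid_[:, None, :] - self.grid_[None, :, :]) ** 2
                   ).sum(axis=2).astype(float)

        self.quantization_errors_ = []
        for epoch in range(self.epochs):
            frac = epoch / max(self.epochs - 1, 1)
            sigma = sigma0 * (sigma1 / sigma0) ** frac if sigma0 > 0 else sigma1
            bmu = self._bmus(X)
            qe = float(((X - self.codebook_[bmu]) ** 2).sum(axis=1).mean())
            self.quantization_errors_.append(qe)
            h = np.exp(-grid_d2 / (2.0 * sigma**2))  # (cell, cell)
            h[h < 1e-12] = 0.0
            weights = h[:, bmu]                      # (cell, sample)
            denom = weights.sum(axis=1)
            numer = weights @ X
            update = denom > 0
            self.codebook_[update] = numer[update] / denom[update, None]
        self.bmu_ = self._bmus(X)
        self.quantization_errors_ = np.array(self.quantization_errors_)
        return self

    def transform(self, X) -> np.ndarray:
        """BMU cell index per sample."""
        check_is_fitted(self, "codebook_")
        return self._bmus(np.asarray(X, dtype=float))

    predict = transform

    def quantization_error(self, X) -> float:
        check_is_fitted(self, "codebook_")
        X = np.asarray(X, dtype=float)
        bmu = self._bmus(X)
        return float(np.sqrt(((X - self.codebook_[bmu]) ** 2).sum(axis=1)).mean())

    def group_cells(self, k: int = 6) -> np.ndarray:
        """Ward-cluster the codebook vectors into exactly k cell groups."""
        check_is_fitted(self, "codebook_")
        n_cells = self.codebook_.shape[0]
        if k > n_cells:
            raise ValueError(f"requested {k} groups for {n_cells} cells")
        if k == n_cells:
            self.cell_group_ = np.arange(1, n_cells + 1)
            return self.cell_group_
        link = hierarchy.linkage(self.codebook_, method="ward")
        self.cell_group_ = hierarchy.fcluster(link, t=k, criterion="maxclust")
        return self.cell_group_


def fit_som(X, rows: int | None = None, cols: int | None = None,
            epochs: int = 20, seed: int = 0) -> SelfOrganizingMap:
    """Functional wrapper over :class:`SelfOrganizingMap`."""
    return SelfOrganizingMap(rows=rows, cols=cols, epochs=epochs,
                             random_state=seed).fit(X)


def group_cells(som: SelfOrganizingMap, k: int = 6) -> np.ndarray:
    return som.group_cells(k)


def cell_statistics(som: SelfOrganizingMap, labels, scores=None) -> pd.DataFrame:
    """Per-cell sample count, MetS fraction and mean score.

    ``labels`` are the binary MetS calls aligned with the training
    samples; ``scores`` (optional) a per-sample risk score.  Empty cells
    are flagged and carry NaN statistics.
    """
    check_is_fitted(som, "bmu_")
    labels = np.asarray(labels).ravel()
    if labels.size != som.bmu_.size:
        raise ValueError("labels not aligned with the fitted samples")
    if scores is not None:
        scores = np.asarray(scores, dtype=float).ravel()
        if scores.size != som.bmu_.size:
            raise ValueError("scores not aligned with the fitted samples")
    groups = getattr(som, "cell_group_", np.zeros(som.codebook_.shape[0], int))
    rows = []
    for cell in range(som.codebook_.shape[0]):
        members = som.bmu_ == cell
        count = int(members.sum())
        rows.append({
            "cell": cell,
            "row": int(som.grid_[cell, 0]),
            "col": int(som.grid_[cell, 1]),
            "group": int(groups[cell]),
            "count": count,
            "empty": count == 0,
            "mets_fraction": float(labels[members].mean()) if count else np.nan,
            "mean_score": (float(scores[members].mean())
                           if (scores is not None and count) else np.nan),
        })
    return pd.DataFrame(rows)
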