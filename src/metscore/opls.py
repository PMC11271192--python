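"""Orthogonal PLS discriminant analysis (1 predictive + n orthogonal components).

O-PLS-DA separates the part of X that covaries with a binary class label
from structured variation orthogonal to it.  The orthogonal-signal-
correction scheme implemented here is the standard one: compute the PLS
weight ``w`` from the centred response, split each loading into its
component along ``w`` and the remainder, use the remainder as an
orthogonal weight, deflate X by that orthogonal component, and refit the
predictive component on the filtered matrix.  With a single response
column the weight step is closed-form (``w = X'y / ||X'y||``), so no
iteration is needed; the predictive score ``t_pred`` is the model's
measure of progression toward the positive class.

Preprocessing follows metabolomics convention for concentration data: a
log transform (offset-shifted where zeros occur) followed by autoscaling
(per-variable centring and unit-SD scaling) with parameters learned on
the training set and frozen for projection.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

_TOL = 1e-10


def _as_matrix(X, variables=None):
    if isinstance(X, pd.DataFrame):
        if variables is not None:
            missing = [v for v in variables if v not in X.columns]
            if missing:
                raise ValueError(f"missing model variables: {missing}")
            X = X[list(variables)]
        return X.to_numpy(dtype=float), list(X.columns)
    arr = np.asarray(X, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    names = [f"x{j}" for j in range(arr.shape[1])] if variables is None \
        else list(variables)
    return arr, names


def compute_log_offsets(X: np.ndarray) -> np.ndarray:
    """Per-variable offsets for the log transform.

    Zero when a variable is strictly positive; half its smallest positive
    value when zeros occur (so log arguments stay positive).
    """
    if np.any(X < 0):
        raise ValueError("concentration inputs must be nonnegative")
    offsets = np.zeros(X.shape[1])
    for j in range(X.shape[1]):
        col = X[:, j]
        if np.any(col == 0):
            positive = col[col > 0]
            if positive.size == 0:
                raise ValueError(f"variable column {j} is all zero")
            offsets[j] = positive.min() / 2.0
    return offsets


def preprocess(X: np.ndarray, offsets: np.ndarray,
               center: np.ndarray | None = None,
               scale: np.ndarray | None = None):
    """log(x + offset) then autoscale; fits center/scale when not given.

    Returns (Z, center, scale).  Applying stored parameters to the
    training data reproduces the training matrix exactly.
    """
    if np.any(X < 0):
        raise ValueError("concentration inputs must be nonnegative")
    L = np.log(X + offsets[None, :])
    if center is None:
        center = L.mean(axis=0)
        scale = L.std(axis=0, ddof=1)
        if np.any(~np.isfinite(scale)) or np.any(scale <= 0):
            bad = np.where(~(scale > 0))[0]
            raise ValueError(
                f"zero variance after log transform in columns {bad.tolist()}")
    return (L - center[None, :]) / scale[None, :], center, scale


class OplsDiscriminant(BaseEstimator, TransformerMixin):
    """O-PLS-DA for a binary class, scikit-learn style.

    Parameters
    ----------
    n_orth : int
        Number of orthogonal components to strip (default 1).
    log_transform : bool
        Apply the offset log transform before autoscaling.  Disable when
        the input is already on a transformed scale.

    Attributes (after :meth:`fit`)
    ------------------------------
    variables_ : list of input variable names
    offsets_, center_, scale_ : preprocessing parameters
    w_ : unit-norm predictive weight vector
    p_ : predictive loading vector
    w_orth_, p_orth_ : (n_orth, p) orthogonal weights / loadings
    c_ : response loading
    t_pred_, t_orth_ : training scores
    """

    def __init__(self, n_orth: int = 1, log_transform: bool = True,
                 max_iter: int = 500, tol: float = _TOL):
        self.n_orth = n_orth
        self.log_transform = log_transform
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, y):
        Xm, names = _as_matrix(X)
        y = np.asarray(y, dtype=float).ravel()
        classes = np.unique(y)
        if classes.size != 2:
            raise ValueError(
                f"O-PLS-DA needs exactly two classes, got {classes.tolist()}")
        if Xm.shape[0] != y.size:
            raise ValueError("X and y have different lengths")
        if Xm.shape[0] < self.n_orth + 3:
            raise ValueError("too few samples for the requested components")
        # encode as 0/1 and centre
        yb = (y == classes.max()).astype(float)
        yc = yb - yb.mean()

        if self.log_transform:
            offsets = compute_log_offsets(Xm)
            Z, center, scale = preprocess(Xm, offsets)
        else:
            offsets = np.zeros(Xm.shape[1])
            center = Xm.mean(axis=0)
            scale = Xm.std(axis=0, ddof=1)
            if np.any(~(scale > 0)):
                raise ValueError("zero-variance input column")
            Z = (Xm - center) / scale

        w_orth_list, p_orth_list, t_orth_list = [], [], []
        Zf = Z.copy()
        for _ in range(self.n_orth):
            w = Zf.T @ yc
            nw = np.linalg.norm(w)
            if nw < self.tol:
                raise ValueError("response carries no covariance with X")
            w /= nw
            t = Zf @ w
            p = Zf.T @ t / (t @ t)
            w_o = p - (w @ p) * w
            n_o = np.linalg.norm(w_o)
            if n_o < 1e-8:  # no orthogonal structured variation left
                break
            w_o /= n_o
            t_o = Zf @ w_o
            p_o = Zf.T @ t_o / (t_o @ t_o)
            Zf = Zf - np.outer(t_o, p_o)
            w_orth_list.append(w_o)
            p_orth_list.append(p_o)
            t_orth_list.append(t_o)

        w = Zf.T @ yc
        w /= np.linalg.norm(w)
        t = Zf @ w
        if t @ yc < 0:  # t_pred positively associated with class 1
            w, t = -w, -t
        p = Zf.T @ t / (t @ t)
        c = (yc @ t) / (t @ t)

        self.variables_ = names
        self.classes_ = classes
        self.offsets_, self.center_, self.scale_ = offsets, center, scale
        self.w_, self.p_, self.c_ = w, p, float(c)
        self.w_orth_ = (np.vstack(w_orth_list) if w_orth_list
                        else np.zeros((0, Z.shape[1])))
        self.p_orth_ = (np.vstack(p_orth_list) if p_orth_list
                        else np.zeros((0, Z.shape[1])))
        self.t_pred_ = t
        self.t_orth_ = (np.column_stack(t_orth_list) if t_orth_list
                        else np.zeros((Z.shape[0], 0)))
        return self

    def _preprocess_new(self, X) -> np.ndarray:
        Xm, _ = _as_matrix(X, self.variables_)
        if self.log_transform:
            Z, _, _ = preprocess(Xm, self.offsets_, self.center_, self.scale_)
        else:
            Z = (Xm - self.center_) / self.scale_
        return Z

    def transform(self, X):
        """(t_pred, t_orth) for new raw samples."""
        check_is_fitted(self, "w_")
        Zf = self._preprocess_new(X)
        t_orth = np.zeros((Zf.shape[0], self.w_orth_.shape[0]))
        for k in range(self.w_orth_.shape[0]):
            t_o = Zf @ self.w_orth_[k]
            Zf = Zf - np.outer(t_o, self.p_orth_[k])
            t_orth[:, k] = t_o
        return Zf @ self.w_, t_orth

    def decision_function(self, X) -> np.ndarray:
        return self.transform(X)[0]

    def predict(self, X) -> np.ndarray:
        """Class call at t_pred > 0 (use the calibrated threshold downstream)."""
        return (self.decision_function(X) > 0).astype(int)

    def variable_influence(self) -> pd.DataFrame:
        """Signed influence per variable, ranked by |predictive loading|.

        The magnitude of the predictive loading measures how much a
        variable contributes to the discriminant direction; its sign says
        whether the variable is elevated (positive) or reduced in the
        positive class.
        """
        check_is_fitted(self, "w_")
        table = pd.DataFrame({
            "variable": self.variables_,
            "influence": self.p_,
            "sign": np.sign(self.p_).astype(int),
        })
        return (table.reindex(table["influence"].abs()
                              .sort_values(ascending=False).index)
                .reset_index(drop=True))


def fit_oplsda(X, y, n_orth: int = 1, log_transform: bool = True) -> OplsDiscriminant:
    """Functional wrapper over :class:`OplsDiscriminant`."""
    return OplsDiscriminant(n_orth=n_orth, log_transform=log_transform).fit(X, y)


def project(model: OplsDiscriminant, X):
    """Scores (t_pred, t_orth) of new samples under a fitted model."""
    return model.transform(X)


def variable_influence(model: OplsDiscriminant) -> pd.DataFrame:
    return model.variable_influence()
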