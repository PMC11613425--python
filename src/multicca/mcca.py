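"""Regularized multi-set canonical correlation analysis (SUMCOR form).

Given K aligned data matrices ``X_i`` (samples x features, standardized),
the model finds, for each component ``a``, one weight vector per view
maximizing the sum of pairwise cross-products between projected views::

    maximize   sum_i sum_{j != i}  w_ia' X_i' X_j w_ja
    subject to (1 - c_i) w_ia' X_i' X_i w_ia + c_i w_ia' w_ia = 1
               w_ia' X_i' X_i w_ib = 0   for all b < a, per view

With ``c_i = 0`` the constraint fixes each canonical variate's norm, so
the objective is exactly the sum of pairwise canonical correlations; at
``c_i = 1`` it degenerates to unit-norm weights and the solver maximizes
summed cross-covariances instead.  The per-view ridge term makes the
problem well posed when a view has more features than samples.

Solver
------
Components are extracted sequentially.  For each component the pooled
generalized eigenproblem ``C w = lambda B w`` (C: off-diagonal blocks
``X_i' X_j``; B: block-diagonal ``(1-c_i) X_i' X_i + c_i I``) provides a
deterministic starting point, which is then refined by Horst-style
alternating maximization — each view's weight is updated in closed form
holding the others fixed — until the objective stabilizes.  For two views
the eigenproblem is already exact and the refinement is a no-op up to
round-off; for K > 2 the refinement enforces the per-view constraints
exactly rather than in the pooled relaxation.  Cross-component
orthogonality is imposed by restricting each later component to the null
space of the earlier constraint vectors ``X_i' X_i w_ib`` within each view.

Canonical weight vectors are sign-indeterminate.  The gauge is fixed by
making the largest-magnitude entry of the first view's weight vector
positive, then flipping each remaining view so its training variate
correlates non-negatively with the first view's — per-view flips done
independently could silently negate cross-view correlations.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

__all__ = ["MultisetCCA", "fit_mcca", "project", "objective_value",
           "standardize_fit", "standardize_apply"]


def _as_matrix(view) -> tuple[np.ndarray, list[str] | None]:
    if isinstance(view, pd.DataFrame):
        return view.to_numpy(dtype=float), [str(c) for c in view.columns]
    x = np.asarray(view, dtype=float)
    if x.ndim != 2:
        raise ValueError("each view must be a 2-D samples x features matrix")
    return x, None


class MultisetCCA(BaseEstimator):
    """Multi-set CCA estimator over K >= 2 aligned views.

    Parameters
    ----------
    n_components : int
        Number of component sets m to extract.
    c : float or sequence of float
        Per-view regularization in [0, 1] blending the variate-norm
        constraint (c=0, correlation maximization) with a unit weight-norm
        constraint (c=1, covariance maximization).  A scalar is shared
        across views.  ``c_i > 0`` is required whenever a view has at
        least as many features as samples.
    scale : bool
        Standardize each feature (train mean 0, SD 1) before fitting;
        test data is transformed with the training parameters.
        Zero-variance features are dropped with a warning.
    max_iter, tol : int, float
        Alternating-maximization stopping rule per component.

    Attributes
    ----------
    weights_ : list of ndarray, each (n kept features, m)
    c_ : ndarray (K,), means_, scales_ : per-view standardization
    objective_values_ : ndarray (m,), training objective per component
    dropped_features_ : list of list of str, zero-variance columns removed
    """

    def __init__(self, n_components: int = 1,
                 c: float | Sequence[float] = 0.0, scale: bool = True,
                 max_iter: int = 1000, tol: float = 1e-12):
        self.n_components = n_components
        self.c = c
        self.scale = scale
        self.max_iter = max_iter
        self.tol = tol

    # ------------------------------------------------------------------ fit
    def fit(self, views: Sequence, y=None) -> "MultisetCCA":
        mats, names = [], []
        for v in views:
            x, cols = _as_matrix(v)
            mats.append(x)
            names.append(cols)
        K = len(mats)
        if K < 2:
            raise ValueError("need at least two views")
        n = mats[0].shape[0]
        if any(x.shape[0] != n for x in mats):
            raise ValueError("views have differing numbers of rows; "
                             "subjects must be aligned across views")
        if any(np.isnan(x).any() for x in mats):
            raise ValueError("views contain missing values")

        c = np.asarray(self.c, dtype=float)
        if c.ndim == 0:
            c = np.full(K, float(c))
        if c.shape != (K,):
            raise ValueError(f"c must be scalar or length-{K}")
        if np.any((c < 0) | (c > 1)):
            raise ValueError("regularization c must lie in [0, 1]")

        self.n_views_ = K
        self.n_samples_ = n
        self.c_ = c
        self.feature_names_in_ = [
            cols if cols is not None
            else [f"x{i}_{j}" for j in range(x.shape[1])]
            for i, (x, cols) in enumerate(zip(mats, names))]

        # Standardization with zero-variance drop.
        self.means_, self.scales_ = [], []
        self.kept_idx_, self.dropped_features_ = [], []
        Xs = []
        for i, x in enumerate(mats):
            mu = x.mean(axis=0)
            sd = x.std(axis=0)
            keep = sd > 0
            if not keep.all():
                dropped = [self.feature_names_in_[i][j]
                           for j in np.flatnonzero(~keep)]
                warnings.warn(
                    f"view {i}: dropping {len(dropped)} zero-variance "
                    f"feature(s): {dropped[:5]}", UserWarning)
            else:
                dropped = []
            self.dropped_features_.append(dropped)
            self.kept_idx_.append(np.flatnonzero(keep))
            if self.scale:
                self.means_.append(mu[keep])
                self.scales_.append(sd[keep])
                Xs.append((x[:, keep] - mu[keep]) / sd[keep])
            else:
                self.means_.append(np.zeros(int(keep.sum())))
                self.scales_.append(np.ones(int(keep.sum())))
                Xs.append(x[:, keep])

        dims = [x.shape[1] for x in Xs]
        m = int(self.n_components)
        if m < 1:
            raise ValueError("n_components must be positive")
        if m > min(dims) or m > n:
            raise ValueError(
                f"n_components={m} exceeds the smallest view dimension "
                f"({min(dims)}) or the sample count ({n})")
        for i, d in enumerate(dims):
            if c[i] == 0.0 and d >= n:
                raise ValueError(
                    f"view {i} has {d} features for {n} samples; the "
                    "constraint matrix is singular with c=0 — "
                    "regularization c > 0 is required")

        weights, objectives = self._solve(Xs, c, m)
        self._fix_signs(Xs, weights)

        # Order by decreasing training objective; break near-ties (<1e-8)
        # lexicographically on the first view's weights for determinism.
        order = sorted(range(m), key=lambda a: (
            -np.round(objectives[a] / 1e-8) * 1e-8,
            tuple(np.round(weights[0][:, a], 10))))
        self.weights_ = [w[:, order] for w in weights]
        self.objective_values_ = objectives[order]
        return self

    def _solve(self, Xs, c, m):
        K = len(Xs)
        dims = [x.shape[1] for x in Xs]
        weights = [np.zeros((d, m)) for d in dims]
        objectives = np.zeros(m)
        n_iter = np.zeros(m, dtype=int)
        bases = [np.eye(d) for d in dims]  # feasible (orthogonality) subspace

        for a in range(m):
            Y = [x @ nb for x, nb in zip(Xs, bases)]
            M = [(1.0 - c[i]) * (Y[i].T @ Y[i])
                 + c[i] * np.eye(Y[i].shape[1]) for i in range(K)]
            v = self._eig_init(Y, M)
            v, obj, it = self._refine(Y, M, v)
            for i in range(K):
                weights[i][:, a] = bases[i] @ v[i]
            objectives[a] = obj
            n_iter[a] = it
            if a + 1 < m:
                bases = [
                    _nullspace_within(bases[i],
                                      Xs[i].T @ (Xs[i] @ weights[i][:, a]))
                    for i in range(K)]
        self.n_iter_ = n_iter
        return weights, objectives

    @staticmethod
    def _eig_init(Y, M):
        """Leading eigenvector of the pooled problem C v = lambda B v."""
        dims = [y.shape[1] for y in Y]
        off = np.cumsum([0] + dims)
        C = np.zeros((off[-1], off[-1]))
        B = np.zeros_like(C)
        for i, yi in enumerate(Y):
            B[off[i]:off[i + 1], off[i]:off[i + 1]] = M[i]
            for j, yj in enumerate(Y):
                if i != j:
                    C[off[i]:off[i + 1], off[j]:off[j + 1]] = yi.T @ yj
        w = linalg.eigh(C, B, subset_by_index=[off[-1] - 1, off[-1] - 1])[1][:, 0]
        v = []
        for i in range(len(Y)):
            vi = w[off[i]:off[i + 1]]
            nrm = float(vi @ M[i] @ vi)
            if nrm <= 1e-300:  # view absent from the pooled eigenvector
                vi = np.zeros(dims[i])
                vi[0] = 1.0
                nrm = float(vi @ M[i] @ vi)
            v.append(vi / np.sqrt(nrm))
        return v

    def _refine(self, Y, M, v):
        """Alternating maximization under exact per-view constraints."""
        K = len(Y)
        solve = [linalg.cho_factor(Mi) for Mi in M]
        t = [Y[i] @ v[i] for i in range(K)]
        obj = _sumcor(Y, v)
        for it in range(1, self.max_iter + 1):
            for i in range(K):
                u = Y[i].T @ (np.sum(t, axis=0) - t[i])
                vi = linalg.cho_solve(solve[i], u)
                nrm = float(vi @ M[i] @ vi)
                if nrm > 1e-300:
                    v[i] = vi / np.sqrt(nrm)
                    t[i] = Y[i] @ v[i]
            new = _sumcor(Y, v)
            if abs(new - obj) <= self.tol * max(1.0, abs(new)):
                obj = new
                break
            obj = new
        return v, obj, it

    def _fix_signs(self, Xs, weights):
        m = weights[0].shape[1]
        for a in range(m):
            w1 = weights[0][:, a]
            if w1[np.argmax(np.abs(w1))] < 0:
                weights[0][:, a] = -w1
            t1 = Xs[0] @ weights[0][:, a]
            for i in range(1, len(Xs)):
                ti = Xs[i] @ weights[i][:, a]
                if float(t1 @ ti) < 0:
                    weights[i][:, a] = -weights[i][:, a]

    # ------------------------------------------------------------ transform
    def transform(self, views: Sequence) -> list[np.ndarray]:
        """Project views into canonical-variate space with training
        standardization; returns one (n, m) score array per view."""
        check_is_fitted(self, "weights_")
        if len(views) != self.n_views_:
            raise ValueError(
                f"model was fitted on {self.n_views_} views, got {len(views)}")
        scores = []
        for i, v in enumerate(views):
            x, cols = _as_matrix(v)
            if cols is not None:
                expected = [self.feature_names_in_[i][j]
                            for j in self.kept_idx_[i]]
                missing = [f for f in expected if f not in cols]
                if missing:
                    raise ValueError(
                        f"view {i} is missing model features: {missing[:5]}")
                idx = [cols.index(f) for f in expected]
                x = x[:, idx]
            else:
                if x.shape[1] != len(self.feature_names_in_[i]):
                    raise ValueError(
                        f"view {i} has {x.shape[1]} features, expected "
                        f"{len(self.feature_names_in_[i])}")
                x = x[:, self.kept_idx_[i]]
            z = (x - self.means_[i]) / self.scales_[i]
            scores.append(z @ self.weights_[i])
        return scores

    def fit_transform(self, views: Sequence, y=None) -> list[np.ndarray]:
        return self.fit(views).transform(views)

    def objective(self, views: Sequence, component: int) -> float:
        """Objective sum_{i != j} w_ia' X_i' X_j w_ja on standardized data."""
        t = self.transform(views)
        v = [ti[:, component] for ti in t]
        return float(sum(v[i] @ v[j]
                         for i in range(len(v)) for j in range(len(v))
                         if i != j))


def _sumcor(Y, v) -> float:
    t = [Y[i] @ v[i] for i in range(len(Y))]
    s = np.sum(t, axis=0)
    return float(s @ s - sum(ti @ ti for ti in t))


def _nullspace_within(basis: np.ndarray, g: np.ndarray) -> np.ndarray:
    """Shrink an orthonormal basis to the part orthogonal to vector g."""
    gb = basis.T @ g
    nrm = np.linalg.norm(gb)
    if nrm == 0.0:
        return basis
    null = linalg.null_space(gb[None, :] / nrm)
    return basis @ null


# --------------------------------------------------------- thin functional API

def standardize_fit(view: pd.DataFrame) -> dict:
    """Learn per-feature center/scale on training rows; zero-variance
    features are marked dropped."""
    x = view.to_numpy(dtype=float)
    mu, sd = x.mean(axis=0), x.std(axis=0)
    keep = sd > 0
    dropped = [str(c) for c, k in zip(view.columns, keep) if not k]
    if dropped:
        warnings.warn(f"dropping {len(dropped)} zero-variance feature(s): "
                      f"{dropped[:5]}", UserWarning)
    cols = [str(c) for c, k in zip(view.columns, keep) if k]
    return {"features": cols, "mean": mu[keep], "scale": sd[keep],
            "dropped": dropped}


def standardize_apply(params: dict, view: pd.DataFrame) -> pd.DataFrame:
    """Apply training standardization to (possibly new) rows — no
    re-centering on the new data."""
    z = (view[params["features"]].to_numpy(dtype=float)
         - params["mean"]) / params["scale"]
    return pd.DataFrame(z, index=view.index, columns=params["features"])


def _check_aligned(views: Sequence[pd.DataFrame]) -> None:
    frames = [v for v in views if isinstance(v, pd.DataFrame)]
    for v in frames[1:]:
        if not v.index.equals(frames[0].index):
            raise ValueError("views are not aligned on the same subjects; "
                             "align by subject_id before fitting")


def fit_mcca(views: Sequence, c: float | Sequence[float],
             n_components: int, **kwargs) -> MultisetCCA:
    """Fit a :class:`MultisetCCA` on aligned views (DataFrames checked
    for identical subject indices)."""
    _check_aligned(views)
    return MultisetCCA(n_components=n_components, c=c, **kwargs).fit(views)


def project(model: MultisetCCA, views: Sequence) -> list[pd.DataFrame]:
    """Latent scores per view as DataFrames (components cv1..cvm),
    indexed like the input when the input carries an index."""
    _check_aligned(views)
    scores = model.transform(views)
    cols = [f"cv{a + 1}" for a in range(model.n_components)]
    out = []
    for v, s in zip(views, scores):
        idx = v.index if isinstance(v, pd.DataFrame) else None
        out.append(pd.DataFrame(s, index=idx, columns=cols))
    return out


def objective_value(model: MultisetCCA, views: Sequence,
                    component: int) -> float:
    """Training-style objective for one component set on given views."""
    return model.objective(views, component)
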