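"""Data splitting, regularization selection and the component-count rule.

The analysis protocol holds out 20% of subjects, stratified on the
maturation group, before any model fitting; the regularization strength c
is chosen by stratified 3-fold cross-validation inside the training
partition, scoring each candidate by the summed held-out pairwise
canonical correlations; and the number of component sets m is the
smallest number of principal components explaining a target fraction
(default 90%) of the variance of the smallest view.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, train_test_split

from .mcca import MultisetCCA
from .simulate import MultiViewDataset

__all__ = ["SplitSpec", "split_train_test", "make_cv_folds",
           "choose_n_components", "cv_select_c", "DEFAULT_C_GRID"]

logger = logging.getLogger(__name__)

#: 7 log-spaced ridge candidates spanning negligible to covariance-limit
DEFAULT_C_GRID: tuple[float, ...] = tuple(np.logspace(-4, 0, 7))


@dataclass
class SplitSpec:
    train_fraction: float = 0.8
    n_folds: int = 3
    stratify_on: str = "group"
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.n_folds < 2:
            raise ValueError("n_folds must be at least 2")


def split_train_test(dataset: MultiViewDataset, spec: SplitSpec
                     ) -> tuple[MultiViewDataset, MultiViewDataset]:
    """Stratified train/test split over subjects (deterministic per seed).

    Subjects labelled ``excluded`` in the stratification column are left
    out entirely — the two-group analysis never sees them.
    """
    spec.validate()
    meta = dataset.metadata
    strata = meta[spec.stratify_on].astype(str)
    keep = strata != "excluded"
    ids = meta.index[keep]
    strata = strata[keep]
    counts = strata.value_counts()
    if (counts < 2).any():
        bad = counts[counts < 2].index.tolist()
        raise ValueError(f"stratum with fewer than 2 members: {bad}")
    train_ids, test_ids = train_test_split(
        ids, train_size=spec.train_fraction, stratify=strata,
        random_state=spec.seed)
    return dataset.subset(sorted(train_ids)), dataset.subset(sorted(test_ids))


def make_cv_folds(train: MultiViewDataset, spec: SplitSpec
                  ) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified K-fold index pairs (fit_idx, val_idx) over training rows."""
    strata = train.metadata[spec.stratify_on].astype(str).to_numpy()
    skf = StratifiedKFold(n_splits=spec.n_folds, shuffle=True,
                          random_state=spec.seed)
    return [(tr, va) for tr, va in skf.split(np.zeros(len(strata)), strata)]


def choose_n_components(view: pd.DataFrame,
                        variance_threshold: float = 0.90) -> int:
    """Smallest m whose top principal components explain at least the
    threshold fraction of the variance of the standardized view."""
    if not 0.0 < variance_threshold <= 1.0:
        raise ValueError("variance_threshold must lie in (0, 1]")
    x = view.to_numpy(dtype=float)
    sd = x.std(axis=0)
    x = x[:, sd > 0]
    if x.shape[1] == 0:
        raise ValueError("view has no non-constant features")
    z = (x - x.mean(axis=0)) / x.std(axis=0)
    ev = np.linalg.svd(z, compute_uv=False) ** 2
    frac = np.cumsum(ev) / ev.sum()
    return int(np.searchsorted(frac, variance_threshold - 1e-12) + 1)


def _holdout_score(model: MultisetCCA, views_val) -> float:
    """Sum over components and view pairs of held-out correlations."""
    scores = model.transform(views_val)
    K, m = len(scores), scores[0].shape[1]
    total = 0.0
    for a in range(m):
        cols = np.column_stack([s[:, a] for s in scores])
        sd = cols.std(axis=0)
        if np.any(sd == 0):
            continue
        r = np.corrcoef(cols, rowvar=False)
        total += float(r[np.triu_indices(K, k=1)].sum())
    return total


def cv_select_c(train: MultiViewDataset, grid, spec: SplitSpec,
                n_components: int, return_table: bool = False):
    """Pick c from a grid by stratified CV on the training partition.

    Each candidate is fitted on n_folds-1 folds and scored on the held-out
    fold by the summed pairwise canonical correlations across all
    component sets; the argmax is returned, ties going to the smaller c.
    """
    grid = sorted(float(g) for g in grid)
    if not grid:
        raise ValueError("candidate grid is empty")
    folds = make_cv_folds(train, spec)
    n = train.n_subjects
    rows = []
    for c in grid:
        fold_scores = []
        for tr, va in folds:
            fit_views = [v.iloc[tr] for v in train.views]
            val_views = [v.iloc[va] for v in train.views]
            if any(v.shape[1] >= len(tr) for v in fit_views) and c == 0.0:
                fold_scores = None
                break
            try:
                model = MultisetCCA(n_components=n_components, c=c).fit(
                    fit_views)
            except ValueError:
                fold_scores = None
                break
            fold_scores.append(_holdout_score(model, val_views))
        if fold_scores is None:
            logger.info("c=%g infeasible at n=%d; skipped", c, n)
            continue
        rows.append({"c": c, "cv_score": float(np.mean(fold_scores))})
    if not rows:
        raise ValueError("no feasible candidate in the c grid")
    table = pd.DataFrame(rows)
    # ties (and the argmax) resolve to the smallest c: stable sort on score
    best = table.sort_values(["cv_score", "c"],
                             ascending=[False, True]).iloc[0]
    n_pairs = len(train.views) * (len(train.views) - 1) // 2
    if best["cv_score"] < 0.1 * n_pairs * n_components:
        logger.warning("low cross-view signal: best CV score %.3f",
                       best["cv_score"])
    if return_table:
        return float(best["c"]), table
    return float(best["c"])
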