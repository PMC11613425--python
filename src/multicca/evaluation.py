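"""Result surfaces: hold-out correlation tables, group ANOVA on latents,
feature attribution by shared variance, and the split-resampling
stability protocol.

All quantities are computed on hold-out projections by default, since
training-set canonical correlations are optimistically biased.  Feature
attribution uses the *shared variance percentage* — 100 x the squared
Pearson correlation between an observed feature and its view's canonical
variate — which, unlike the raw canonical weight, is insensitive to
multicollinearity among features.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .mcca import MultisetCCA, project
from .model_selection import SplitSpec, cv_select_c, split_train_test
from .simulate import MultiViewDataset

__all__ = ["pairwise_correlations", "fdr_adjust", "shared_variance",
           "top_k_features", "group_anova", "stability_analysis",
           "StabilityResult"]

logger = logging.getLogger(__name__)


def fdr_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def pairwise_correlations(scores: Sequence[pd.DataFrame],
                          view_names: Sequence[str] | None = None,
                          alpha: float = 0.05) -> pd.DataFrame:
    """Correlation of canonical variates for every view pair and
    component set, with two-sided p (t transform, n-2 df) and BH q over
    the whole pairs x sets family.

    Returns a tidy table: component, view_i, view_j, r, p, q, n,
    significant (q < alpha).
    """
    K = len(scores)
    if view_names is None:
        view_names = [f"view{i + 1}" for i in range(K)]
    n = len(scores[0])
    if n < 3:
        raise ValueError("need at least 3 subjects for correlation tests")
    m = scores[0].shape[1]
    rows = []
    for a in range(m):
        for i in range(K):
            for j in range(i + 1, K):
                x = scores[i].iloc[:, a].to_numpy()
                y = scores[j].iloc[:, a].to_numpy()
                if x.std() == 0 or y.std() == 0:
                    raise ValueError(
                        f"zero-variance canonical variate (set {a + 1}, "
                        f"views {view_names[i]}/{view_names[j]}); "
                        "correlation undefined")
                r, p = stats.pearsonr(x, y)
                rows.append({"component": a + 1, "view_i": view_names[i],
                             "view_j": view_names[j], "r": float(r),
                             "p": float(p), "n": n})
    table = pd.DataFrame(rows)
    table["q"] = fdr_adjust(table["p"].to_numpy())
    table["significant"] = table["q"] < alpha
    return table


def shared_variance(view: pd.DataFrame, scores: pd.DataFrame,
                    weights: np.ndarray | None = None) -> pd.DataFrame:
    """Per-feature contribution table for one view.

    For feature f and component a: ``100 * corr(X[:, f], score[:, a])**2``.
    Constant features contribute 0 (with a warning).  Optionally attaches
    the canonical weights and a rank per component (1 = largest shared
    variance; ties broken by feature name).
    """
    if len(view) != len(scores):
        raise ValueError("view and scores have different numbers of rows")
    x = view.to_numpy(dtype=float)
    s = scores.to_numpy(dtype=float)
    sd = x.std(axis=0)
    if np.any(sd == 0):
        logger.warning("%d constant feature(s) assigned 0%% shared variance",
                       int((sd == 0).sum()))
    xc = x - x.mean(axis=0)
    sc = s - s.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (xc.T @ sc) / np.outer(
            np.sqrt((xc ** 2).sum(axis=0)), np.sqrt((sc ** 2).sum(axis=0)))
    corr = np.nan_to_num(corr)
    rows = []
    for a in range(s.shape[1]):
        sv = 100.0 * corr[:, a] ** 2
        order = sorted(range(len(sv)),
                       key=lambda f: (-sv[f], str(view.columns[f])))
        rank = np.empty(len(sv), dtype=int)
        rank[order] = np.arange(1, len(sv) + 1)
        for f, name in enumerate(view.columns):
            rows.append({"feature": str(name), "component": a + 1,
                         "weight": (float(weights[f, a])
                                    if weights is not None else np.nan),
                         "shared_variance_pct": float(sv[f]),
                         "rank": int(rank[f])})
    return pd.DataFrame(rows)


def top_k_features(contribs: pd.DataFrame, k: int = 5) -> pd.DataFrame:
    """Top-k features per component by shared variance percentage,
    deterministic lexicographic tie-break on the feature name."""
    out = []
    for a, grp in contribs.groupby("component"):
        if k > len(grp):
            raise ValueError(f"k={k} exceeds feature count {len(grp)}")
        ordered = grp.sort_values(
            ["shared_variance_pct", "feature"],
            ascending=[False, True], kind="mergesort")
        out.append(ordered.head(k))
    return pd.concat(out, ignore_index=True)


def group_anova(scores: Sequence[pd.DataFrame], labels: pd.Series,
                view_names: Sequence[str] | None = None) -> pd.DataFrame:
    """One-way ANOVA of accelerated vs delayed on every view-latent and
    component set.

    With two groups F equals the squared equal-variance two-sample t
    statistic; group means are reported alongside F and p.
    """
    if view_names is None:
        view_names = [f"view{i + 1}" for i in range(len(scores))]
    lab = labels.astype(str)
    mask_a = (lab == "accelerated").to_numpy()
    mask_d = (lab == "delayed").to_numpy()
    if mask_a.sum() < 2 or mask_d.sum() < 2:
        raise ValueError("each group needs at least 2 members for ANOVA")
    rows = []
    for a in range(scores[0].shape[1]):
        for i, sc in enumerate(scores):
            v = sc.iloc[:, a].to_numpy()
            f, p = stats.f_oneway(v[mask_a], v[mask_d])
            rows.append({"component": a + 1, "view": view_names[i],
                         "F": float(f), "p": float(p),
                         "mean_accelerated": float(v[mask_a].mean()),
                         "mean_delayed": float(v[mask_d].mean())})
    return pd.DataFrame(rows)


@dataclass
class StabilityResult:
    """Aggregate of the repeated-split protocol.

    ``table`` has one row per view/component/feature with the mean
    canonical weight and mean shared variance percentage across
    iterations, their 2.5/97.5 empirical percentile bounds, and the
    percentage of iterations in which the feature entered the hold-out
    Top-k list.
    """

    table: pd.DataFrame
    n_iterations: int
    n_failed: int
    selected_c: list[float]


def stability_analysis(dataset: MultiViewDataset, spec: SplitSpec,
                       n_components: int, n_iterations: int = 100,
                       k: int = 5, c: float | None = None,
                       c_grid: Sequence[float] | None = None,
                       view_names: Sequence[str] | None = None
                       ) -> StabilityResult:
    """Repeat the full split -> (select c) -> fit -> hold-out attribution
    protocol ``n_iterations`` times with fresh random 80/20 splits.

    When ``c`` is None the regularization is re-selected by CV inside
    each iteration's training partition (``c_grid`` required); otherwise
    the given value is reused throughout.  Before averaging, each
    iteration's weight vectors are sign-aligned to the first successful
    iteration by the sign of the inner product per view-component, since
    canonical weights carry no intrinsic sign.
    """
    if view_names is None:
        view_names = list(dataset.view_names)
    if c is None and c_grid is None:
        raise ValueError("provide either a fixed c or a CV grid")
    weight_draws: list[list[np.ndarray]] = []
    sv_draws: list[list[np.ndarray]] = []
    top_hits: list[list[np.ndarray]] = []
    selected_c: list[float] = []
    feature_names: list[list[str]] | None = None
    n_failed = 0
    for it in range(n_iterations):
        it_spec = SplitSpec(train_fraction=spec.train_fraction,
                            n_folds=spec.n_folds,
                            stratify_on=spec.stratify_on,
                            seed=spec.seed + it)
        try:
            train, test = split_train_test(dataset, it_spec)
            c_it = (cv_select_c(train, c_grid, it_spec, n_components)
                    if c is None else float(c))
            model = MultisetCCA(n_components=n_components, c=c_it).fit(
                train.views)
            test_scores = project(model, test.views)
        except Exception as exc:  # noqa: BLE001 — protocol excludes failures
            logger.warning("stability iteration %d failed: %s", it, exc)
            n_failed += 1
            continue
        selected_c.append(c_it)
        if feature_names is None:
            feature_names = [[model.feature_names_in_[i][j]
                              for j in model.kept_idx_[i]]
                             for i in range(model.n_views_)]
        it_w, it_sv, it_top = [], [], []
        for i in range(model.n_views_):
            w = model.weights_[i].copy()
            if weight_draws:  # sign-align to the reference iteration
                ref = weight_draws[0][i]
                for a in range(w.shape[1]):
                    if float(ref[:, a] @ w[:, a]) < 0:
                        w[:, a] = -w[:, a]
            contrib = shared_variance(
                test.views[i][feature_names[i]], test_scores[i], weights=w)
            sv = contrib.pivot(index="feature", columns="component",
                               values="shared_variance_pct")
            sv = sv.loc[feature_names[i]].to_numpy()
            top = np.zeros_like(sv, dtype=bool)
            kk = min(k, sv.shape[0])
            tk = top_k_features(contrib, k=kk)
            pos = {f: p for p, f in enumerate(feature_names[i])}
            for _, row in tk.iterrows():
                top[pos[row["feature"]], int(row["component"]) - 1] = True
            it_w.append(w)
            it_sv.append(sv)
            it_top.append(top)
        weight_draws.append(it_w)
        sv_draws.append(it_sv)
        top_hits.append(it_top)
    n_ok = len(weight_draws)
    if n_ok == 0:
        raise RuntimeError("all stability iterations failed")
    rows = []
    for i, names in enumerate(feature_names):
        w = np.stack([d[i] for d in weight_draws])      # iter x d x m
        sv = np.stack([d[i] for d in sv_draws])
        hits = np.stack([d[i] for d in top_hits])
        for a in range(w.shape[2]):
            w_lo, w_hi = np.percentile(w[:, :, a], [2.5, 97.5], axis=0)
            s_lo, s_hi = np.percentile(sv[:, :, a], [2.5, 97.5], axis=0)
            for f, name in enumerate(names):
                rows.append({
                    "view": view_names[i], "component": a + 1,
                    "feature": name,
                    "weight_mean": float(w[:, f, a].mean()),
                    "weight_ci_low": float(w_lo[f]),
                    "weight_ci_high": float(w_hi[f]),
                    "shared_variance_mean": float(sv[:, f, a].mean()),
                    "shared_variance_ci_low": float(s_lo[f]),
                    "shared_variance_ci_high": float(s_hi[f]),
                    "topk_frequency_pct":
                        float(100.0 * hits[:, f, a].mean()),
                })
    return StabilityResult(table=pd.DataFrame(rows), n_iterations=n_ok,
                           n_failed=n_failed, selected_c=selected_c)
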