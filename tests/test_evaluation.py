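"""Correlation reports with BH adjustment, shared-variance attribution,
group ANOVA, and the repeated-split stability protocol."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from multicca import (MultisetCCA, SplitSpec, SyntheticConfig, fdr_adjust,
                      generate_multiview, group_anova, pairwise_correlations,
                      shared_variance, stability_analysis, top_k_features)
from multicca.mcca import project
from conftest import make_noise_dataset


def scores_frame(arr):
    arr = np.atleast_2d(arr.T).T
    return pd.DataFrame(arr, columns=[f"cv{a+1}" for a in
                                      range(arr.shape[1])])


# ----------------------------------------------------------------------- FDR

@pytest.mark.parametrize("p, expected", [
    ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),  # hand BH
    ([0.2, 0.2, 0.2], [0.2, 0.2, 0.2]),                    # all equal
    ([0.37], [0.37]),                                      # single p
])
def test_fdr_hand_examples(p, expected):
    np.testing.assert_allclose(fdr_adjust(p), expected, atol=1e-12)


@given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
@settings(max_examples=60, deadline=None, derandomize=True)
def test_fdr_properties(pvals):
    q = fdr_adjust(pvals)
    assert np.all(q >= np.asarray(pvals) - 1e-12)   # q >= p
    assert np.all(q <= 1 + 1e-12)
    order = np.argsort(pvals)
    assert np.all(np.diff(q[order]) >= -1e-12)      # monotone step-up


def test_fdr_rejects_out_of_range():
    with pytest.raises(ValueError):
        fdr_adjust([0.5, 1.5])


# -------------------------------------------------------------- correlations

def test_pairwise_identical_scores(rng):
    x = rng.standard_normal(50)
    rep = pairwise_correlations([scores_frame(x), scores_frame(x)])
    assert rep["r"].iloc[0] == pytest.approx(1.0)
    assert rep["q"].iloc[0] >= rep["p"].iloc[0] - 1e-15


def test_pairwise_null_scores_small_r(rng):
    a, b = rng.standard_normal((2, 10_000))
    rep = pairwise_correlations([scores_frame(a), scores_frame(b)])
    assert abs(rep["r"].iloc[0]) < 0.05


def test_pairwise_null_p_uniform(rng):
    ps = []
    for _ in range(200):
        a, b = rng.standard_normal((2, 60))
        ps.append(pairwise_correlations(
            [scores_frame(a), scores_frame(b)])["p"].iloc[0])
    ps = np.asarray(ps)
    # calibration: empirical CDF near uniform at a few quantiles
    for q in (0.2, 0.5, 0.8):
        assert (ps < q).mean() == pytest.approx(q, abs=0.1)


def test_pairwise_recovers_planted_r(planted_dataset_no_shift):
    ds, truth = planted_dataset_no_shift
    tr = [v.iloc[:1000] for v in ds.views]
    te = [v.iloc[1000:] for v in ds.views]
    model = MultisetCCA(n_components=1, c=1e-3).fit(tr)
    rep = pairwise_correlations(project(model, te), ds.view_names)
    rstar = truth.expected_pairwise_correlation[0, 1, 0]
    assert np.allclose(rep["r"], rstar, atol=0.06)
    assert rep["significant"].all()


def test_pairwise_zero_variance_error(rng):
    x = rng.standard_normal(30)
    with pytest.raises(ValueError, match="zero-variance"):
        pairwise_correlations([scores_frame(x),
                               scores_frame(np.zeros(30))])


def test_pairwise_family_is_pairs_times_sets(rng):
    s = [scores_frame(rng.standard_normal((40, 3))) for _ in range(4)]
    rep = pairwise_correlations(s)
    assert len(rep) == 6 * 3
    # BH over the whole family: q computed jointly
    np.testing.assert_allclose(rep["q"], fdr_adjust(rep["p"]))


# ----------------------------------------------------------- shared variance

def test_shared_variance_extremes(rng):
    x = rng.standard_normal(5000)
    view = pd.DataFrame({"same": x, "indep": rng.standard_normal(5000),
                         "const": np.ones(5000)})
    tab = shared_variance(view, scores_frame(x))
    sv = tab.set_index("feature")["shared_variance_pct"]
    assert sv["same"] == pytest.approx(100.0, abs=1e-9)
    assert sv["indep"] < 0.5
    assert sv["const"] == 0.0
    assert tab["rank"].tolist()[0:1] == [1] or (
        tab.set_index("feature")["rank"]["same"] == 1)


def test_shared_variance_dominant_planted_feature():
    """The feature with the largest planted loading magnitude attains the
    largest shared variance for its component."""
    cfg = SyntheticConfig(n_subjects=5000, view_dims=(10, 10),
                          n_components=1, latent_fidelity=0.9,
                          group_effect=(0.0,), seed=8)
    ds, truth = generate_multiview(cfg)
    model = MultisetCCA(n_components=1, c=1e-3).fit(ds.views)
    scores = project(model, ds.views)
    for i in range(2):
        tab = shared_variance(ds.views[i], scores[i])
        best = tab.loc[tab["rank"] == 1, "feature"].iloc[0]
        planted = ds.views[i].columns[
            np.argmax(np.abs(truth.loadings[i][:, 0]))]
        assert best == planted


def test_shared_variance_bounds(planted_dataset):
    ds, _ = planted_dataset
    model = MultisetCCA(n_components=2, c=1e-3).fit(
        [v.iloc[:500] for v in ds.views])
    scores = project(model, [v.iloc[:500] for v in ds.views])
    tab = shared_variance(ds.views[0].iloc[:500], scores[0])
    assert tab["shared_variance_pct"].between(0, 100).all()


# ------------------------------------------------------------------- top-k

def test_top_k_full_ranking_and_ties():
    contribs = pd.DataFrame({
        "feature": ["b", "a", "c", "d"],
        "component": 1,
        "weight": 0.0,
        "shared_variance_pct": [50.0, 50.0, 10.0, 5.0],
        "rank": [1, 2, 3, 4],
    })
    full = top_k_features(contribs, k=4)
    assert full["feature"].tolist() == ["a", "b", "c", "d"]  # tie: lexicographic
    top2 = top_k_features(contribs, k=2)
    assert top2["feature"].tolist() == ["a", "b"]
    with pytest.raises(ValueError):
        top_k_features(contribs, k=5)


# -------------------------------------------------------------------- ANOVA

def test_anova_hand_example():
    s = scores_frame(np.array([1.0, 2, 3, 4, 5, 6]))
    labels = pd.Series(["accelerated"] * 3 + ["delayed"] * 3)
    rep = group_anova([s], labels)
    assert rep["F"].iloc[0] == pytest.approx(13.5)
    assert rep["mean_accelerated"].iloc[0] == pytest.approx(2.0)
    assert rep["mean_delayed"].iloc[0] == pytest.approx(5.0)


def test_anova_equals_squared_t(rng):
    from scipy import stats
    x = rng.standard_normal(80)
    labels = pd.Series(np.where(np.arange(80) % 2, "accelerated", "delayed"))
    rep = group_anova([scores_frame(x)], labels)
    t = stats.ttest_ind(x[labels == "accelerated"], x[labels == "delayed"],
                        equal_var=True)
    assert rep["F"].iloc[0] == pytest.approx(t.statistic ** 2, rel=1e-10)
    assert rep["p"].iloc[0] == pytest.approx(t.pvalue, rel=1e-10)


def test_anova_permutation_calibration(rng):
    x = rng.standard_normal(60)
    ps = []
    for _ in range(300):
        lab = pd.Series(rng.permutation(
            ["accelerated"] * 30 + ["delayed"] * 30))
        ps.append(group_anova([scores_frame(x)], lab)["p"].iloc[0])
    assert (np.asarray(ps) < 0.05).mean() == pytest.approx(0.05, abs=0.04)


def test_anova_small_group_error(rng):
    s = scores_frame(rng.standard_normal(10))
    labels = pd.Series(["accelerated"] + ["delayed"] * 9)
    with pytest.raises(ValueError, match="at least 2"):
        group_anova([s], labels)


# ---------------------------------------------------------------- stability

def test_stability_dominant_feature_always_top5():
    cfg = SyntheticConfig(n_subjects=1200, view_dims=(20, 12), n_components=1,
                          latent_fidelity=0.9, group_effect=(0.0,),
                          dominant_loading=4.0, seed=9)
    ds, truth = generate_multiview(cfg)
    res = stability_analysis(ds.subset(list(ds.metadata.index)),
                             SplitSpec(stratify_on="group", seed=0),
                             n_components=1, n_iterations=10, k=5, c=1e-3)
    tab = res.table
    dominant = ds.views[0].columns[np.argmax(np.abs(truth.loadings[0][:, 0]))]
    row = tab[(tab["view"] == "view1") & (tab["feature"] == dominant)]
    assert row["topk_frequency_pct"].iloc[0] == 100.0
    # sign-aligned mean weight CI excludes zero for the dominant feature
    assert (row["weight_ci_low"].iloc[0] > 0
            or row["weight_ci_high"].iloc[0] < 0)
    assert res.n_failed == 0


def test_stability_sign_alignment_gauge(monkeypatch):
    """Randomly negating fitted weights across iterations must not change
    the aligned mean weight magnitudes."""
    cfg = SyntheticConfig(n_subjects=800, view_dims=(8, 8), n_components=1,
                          latent_fidelity=0.9, group_effect=(0.0,), seed=10)
    ds, _ = generate_multiview(cfg)
    spec = SplitSpec(seed=0)
    base = stability_analysis(ds, spec, 1, n_iterations=6, k=3, c=1e-3)

    import multicca.evaluation as ev
    orig_fit = MultisetCCA.fit
    call = {"i": 0}

    def flipping_fit(self, views, y=None):
        orig_fit(self, views)
        call["i"] += 1
        if call["i"] % 2 == 0:  # negate every other iteration's weights
            self.weights_ = [-w for w in self.weights_]
        return self

    monkeypatch.setattr(ev.MultisetCCA, "fit", flipping_fit)
    flipped = stability_analysis(ds, spec, 1, n_iterations=6, k=3, c=1e-3)
    np.testing.assert_allclose(
        np.abs(flipped.table["weight_mean"].to_numpy()),
        np.abs(base.table["weight_mean"].to_numpy()), atol=1e-10)


def test_stability_noise_frequencies_near_chance():
    """Under pure noise the expected Top-k frequency of every feature is
    k/d.  Within one dataset the repeated splits overlap heavily, so
    frequencies must be averaged over independent datasets before being
    compared with chance; the bound allows fully dependent iterations
    (one effective draw per dataset)."""
    freqs = []
    n_rep = 6
    for s in range(n_rep):
        ds = make_noise_dataset(n=500, dims=(20, 20), seed=100 + s)
        res = stability_analysis(ds, SplitSpec(seed=s), n_components=1,
                                 n_iterations=6, k=5, c=1e-3)
        t = res.table.sort_values(["view", "feature"])
        freqs.append(t["topk_frequency_pct"].to_numpy())
        # exactly k of d features chosen per iteration => mean k/d exactly
        assert t["topk_frequency_pct"].mean() == pytest.approx(25.0,
                                                               abs=1e-9)
    per_feature = np.mean(freqs, axis=0)
    bound = 25.0 + 3 * 100 * np.sqrt(0.25 * 0.75 / n_rep)
    assert per_feature.max() <= bound


def test_stability_ci_ordering(planted_dataset):
    ds, _ = planted_dataset
    res = stability_analysis(ds, SplitSpec(seed=1), n_components=1,
                             n_iterations=5, k=3, c=1e-3)
    t = res.table
    assert (t["weight_ci_low"] <= t["weight_mean"] + 1e-12).all()
    assert (t["weight_mean"] <= t["weight_ci_high"] + 1e-12).all()
    assert t["topk_frequency_pct"].between(0, 100).all()
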