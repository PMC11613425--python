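"""Synthetic multiview data with planted low-rank cross-view structure.

The generator emulates the statistical skeleton of a multimodal imaging
study: K per-subject feature matrices ("views") that share m latent
components, a normally distributed brain-age gap that stratifies subjects
into accelerated / delayed maturation groups, a group shift planted on
selected latent components, and cognitive composite scores linearly tied
to the first latent with age/gender fixed effects and site/family random
intercepts.

Construction
------------
For subject s and component k a shared latent ``z_k ~ N(0, 1)`` is drawn.
View i observes it with fidelity ``rho[i, k]``::

    s_ik = rho[i, k] * z_k + sqrt(1 - rho[i, k]**2) * eps_ik

and embeds the m scores into feature space through a random column-
orthonormal loading matrix ``Q_i`` (d_i x m) plus isotropic noise::

    X_i = S_i @ Q_i.T + sigma * E_i

Because the Q_i are orthonormal, the best linear variate of view i for
component k is the projection onto ``q_ik``, and the attainable
cross-view correlation has the closed form::

    r*[i, j, k] = rho[i, k] * rho[j, k] / (1 + sigma**2)

which downstream recovery tests use as ground truth.

Group labels come from thresholding the z-scored gap at ``+-gap_threshold``
(strict inequalities; the middle band is excluded).  The group effect
``delta[k]`` is added to the latent scores of accelerated subjects *after*
labelling and the views are re-embedded, so ``delta`` is exactly the
standardized latent mean shift a downstream ANOVA should detect (scaled by
each view's fidelity).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "MultiViewDataset",
    "generate_multiview",
    "expected_correlations",
]

# Stage names for per-stream child seeds; fixed order => reproducibility.
_STREAMS = ("latents", "view_noise", "loadings", "embed_noise", "gap",
            "demographics", "cognition")


@dataclass
class SyntheticConfig:
    """Parameters of the planted multiview design.

    Defaults are a scaled-down analogue of a four-view brain/environment
    analysis (three wide "brain" views and one narrow "environment" view)
    sized for fast tests; pass ``view_dims=(100, 152, 1378, 9)`` and a
    larger ``n_subjects`` for a full-size instance.
    """

    n_subjects: int = 2000
    view_dims: Sequence[int] = (20, 30, 60, 9)
    n_components: int = 4
    #: scalar (shared), per-component vector, or full (K, m) matrix in [0, 1]
    latent_fidelity: float | Sequence[float] | np.ndarray = 0.9
    feature_noise_sd: float = 0.1
    #: standardized latent mean shift for the accelerated group, length m
    group_effect: Sequence[float] | None = None
    gap_threshold: float = 0.41
    #: slope of the cognitive composites on the component-1 latent
    cognition_effect: float = 0.3
    #: if set, concentrates each view's component-1 loading on its first
    #: feature (relative magnitude of the planted entry before
    #: orthonormalization), making that feature dominate attribution
    dominant_loading: float | None = None
    n_sites: int = 10
    sibling_fraction: float = 0.1
    site_sd: float = 0.3
    family_sd: float = 0.3
    cognition_noise_sd: float = 1.0
    age_slope: float = 0.05
    gender_slope: float = 0.1
    seed: int = 0

    def fidelity_matrix(self) -> np.ndarray:
        K, m = len(self.view_dims), self.n_components
        rho = np.asarray(self.latent_fidelity, dtype=float)
        if rho.ndim == 0:
            rho = np.full((K, m), float(rho))
        elif rho.ndim == 1:
            if rho.shape[0] != m:
                raise ValueError(
                    f"latent_fidelity vector has length {rho.shape[0]}, "
                    f"expected n_components={m}")
            rho = np.tile(rho, (K, 1))
        if rho.shape != (K, m):
            raise ValueError(
                f"latent_fidelity shape {rho.shape} does not match "
                f"(n_views, n_components)=({K}, {m})")
        return rho

    def group_effect_vector(self) -> np.ndarray:
        m = self.n_components
        if self.group_effect is None:
            delta = np.zeros(m)
            if m >= 2:
                delta[1] = 0.2  # group difference carried by component 2
            return delta
        delta = np.asarray(self.group_effect, dtype=float)
        if delta.shape != (m,):
            raise ValueError(
                f"group_effect has shape {delta.shape}, expected ({m},)")
        return delta

    def validate(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be at least 2")
        if self.n_components < 1:
            raise ValueError("n_components must be positive")
        if any(d < self.n_components for d in self.view_dims):
            raise ValueError(
                "every view dimension must be >= n_components "
                f"(got dims {tuple(self.view_dims)}, m={self.n_components})")
        rho = self.fidelity_matrix()
        if np.any(rho < 0) or np.any(rho > 1):
            raise ValueError("latent_fidelity entries must lie in [0, 1]")
        if self.feature_noise_sd < 0:
            raise ValueError("feature_noise_sd must be non-negative")
        if self.gap_threshold <= 0:
            raise ValueError("gap_threshold must be positive")
        self.group_effect_vector()


@dataclass
class SyntheticTruth:
    """Planted ground truth accompanying a generated dataset."""

    loadings: list[np.ndarray]          # per-view d_i x m, columnwise orthonormal
    latent_fidelity: np.ndarray         # (K, m)
    feature_noise_sd: float
    expected_pairwise_correlation: np.ndarray  # (K, K, m)
    group: pd.Series                    # per-subject label
    group_effect: np.ndarray            # (m,)
    cognition_effect: float
    latents: np.ndarray                 # n x m shared latents (post group shift)
    view_scores: list[np.ndarray]       # per-view n x m latent scores


@dataclass
class MultiViewDataset:
    """K aligned subjects-x-features tables plus subject metadata.

    Each view is a DataFrame indexed by ``subject_id`` with named feature
    columns; metadata carries age, gender (Male=0, Female=1), site, family,
    brain-age gap, group label and three cognitive composites.
    """

    views: list[pd.DataFrame]
    metadata: pd.DataFrame
    view_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.view_names:
            self.view_names = [f"view{i + 1}" for i in range(len(self.views))]

    @property
    def n_subjects(self) -> int:
        return len(self.metadata)

    def subset(self, subject_ids: Sequence[str]) -> "MultiViewDataset":
        """Row-subset every view and the metadata to the given IDs."""
        ids = list(subject_ids)
        return MultiViewDataset(
            views=[v.loc[ids] for v in self.views],
            metadata=self.metadata.loc[ids],
            view_names=list(self.view_names),
        )


def _embed(scores: list[np.ndarray], loadings: list[np.ndarray],
           embed_noise: list[np.ndarray], sigma: float) -> list[np.ndarray]:
    return [s @ q.T + sigma * e
            for s, q, e in zip(scores, loadings, embed_noise)]


def generate_multiview(config: SyntheticConfig
                       ) -> tuple[MultiViewDataset, SyntheticTruth]:
    """Generate one dataset and its planted truth.

    All randomness derives from ``config.seed`` through named substreams,
    so identical configs give bit-identical output and enlarging one stage
    (e.g. more subjects) does not scramble another.
    """
    config.validate()
    n, dims = config.n_subjects, list(config.view_dims)
    K, m = len(dims), config.n_components
    rho = config.fidelity_matrix()
    sigma = config.feature_noise_sd
    delta = config.group_effect_vector()

    root = np.random.SeedSequence(config.seed)
    rngs = {name: np.random.default_rng(child)
            for name, child in zip(_STREAMS, root.spawn(len(_STREAMS)))}

    z = rngs["latents"].standard_normal((n, m))
    eps = [rngs["view_noise"].standard_normal((n, m)) for _ in range(K)]
    loadings = []
    for d in dims:
        a = rngs["loadings"].standard_normal((d, m))
        if config.dominant_loading is not None:
            a[0, 0] = config.dominant_loading * np.sqrt(d)
        q, _ = np.linalg.qr(a)
        loadings.append(q[:, :m])
    embed_noise = [rngs["embed_noise"].standard_normal((n, d)) for d in dims]

    # Brain-age gap and strict threshold partition on its z-score.
    gap = rngs["gap"].standard_normal(n)
    zgap = (gap - gap.mean()) / gap.std()
    group = np.where(zgap > config.gap_threshold, "accelerated",
                     np.where(zgap < -config.gap_threshold, "delayed",
                              "excluded"))

    # Plant the group effect after labelling, then (re-)embed.
    z_shifted = z.copy()
    z_shifted[group == "accelerated"] += delta
    scores = [rho[i] * z_shifted + np.sqrt(1.0 - rho[i] ** 2) * eps[i]
              for i in range(K)]
    X = _embed(scores, loadings, embed_noise, sigma)

    subject_ids = [f"S{j:06d}" for j in range(n)]
    views = []
    for i, (d, x) in enumerate(zip(dims, X)):
        cols = [f"v{i + 1}_f{f + 1}" for f in range(d)]
        views.append(pd.DataFrame(x, index=pd.Index(subject_ids,
                                                    name="subject_id"),
                                  columns=cols))

    demo = rngs["demographics"]
    age = demo.uniform(9.0, 11.0, size=n)
    gender = demo.integers(0, 2, size=n)          # Male=0, Female=1
    site = demo.integers(0, config.n_sites, size=n)
    # Families nested in site: a sibling_fraction of subjects share the
    # family of another same-site subject; the rest are singletons.
    family = np.arange(n)
    n_sib = int(round(config.sibling_fraction * n))
    if n_sib:
        sib = demo.choice(n, size=n_sib, replace=False)
        for j in sib:
            same_site = np.flatnonzero((site == site[j]) & (family != j))
            if same_site.size:
                family[j] = family[demo.choice(same_site)]
    site_labels = np.array([f"site{s:02d}" for s in site])
    family_labels = np.array([f"fam{f:06d}" for f in family])

    cog = rngs["cognition"]
    site_re = cog.normal(0.0, config.site_sd, size=config.n_sites)[site]
    fam_effects = {f: cog.normal(0.0, config.family_sd)
                   for f in np.unique(family)}
    family_re = np.array([fam_effects[f] for f in family])
    fixed = (config.age_slope * (age - age.mean())
             + config.gender_slope * gender + site_re + family_re)
    slopes = {"cog_total": config.cognition_effect,
              "cog_fluid": config.cognition_effect,
              "cog_crystallized": 0.5 * config.cognition_effect}
    cognition = {name: (slope * z_shifted[:, 0] + fixed
                        + cog.normal(0.0, config.cognition_noise_sd, size=n))
                 for name, slope in slopes.items()}

    metadata = pd.DataFrame({
        "age": age,
        "gender": gender,
        "site": site_labels,
        "family": family_labels,
        "gap": gap,
        "group": group,
        **cognition,
    }, index=pd.Index(subject_ids, name="subject_id"))

    truth = SyntheticTruth(
        loadings=loadings,
        latent_fidelity=rho,
        feature_noise_sd=sigma,
        expected_pairwise_correlation=_expected_r(rho, sigma),
        group=metadata["group"],
        group_effect=delta,
        cognition_effect=config.cognition_effect,
        latents=z_shifted,
        view_scores=scores,
    )
    dataset = MultiViewDataset(views=views, metadata=metadata)
    return dataset, truth


def _expected_r(rho: np.ndarray, sigma: float) -> np.ndarray:
    K, m = rho.shape
    r = np.empty((K, K, m))
    for k in range(m):
        outer = np.outer(rho[:, k], rho[:, k])
        r[:, :, k] = outer / (1.0 + sigma ** 2)
    return r


def expected_correlations(truth: SyntheticTruth) -> np.ndarray:
    """Closed-form best pairwise variate correlation r*[i, j, k].

    ``r* = rho[i, k] * rho[j, k] / (1 + sigma**2)`` — the correlation
    attained by projecting each view onto its planted loading direction.
    """
    return _expected_r(truth.latent_fidelity, truth.feature_noise_sd)
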