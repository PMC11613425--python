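"""End-to-end orchestration: load/simulate -> group -> split -> select ->
fit -> hold-out evaluation -> associations -> stability.

Every run writes tab-delimited report tables (hold-out pairwise
correlations, group ANOVA, per-view Top-k attribution with stability
columns, mixed-model coefficient tables), the serialized model, and a
JSON manifest carrying the configuration hash so reruns are traceable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as mio
from .associations import GROUP_CODES, fit_mixed_model
from .evaluation import (group_anova, pairwise_correlations, shared_variance,
                         stability_analysis, top_k_features)
from .grouping import assign_groups
from .mcca import MultisetCCA, project
from .model_selection import (DEFAULT_C_GRID, SplitSpec, choose_n_components,
                              cv_select_c, split_train_test)
from .simulate import MultiViewDataset, SyntheticConfig, generate_multiview

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger(__name__)

COGNITION_COLUMNS = ("cog_total", "cog_fluid", "cog_crystallized")


@dataclass
class PipelineConfig:
    """Fully serializable description of one pipeline run."""

    #: either paths to view TSVs + metadata TSV, or a synthetic config
    view_paths: list[str] | None = None
    metadata_path: str | None = None
    synthetic: SyntheticConfig | None = None
    split: SplitSpec = field(default_factory=SplitSpec)
    c_grid: list[float] = field(default_factory=lambda: list(DEFAULT_C_GRID))
    fixed_c: float | None = None
    n_components: int | None = None        # None => PCA variance rule
    variance_threshold: float = 0.90
    gap_threshold: float = 0.41
    top_k: int = 5
    n_stability_iterations: int = 100
    stability_reselect_c: bool = True
    alpha: float = 0.05
    output_dir: str = "multicca_output"
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _load(config: PipelineConfig) -> MultiViewDataset:
    if config.synthetic is not None:
        dataset, _ = generate_multiview(config.synthetic)
        return dataset
    if not config.view_paths or not config.metadata_path:
        raise ValueError("config needs either synthetic settings or "
                         "view_paths plus metadata_path")
    return mio.read_dataset(config.view_paths, config.metadata_path)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns a dict of in-memory results and writes
    the report bundle under ``config.output_dir``."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    dataset = _load(config)
    if "gap" in dataset.metadata.columns:
        dataset = MultiViewDataset(
            views=dataset.views,
            metadata=assign_groups(dataset.metadata,
                                   threshold=config.gap_threshold),
            view_names=dataset.view_names)

    spec = dataclasses.replace(config.split, seed=config.seed)
    train, test = split_train_test(dataset, spec)
    # split manifest: evaluation-only rows are recorded before any fitting
    pd.DataFrame({
        "subject_id": list(train.metadata.index) + list(test.metadata.index),
        "partition": ["train"] * train.n_subjects + ["test"] * test.n_subjects,
    }).to_csv(outdir / "split_manifest.tsv", sep="\t", index=False)

    smallest = min(range(len(train.views)),
                   key=lambda i: train.views[i].shape[1])
    m = (config.n_components if config.n_components is not None else
         choose_n_components(train.views[smallest],
                             config.variance_threshold))
    logger.info("using m=%d component sets", m)

    if config.fixed_c is not None:
        c, cv_table = float(config.fixed_c), None
    else:
        c, cv_table = cv_select_c(train, config.c_grid, spec, m,
                                  return_table=True)
        cv_table.to_csv(outdir / "cv_scores.tsv", sep="\t", index=False)
    logger.info("regularization c=%g", c)

    model = MultisetCCA(n_components=m, c=c).fit(train.views)
    provenance = {"config_hash": config.config_hash(), "seed": config.seed,
                  "selected_c": c, "n_components": m}
    mio.save_model(model, outdir / "model.json", provenance=provenance)

    test_scores = project(model, test.views)
    corr = pairwise_correlations(test_scores, dataset.view_names,
                                 alpha=config.alpha)
    corr.to_csv(outdir / "holdout_correlations.tsv", sep="\t", index=False)

    anova = group_anova(test_scores, test.metadata["group"],
                        dataset.view_names)
    anova.to_csv(outdir / "group_anova.tsv", sep="\t", index=False)

    contribs, tops = {}, {}
    for i, name in enumerate(dataset.view_names):
        kept = [model.feature_names_in_[i][j] for j in model.kept_idx_[i]]
        contribs[name] = shared_variance(test.views[i][kept], test_scores[i],
                                         weights=model.weights_[i])
        tops[name] = top_k_features(contribs[name],
                                    k=min(config.top_k, len(kept)))
        tops[name].to_csv(outdir / f"top_features_{name}.tsv", sep="\t",
                          index=False)

    associations = _association_stage(test, test_scores, dataset.view_names)
    associations.to_csv(outdir / "associations.tsv", sep="\t", index=False)

    stability = None
    if config.n_stability_iterations > 0:
        stability = stability_analysis(
            dataset, spec, m, n_iterations=config.n_stability_iterations,
            k=config.top_k,
            c=None if config.stability_reselect_c else c,
            c_grid=config.c_grid, view_names=dataset.view_names)
        stability.table.to_csv(outdir / "stability.tsv", sep="\t",
                               index=False)

    manifest = {
        "config": config.to_dict(), "config_hash": config.config_hash(),
        "n_components": m, "selected_c": c,
        "n_train": train.n_subjects, "n_test": test.n_subjects,
        "outputs": sorted(p.name for p in outdir.glob("*.tsv")),
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, default=str))

    return {"dataset": dataset, "train": train, "test": test, "model": model,
            "n_components": m, "selected_c": c, "cv_table": cv_table,
            "correlations": corr, "anova": anova, "contributions": contribs,
            "top_features": tops, "associations": associations,
            "stability": stability}


def _association_stage(test: MultiViewDataset, test_scores,
                       view_names) -> pd.DataFrame:
    """Mixed models of each cognitive composite on (a) the maturation
    group and (b) each brain canonical variable, on hold-out subjects."""
    meta = test.metadata
    cogs = [c for c in COGNITION_COLUMNS if c in meta.columns]
    rows = []
    base = pd.DataFrame({"age": meta["age"], "gender": meta["gender"]},
                        index=meta.index)
    group_code = meta["group"].map(GROUP_CODES)
    for cog in cogs:
        fixed = base.assign(group=group_code)
        res = fit_mixed_model(meta[cog], fixed, meta["site"], meta["family"])
        eff = res.coef("group")
        rows.append({"outcome": cog, "predictor": "group",
                     "estimate": eff["estimate"], "se": eff["se"],
                     "t": eff["t"], "p": eff["p"], "n": res.n})
        for i, vname in enumerate(view_names):
            for a in range(test_scores[i].shape[1]):
                col = f"{vname}_cv{a + 1}"
                fixed = base.assign(**{col: test_scores[i].iloc[:, a].values})
                res = fit_mixed_model(meta[cog], fixed, meta["site"],
                                      meta["family"])
                eff = res.coef(col)
                rows.append({"outcome": cog, "predictor": col,
                             "estimate": eff["estimate"], "se": eff["se"],
                             "t": eff["t"], "p": eff["p"], "n": res.n})
    return pd.DataFrame(rows)
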