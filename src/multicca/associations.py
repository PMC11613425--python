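"""Linear mixed-effects association models.

Cognition (a composite score) is regressed on age, gender and either the
maturation group (coded Accelerated=3, Delayed=2) or a brain canonical
variable, with random intercepts for acquisition site and for family
nested within site.  Family labels are prefixed with their site before
fitting, so the nested structure is expressed as a site grouping with a
family variance component — equivalent to nested intercepts whenever
families never span sites.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.regression.mixed_linear_model import MixedLM

__all__ = ["MixedModelResult", "fit_mixed_model", "GROUP_CODES"]

logger = logging.getLogger(__name__)

GROUP_CODES = {"accelerated": 3, "delayed": 2}


@dataclass
class MixedModelResult:
    """Fixed-effect table plus variance components of one REML fit."""

    fixed_effects: pd.DataFrame   # estimate, se, t, p per term (incl. Intercept)
    variance_components: dict[str, float]  # site, family, residual variances
    n: int
    n_groups: int
    n_dropped: int                # listwise-deleted rows
    converged: bool

    def coef(self, term: str) -> pd.Series:
        return self.fixed_effects.loc[term]


def fit_mixed_model(outcome: pd.Series, fixed: pd.DataFrame,
                    site: pd.Series, family: pd.Series) -> MixedModelResult:
    """REML fit of ``outcome ~ 1 + fixed`` with random intercepts for
    site and for family nested within site.

    Rows with any missing value are listwise-deleted (count reported).
    Variance components may converge to the boundary 0.  Raises on a
    singular fixed-effect design, naming the collinear columns.
    """
    safe = {col: f"f{j}" for j, col in enumerate(fixed.columns)}
    df = pd.DataFrame({"y": pd.to_numeric(outcome.to_numpy(),
                                          errors="coerce")})
    for col, name in safe.items():
        df[name] = pd.to_numeric(fixed[col].to_numpy(), errors="coerce")
    df["site"] = site.astype(str).to_numpy()
    df["fam"] = df["site"] + ":" + family.astype(str).to_numpy()
    n_before = len(df)
    df = df.dropna().reset_index(drop=True)
    n_dropped = n_before - len(df)
    if n_dropped:
        logger.info("listwise deletion removed %d row(s)", n_dropped)

    X = np.column_stack([np.ones(len(df))]
                        + [df[name].to_numpy() for name in safe.values()])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        bad = [col for j, col in enumerate(fixed.columns)
               if np.linalg.matrix_rank(np.delete(X, j + 1, axis=1)) == rank]
        raise ValueError(f"singular fixed-effect design; "
                         f"collinear columns: {bad}")

    formula = "y ~ " + (" + ".join(safe.values()) if safe else "1")
    model = MixedLM.from_formula(
        formula, data=df, groups="site", re_formula="1",
        vc_formula={"family": "0 + C(fam)"})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # boundary-variance warnings
        fit = model.fit(reml=True, method="lbfgs", maxiter=500)
        if not fit.converged:  # boundary variances often need a
            fit = model.fit(reml=True, method="powell",  # gradient-free pass
                            maxiter=2000)

    back = {v: k for k, v in safe.items()}
    fe_names = list(fit.fe_params.index)
    fe = pd.DataFrame({
        "estimate": fit.fe_params.to_numpy(),
        "se": fit.bse_fe.to_numpy(),
    }, index=[back.get(t, t) for t in fe_names])
    fe["t"] = fe["estimate"] / fe["se"]
    fe["p"] = fit.pvalues.loc[fe_names].to_numpy()

    vc = {
        "site": float(fit.cov_re.iloc[0, 0]) if fit.cov_re.size else 0.0,
        "family": float(fit.vcomp[0]) if fit.vcomp.size else 0.0,
        "residual": float(fit.scale),
    }
    return MixedModelResult(
        fixed_effects=fe,
        variance_components=vc,
        n=len(df),
        n_groups=int(df["site"].nunique()),
        n_dropped=n_dropped,
        converged=bool(fit.converged),
    )
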