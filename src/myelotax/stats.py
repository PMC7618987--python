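"""Composition statistics: Gini coefficients, hypergeometric enrichment with
Benjamini–Hochberg correction, and the cluster-diversity count GLM."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DiversityRecord",
    "GLMResult",
    "gini_coefficient",
    "enrichment_hypergeometric",
    "bh_adjust",
    "cluster_diversity_glm",
]


def gini_coefficient(shares: Sequence[float]) -> float:
    """Gini inequality index G = sum_ij |x_i - x_j| / (2 n^2 mu), in [0, 1).

    Equal shares give 0; a single nonzero entry among k gives 1 - 1/k. The
    measure is scale-invariant. All-zero or negative input is rejected."""
    x = np.asarray(shares, dtype=float)
    if x.size == 0:
        raise ValueError("empty share vector")
    if (x < 0).any():
        raise ValueError("shares must be nonnegative")
    mu = x.mean()
    if mu == 0:
        raise ValueError("all-zero share vector has no defined Gini coefficient")
    diff_sum = np.abs(x[:, None] - x[None, :]).sum()
    return float(diff_sum / (2 * x.size**2 * mu))


def enrichment_hypergeometric(
    hits_in_group: int, group_size: int, hits_total: int, population: int
) -> tuple[float, float]:
    """Upper-tail hypergeometric test P(X >= hits_in_group) plus the fold
    enrichment observed/expected.

    Models drawing `group_size` cells from `population` of which `hits_total`
    carry the property of interest."""
    if not (0 <= hits_in_group <= min(group_size, hits_total)):
        raise ValueError("hits_in_group must be <= min(group_size, hits_total) and >= 0")
    if population < group_size or population < hits_total:
        raise ValueError("population must be at least group_size and hits_total")
    p_upper = float(hypergeom.sf(hits_in_group - 1, population, hits_total, group_size))
    expected = group_size * hits_total / population
    fold = hits_in_group / expected if expected > 0 else float("nan")
    return p_upper, fold


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    arr = np.asarray(p, dtype=float)
    if arr.size == 0:
        return arr
    if ((arr < 0) | (arr > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


@dataclass(frozen=True)
class DiversityRecord:
    """Distinct-cluster and nucleus counts for one region x condition stratum."""

    region: str
    condition_class: str  # homeostasis | non_homeostasis
    n_clusters: int
    n_nuclei: int
    patient: str | None = None

    def __post_init__(self) -> None:
        if self.n_clusters < 0 or self.n_nuclei < 0:
            raise ValueError("counts must be nonnegative")
        if self.n_clusters > self.n_nuclei:
            raise ValueError("n_clusters cannot exceed n_nuclei")
        if self.condition_class not in ("homeostasis", "non_homeostasis"):
            raise ValueError(f"unknown condition_class {self.condition_class!r}")


@dataclass
class GLMResult:
    rate_ratio: float
    wald_p: float
    dispersion: float
    family_used: str  # poisson | negative_binomial
    coefficients: pd.DataFrame
    conf_int: tuple[float, float]


def cluster_diversity_glm(
    records: Sequence[DiversityRecord],
    dispersion_cutoff: float = 1.5,
    random_effect: str | None = None,
) -> GLMResult:
    """Model cluster diversity: n_clusters ~ condition + log(n_nuclei), log link.

    A Poisson GLM is fit first; the Pearson-residual dispersion (sum of squared
    Pearson residuals over residual df) is computed, and if it exceeds
    `dispersion_cutoff` the model is refit as negative binomial (MLE of the
    dispersion parameter). The rate ratio is exp(condition coefficient)
    contrasting non_homeostasis against homeostasis, with a two-sided Wald p.

    `random_effect` in {"region", "patient"} adds an approximate (variational
    Bayes) random intercept on the Poisson model; dispersion-based family
    switching is unavailable on that path.
    """
    if len(records) < 3:
        raise ValueError("at least three records are required")
    df = pd.DataFrame([r.__dict__ for r in records])
    if df["condition_class"].nunique() < 2:
        raise ValueError("both condition classes must be present")
    df["is_disease"] = (df["condition_class"] == "non_homeostasis").astype(float)
    df["log_nuclei"] = np.log(df["n_nuclei"].clip(lower=1))

    exog_cols = ["is_disease"]
    if df["log_nuclei"].nunique() > 1:  # constant covariate would be collinear
        exog_cols.append("log_nuclei")

    if random_effect is not None:
        from statsmodels.genmod.bayes_mixed_glm import PoissonBayesMixedGLM

        if random_effect not in ("region", "patient"):
            raise ValueError("random_effect must be 'region' or 'patient'")
        if df[random_effect].isna().any():
            raise ValueError(f"{random_effect} missing for some records")
        formula = "n_clusters ~ " + " + ".join(exog_cols)
        model = PoissonBayesMixedGLM.from_formula(
            formula, {"grp": f"0 + C({random_effect})"}, df
        )
        fit = model.fit_vb()
        names = list(fit.model.exog_names)
        i = names.index("is_disease")
        coef, sd = fit.fe_mean[i], fit.fe_sd[i]
        from scipy.stats import norm

        p = 2 * norm.sf(abs(coef / sd))
        coefs = pd.DataFrame({"coef": fit.fe_mean, "sd": fit.fe_sd}, index=names)
        return GLMResult(
            rate_ratio=float(np.exp(coef)),
            wald_p=float(p),
            dispersion=float("nan"),
            family_used="poisson_mixed_vb",
            coefficients=coefs,
            conf_int=(float(np.exp(coef - 1.96 * sd)), float(np.exp(coef + 1.96 * sd))),
        )

    exog = sm.add_constant(df[exog_cols], has_constant="add")
    endog = df["n_clusters"].to_numpy(dtype=float)
    poisson = sm.GLM(endog, exog, family=sm.families.Poisson()).fit()
    dof = max(int(poisson.df_resid), 1)
    dispersion = float((poisson.resid_pearson**2).sum() / dof)

    if dispersion > dispersion_cutoff:
        nb = sm.NegativeBinomial(endog, exog).fit(disp=False, maxiter=200)
        if not nb.mle_retvals.get("converged", True):
            raise RuntimeError("negative binomial fit did not converge")
        params, bse, pvals = nb.params, nb.bse, nb.pvalues
        family = "negative_binomial"
        source = nb
    else:
        params, bse, pvals = poisson.params, poisson.bse, poisson.pvalues
        family = "poisson"
        source = poisson

    coef = float(params["is_disease"])
    se = float(bse["is_disease"])
    if not np.isfinite(se) or se > 1e3:
        raise RuntimeError("condition coefficient is not identified (separation?)")
    coefs = pd.DataFrame({"coef": params, "se": bse, "p": pvals})
    return GLMResult(
        rate_ratio=float(np.exp(coef)),
        wald_p=float(pvals["is_disease"]),
        dispersion=dispersion,
        family_used=family,
        coefficients=coefs,
        conf_int=(float(np.exp(coef - 1.96 * se)), float(np.exp(coef + 1.96 * se))),
    )
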