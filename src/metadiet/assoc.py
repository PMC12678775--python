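"""Univariate association engine.

Linear mixed models with a per-family random intercept (REML), an
effective-number-of-tests (Meff) Bonferroni correction derived from the
eigenvalue variance of a correlation matrix, direction-consistent
fixed-effects meta-analysis across cohorts, Benjamini-Hochberg FDR, and a
rank-sum comparison of association strength between two result sets.

Scaling conventions: exposures are inverse-rank transformed, outcomes
inverse-normal, covariates standardized to mean 0 / SD 1, so slopes are
comparable across exposure-outcome pairs. Inference on the exposure slope
uses a Wald z statistic against the normal reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._lmm import FamilyDesign, reml_scan

__all__ = [
    "AssocResult",
    "fit_lmm",
    "association_scan",
    "meff",
    "bonferroni_threshold",
    "fixed_effects_meta",
    "bh_fdr",
    "compare_matrix_strength",
]


@dataclass
class AssocResult:
    exposure: str
    outcome: str
    beta: float
    se: float
    p: float
    cohort: str = ""
    n: int = 0
    icc: float = np.nan
    converged: bool = True


def _design(exposure, covariates):
    x = np.asarray(exposure, dtype=float)
    n = x.shape[0]
    cols = [np.ones(n)]
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        C = (C - C.mean(axis=0)) / C.std(axis=0, ddof=0)
        cols.append(C)
    cols.append(x.reshape(n, -1))
    return np.column_stack(cols)


def fit_lmm(outcome, exposure, covariates, families, cohort: str = "",
            exposure_name: str = "exposure", outcome_name: str = "outcome"):
    """One mixed-model association: outcome ~ exposure + covariates + (1|family).

    Falls back to OLS (flagged via ``converged=False``) if the REML fit
    fails, which for this one-dimensional variance profile essentially
    never happens.
    """
    y = np.asarray(outcome, dtype=float)
    X = _design(exposure, covariates)
    try:
        design = FamilyDesign(families)
        res = reml_scan(y.reshape(-1, 1), X, design, refine=True)
        return AssocResult(
            exposure_name, outcome_name,
            float(res["beta"][0]), float(res["se"][0]), float(res["p"][0]),
            cohort, y.shape[0], float(res["icc"][0]), True,
        )
    except np.linalg.LinAlgError:
        beta, res_ss, *_ = np.linalg.lstsq(X, y, rcond=None)
        dof = y.shape[0] - X.shape[1]
        s2 = float(res_ss[0]) / dof if res_ss.size else np.nan
        cov = s2 * np.linalg.inv(X.T @ X)
        se = np.sqrt(cov[-1, -1])
        z = beta[-1] / se
        return AssocResult(
            exposure_name, outcome_name, float(beta[-1]), float(se),
            float(2 * stats.norm.sf(abs(z))), cohort, y.shape[0],
            0.0, False,
        )


def association_scan(outcomes: pd.DataFrame, exposures: pd.DataFrame,
                     covariates, families, cohort: str = "",
                     refine: bool = False) -> pd.DataFrame:
    """Scan every exposure against every outcome with family random intercepts.

    Batched: all outcomes for a given exposure are fitted simultaneously on
    a profiled-REML theta grid (set ``refine=True`` to polish each theta by
    scalar search; grid resolution is ample for scan-level inference).
    """
    design = FamilyDesign(np.asarray(families))
    Y = outcomes.to_numpy(dtype=float)
    rows = []
    for exp_name in exposures.columns:
        X = _design(exposures[exp_name].to_numpy(), covariates)
        res = reml_scan(Y, X, design, refine=refine)
        for j, out_name in enumerate(outcomes.columns):
            rows.append(
                (exp_name, out_name, res["beta"][j], res["se"][j],
                 res["p"][j], cohort, Y.shape[0], res["icc"][j])
            )
    return pd.DataFrame(
        rows,
        columns=["exposure", "outcome", "beta", "se", "p", "cohort", "n", "icc"],
    )


def meff(corr_matrix) -> float:
    """Effective number of independent tests (Nyholt).

    Meff = 1 + (M - 1) (1 - Var(lambda)/M) with Var(lambda) the sample
    variance (denominator M - 1) of the correlation-matrix eigenvalues.
    """
    R = np.asarray(corr_matrix, dtype=float)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(R, R.T, atol=1e-8):
        raise ValueError("correlation matrix must be symmetric")
    M = R.shape[0]
    if M == 1:
        return 1.0
    lam = np.linalg.eigvalsh(R)
    var = lam.var(ddof=1)
    return float(1.0 + (M - 1) * (1.0 - var / M))


def bonferroni_threshold(alpha: float = 0.05, meff_components=()) -> float:
    """alpha divided by the product of effective test counts per block."""
    comps = list(meff_components)
    if not comps:
        raise ValueError("at least one Meff component is required")
    if any(c < 1 for c in comps):
        raise ValueError("Meff components must be >= 1")
    return alpha / float(np.prod(comps))


def fixed_effects_meta(results: pd.DataFrame, threshold: float = None) -> pd.DataFrame:
    """Direction-filtered inverse-variance fixed-effects meta-analysis.

    ``results`` holds per-cohort rows (exposure, outcome, beta, se, ...).
    Pairs whose cohort-level effect directions disagree are retained but
    marked ``direction_consistent=False`` and not pooled. ``threshold``
    (typically the discovery-cohort Meff-Bonferroni bound) sets
    ``passes_threshold``.
    """
    key = results["exposure"].astype(str) + "\x1f" + results["outcome"].astype(str)
    codes, inverse = np.unique(key.to_numpy(), return_inverse=True)
    order = np.argsort(inverse, kind="stable")
    inv_sorted = inverse[order]
    starts = np.flatnonzero(np.r_[True, np.diff(inv_sorted) != 0])
    beta = results["beta"].to_numpy(dtype=float)[order]
    se = results["se"].to_numpy(dtype=float)[order]
    nvec = results["n"].to_numpy()[order]
    counts = np.add.reduceat(np.ones_like(beta), starts)
    pos = np.add.reduceat((beta > 0).astype(float), starts)
    neg = np.add.reduceat((beta < 0).astype(float), starts)
    consistent = (pos == counts) | (neg == counts) | (counts == 1)
    w = 1.0 / se ** 2
    wsum = np.add.reduceat(w, starts)
    pooled = np.add.reduceat(w * beta, starts) / wsum
    pooled_se = 1.0 / np.sqrt(wsum)
    p = 2 * stats.norm.sf(np.abs(pooled / pooled_se))
    pooled[~consistent] = np.nan
    pooled_se[~consistent] = np.nan
    p = np.where(consistent, p, np.nan)
    exp_out = np.array([c.split("\x1f") for c in codes])
    out = pd.DataFrame(
        {
            "exposure": exp_out[:, 0], "outcome": exp_out[:, 1],
            "beta": pooled, "se": pooled_se, "p": p,
            "n_cohorts": counts.astype(int),
            "n": np.add.reduceat(nvec.astype(float), starts).astype(int),
            "direction_consistent": consistent,
        }
    )
    out["passes_threshold"] = (
        out["direction_consistent"] & (threshold is not None)
        & (out["p"] < (threshold if threshold is not None else np.inf))
    )
    return out


def bh_fdr(pvals):
    """Benjamini-Hochberg step-up adjusted q-values."""
    p = np.asarray(pvals, dtype=float)
    return multipletests(p, method="fdr_bh")[1]


def compare_matrix_strength(pvals_a, pvals_b):
    """Wilcoxon rank-sum test on -log10 p between two association sets.

    Returns (two-sided p, which collection is stochastically stronger:
    'A', 'B' or 'tie').
    """
    a = -np.log10(np.asarray(pvals_a, dtype=float))
    b = -np.log10(np.asarray(pvals_b, dtype=float))
    if a.size == 0 or b.size == 0:
        raise ValueError("both association collections must be nonempty")
    stat = stats.mannwhitneyu(a, b, alternative="two-sided")
    auc = stat.statistic / (a.size * b.size)
    stronger = "A" if auc > 0.5 else ("B" if auc < 0.5 else "tie")
    return float(stat.pvalue), stronger
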