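"""Causal mediation screen for exposure -> mediator -> outcome trios.

Trios are formed from mutually associated (food group, metabolite,
species) triples — all three pairwise associations passing their
respective thresholds — and screened with the classical two-model
product-of-coefficients approach: a mediator model m ~ x + covariates and
an outcome model y ~ x + m + covariates, both with family random
intercepts. Inference is quasi-Bayesian: coefficient vectors are drawn
from each model's normal sampling distribution, and per draw ACME = a*b,
ADE = c', total = ACME + ADE (the additivity holds exactly for every
draw). These are statistical screens; significance is compatibility with
mediation, not proof of causality.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._lmm import fit_reml

__all__ = ["MediationResult", "enumerate_trios", "mediate"]


@dataclass
class MediationResult:
    acme: float
    ade: float
    total_effect: float
    prop_mediated: float
    prop_mediated_raw: float
    p_acme: float
    p_ade: float
    p_total: float
    acme_ci: tuple
    ade_ci: tuple
    n_sim: int
    a: float
    b: float
    c_prime: float


def enumerate_trios(food_metabolite: pd.DataFrame,
                    food_species: pd.DataFrame,
                    metabolite_species: pd.DataFrame) -> pd.DataFrame:
    """All (food group, metabolite, species) triples whose three edges pass.

    Inputs are association tables already filtered to significant edges,
    with columns naming the two endpoints: (exposure=food, outcome=
    metabolite), (exposure=food, outcome=species), (exposure=metabolite,
    outcome=species) — column order per table: 'exposure'/'outcome'.
    Both causal orderings are emitted for every triple: metabolite as
    mediator of diet -> species, and species as mediator of diet ->
    metabolite.
    """
    fm = food_metabolite[["exposure", "outcome"]].drop_duplicates()
    fs = food_species[["exposure", "outcome"]].drop_duplicates()
    ms = metabolite_species[["exposure", "outcome"]].drop_duplicates()
    merged = fm.rename(columns={"outcome": "metabolite", "exposure": "food"}) \
        .merge(fs.rename(columns={"outcome": "species", "exposure": "food"}),
               on="food") \
        .merge(ms.rename(columns={"exposure": "metabolite",
                                  "outcome": "species"}),
               on=["metabolite", "species"])
    rows = []
    for _, r in merged.iterrows():
        rows.append({"exposure": r["food"], "mediator": r["metabolite"],
                     "outcome": r["species"], "direction": "metabolite_mediates"})
        rows.append({"exposure": r["food"], "mediator": r["species"],
                     "outcome": r["metabolite"], "direction": "species_mediates"})
    return pd.DataFrame(rows, columns=["exposure", "mediator", "outcome",
                                       "direction"])


def mediate(exposure, mediator, outcome, covariates, families,
            n_sim: int = 1000, seed: int = 0,
            prop_clip: tuple = (-1.0, 2.0)) -> MediationResult:
    """Quasi-Bayesian mediation analysis of one trio.

    Fits the two family-random-intercept models by REML, draws
    (a, b, c') jointly from their normal sampling distributions ``n_sim``
    times, and summarises ACME, ADE and the total effect from the draws.
    Two-sided p values are twice the smaller tail mass at zero. The
    proportion mediated (ACME / total) is clipped to ``prop_clip`` for
    reporting stability near zero total effects; the raw value is kept.
    """
    x = np.asarray(exposure, dtype=float)
    m = np.asarray(mediator, dtype=float)
    y = np.asarray(outcome, dtype=float)
    if np.array_equal(m, y):
        raise ValueError("mediator and outcome are identical")
    n = x.size
    if covariates is not None and np.size(covariates):
        C = np.asarray(covariates, dtype=float).reshape(n, -1)
        C = (C - C.mean(axis=0)) / C.std(axis=0, ddof=0)
    else:
        C = np.zeros((n, 0))
    ones = np.ones((n, 1))

    # mediator model: m ~ x + covariates; 'a' is the exposure slope
    Xm = np.hstack([ones, C, x[:, None]])
    beta_m, cov_m, _, _ = fit_reml(m, Xm, families)
    a_hat, a_var = beta_m[-1], cov_m[-1, -1]

    # outcome model: y ~ x + m + covariates; 'c_prime' and 'b'
    Xy = np.hstack([ones, C, x[:, None], m[:, None]])
    beta_y, cov_y, _, _ = fit_reml(y, Xy, families)
    cp_hat, b_hat = beta_y[-2], beta_y[-1]
    cov_cb = cov_y[-2:, -2:]

    rng = np.random.default_rng(seed)
    a_draws = rng.normal(a_hat, np.sqrt(a_var), n_sim)
    cb_draws = rng.multivariate_normal([cp_hat, b_hat], cov_cb, n_sim)
    acme_d = a_draws * cb_draws[:, 1]
    ade_d = cb_draws[:, 0]
    total_d = acme_d + ade_d

    def _p(draws):
        lo = np.mean(draws <= 0)
        hi = np.mean(draws >= 0)
        return float(min(1.0, 2 * min(lo, hi)))

    acme = float(acme_d.mean())
    ade = float(ade_d.mean())
    total = float(total_d.mean())
    prop_raw = acme / total if total != 0 else np.nan
    prop = float(np.clip(prop_raw, *prop_clip)) if np.isfinite(prop_raw) else np.nan
    return MediationResult(
        acme=acme, ade=ade, total_effect=total,
        prop_mediated=prop, prop_mediated_raw=float(prop_raw),
        p_acme=_p(acme_d), p_ade=_p(ade_d), p_total=_p(total_d),
        acme_ci=tuple(np.percentile(acme_d, [2.5, 97.5])),
        ade_ci=tuple(np.percentile(ade_d, [2.5, 97.5])),
        n_sim=n_sim, a=float(a_hat), b=float(b_hat), c_prime=float(cp_hat),
    )
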