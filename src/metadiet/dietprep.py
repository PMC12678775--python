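"""FFQ quality control, food-group aggregation and transformation.

The preparation chain is: completeness filter (records with more than
``max_unanswered`` blank line items are dropped), energy plausibility filter
(energy intake / Harris-Benedict basal metabolic rate more than 2 SD from
the cohort mean), aggregation of line items into 20 food and beverage
groups, residual-method energy adjustment, and rank-based inverse-normal
transformation for downstream association models. The two exclusion filters
are applied in that fixed order and the energy-ratio statistics are
computed on the completeness survivors only.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "exclude_incomplete",
    "harris_benedict_bmr",
    "exclude_energy_outliers",
    "aggregate_food_groups",
    "energy_adjust_residual",
    "energy_adjust_matrix",
    "inverse_rank_transform",
    "prepare_food_groups",
]


def exclude_incomplete(ffq: pd.DataFrame, max_unanswered: int = 10):
    """Drop records with more than ``max_unanswered`` blank line items.

    Returns (retained DataFrame, exclusion log DataFrame). The rule is
    strict: exactly ``max_unanswered`` blanks is still retained.
    """
    n_missing = ffq.isna().sum(axis=1)
    keep = n_missing <= max_unanswered
    log = pd.DataFrame(
        {
            "participant_id": ffq.index[~keep],
            "n_unanswered": n_missing[~keep].to_numpy(),
            "reason": f"more than {max_unanswered} unanswered line items",
        }
    )
    return ffq.loc[keep], log


def harris_benedict_bmr(sex, weight_kg, height_cm, age_years):
    """Basal metabolic rate (kcal/day), original Harris-Benedict equations.

    ``sex`` uses 0 = female, 1 = male. Vectorised over array inputs.
    """
    sex = np.asarray(sex)
    w = np.asarray(weight_kg, dtype=float)
    h = np.asarray(height_cm, dtype=float)
    a = np.asarray(age_years, dtype=float)
    if np.any(w <= 0) or np.any(h <= 0):
        raise ValueError("weight and height must be positive")
    female = 655.1 + 9.563 * w + 1.850 * h - 4.676 * a
    male = 66.47 + 13.75 * w + 5.003 * h - 6.755 * a
    return np.where(sex == 1, male, female)


def exclude_energy_outliers(energy_kcal, bmr_kcal, sd_mult: float = 2.0,
                            log_ratio: bool = False):
    """Drop records whose energy/BMR ratio is > ``sd_mult`` SD from the mean.

    Returns (boolean keep mask aligned with the input index, log DataFrame).
    ``log_ratio`` switches the statistic to log(energy/BMR).
    """
    energy = pd.Series(np.asarray(energy_kcal, dtype=float),
                       index=getattr(energy_kcal, "index", None))
    ratio = energy.to_numpy() / np.asarray(bmr_kcal, dtype=float)
    if log_ratio:
        ratio = np.log(ratio)
    if ratio.size < 3:
        warnings.warn("fewer than 3 records; energy-ratio filter skipped")
        keep = np.ones(ratio.size, dtype=bool)
    else:
        sd = ratio.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            keep = np.ones(ratio.size, dtype=bool)
        else:
            keep = np.abs(ratio - ratio.mean()) <= sd_mult * sd
    keep = pd.Series(keep, index=energy.index)
    log = pd.DataFrame(
        {
            "participant_id": energy.index[~keep.to_numpy()],
            "ratio": ratio[~keep.to_numpy()],
            "reason": f"energy/BMR ratio beyond {sd_mult} SD",
        }
    )
    return keep, log


def aggregate_food_groups(ffq: pd.DataFrame, mapping: dict,
                          expected_groups=None) -> pd.DataFrame:
    """Sum line-item intakes into food groups.

    ``mapping`` maps line-item column -> group name; items absent from the
    mapping are ignored. Unanswered (missing) items count as zero intake.
    """
    groups = {}
    for item, group in mapping.items():
        if isinstance(group, (list, tuple, set)):
            raise ValueError(f"line item {item!r} mapped to multiple groups")
        groups.setdefault(group, []).append(item)
    if expected_groups is not None:
        missing = set(expected_groups) - set(groups)
        if missing:
            raise ValueError(f"mapping lacks groups: {sorted(missing)}")
    out = {}
    for group, items in groups.items():
        present = [i for i in items if i in ffq.columns]
        out[group] = ffq[present].fillna(0.0).sum(axis=1)
    cols = list(expected_groups) if expected_groups is not None else sorted(out)
    return pd.DataFrame(out)[cols]


def energy_adjust_residual(intake, energy):
    """Residual-method energy adjustment of one intake vector.

    Regresses intake on total energy and returns residual + mean intake, so
    the adjusted values are uncorrelated with energy but stay on the
    original scale.
    """
    x = np.asarray(energy, dtype=float)
    y = np.asarray(intake, dtype=float)
    if x.size != y.size:
        raise ValueError("intake and energy must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 records for the residual method")
    sx = x.std()
    if sx == 0:
        warnings.warn("constant energy; returning mean-centred intake + mean")
        return y - y.mean() + y.mean()
    slope = np.cov(x, y, ddof=0)[0, 1] / x.var()
    resid = y - (y.mean() + slope * (x - x.mean()))
    return resid + y.mean()


def energy_adjust_matrix(foodgroups: pd.DataFrame, energy) -> pd.DataFrame:
    """Apply the residual method column-wise to a food-group matrix."""
    adj = {
        c: energy_adjust_residual(foodgroups[c].to_numpy(), energy)
        for c in foodgroups.columns
    }
    return pd.DataFrame(adj, index=foodgroups.index)


def inverse_rank_transform(values, c: float = 3.0 / 8.0):
    """Rank-based inverse-normal scores (Blom offset by default).

    Average ranks for ties; raises if the input carries no ordering
    information (all values tied).
    """
    x = np.asarray(values, dtype=float)
    if np.unique(x[~np.isnan(x)]).size < 2:
        raise ValueError("inverse rank transform needs >= 2 distinct values")
    n = np.sum(~np.isnan(x))
    ranks = stats.rankdata(x, method="average", nan_policy="omit")
    with np.errstate(invalid="ignore"):
        scores = stats.norm.ppf((ranks - c) / (n - 2 * c + 1))
    if isinstance(values, pd.Series):
        return pd.Series(scores, index=values.index)
    return scores


def prepare_food_groups(ffq_items: pd.DataFrame, nutrients: pd.DataFrame,
                        participants: pd.DataFrame, mapping: dict,
                        max_unanswered: int = 10, sd_mult: float = 2.0,
                        log_ratio: bool = False):
    """Full FFQ preparation for one cohort.

    Returns (energy-adjusted food-group matrix, raw food-group matrix,
    exclusion log). Exclusion order is fixed: completeness first, then the
    energy/BMR filter on the survivors.
    """
    retained, log1 = exclude_incomplete(ffq_items, max_unanswered)
    part = participants.loc[retained.index]
    nutr = nutrients.loc[retained.index]
    bmr = harris_benedict_bmr(
        part["sex"], part["weight_kg"], part["height_cm"], part["age_years"]
    )
    keep, log2 = exclude_energy_outliers(
        nutr["energy_kcal"], bmr, sd_mult=sd_mult, log_ratio=log_ratio
    )
    retained = retained.loc[keep.to_numpy()]
    nutr = nutr.loc[retained.index]
    raw = aggregate_food_groups(retained, mapping)
    adjusted = energy_adjust_matrix(raw, nutr["energy_kcal"].to_numpy())
    log = pd.concat([log1, log2], ignore_index=True)
    return adjusted, raw, log
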