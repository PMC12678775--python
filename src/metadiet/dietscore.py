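"""The seven a priori dietary indices and 10-year ASCVD risk.

Indices: the plant-based diet index family (PDI, hPDI, uPDI; quintile-scored
sums over 18 components, range 18-90), DASH (8 components, range 8-40),
the alternate Mediterranean score aMED (9 median-based components, 0-9) and
the total percentage of diet weight from plant or meat groups. Quintiles
and medians are always cohort-internal, so scores express *relative*
adherence within a cohort. Component-to-food-group membership lives in a
JSON config (``data/index_definitions.json``), not in code.

ASCVD risk uses the pooled cohort equations: sex- and race-specific
coefficients on log-transformed continuous terms, risk = 1 - S0^exp(L -
mean_L). Coefficients ship as config (``data/ascvd_coefficients.json``).
"""

from __future__ import annotations

import json
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "load_index_definitions",
    "load_ascvd_coefficients",
    "quintile_scores",
    "score_pdi_family",
    "score_dash",
    "score_amed",
    "plant_meat_percent",
    "score_all_indices",
    "ascvd_10yr_risk",
]


def load_index_definitions():
    with resources.files("metadiet.data").joinpath("index_definitions.json").open() as fh:
        return json.load(fh)


def load_ascvd_coefficients():
    with resources.files("metadiet.data").joinpath("ascvd_coefficients.json").open() as fh:
        return json.load(fh)


def _component_value(table: pd.DataFrame, nutrients, columns):
    """Sum the referenced columns; 'nutrient:' entries come from nutrients."""
    total = np.zeros(len(table))
    for col in columns:
        if col.startswith("nutrient:"):
            if nutrients is None:
                raise ValueError(f"component {col!r} needs a nutrient table")
            total = total + nutrients[col.split(":", 1)[1]].to_numpy(dtype=float)
        else:
            if col not in table.columns:
                raise ValueError(f"missing index component group {col!r}")
            total = total + table[col].to_numpy(dtype=float)
    return total


def quintile_scores(values, reverse: bool = False):
    """Within-cohort quintile scores 1..5 (5..1 when reversed).

    Quintile edges are the empirical 20/40/60/80 percentiles; values tied
    with an edge fall in the lower quintile.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 5:
        raise ValueError("quintile scoring needs at least 5 observations")
    edges = np.percentile(x, [20, 40, 60, 80])
    score = 1 + (x[:, None] > edges[None, :]).sum(axis=1)
    if reverse:
        score = 6 - score
    return score


def score_pdi_family(foodgroups: pd.DataFrame, definitions=None,
                     variant: str = "PDI", nutrients=None):
    """PDI / hPDI / uPDI: sum of 18 quintile-scored components.

    Positive scoring per variant: PDI rewards all plant components; hPDI
    rewards healthy-plant only; uPDI rewards less-healthy-plant only; all
    remaining components are reverse-scored.
    """
    defs = (definitions or load_index_definitions())["pdi_family"]
    positive = {
        "PDI": {"healthy_plant", "less_healthy_plant"},
        "hPDI": {"healthy_plant"},
        "uPDI": {"less_healthy_plant"},
    }
    if variant not in positive:
        raise ValueError(f"unknown PDI variant {variant!r}")
    total = np.zeros(len(foodgroups), dtype=int)
    for cls, components in defs.items():
        rev = cls not in positive[variant]
        for comp in components:
            v = _component_value(foodgroups, nutrients, comp)
            total += quintile_scores(v, reverse=rev)
    return pd.Series(total, index=foodgroups.index, name=variant)


def score_dash(foodgroups: pd.DataFrame, definitions=None, nutrients=None):
    """DASH: 5 encouraged + 3 discouraged quintile-scored components (8-40)."""
    defs = (definitions or load_index_definitions())["dash"]
    total = np.zeros(len(foodgroups), dtype=int)
    for comp in defs["encouraged"]:
        total += quintile_scores(_component_value(foodgroups, nutrients, comp))
    for comp in defs["discouraged"]:
        total += quintile_scores(
            _component_value(foodgroups, nutrients, comp), reverse=True
        )
    return pd.Series(total, index=foodgroups.index, name="DASH")


def score_amed(foodgroups: pd.DataFrame, sex, definitions=None,
               nutrients=None):
    """aMED: one point per beneficial component above the cohort median,
    red/processed meat below the median, and alcohol inside a sex-specific
    moderate-intake window (0-9)."""
    if len(foodgroups) < 2:
        raise ValueError("aMED needs at least 2 participants")
    defs = (definitions or load_index_definitions())["amed"]
    sex = np.asarray(sex)
    total = np.zeros(len(foodgroups), dtype=int)
    for comp in defs["above_median"]:
        v = _component_value(foodgroups, nutrients, comp)
        total += (v > np.median(v)).astype(int)
    for comp in defs["below_median"]:
        v = _component_value(foodgroups, nutrients, comp)
        total += (v < np.median(v)).astype(int)
    alc = foodgroups[defs["alcohol_group"]].to_numpy(dtype=float)
    lo = np.where(sex == 1, defs["alcohol_window_male"][0],
                  defs["alcohol_window_female"][0])
    hi = np.where(sex == 1, defs["alcohol_window_male"][1],
                  defs["alcohol_window_female"][1])
    total += ((alc >= lo) & (alc <= hi)).astype(int)
    return pd.Series(total, index=foodgroups.index, name="aMED")


def plant_meat_percent(foodgroups: pd.DataFrame, definitions=None):
    """Percent of total dietary grams from plant groups and from meat groups.

    Computed on raw (unadjusted) gram intakes.
    """
    defs = (definitions or load_index_definitions())["plant_meat"]
    total = foodgroups.sum(axis=1).to_numpy(dtype=float)
    if np.any(total <= 0):
        raise ValueError("zero total intake for at least one participant")
    plant_cols = [g for g in defs["plant_groups"] if g in foodgroups.columns]
    meat_cols = [g for g in defs["meat_groups"] if g in foodgroups.columns]
    plant = foodgroups[plant_cols].sum(axis=1).to_numpy() / total * 100.0
    meat = (foodgroups[meat_cols].sum(axis=1).to_numpy() / total * 100.0
            if meat_cols else np.zeros(len(foodgroups)))
    return (pd.Series(plant, index=foodgroups.index, name="plant_pct"),
            pd.Series(meat, index=foodgroups.index, name="meat_pct"))


def score_all_indices(adjusted: pd.DataFrame, raw: pd.DataFrame, sex,
                      nutrients=None, definitions=None) -> pd.DataFrame:
    """All seven indices: quintile/median indices on energy-adjusted intakes,
    diet-composition percentages on raw grams."""
    defs = definitions or load_index_definitions()
    out = pd.DataFrame(index=adjusted.index)
    for variant in ("PDI", "hPDI", "uPDI"):
        out[variant] = score_pdi_family(adjusted, defs, variant, nutrients)
    out["DASH"] = score_dash(adjusted, defs, nutrients)
    out["aMED"] = score_amed(adjusted, sex, defs, nutrients)
    plant, meat = plant_meat_percent(raw, defs)
    out["plant_pct"] = plant
    out["meat_pct"] = meat
    return out


def _terms(age, tc, hdl, sbp, treated, smoker, diabetes):
    la = np.log(age)
    vals = {
        "ln_age": la, "ln_age_sq": la ** 2,
        "ln_tc": np.log(tc), "ln_age_ln_tc": la * np.log(tc),
        "ln_hdl": np.log(hdl), "ln_age_ln_hdl": la * np.log(hdl),
        "ln_sbp_treated": np.log(sbp) * treated,
        "ln_age_ln_sbp_treated": la * np.log(sbp) * treated,
        "ln_sbp_untreated": np.log(sbp) * (1 - treated),
        "ln_age_ln_sbp_untreated": la * np.log(sbp) * (1 - treated),
        "smoker": smoker, "ln_age_smoker": la * smoker,
        "diabetes": diabetes,
    }
    return vals


def ascvd_10yr_risk(profile, coefficients=None) -> float:
    """10-year risk of a first hard ASCVD event for one risk profile.

    ``profile`` is a mapping with keys age_years, sex (0 female / 1 male),
    race_group ('white'/'black'), total_chol_mgdl, hdl_mgdl, sbp_mmhg,
    on_htn_meds, diabetes, smoker. Ages of 80 and over are ineligible.
    """
    coeffs = coefficients or load_ascvd_coefficients()
    age = float(profile["age_years"])
    if age >= 80:
        raise ValueError("ASCVD pooled cohort equations apply below age 80")
    sex = "male" if int(profile["sex"]) == 1 else "female"
    race = str(profile["race_group"]).lower()
    key = f"{sex}_{race}"
    if key not in coeffs:
        raise ValueError(f"no coefficient stratum for {key!r}")
    stratum = coeffs[key]
    terms = _terms(
        age, float(profile["total_chol_mgdl"]), float(profile["hdl_mgdl"]),
        float(profile["sbp_mmhg"]), int(profile["on_htn_meds"]),
        int(profile["smoker"]), int(profile["diabetes"]),
    )
    L = sum(c * terms[name] for name, c in stratum["coefficients"].items())
    risk = 1.0 - stratum["S0"] ** np.exp(L - stratum["mean_L"])
    return float(risk)


def ascvd_risk_table(profiles: pd.DataFrame, coefficients=None) -> pd.Series:
    """Vector of risks for all eligible (< 80 y) rows; others are dropped."""
    coeffs = coefficients or load_ascvd_coefficients()
    eligible = profiles[profiles["age_years"] < 80]
    risks = [
        ascvd_10yr_risk(row, coeffs) for _, row in eligible.iterrows()
    ]
    return pd.Series(risks, index=eligible.index, name="ascvd_10yr_risk")
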