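"""Synthetic twin-cohort generator with planted ground truth.

Emulates the data layout of a two-cohort (discovery + replication) study of
habitual diet, the faecal metabolome and the gut microbiome:

* participants with twin-family structure (MZ pairs sharing a full family
  effect, DZ pairs sharing half, singletons none) and basic covariates;
* 131 FFQ line items aggregating into 20 food and beverage groups whose
  log-intakes are right-skewed and correlated through one latent
  plant-vs-animal axis;
* nutrient totals (energy, macronutrients, sodium) derived from the line
  items so that residual energy adjustment has real work to do;
* a metabolite intensity matrix with run-day multiplicative drift,
  per-metabolite MCAR missingness, and planted linear diet effects on the
  latent (inverse-normal) scale;
* compositional species counts with planted metabolite links;
* planted exposure -> mediator -> outcome trios for the mediation screen.

Every planted quantity is recorded in a :class:`TruthRegistry` so that
downstream stages can be tested for recovery. Generation is deterministic
given ``SynthConfig.seed``; effect directions and magnitudes are shared
between the two cohorts, noise is cohort specific.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "FOOD_GROUPS",
    "SynthConfig",
    "TruthRegistry",
    "CohortBundle",
    "generate_cohorts",
    "generate_ascvd_inputs",
    "default_item_mapping",
    "write_bundle",
]

# name: (median g/day, log-sd, loading on plant-vs-animal axis, kcal/g,
#        category, n FFQ line items)
FOOD_GROUPS = {
    "fruits":            (150.0, 0.6,  0.50, 0.60, "plant", 7),
    "vegetables":        (200.0, 0.5,  0.60, 0.35, "plant", 7),
    "legumes":           (30.0,  0.8,  0.50, 1.00, "plant", 7),
    "nuts_seeds":        (10.0,  1.0,  0.50, 6.00, "plant", 6),
    "whole_grains":      (80.0,  0.7,  0.40, 2.50, "plant", 7),
    "refined_grains":    (120.0, 0.6, -0.10, 2.60, "plant", 7),
    "potatoes":          (80.0,  0.6, -0.10, 0.90, "plant", 6),
    "sweets_desserts":   (50.0,  0.8, -0.20, 4.00, "plant", 7),
    "sugary_beverages":  (100.0, 1.2, -0.30, 0.40, "plant", 6),
    "fruit_juice":       (60.0,  1.0,  0.10, 0.45, "plant", 6),
    "tea_coffee":        (500.0, 0.7,  0.10, 0.05, "plant", 7),
    "vegetable_oils":    (15.0,  0.7,  0.30, 8.80, "plant", 6),
    "red_meat":          (50.0,  0.8, -0.60, 2.20, "animal", 7),
    "processed_meat":    (25.0,  0.9, -0.60, 3.00, "animal", 6),
    "poultry":           (40.0,  0.8, -0.30, 1.70, "animal", 6),
    "fish_seafood":      (30.0,  0.9,  0.20, 1.50, "animal", 7),
    "eggs":              (25.0,  0.8, -0.20, 1.40, "animal", 6),
    "dairy_lowfat":      (150.0, 0.9,  0.00, 0.50, "animal", 7),
    "dairy_highfat":     (60.0,  0.8, -0.30, 1.50, "animal", 7),
    "alcohol":           (8.0,   1.5,  0.00, 0.70, "other", 6),
}

_PROTEIN_FRAC = {
    "red_meat": 0.20, "processed_meat": 0.15, "poultry": 0.22,
    "fish_seafood": 0.18, "eggs": 0.13, "dairy_lowfat": 0.035,
    "dairy_highfat": 0.05, "legumes": 0.08, "nuts_seeds": 0.20,
    "whole_grains": 0.10, "refined_grains": 0.09,
}
_FAT_FRAC = {
    "vegetable_oils": 0.95, "nuts_seeds": 0.50, "dairy_highfat": 0.25,
    "processed_meat": 0.25, "red_meat": 0.15, "eggs": 0.10,
    "sweets_desserts": 0.18, "dairy_lowfat": 0.015, "poultry": 0.08,
    "fish_seafood": 0.06,
}
_SODIUM_MG_PER_G = {
    "processed_meat": 10.0, "sweets_desserts": 2.0, "refined_grains": 4.0,
    "whole_grains": 3.0, "dairy_highfat": 5.0, "red_meat": 0.7,
    "fish_seafood": 3.0, "potatoes": 0.5, "vegetables": 0.3,
}

_SUPERPATHWAYS = [
    "Amino Acid", "Peptide", "Carbohydrate", "Energy", "Lipid",
    "Nucleotide", "Cofactors and Vitamins", "Xenobiotics",
]


@dataclass
class SynthConfig:
    """Study conditions for the synthetic cohorts.

    Defaults follow the emulated two-cohort design: twin composition
    MZ : DZ : unpaired of roughly 0.45 : 0.29 : 0.26 of individuals, 20
    food groups from 131 FFQ line items, right-skewed intakes organised
    along one plant-vs-animal axis, and metabolite effects expressed as
    standardized slopes on the inverse-normal scale.
    """

    n_discovery: int = 400
    n_replication: int = 400
    frac_mz_pairs: float = 0.45
    frac_dz_pairs: float = 0.29
    n_food_groups: int = 20
    n_metabolites: int = 200
    n_species: int = 100
    n_informative_metabolites: int = 20
    effect_size_beta: float = 0.25
    family_icc: float = 0.3
    missing_rate_range: tuple = (0.0, 0.30)
    mediation_trios: list = None
    # share of log-intake variance carried by the latent plant-vs-animal
    # factor is loading**2 per group; setting latent_scale=0 decouples groups
    latent_scale: float = 1.0
    species_link_gamma: float = 0.3
    # each linked metabolite perturbs this many species; >1 gives a
    # metabolite a community-wide (PERMANOVA-visible) footprint
    species_links_per_metabolite: int = 1
    n_run_days: int = 8
    run_day_drift_sd: float = 0.3
    seed: int = 0

    def __post_init__(self):
        for name in ("frac_mz_pairs", "frac_dz_pairs", "family_icc"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.frac_mz_pairs + self.frac_dz_pairs > 1.0:
            raise ValueError("frac_mz_pairs + frac_dz_pairs exceeds 1")
        if self.n_informative_metabolites > self.n_metabolites:
            raise ValueError(
                "n_informative_metabolites exceeds n_metabolites"
            )
        lo, hi = self.missing_rate_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("missing_rate_range must be an interval in [0, 1]")
        if self.n_food_groups > len(FOOD_GROUPS):
            raise ValueError(
                f"n_food_groups at most {len(FOOD_GROUPS)} supported"
            )
        if self.mediation_trios is None:
            self.mediation_trios = default_mediation_trios()
        groups = list(FOOD_GROUPS)[: self.n_food_groups]
        for trio in self.mediation_trios:
            if trio["exposure"] not in groups:
                raise ValueError(
                    f"mediation trio exposure {trio['exposure']!r} is not a "
                    "generated food group"
                )


def default_mediation_trios():
    # a*b/(a*b + c') = 0.4 for each planted trio
    return [
        {"exposure": "red_meat", "a": 0.5, "b": 0.4, "c_prime": 0.3},
        {"exposure": "nuts_seeds", "a": 0.5, "b": 0.4, "c_prime": 0.3},
        {"exposure": "vegetables", "a": 0.5, "b": 0.4, "c_prime": 0.3},
    ]


@dataclass
class TruthRegistry:
    diet_metabolite_effects: list = field(default_factory=list)
    metabolite_species_effects: list = field(default_factory=list)
    mediation_params: list = field(default_factory=list)
    informative_feature_ids: set = field(default_factory=set)
    latent_index_groups: list = field(default_factory=list)

    def to_json(self):
        d = dataclasses.asdict(self)
        d["informative_feature_ids"] = sorted(self.informative_feature_ids)
        return json.dumps(d, indent=1)


@dataclass
class CohortBundle:
    name: str
    participants: pd.DataFrame
    ffq_line_items: pd.DataFrame
    nutrients: pd.DataFrame
    metabolites_raw: pd.DataFrame
    metabolite_annotation: pd.DataFrame
    run_day: pd.Series
    species_counts: pd.DataFrame
    truth: TruthRegistry
    item_mapping: dict
    latent_diet_axis: pd.Series


def default_item_mapping(n_food_groups=20):
    """item -> food-group mapping for the 131 synthetic FFQ line items."""
    mapping = {}
    for g, (name, spec) in enumerate(FOOD_GROUPS.items()):
        if g >= n_food_groups:
            break
        for j in range(spec[5]):
            mapping[f"item_{name}_{j}"] = name
    return mapping


def _family_structure(n, cfg, rng):
    """Assign family ids and zygosity; returns (family_ids, zygosity)."""
    n_mz = int(round(n * cfg.frac_mz_pairs / 2)) * 2
    n_dz = int(round(n * cfg.frac_dz_pairs / 2)) * 2
    if n_mz + n_dz > n:
        n_dz = max(0, (n - n_mz) // 2 * 2)
    fam, zyg = [], []
    fid = 0
    for _ in range(n_mz // 2):
        fam += [fid, fid]; zyg += ["MZ", "MZ"]; fid += 1
    for _ in range(n_dz // 2):
        fam += [fid, fid]; zyg += ["DZ", "DZ"]; fid += 1
    while len(fam) < n:
        fam.append(fid); zyg.append("UP"); fid += 1
    order = rng.permutation(n)
    return np.array(fam)[order], np.array(zyg)[order]


def _family_effect(family_ids, zygosity, rng):
    """Standard-normal per-person effect: MZ share fully, DZ share half."""
    fam_codes, inv = np.unique(family_ids, return_inverse=True)
    shared = rng.standard_normal(fam_codes.size)[inv]
    own = rng.standard_normal(family_ids.size)
    out = np.where(
        zygosity == "MZ", shared,
        np.where(
            zygosity == "DZ",
            np.sqrt(0.5) * shared + np.sqrt(0.5) * own,
            own,
        ),
    )
    return out


def _make_cohort(name, n, cfg, shared, rng):
    groups = shared["groups"]
    n_g = len(groups)
    prefix = name[:4]

    family_ids, zygosity = _family_structure(n, cfg, rng)
    pid = [f"{prefix}_{i:05d}" for i in range(n)]
    sex = (rng.random(n) < 0.15).astype(int)  # 0 female, 1 male
    age = np.clip(rng.normal(58, 13, n), 20, 95)
    height = np.where(sex == 1, rng.normal(177, 7, n), rng.normal(164, 7, n))
    weight = np.clip(rng.normal(70, 14, n) + 6 * sex, 40, 160)
    participants = pd.DataFrame(
        {
            "participant_id": pid, "family_id": [f"fam_{prefix}_{f}" for f in family_ids],
            "zygosity": zygosity, "cohort": name, "sex": sex,
            "age_years": age, "weight_kg": weight, "height_cm": height,
            "bmi": weight / (height / 100.0) ** 2,
        }
    ).set_index("participant_id")

    # latent plant-vs-animal axis, partly family-shared
    z_fam = _family_effect(family_ids, zygosity, rng)
    z = np.sqrt(0.3) * z_fam + np.sqrt(0.7) * rng.standard_normal(n)

    # food-group latent normals and gram intakes
    latent = np.empty((n, n_g))
    intakes = np.empty((n, n_g))
    for j, g in enumerate(groups):
        median, sd, lam, *_ = FOOD_GROUPS[g]
        lam = lam * cfg.latent_scale
        latent[:, j] = lam * z + np.sqrt(max(1 - lam ** 2, 1e-9)) * rng.standard_normal(n)
        intakes[:, j] = np.exp(np.log(median) + sd * latent[:, j])

    # planted energy over/under-reporters to exercise the energy-ratio filter
    report = np.ones(n)
    flag = rng.random(n)
    report[flag < 0.01] = 3.0
    report[flag > 0.995] = 0.25
    intakes = intakes * report[:, None]

    dens = np.array([FOOD_GROUPS[g][3] for g in groups])
    energy = intakes @ dens * np.exp(rng.normal(0, 0.05, n))
    protein = intakes @ np.array([_PROTEIN_FRAC.get(g, 0.02) for g in groups])
    fat = intakes @ np.array([_FAT_FRAC.get(g, 0.01) for g in groups])
    carb = np.maximum((energy - 4 * protein - 9 * fat), 40.0) / 4.0
    sodium = intakes @ np.array([_SODIUM_MG_PER_G.get(g, 0.2) for g in groups])
    nutrients = pd.DataFrame(
        {
            "energy_kcal": energy,
            "protein_g": protein * np.exp(rng.normal(0, 0.05, n)),
            "fat_g": fat * np.exp(rng.normal(0, 0.05, n)),
            "carbohydrate_g": carb,
            "sodium_mg": sodium * np.exp(rng.normal(0, 0.08, n)),
        },
        index=participants.index,
    )

    # split group intakes over their FFQ line items with fixed weights
    item_cols, item_vals = [], []
    for j, g in enumerate(groups):
        w = shared["item_weights"][g]
        for k, wk in enumerate(w):
            item_cols.append(f"item_{g}_{k}")
            item_vals.append(intakes[:, j] * wk)
    ffq = pd.DataFrame(
        np.column_stack(item_vals), index=participants.index, columns=item_cols
    )
    # unanswered line items -> NA; a small tail of participants exceeds the
    # 10-item completeness gate
    n_unans = rng.poisson(1.5, n)
    heavy = rng.random(n) < 0.03
    n_unans[heavy] = rng.poisson(14, heavy.sum())
    arr = ffq.to_numpy()
    for i in range(n):
        k = min(n_unans[i], arr.shape[1])
        if k:
            arr[i, rng.choice(arr.shape[1], k, replace=False)] = np.nan
    ffq = pd.DataFrame(arr, index=ffq.index, columns=ffq.columns)

    # metabolites on the latent inverse-normal scale
    beta = cfg.effect_size_beta
    icc = cfg.family_icc
    M = cfg.n_metabolites
    u = np.column_stack(
        [_family_effect(family_ids, zygosity, rng) for _ in range(M)]
    )
    eps = rng.standard_normal((n, M))
    resid = np.sqrt(icc) * u + np.sqrt(1 - icc) * eps
    latent_met = np.empty((n, M))
    for j in range(M):
        g_idx = shared["met_link"][j]
        if g_idx >= 0:
            latent_met[:, j] = beta * latent[:, g_idx] + np.sqrt(max(1 - beta ** 2, 1e-9)) * resid[:, j]
        else:
            latent_met[:, j] = resid[:, j]

    # planted mediation trios overwrite reserved metabolite / species columns
    trio_records = []
    trio_outcome_latent = {}
    for t, trio in enumerate(cfg.mediation_trios):
        a, b, cpr = trio["a"], trio["b"], trio["c_prime"]
        g_idx = groups.index(trio["exposure"])
        x = latent[:, g_idx]
        met_j = shared["trio_mediator_idx"][t]
        med_resid = np.sqrt(icc) * _family_effect(family_ids, zygosity, rng) \
            + np.sqrt(1 - icc) * rng.standard_normal(n)
        med = a * x + np.sqrt(max(1 - a ** 2, 1e-9)) * med_resid
        latent_met[:, met_j] = med
        var_lin = b ** 2 + cpr ** 2 + 2 * a * b * cpr
        out = b * med + cpr * x + np.sqrt(max(1 - var_lin, 0.1)) * rng.standard_normal(n)
        sp_idx = shared["trio_species_idx"][t]
        trio_outcome_latent[sp_idx] = out
        denom = a * b + cpr
        trio_records.append(
            {
                "exposure": trio["exposure"],
                "mediator": f"met_{met_j:04d}",
                "outcome": f"sp_{sp_idx:04d}",
                "a": a, "b": b, "c_prime": cpr,
                "true_prop_mediated": a * b / denom if denom else np.nan,
            }
        )

    met_names = [f"met_{j:04d}" for j in range(M)]
    run_day = pd.Series(
        np.arange(n) % cfg.n_run_days, index=participants.index, name="run_day"
    )
    drift = shared["rng_drift"].lognormal(0.0, cfg.run_day_drift_sd, (cfg.n_run_days, M))
    intensities = np.exp(0.5 * latent_met) * drift[run_day.to_numpy()]

    miss_rate = rng.uniform(*cfg.missing_rate_range, M)
    miss_rate[shared["trio_mediator_idx"]] = 0.0  # planted mediators stay measured
    mask = rng.random((n, M)) < miss_rate[None, :]
    intensities = np.where(mask, np.nan, intensities)
    metabolites = pd.DataFrame(intensities, index=participants.index, columns=met_names)

    annotation = pd.DataFrame(
        {
            "metabolite": met_names,
            "superpathway": [_SUPERPATHWAYS[j % len(_SUPERPATHWAYS)] for j in range(M)],
            "subpathway": [f"subpathway_{j % 25:02d}" for j in range(M)],
            "characterised": [(j % 5) != 4 for j in range(M)],
        }
    ).set_index("metabolite")

    # species: log-normal with planted metabolite links, closed + counted
    S = cfg.n_species
    base = shared["species_base"]
    log_ab = base[None, :] + rng.standard_normal((n, S))
    for (met_j, sp_j, gamma) in shared["species_links"]:
        log_ab[:, sp_j] += gamma * latent_met[:, met_j]
    for sp_j, out in trio_outcome_latent.items():
        log_ab[:, sp_j] = base[sp_j] + out
    rel = np.exp(log_ab)
    rel /= rel.sum(axis=1, keepdims=True)
    depth = np.exp(rng.normal(np.log(5e4), 0.3, n))
    counts = rng.poisson(depth[:, None] * rel).astype(float)
    species = pd.DataFrame(
        counts, index=participants.index,
        columns=[f"sp_{j:04d}" for j in range(S)],
    )

    truth = TruthRegistry(
        diet_metabolite_effects=[
            (groups[shared["met_link"][j]], f"met_{j:04d}", beta)
            for j in range(M) if shared["met_link"][j] >= 0
        ],
        metabolite_species_effects=[
            (f"met_{mj:04d}", f"sp_{sj:04d}", g)
            for (mj, sj, g) in shared["species_links"]
        ],
        mediation_params=trio_records,
        informative_feature_ids={
            f"met_{j:04d}" for j in range(M) if shared["met_link"][j] >= 0
        },
        latent_index_groups=[
            groups[shared["met_link"][j]] for j in range(M)
            if shared["met_link"][j] >= 0
        ],
    )

    return CohortBundle(
        name=name,
        participants=participants,
        ffq_line_items=ffq,
        nutrients=nutrients,
        metabolites_raw=metabolites,
        metabolite_annotation=annotation,
        run_day=run_day,
        species_counts=species,
        truth=truth,
        item_mapping=default_item_mapping(n_g),
        latent_diet_axis=pd.Series(z, index=participants.index, name="latent_diet_axis"),
    )


def generate_cohorts(config: SynthConfig):
    """Generate the (discovery, replication) cohort pair.

    Planted effect assignments (which metabolite tracks which food group,
    which species links to which metabolite, run-day drift factors, FFQ item
    weights) are drawn once and shared between cohorts; participant-level
    noise is cohort specific.
    """
    cfg = config
    ss = np.random.SeedSequence(cfg.seed)
    rng_shared, rng_disc, rng_repl, rng_drift = [
        np.random.default_rng(s) for s in ss.spawn(4)
    ]
    groups = list(FOOD_GROUPS)[: cfg.n_food_groups]

    met_link = np.full(cfg.n_metabolites, -1)
    for j in range(cfg.n_informative_metabolites):
        met_link[j] = j % cfg.n_food_groups

    n_trios = len(cfg.mediation_trios)
    # reserve non-informative metabolites / abundant species for trios
    trio_mediator_idx = np.arange(
        cfg.n_metabolites - n_trios, cfg.n_metabolites
    )
    trio_species_idx = np.arange(cfg.n_species - n_trios, cfg.n_species)

    species_base = rng_shared.normal(0.0, 2.0, cfg.n_species)
    # a rare tail so the prevalence filter has something to remove
    n_rare = max(cfg.n_species // 5, 1)
    rare_idx = np.arange(cfg.n_species - n_trios - n_rare, cfg.n_species - n_trios)
    species_base[rare_idx] = -9.0
    species_base[trio_species_idx] = 1.0

    n_links = min(cfg.n_informative_metabolites, 10)
    linkable_sp = [
        j for j in range(cfg.n_species)
        if j not in set(rare_idx) and j not in set(trio_species_idx)
    ]
    K = max(int(cfg.species_links_per_metabolite), 1)
    species_links = [
        (j, linkable_sp[(j * K + t) % len(linkable_sp)],
         cfg.species_link_gamma)
        for j in range(n_links) for t in range(K)
    ]

    item_weights = {}
    for g in groups:
        k = FOOD_GROUPS[g][5]
        w = rng_shared.dirichlet(np.full(k, 2.0))
        item_weights[g] = w

    shared = {
        "groups": groups,
        "met_link": met_link,
        "species_base": species_base,
        "species_links": species_links,
        "item_weights": item_weights,
        "trio_mediator_idx": trio_mediator_idx,
        "trio_species_idx": trio_species_idx,
        "rng_drift": rng_drift,
    }

    disc = _make_cohort("discovery", cfg.n_discovery, cfg, shared, rng_disc)
    # drift factors are per-cohort runs; redraw from the same stream
    repl = _make_cohort("replication", cfg.n_replication, cfg, shared, rng_repl)
    return disc, repl


def generate_ascvd_inputs(participants: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Plausible cardiovascular risk-factor table for the given participants.

    Continuous factors are drawn from population-typical ranges; binary
    treatment / diabetes / smoking flags are Bernoulli. Ages come from the
    participant table so the downstream under-80 eligibility filter applies.
    """
    rng = np.random.default_rng(seed)
    n = len(participants)
    if n == 0:
        return pd.DataFrame(
            columns=[
                "age_years", "sex", "race_group", "total_chol_mgdl",
                "hdl_mgdl", "sbp_mmhg", "on_htn_meds", "diabetes", "smoker",
            ]
        )
    out = pd.DataFrame(index=participants.index)
    out["age_years"] = participants["age_years"].to_numpy()
    out["sex"] = participants["sex"].to_numpy()
    out["race_group"] = np.where(rng.random(n) < 0.05, "black", "white")
    out["total_chol_mgdl"] = np.clip(rng.normal(205, 35, n), 120, 320)
    out["hdl_mgdl"] = np.clip(rng.normal(55, 14, n), 22, 100)
    out["sbp_mmhg"] = np.clip(rng.normal(125, 15, n), 92, 190)
    out["on_htn_meds"] = (rng.random(n) < 0.20).astype(int)
    out["diabetes"] = (rng.random(n) < 0.08).astype(int)
    out["smoker"] = (rng.random(n) < 0.12).astype(int)
    return out


def write_bundle(bundle: CohortBundle, outdir) -> None:
    """Write one cohort as flat TSV files plus truth.json ('NA' = missing)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle.participants.to_csv(outdir / "participants.tsv", sep="\t", na_rep="NA")
    ffq = bundle.ffq_line_items.join(bundle.nutrients)
    ffq.to_csv(outdir / "ffq.tsv", sep="\t", na_rep="NA")
    met = bundle.metabolites_raw.copy()
    met.insert(0, "run_day", bundle.run_day)
    met.to_csv(outdir / "metabolites.tsv", sep="\t", na_rep="NA")
    bundle.metabolite_annotation.to_csv(
        outdir / "metabolite_annotation.tsv", sep="\t"
    )
    bundle.species_counts.to_csv(outdir / "species.tsv", sep="\t")
    (outdir / "truth.json").write_text(bundle.truth.to_json())
    (outdir / "item_mapping.json").write_text(json.dumps(bundle.item_mapping, indent=1))
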