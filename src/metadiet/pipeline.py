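"""End-to-end pipeline: simulate -> dietprep -> score -> omicsprep ->
predict -> assoc -> multivar -> mediate.

Each stage writes flat TSV outputs ('NA' marks missing values) into the
run directory, and a manifest records the configuration, per-stage seeds
and output files so that a run can be reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import assoc as assoc_mod
from . import dietprep, dietscore, mediate as mediate_mod, multivar, omicsprep, predict
from .synthio import SynthConfig, generate_ascvd_inputs, generate_cohorts, write_bundle

__all__ = ["PipelineConfig", "run_pipeline"]

_STAGES = ["simulate", "dietprep", "score", "omicsprep", "predict",
           "assoc", "multivar", "mediate"]


@dataclass
class PipelineConfig:
    out_dir: str = "metadiet_run"
    seed: int = 0
    synth: dict = field(default_factory=dict)
    stages: dict = field(default_factory=lambda: {s: True for s in _STAGES})
    alpha: float = 0.05
    fdr_food_species: float = 0.10
    fdr_metabolite_species: float = 0.01
    max_missing_frac: float = 0.20
    min_prevalence: float = 0.10
    predict_targets: list = field(default_factory=lambda: ["DASH"])
    boruta_iter: int = 100
    boruta_trees: int = 48
    n_estimators: int = 200
    cv_repeats: int = 2
    grid: list = None
    n_boot: int = 200
    rfe_tolerance: float = 0.05
    permanova_n_perm: int = 999
    permanova_top_k: int = 5
    mediation_n_sim: int = 1000
    mediation_max_trios: int = 20
    drop_flagged_samples: bool = False

    @classmethod
    def from_yaml(cls, path):
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown pipeline config keys: {sorted(unknown)}")
        return cls(**raw)


def _covars(participants, index):
    return participants.loc[index, ["age_years", "sex", "bmi"]].to_numpy(float)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in order; returns the run manifest."""
    cfg = config
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages_on = {s: cfg.stages.get(s, True) for s in _STAGES}
    manifest = {
        "package_version": __version__,
        "python": platform.python_version(),
        "seed": cfg.seed,
        "config": {
            k: (v if not isinstance(v, dict) else dict(v))
            for k, v in dataclasses.asdict(cfg).items()
        },
        "stages": {},
    }
    state = {}

    def _done(stage, **outputs):
        manifest["stages"][stage] = {"outputs": sorted(outputs)}
        for k, v in outputs.items():
            state[k] = v

    def _need(stage, *keys):
        for k in keys:
            if k not in state:
                raise RuntimeError(
                    f"stage '{stage}' needs '{k}', produced by an earlier "
                    "stage that did not run"
                )

    # ---- simulate -------------------------------------------------------
    if stages_on["simulate"]:
        synth_cfg = SynthConfig(seed=cfg.seed, **cfg.synth)
        disc, repl = generate_cohorts(synth_cfg)
        for b in (disc, repl):
            write_bundle(b, out / b.name)
        _done("simulate", cohorts={"discovery": disc, "replication": repl})

    # ---- dietprep -------------------------------------------------------
    if stages_on["dietprep"]:
        _need("dietprep", "cohorts")
        fg = {}
        for name, b in state["cohorts"].items():
            adjusted, raw, log = dietprep.prepare_food_groups(
                b.ffq_line_items, b.nutrients, b.participants, b.item_mapping
            )
            adjusted.to_csv(out / name / "foodgroups.tsv", sep="\t")
            log.to_csv(out / name / "ffq_exclusions.tsv", sep="\t", index=False)
            fg[name] = {"adjusted": adjusted, "raw": raw, "log": log}
        _done("dietprep", foodgroups=fg)

    # ---- score ----------------------------------------------------------
    if stages_on["score"]:
        _need("score", "cohorts", "foodgroups")
        indices = {}
        for name, b in state["cohorts"].items():
            fg = state["foodgroups"][name]
            idx = fg["adjusted"].index
            scores = dietscore.score_all_indices(
                fg["adjusted"], fg["raw"],
                b.participants.loc[idx, "sex"].to_numpy(),
                nutrients=b.nutrients.loc[idx],
            )
            risk_inputs = generate_ascvd_inputs(
                b.participants.loc[idx], seed=cfg.seed + 17
            )
            risk = dietscore.ascvd_risk_table(risk_inputs)
            scores = scores.join(risk)
            scores.to_csv(out / name / "indices.tsv", sep="\t", na_rep="NA")
            indices[name] = scores
        _done("score", indices=indices)

    # ---- omicsprep ------------------------------------------------------
    if stages_on["omicsprep"]:
        _need("omicsprep", "cohorts")
        mets, species_clr, diversity, bray = {}, {}, {}, {}
        for name, b in state["cohorts"].items():
            m, dropped = omicsprep.process_metabolites(
                b.metabolites_raw, b.run_day, cfg.max_missing_frac
            )
            m.to_csv(out / name / "metabolites_processed.tsv", sep="\t")
            rel = omicsprep.close_composition(b.species_counts)
            rel = omicsprep.prevalence_filter(rel, cfg.min_prevalence)
            rel = omicsprep.close_composition(rel)
            clr = omicsprep.clr_transform(rel)
            clr.to_csv(out / name / "species_clr.tsv", sep="\t")
            div = omicsprep.shannon_table(rel)
            D = omicsprep.bray_curtis(rel.to_numpy())
            flags = omicsprep.pcoa_outlier_flag(
                pd.DataFrame(D, index=rel.index, columns=rel.index)
            )
            pd.DataFrame({"shannon": div, "flagged": flags}).to_csv(
                out / name / "diversity.tsv", sep="\t"
            )
            if cfg.drop_flagged_samples:
                keep = flags.index[~flags]
                m, clr, rel = m.loc[keep], clr.loc[keep], rel.loc[keep]
                D = omicsprep.bray_curtis(rel.to_numpy())
            mets[name], species_clr[name] = m, clr
            diversity[name] = div
            bray[name] = pd.DataFrame(D, index=rel.index, columns=rel.index)
        _done("omicsprep", metabolites=mets, species_clr=species_clr,
              diversity=diversity, bray=bray)

    # ---- predict --------------------------------------------------------
    if stages_on["predict"]:
        _need("predict", "cohorts", "indices", "metabolites")
        rows, rfe_rows, rfe_results = [], [], []
        for target in cfg.predict_targets:
            feats, scores, fams, val = _prediction_inputs(state, target)
            res = predict.run_diet_prediction(
                feats, scores, fams, validation=val, task="classify",
                boruta_iter=cfg.boruta_iter, boruta_trees=cfg.boruta_trees,
                grid=cfg.grid, cv_repeats=cfg.cv_repeats,
                n_estimators=cfg.n_estimators,
                rfe_tolerance=cfg.rfe_tolerance, n_boot=cfg.n_boot,
                seed=cfg.seed,
            )
            ev, vev = res["test_eval"], res.get("validation_eval")
            rows.append({
                "target": target, "auc_test": ev.auc,
                "auc_test_lo": ev.auc_ci[0], "auc_test_hi": ev.auc_ci[1],
                "auc_validation": vev.auc if vev else np.nan,
                "n_features": len(res["selected_features"]),
            })
            if "rfe" in res:
                rfe_results.append(res["rfe"])
                traj = res["rfe"].trajectory.assign(target=target)
                rfe_rows.append(traj)
        eval_df = pd.DataFrame(rows)
        eval_df.to_csv(out / "eval.tsv", sep="\t", index=False)
        if rfe_rows:
            pd.concat(rfe_rows).to_csv(out / "rfe_trajectories.tsv",
                                       sep="\t", index=False)
        panel = predict.build_panel(rfe_results)
        (out / "panel.json").write_text(json.dumps(panel, indent=1))
        _done("predict", eval=eval_df, panel=panel)

    # ---- assoc ----------------------------------------------------------
    if stages_on["assoc"]:
        _need("assoc", "cohorts", "foodgroups", "metabolites", "species_clr")
        per_cohort, thresholds = {}, {}
        scans = {}
        for name, b in state["cohorts"].items():
            scans[name] = _cohort_scans(state, name, b)
            scans[name]["food_metabolite"].to_csv(
                out / f"assoc_{name}.tsv", sep="\t", index=False
            )
        # Meff-Bonferroni threshold from the discovery cohort
        fg_int = scans["discovery"]["exposures"]
        met_int = scans["discovery"]["outcomes"]
        meff_fg = assoc_mod.meff(np.corrcoef(fg_int.to_numpy().T))
        meff_met = assoc_mod.meff(np.corrcoef(met_int.to_numpy().T))
        threshold = assoc_mod.bonferroni_threshold(cfg.alpha, [meff_fg, meff_met])
        fm = pd.concat(
            [scans[n]["food_metabolite"] for n in scans], ignore_index=True
        )
        meta_fm = assoc_mod.fixed_effects_meta(fm, threshold=threshold)
        meta_fm["q"] = np.nan
        ok = meta_fm["p"].notna()
        meta_fm.loc[ok, "q"] = assoc_mod.bh_fdr(meta_fm.loc[ok, "p"])
        meta_fm.to_csv(out / "meta.tsv", sep="\t", index=False)

        fs = pd.concat([scans[n]["food_species"] for n in scans],
                       ignore_index=True)
        meta_fs = assoc_mod.fixed_effects_meta(fs)
        ok = meta_fs["p"].notna()
        meta_fs["q"] = np.nan
        meta_fs.loc[ok, "q"] = assoc_mod.bh_fdr(meta_fs.loc[ok, "p"])
        ms = pd.concat([scans[n]["metabolite_species"] for n in scans],
                       ignore_index=True)
        meta_ms = assoc_mod.fixed_effects_meta(ms)
        ok = meta_ms["p"].notna()
        meta_ms["q"] = np.nan
        meta_ms.loc[ok, "q"] = assoc_mod.bh_fdr(meta_ms.loc[ok, "p"])
        _done("assoc", meta_food_metabolite=meta_fm, meta_food_species=meta_fs,
              meta_metabolite_species=meta_ms, bonferroni_threshold=threshold)

    # ---- multivar -------------------------------------------------------
    if stages_on["multivar"]:
        _need("multivar", "cohorts", "metabolites", "bray",
              "meta_food_metabolite")
        meta = state["meta_food_metabolite"]
        hits = meta[meta["passes_threshold"]]
        top = (
            hits.sort_values("p").drop_duplicates("outcome")
            .head(cfg.permanova_top_k)["outcome"].tolist()
        )
        if not top:
            top = meta.sort_values("p").drop_duplicates("outcome") \
                .head(cfg.permanova_top_k)["outcome"].tolist()
        perm_rows = []
        for met in top:
            r2s, ns = [], []
            for name, b in state["cohorts"].items():
                mets = state["metabolites"][name]
                D = state["bray"][name]
                common = mets.index.intersection(D.index)
                fams = b.participants.loc[common, "family_id"]
                keep_pos = multivar.dedup_twins(fams, seed=cfg.seed)
                ids = common[keep_pos]
                res = multivar.permanova(
                    D.loc[ids, ids].to_numpy(),
                    _covars(b.participants, ids),
                    mets.loc[ids, met].to_numpy(),
                    term_name=met, n_perm=cfg.permanova_n_perm,
                    seed=cfg.seed,
                )
                perm_rows.append({"cohort": name, "metabolite": met,
                                  "r2": res.r2, "pseudo_f": res.pseudo_f,
                                  "p_perm": res.p_perm, "n": len(ids)})
                r2s.append(res.r2); ns.append(len(ids))
            perm_rows.append({"cohort": "weighted", "metabolite": met,
                              "r2": multivar.weighted_r2(r2s, ns),
                              "pseudo_f": np.nan, "p_perm": np.nan,
                              "n": sum(ns)})
        perm_df = pd.DataFrame(perm_rows)
        perm_df.to_csv(out / "permanova.tsv", sep="\t", index=False)

        # ORA of each food group's significant metabolites, by superpathway
        ann = state["cohorts"]["discovery"].metabolite_annotation
        background = [m for m in meta["outcome"].unique() if m in ann.index]
        pathways = {
            sp: list(ann.index[ann["superpathway"] == sp])
            for sp in ann["superpathway"].unique()
        }
        ora_rows = []
        for fgname, grp in hits.groupby("exposure"):
            tab = multivar.ora_hypergeom(
                grp["outcome"].tolist(), pathways, background
            )
            ora_rows.append(tab.assign(food_group=fgname))
        ora_df = (pd.concat(ora_rows, ignore_index=True)
                  if ora_rows else pd.DataFrame())
        ora_df.to_csv(out / "ora.tsv", sep="\t", index=False)

        # signed association profiles -> ACC clustering
        signed = _signed_matrix(meta)
        clusters = pd.DataFrame()
        if len(signed) >= 3:
            dist = multivar.acc_distance(signed)
            if len(dist) >= 3:
                labels, k, Z, sil = multivar.ward_cluster_optimal(dist)
                clusters = labels.to_frame()
        clusters.to_csv(out / "clusters.tsv", sep="\t")
        _done("multivar", permanova=perm_df, ora=ora_df, clusters=clusters)

    # ---- mediate --------------------------------------------------------
    if stages_on["mediate"]:
        _need("mediate", "cohorts", "foodgroups", "metabolites",
              "species_clr", "meta_food_metabolite", "meta_food_species",
              "meta_metabolite_species")
        fm = state["meta_food_metabolite"]
        fs = state["meta_food_species"]
        ms = state["meta_metabolite_species"]
        trios = mediate_mod.enumerate_trios(
            fm[fm["passes_threshold"]],
            fs[fs["q"] < cfg.fdr_food_species],
            ms[ms["q"] < cfg.fdr_metabolite_species],
        ).head(cfg.mediation_max_trios * 2)
        med_rows = []
        b = state["cohorts"]["discovery"]
        fg = state["foodgroups"]["discovery"]["adjusted"]
        mets = state["metabolites"]["discovery"]
        clr = state["species_clr"]["discovery"]
        common = fg.index.intersection(mets.index).intersection(clr.index)
        for _, trio in trios.iterrows():
            data = {}
            for role in ("exposure", "mediator", "outcome"):
                vid = trio[role]
                if vid in fg.columns:
                    data[role] = dietprep.inverse_rank_transform(
                        fg.loc[common, vid]
                    ).to_numpy()
                elif vid in mets.columns:
                    data[role] = mets.loc[common, vid].to_numpy()
                elif vid in clr.columns:
                    data[role] = clr.loc[common, vid].to_numpy()
            if len(data) < 3:
                continue
            res = mediate_mod.mediate(
                data["exposure"], data["mediator"], data["outcome"],
                _covars(b.participants, common),
                b.participants.loc[common, "family_id"].to_numpy(),
                n_sim=cfg.mediation_n_sim, seed=cfg.seed,
            )
            med_rows.append({
                **trio.to_dict(), "acme": res.acme, "ade": res.ade,
                "total": res.total_effect, "prop_mediated": res.prop_mediated,
                "p_acme": res.p_acme, "p_ade": res.p_ade,
                "acme_lo": res.acme_ci[0], "acme_hi": res.acme_ci[1],
            })
            if len(med_rows) >= cfg.mediation_max_trios:
                break
        med_df = pd.DataFrame(med_rows)
        med_df.to_csv(out / "mediation.tsv", sep="\t", index=False)
        _done("mediate", mediation=med_df)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    manifest["state"] = state
    return manifest


def _prediction_inputs(state, target):
    """Assemble (features, scores, families, validation) for one target."""
    disc = state["cohorts"]["discovery"]
    mets = state["metabolites"]["discovery"]
    scores = state["indices"]["discovery"][target].dropna()
    ids = mets.index.intersection(scores.index)
    feats = mets.loc[ids].copy()
    feats["age"] = disc.participants.loc[ids, "age_years"]
    feats["sex"] = disc.participants.loc[ids, "sex"]
    feats["bmi"] = disc.participants.loc[ids, "bmi"]
    fams = disc.participants.loc[ids, "family_id"]
    val = None
    if "replication" in state["cohorts"]:
        repl = state["cohorts"]["replication"]
        vmets = state["metabolites"]["replication"]
        vscores = state["indices"]["replication"][target].dropna()
        vids = vmets.index.intersection(vscores.index)
        vfeat = vmets.loc[vids].copy()
        vfeat["age"] = repl.participants.loc[vids, "age_years"]
        vfeat["sex"] = repl.participants.loc[vids, "sex"]
        vfeat["bmi"] = repl.participants.loc[vids, "bmi"]
        # only features shared with the discovery matrix can be used
        shared = [c for c in feats.columns if c in vfeat.columns]
        feats = feats[shared]
        val = (vfeat[shared], vscores.loc[vids])
    return feats, scores.loc[ids], fams, val


def _cohort_scans(state, name, bundle):
    """Food-metabolite, food-species and metabolite-species LMM scans."""
    fg = state["foodgroups"][name]["adjusted"]
    mets = state["metabolites"][name]
    clr = state["species_clr"][name]
    idx = fg.index.intersection(mets.index).intersection(clr.index)
    exposures = fg.loc[idx].apply(dietprep.inverse_rank_transform)
    outcomes = mets.loc[idx]
    covars = _covars(bundle.participants, idx)
    fams = bundle.participants.loc[idx, "family_id"].to_numpy()
    fm = assoc_mod.association_scan(outcomes, exposures, covars, fams, cohort=name)
    fs = assoc_mod.association_scan(clr.loc[idx], exposures, covars, fams,
                                    cohort=name)
    ms = assoc_mod.association_scan(clr.loc[idx], outcomes, covars, fams,
                                    cohort=name)
    return {
        "food_metabolite": fm, "food_species": fs, "metabolite_species": ms,
        "exposures": exposures, "outcomes": outcomes, "index": idx,
    }


def _signed_matrix(meta: pd.DataFrame, min_assoc: int = 4) -> pd.DataFrame:
    """Metabolite x food-group matrix of {-1, 0, +1} significant directions,
    restricted to metabolites significant for at least ``min_assoc`` groups."""
    sig = meta[meta["passes_threshold"]]
    if sig.empty:
        return pd.DataFrame()
    mat = pd.pivot_table(
        sig.assign(sign=np.sign(sig["beta"])),
        index="outcome", columns="exposure", values="sign", fill_value=0.0,
        aggfunc="first",
    )
    keep = (mat != 0).sum(axis=1) >= min_assoc
    return mat.loc[keep]
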