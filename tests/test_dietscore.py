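import numpy as np
import pandas as pd
import pytest

from metadiet import dietprep, dietscore
from metadiet.dietscore import (
    ascvd_10yr_risk,
    load_ascvd_coefficients,
    plant_meat_percent,
    quintile_scores,
    score_all_indices,
    score_amed,
    score_dash,
    score_pdi_family,
)


class TestQuintiles:
    def test_percentile_bins_for_one_to_ten(self):
        assert quintile_scores(np.arange(1, 11)).tolist() == \
            [1, 1, 2, 2, 3, 3, 4, 4, 5, 5]

    def test_top_value_scores_five_and_reverse(self):
        v = np.arange(1, 101, dtype=float)
        assert quintile_scores(v)[-1] == 5
        assert quintile_scores(v, reverse=True)[-1] == 1

    def test_constant_vector_ties_to_lowest_quintile(self):
        v = np.full(20, 3.0)
        assert set(quintile_scores(v)) == {1}
        assert set(quintile_scores(v, reverse=True)) == {5}

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=40)
        perm = rng.permutation(40)
        assert (quintile_scores(v)[perm] == quintile_scores(v[perm])).all()

    def test_too_few_observations(self):
        with pytest.raises(ValueError):
            quintile_scores([1.0, 2.0])


def _toy_defs():
    return {
        "pdi_family": {
            "healthy_plant": [["veg"]],
            "less_healthy_plant": [["juice"]],
            "animal": [["meat"]],
        },
        "dash": {"encouraged": [["veg"]], "discouraged": [["meat"]]},
        "amed": {
            "above_median": [["veg"]],
            "below_median": [["meat"]],
            "alcohol_group": "alcohol",
            "alcohol_window_female": [5.0, 15.0],
            "alcohol_window_male": [10.0, 25.0],
        },
        "plant_meat": {"plant_groups": ["veg", "juice"],
                       "meat_groups": ["meat"]},
    }


def _toy_cohort():
    # 10 participants; veg increasing, meat decreasing, juice shuffled
    return pd.DataFrame({
        "veg": np.arange(1.0, 11.0),
        "meat": np.arange(10.0, 0.0, -1.0),
        "juice": [3.0, 1, 4, 1, 5, 9, 2, 6, 5, 3],
        "alcohol": [0.0, 6, 12, 20, 2, 8, 30, 11, 5, 0],
    })


class TestPDIFamily:
    def test_hand_tally_on_toy_cohort(self):
        fg = _toy_cohort()
        defs = _toy_defs()
        # quintile scores: veg = 1,1,2,2,3,3,4,4,5,5 ; meat reversed mirrors
        pdi = score_pdi_family(fg, defs, "PDI")
        veg_q = quintile_scores(fg["veg"].to_numpy())
        juice_q = quintile_scores(fg["juice"].to_numpy())
        meat_rq = quintile_scores(fg["meat"].to_numpy(), reverse=True)
        assert (pdi.to_numpy() == veg_q + juice_q + meat_rq).all()

    def test_variant_directions(self):
        fg = _toy_cohort()
        defs = _toy_defs()
        hpdi = score_pdi_family(fg, defs, "hPDI")
        updi = score_pdi_family(fg, defs, "uPDI")
        veg_q = quintile_scores(fg["veg"].to_numpy())
        juice_rq = quintile_scores(fg["juice"].to_numpy(), reverse=True)
        meat_rq = quintile_scores(fg["meat"].to_numpy(), reverse=True)
        assert (hpdi.to_numpy() == veg_q + juice_rq + meat_rq).all()
        juice_q = quintile_scores(fg["juice"].to_numpy())
        veg_rq = quintile_scores(fg["veg"].to_numpy(), reverse=True)
        assert (updi.to_numpy() == juice_q + veg_rq + meat_rq).all()

    def test_missing_component_named(self):
        fg = _toy_cohort().drop(columns=["juice"])
        with pytest.raises(ValueError, match="juice"):
            score_pdi_family(fg, _toy_defs(), "PDI")

    def test_unknown_variant(self):
        with pytest.raises(ValueError):
            score_pdi_family(_toy_cohort(), _toy_defs(), "xPDI")


class TestDashAndAmed:
    def test_dash_hand_tally(self):
        fg = _toy_cohort()
        dash = score_dash(fg, _toy_defs())
        expected = quintile_scores(fg["veg"].to_numpy()) + \
            quintile_scores(fg["meat"].to_numpy(), reverse=True)
        assert (dash.to_numpy() == expected).all()

    def test_amed_hand_tally_with_alcohol_window(self):
        fg = _toy_cohort()
        sex = np.array([0, 0, 0, 0, 0, 1, 1, 1, 1, 1])
        amed = score_amed(fg, sex, _toy_defs())
        veg_pt = (fg["veg"] > fg["veg"].median()).astype(int)
        meat_pt = (fg["meat"] < fg["meat"].median()).astype(int)
        lo = np.where(sex == 1, 10.0, 5.0)
        hi = np.where(sex == 1, 25.0, 15.0)
        alc_pt = ((fg["alcohol"] >= lo) & (fg["alcohol"] <= hi)).astype(int)
        assert (amed.to_numpy() == (veg_pt + meat_pt + alc_pt).to_numpy()).all()

    def test_identical_cohort_scores_zero_beneficial_points(self):
        fg = pd.DataFrame({"veg": [5.0] * 6, "meat": [5.0] * 6,
                           "juice": [1.0] * 6, "alcohol": [0.0] * 6})
        amed = score_amed(fg, np.zeros(6, dtype=int), _toy_defs())
        assert (amed == 0).all()


class TestPlantMeatPercent:
    def test_all_plant(self):
        fg = pd.DataFrame({"veg": [10.0], "juice": [5.0], "meat": [0.0],
                           "alcohol": [0.0]})
        plant, meat = plant_meat_percent(fg, _toy_defs())
        assert plant.iloc[0] == pytest.approx(100.0)
        assert meat.iloc[0] == pytest.approx(0.0)

    def test_thirty_thirty_forty(self):
        fg = pd.DataFrame({"veg": [30.0], "juice": [0.0], "meat": [30.0],
                           "alcohol": [40.0]})
        plant, meat = plant_meat_percent(fg, _toy_defs())
        assert plant.iloc[0] == pytest.approx(30.0)
        assert meat.iloc[0] == pytest.approx(30.0)

    def test_zero_total_rejected(self):
        fg = pd.DataFrame({"veg": [0.0], "juice": [0.0], "meat": [0.0],
                           "alcohol": [0.0]})
        with pytest.raises(ValueError):
            plant_meat_percent(fg, _toy_defs())


def _profile(**kw):
    base = dict(age_years=55, sex=1, race_group="white",
                total_chol_mgdl=213, hdl_mgdl=50, sbp_mmhg=120,
                on_htn_meds=0, diabetes=0, smoker=0)
    base.update(kw)
    return base


class TestAscvdRisk:
    def test_baseline_identity_risk_is_one_minus_s0(self):
        coeffs = {"male_white": {"coefficients": {}, "mean_L": 0.0, "S0": 0.9}}
        assert ascvd_10yr_risk(_profile(), coeffs) == pytest.approx(0.1)

    def test_s0_of_one_gives_zero_risk(self):
        coeffs = {"male_white": {"coefficients": {"ln_age": 2.0},
                                 "mean_L": 0.0, "S0": 1.0}}
        assert ascvd_10yr_risk(_profile(), coeffs) == pytest.approx(0.0)

    def test_published_example_profiles(self):
        # 55-year-old, TC 213, HDL 50, untreated SBP 120, no risk flags
        expected = {
            ("female", "white"): 0.0205,
            ("female", "black"): 0.0303,
            ("male", "white"): 0.0538,
            ("male", "black"): 0.0607,
        }
        for (sex, race), risk in expected.items():
            got = ascvd_10yr_risk(
                _profile(sex=1 if sex == "male" else 0, race_group=race)
            )
            assert got == pytest.approx(risk, abs=1e-3)

    def test_monotone_in_sbp(self):
        risks = [ascvd_10yr_risk(_profile(sbp_mmhg=s)) for s in (110, 130, 160)]
        assert risks[0] < risks[1] < risks[2]

    def test_age_80_ineligible(self):
        with pytest.raises(ValueError):
            ascvd_10yr_risk(_profile(age_years=80))

    def test_missing_stratum(self):
        with pytest.raises(ValueError):
            ascvd_10yr_risk(_profile(race_group="martian"),
                            {"male_white": {"coefficients": {}, "mean_L": 0,
                                            "S0": 0.9}})


class TestIndexRangesOnSyntheticCohort:
    def test_all_indices_within_declared_ranges(self, small_cohorts):
        disc, _ = small_cohorts
        adjusted, raw, _ = dietprep.prepare_food_groups(
            disc.ffq_line_items, disc.nutrients, disc.participants,
            disc.item_mapping,
        )
        idx = adjusted.index
        scores = score_all_indices(
            adjusted, raw, disc.participants.loc[idx, "sex"].to_numpy(),
            nutrients=disc.nutrients.loc[idx],
        )
        assert scores["PDI"].between(18, 90).all()
        assert scores["hPDI"].between(18, 90).all()
        assert scores["uPDI"].between(18, 90).all()
        assert scores["DASH"].between(8, 40).all()
        assert scores["aMED"].between(0, 9).all()
        assert ((scores["plant_pct"] + scores["meat_pct"]) <= 100 + 1e-9).all()
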