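"""Risk profile, design matrices, VIF and the model suite."""

import numpy as np
import pandas as pd
import pytest

from pphq.determinants import (
    DEFAULT_ADJUSTMENT,
    WomanProfile,
    build_design,
    risk_profile,
    risk_profile_series,
    run_model_suite,
    vif,
)
from pphq.io import score_dataframe
from pphq.simulate import GeneratorConfig, generate_cohort


def _woman(**overrides):
    base = dict(
        age_band="25-35",
        country_of_birth="France",
        bmi_band="18.5-25",
        parity_cesarean="primiparous",
        previous_pph=False,
        multiple_pregnancy=False,
        pre_eclampsia=False,
        birth_weight_g=3200.0,
        gestational_age_weeks=39.0,
        delivery_mode_detail="spontaneous_vaginal",
    )
    base.update(overrides)
    return WomanProfile(**base)


class TestRiskProfile:
    def test_macrosomia_alone_qualifies(self):
        assert risk_profile(_woman(birth_weight_g=4200)) is True
        assert risk_profile(_woman(birth_weight_g=4000)) is True  # inclusive

    def test_no_factor(self):
        assert risk_profile(_woman()) is False

    def test_single_boolean_factor(self):
        assert risk_profile(_woman(previous_pph=True)) is True
        assert risk_profile(_woman(multiple_pregnancy=True)) is True
        assert risk_profile(_woman(pre_eclampsia=True)) is True

    def test_missing_birth_weight_undetermined(self):
        assert risk_profile(_woman(birth_weight_g=None)) is None
        # but a positive boolean decides regardless of birth weight
        assert risk_profile(_woman(birth_weight_g=None, pre_eclampsia=True)) is True

    def test_series_matches_scalar(self):
        df = pd.DataFrame(
            {
                "previous_pph": [False, True, False],
                "multiple_pregnancy": [False, False, False],
                "pre_eclampsia": [False, False, False],
                "birth_weight_g": [4100.0, 3000.0, np.nan],
            }
        )
        out = risk_profile_series(df)
        assert out.iloc[0] == True  # noqa: E712
        assert out.iloc[1] == True  # noqa: E712
        assert pd.isna(out.iloc[2])


@pytest.fixture(scope="module")
def analysis_cohort():
    sim = generate_cohort(GeneratorConfig(seed=21, missing_country_rate=0.0))
    scores, _ = score_dataframe(sim.cohort)
    df = sim.cohort.merge(sim.units, on="unit_id").merge(
        scores[["woman_id", "inadequate", "unscoreable"]], on="woman_id"
    )
    df = df[~df["unscoreable"]].copy()
    df["risk_profile"] = risk_profile_series(df)
    df["inadequate"] = df["inadequate"].astype(bool)
    return df


class TestBuildDesign:
    def test_reference_levels_absorbed(self, analysis_cohort):
        y, X, cl = build_design(analysis_cohort, "level_of_care")
        assert X.columns[0] == "const"
        assert "level_of_care=2" in X.columns and "level_of_care=1" in X.columns
        assert not any("=3" in c for c in X.columns)  # level 3 is the reference
        assert len(y) == len(X) == len(cl)

    def test_empty_adjustment_is_characteristic_only(self, analysis_cohort):
        _, X, _ = build_design(analysis_cohort, "status", adjustment_set=())
        assert list(X.columns) == ["const", "status=public_non_university", "status=private"]

    def test_adjustment_columns_order(self, analysis_cohort):
        _, X, _ = build_design(analysis_cohort, "anesthesiologist_24_7")
        assert X.columns[1] == "no_anesthesiologist_24_7"
        assert "country=sub_saharan_africa" in X.columns
        assert "parity=multiparous_prior_cesarean" in X.columns

    def test_single_level_characteristic_warns(self, analysis_cohort):
        df = analysis_cohort.copy()
        df["status"] = "private"
        with pytest.warns(UserWarning, match="single observed level"):
            _, X, _ = build_design(df, "status", adjustment_set=())
        assert list(X.columns) == ["const"]

    def test_absent_level_dropped_with_warning(self, analysis_cohort):
        df = analysis_cohort[analysis_cohort["level_of_care"] != 1]
        with pytest.warns(UserWarning, match="absent"):
            _, X, _ = build_design(df, "level_of_care", adjustment_set=())
        assert "level_of_care=1" not in X.columns


class TestVif:
    def test_orthogonal_columns(self):
        X = pd.DataFrame({"a": [1, 1, -1, -1.0], "b": [1, -1, 1, -1.0]})
        out = vif(X)
        assert out["a"] == pytest.approx(1.0)
        assert out["b"] == pytest.approx(1.0)

    def test_duplicated_column_infinite(self, rng):
        a = rng.normal(size=200)
        X = pd.DataFrame({"a": a, "b": a})
        with pytest.warns(UserWarning, match="collinearity"):
            out = vif(X)
        assert np.isinf(out["a"]) and np.isinf(out["b"])

    def test_known_correlation(self, rng):
        # two standardized regressors with rho = 0.8 -> VIF = 1/(1-0.64)
        n = 20000
        a = rng.normal(size=n)
        b = 0.8 * a + np.sqrt(1 - 0.64) * rng.normal(size=n)
        out = vif(pd.DataFrame({"a": a, "b": b}))
        assert out["a"] == pytest.approx(1 / (1 - 0.64), rel=0.05)

    def test_needs_two_columns(self):
        with pytest.raises(ValueError):
            vif(pd.DataFrame({"a": [1.0, 2.0]}))


class TestModelSuite:
    def test_cesarean_stratum_has_five_models(self, analysis_cohort):
        table = run_model_suite(analysis_cohort, stratum="cesarean")
        assert set(table["model"]) == {f"model_{i}" for i in range(1, 6)}

    def test_vaginal_stratum_adds_combined_model(self, analysis_cohort):
        table = run_model_suite(analysis_cohort, stratum="vaginal")
        assert "model_6" in set(table["model"])
        m6 = table[table["model"] == "model_6"]
        assert set(m6["characteristic"]) == {"status", "annual_deliveries"}
        # model 6 is adjusted-only (no crude duplicate of models 1-2)
        assert set(m6["kind"]) == {"adjusted"}

    def test_reference_rows_have_or_one_and_no_ci(self, analysis_cohort):
        table = run_model_suite(analysis_cohort, stratum="cesarean")
        refs = table[table["reference"]]
        assert (refs["OR"] == 1.0).all()
        assert refs["ci_low"].isna().all() and refs["ci_high"].isna().all()

    def test_stratification_partitions_cohort(self, analysis_cohort):
        n_vag = (analysis_cohort["delivery_mode"] == "vaginal").sum()
        n_ces = (analysis_cohort["delivery_mode"] == "cesarean").sum()
        assert n_vag + n_ces == len(analysis_cohort)

    def test_crude_equals_adjusted_with_empty_adjustment(self, analysis_cohort):
        table = run_model_suite(
            analysis_cohort, stratum="cesarean", adjustment=()
        )
        one = table[(table["model"] == "model_5") & (~table["reference"])]
        crude = one[one["kind"] == "crude"].iloc[0]
        adjusted = one[one["kind"] == "adjusted"].iloc[0]
        assert crude["OR"] == pytest.approx(adjusted["OR"], rel=1e-6)
        assert crude["ci_low"] == pytest.approx(adjusted["ci_low"], rel=1e-6)

    def test_unknown_stratum_rejected(self, analysis_cohort):
        with pytest.raises(ValueError):
            run_model_suite(analysis_cohort, stratum="breech")
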