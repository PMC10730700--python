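"""Table validation, island filtering, collinearity screening, design prep."""

import numpy as np
import pandas as pd
import pytest

from darkbirds import data_prep, synthetic
from darkbirds.data_prep import INTERACTION, ParseError, SchemaError


def _island_frame(rows):
    return pd.DataFrame(
        rows,
        columns=[
            "island_id",
            "archipelago_id",
            "area",
            "isolated_from_mainland",
            "glaciated_lgm",
            "settled_pre1500",
        ],
    )


class TestReadTables:
    def test_demo_dataset_round_trips_with_69_records(self, arch_dataset, tmp_path):
        arch, truth = arch_dataset
        paths = synthetic.write_dataset(tmp_path, arch, truth)
        read, *_ = data_prep.read_tables(paths["archipelagos"])
        assert len(read) == 69
        pd.testing.assert_frame_equal(
            read.reset_index(drop=True), arch.reset_index(drop=True), check_dtype=False
        )

    def test_missing_required_column_is_a_schema_error(self, arch_dataset, tmp_path):
        arch, _ = arch_dataset
        arch.drop(columns=["n_fossil"]).to_csv(tmp_path / "bad.csv", index=False)
        with pytest.raises(SchemaError, match="n_fossil"):
            data_prep.read_tables(tmp_path / "bad.csv")

    def test_non_numeric_count_is_a_parse_error(self, arch_dataset, tmp_path):
        arch, _ = arch_dataset
        bad = arch.copy()
        bad["n_fossil"] = bad["n_fossil"].astype(object)
        bad.loc[3, "n_fossil"] = "many"
        bad.to_csv(tmp_path / "bad.csv", index=False)
        with pytest.raises(ParseError, match="n_fossil"):
            data_prep.read_tables(tmp_path / "bad.csv")

    def test_two_reference_archipelagos_rejected(self, arch_dataset):
        arch, _ = arch_dataset
        bad = arch.copy()
        bad["is_reference"] = True
        with pytest.raises(SchemaError, match="reference"):
            data_prep.validate_archipelagos(bad)


class TestFilterIslands:
    def test_each_rule_excludes_its_own_failure(self):
        # 10 islands: 3 fail exactly one distinct rule each, 7 survive
        rows = [(f"i{k}", "A", 100.0, True, False, True) for k in range(7)]
        rows += [
            ("small", "A", 4.0, True, False, True),  # area rule
            ("joined", "A", 100.0, False, False, True),  # isolation rule
            ("iced", "A", 100.0, True, True, True),  # glaciation rule
        ]
        eligible, tally = data_prep.filter_islands(_island_frame(rows))
        assert len(eligible) == 7
        assert tally == {"area": 1, "isolation": 1, "glaciation": 1, "settlement": 0}

    @pytest.mark.parametrize(
        "area,isolated,glaciated,expect_in",
        [
            (4.0, True, False, False),  # below the 5 km^2 area threshold
            (100.0, True, True, False),  # glaciated at the LGM
            (5.5, True, False, True),
        ],
    )
    def test_single_island_rules(self, area, isolated, glaciated, expect_in):
        isl = _island_frame([("i0", "A", area, isolated, glaciated, True)])
        eligible, _ = data_prep.filter_islands(isl)
        assert (len(eligible) == 1) is expect_in

    def test_idempotent_and_subset(self):
        rows = [(f"i{k}", "A", 3.0 + k, k % 2 == 0, False, True) for k in range(12)]
        isl = _island_frame(rows)
        once, _ = data_prep.filter_islands(isl)
        twice, tally2 = data_prep.filter_islands(once)
        assert set(once["island_id"]) <= set(isl["island_id"])
        assert list(twice["island_id"]) == list(once["island_id"])
        assert all(v == 0 for v in tally2.values())

    def test_empty_input_gives_empty_output_and_zero_tallies(self):
        eligible, tally = data_prep.filter_islands(_island_frame([]))
        assert len(eligible) == 0
        assert all(v == 0 for v in tally.values())


class TestScreenCollinearity:
    def test_duplicated_column_drops_lower_priority_copy(self, arch_dataset):
        arch, _ = arch_dataset
        arch = arch.copy()
        arch["effort_copy"] = arch["research_effort"]
        retained, corr = data_prep.screen_collinearity(
            arch,
            predictors=["research_effort", "effort_copy", "temperature"],
            priority=["research_effort", "effort_copy"],
        )
        assert retained == ["research_effort", "temperature"]
        assert corr.loc["research_effort", "effort_copy"] == pytest.approx(1.0)

    def test_orthogonal_predictors_all_retained(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(size=(500, 4)), columns=list("abcd"))
        retained, _ = data_prep.screen_collinearity(df, predictors=list("abcd"), priority=list("abcd"))
        assert retained == list("abcd")

    def test_shared_latent_factor_pair_loses_one_member(self):
        # pair built with population correlation 0.91 via a common factor
        rho = 0.91
        rng = np.random.default_rng(42)
        z = rng.normal(size=2000)
        a = np.sqrt(rho) * z + np.sqrt(1 - rho) * rng.normal(size=2000)
        b = np.sqrt(rho) * z + np.sqrt(1 - rho) * rng.normal(size=2000)
        df = pd.DataFrame({"a": a, "b": b, "c": rng.normal(size=2000)})
        assert abs(np.corrcoef(a, b)[0, 1]) >= 0.8
        retained, _ = data_prep.screen_collinearity(df, predictors=list("abc"), priority=list("abc"))
        assert retained == ["a", "c"]

    def test_threshold_one_only_drops_exact_duplicates(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=300)
        df = pd.DataFrame({"a": a, "b": a + 0.01 * rng.normal(size=300)})
        retained, _ = data_prep.screen_collinearity(df, predictors=["a", "b"], priority=["a", "b"], threshold=1.0)
        assert retained == ["a", "b"]

    def test_constant_column_is_a_validation_error(self):
        df = pd.DataFrame({"a": np.ones(10), "b": np.arange(10.0)})
        with pytest.raises(ValueError, match="constant"):
            data_prep.screen_collinearity(df, predictors=["a", "b"], priority=["a", "b"])

    def test_default_screen_keeps_twelve_of_fourteen(self, arch_dataset):
        arch, _ = arch_dataset
        retained, _ = data_prep.screen_collinearity(arch)
        assert len(retained) == 12
        assert "sd_area" not in retained and "surrounding_landmass" not in retained
        assert "total_area" in retained and "isolation_distance" in retained


class TestPrepareDesign:
    def test_columns_are_standardized(self, design):
        vals = design.values.drop(columns=[INTERACTION])
        assert np.allclose(vals.mean(), 0.0, atol=1e-9)
        assert np.allclose(vals.std(ddof=1), 1.0, atol=1e-9)

    def test_interaction_is_product_of_scaled_mains(self, design):
        v = design.values
        assert np.allclose(v[INTERACTION], v["total_area"] * v["research_effort"])

    def test_model_space_round_trip(self, arch_dataset, design):
        arch, _ = arch_dataset
        raw = arch["research_effort"].to_numpy(float)
        z = design.to_model_space("research_effort", raw)
        assert np.allclose(design.values["research_effort"], z, atol=1e-9)
        assert np.allclose(design.from_model_space("research_effort", z), raw, rtol=1e-9)

    def test_three_point_column_scales_by_sample_sd(self):
        # sample (n-1) sd of {1,2,3} is 1, so the scaled values are {-1,0,1}
        df = pd.DataFrame({"archipelago_id": ["a", "b", "c"], "x": [1.0, 2.0, 3.0]})
        pm = data_prep.prepare_design(df, ["x"], interaction=None)
        assert np.allclose(pm.values["x"], [-1.0, 0.0, 1.0])
        assert pm.transform_spec["x"]["sd_convention"] == "sample(n-1)"

    def test_log_of_nonpositive_value_names_column_and_row(self):
        df = pd.DataFrame({"archipelago_id": ["a", "b"], "x": [0.0, 2.0], "y": [1.0, 2.0]})
        with pytest.raises(ValueError, match="'x'.*'a'"):
            data_prep.prepare_design(df, ["x", "y"], {"x": "log"}, interaction=None)


class TestVif:
    @staticmethod
    def _orthonormal_centred(n, k, seed):
        # columns orthogonal to each other and to the intercept
        rng = np.random.default_rng(seed)
        q, _ = np.linalg.qr(np.column_stack([np.ones(n), rng.normal(size=(n, k))]))
        return q[:, 1 : k + 1]

    def test_orthogonal_columns_have_unit_vif(self):
        q = self._orthonormal_centred(60, 4, seed=3)
        vif = data_prep.compute_vif(pd.DataFrame(q, columns=list("abcd")))
        assert np.allclose(vif, 1.0, atol=1e-8)

    def test_known_pairwise_correlation_gives_closed_form_vif(self):
        # two columns with exact sample correlation rho=0.6 among orthogonal
        # others: VIF = 1/(1 - rho^2) = 1.5625
        q = self._orthonormal_centred(200, 3, seed=4)
        rho = 0.6
        a = q[:, 0]
        b = rho * q[:, 0] + np.sqrt(1 - rho**2) * q[:, 1]
        df = pd.DataFrame({"a": a, "b": b, "c": q[:, 2]})
        vif = data_prep.compute_vif(df)
        assert vif["a"] == pytest.approx(1.5625, abs=1e-9)
        assert vif["b"] == pytest.approx(1.5625, abs=1e-9)

    def test_duplicated_column_reports_infinite_vif(self):
        rng = np.random.default_rng(5)
        a = rng.normal(size=50)
        vif = data_prep.compute_vif(pd.DataFrame({"a": a, "b": a, "c": rng.normal(size=50)}))
        assert np.isinf(vif["a"]) and np.isinf(vif["b"])

    def test_vif_never_below_one(self, design):
        assert (data_prep.compute_vif(design) >= 1.0 - 1e-12).all()
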