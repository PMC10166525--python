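import numpy as np
import pytest

import stratecho as se
from stratecho.engineer import EngineeringError

from conftest import make_table


def blank_schema_table(schema, fill=0.0):
    n = 4
    p = len(schema.all_features)
    values = np.full((n, p), fill)
    labels = ["WT", "WT", "DB", "DB"]
    return make_table(values, labels, feature_names=schema.all_features)


class TestAbsolutize:
    def test_listed_columns_become_absolute_others_untouched(self):
        t = make_table([[-3.2, -3.2], [0.0, 2.0]], ["WT", "DB"], ["ste_a", "other"])
        out = se.absolutize(t, ["ste_a"])
        assert out.values[0, 0] == 3.2
        assert out.values[1, 0] == 0.0
        assert out.values[0, 1] == -3.2  # untouched
        np.testing.assert_array_equal(out.missing_mask, t.missing_mask)

    def test_unknown_feature_rejected(self):
        t = make_table([[1.0], [2.0]], ["WT", "DB"], ["a"])
        with pytest.raises(KeyError):
            se.absolutize(t, ["nope"])


class TestNormalizeToLVMass:
    def test_per_animal_division(self):
        t = make_table([[10.0, 50.0], [10.0, 100.0]], ["WT", "DB"], ["ste", "mass"])
        out = se.normalize_to_lv_mass(t, ["ste"], "mass")
        assert out.values[0, 0] == pytest.approx(0.2)
        assert out.values[1, 0] == pytest.approx(0.1)
        assert out.values[0, 1] == 50.0  # mass column unchanged

    def test_bad_mass_names_animal(self):
        t = make_table([[10.0, 0.0], [10.0, 100.0]], ["WT", "DB"], ["ste", "mass"])
        with pytest.raises(EngineeringError, match="a0"):
            se.normalize_to_lv_mass(t, ["ste"], "mass")


class TestDeriveRegions:
    def set_combo(self, table, schema, combo, seg_values):
        view, phase, dim, metric = combo
        for seg, v in seg_values.items():
            (j,) = table.column_index([f"{view}_{phase}_{seg}_{dim}_{metric}"])
            table.values[:, j] = v

    def test_region_averages(self, schema):
        t = blank_schema_table(schema)
        combo = ("short", "systolic", "radial", "strain")
        self.set_combo(t, schema, combo, {
            "AntSeptum": 2.0, "PostSeptal": 4.0,  # Septal -> 3
            "AntFree": 1.0, "LatWall": 2.0, "PostWall": 3.0, "InfFreeWall": 4.0,
        })
        out = se.derive_regions(t, schema)
        (septal,) = out.column_index(["short_systolic_Septal_radial_strain"])
        assert out.values[0, septal] == pytest.approx(3.0)
        (free,) = out.column_index(["short_systolic_Free_radial_strain"])
        assert out.values[0, free] == pytest.approx(2.5)
        # Anterior from 2, 1, 2 -> 5/3
        (anterior,) = out.column_index(["short_systolic_Anterior_radial_strain"])
        assert out.values[0, anterior] == pytest.approx((2 + 1 + 2) / 3)

    def test_missing_member_propagation(self, schema):
        t = blank_schema_table(schema)
        f_ant = "short_systolic_AntSeptum_radial_strain"
        f_post = "short_systolic_PostSeptal_radial_strain"
        (ja,), (jp,) = t.column_index([f_ant]), t.column_index([f_post])
        t.values[:, ja] = 2.0
        t.values[:, jp] = 6.0
        t.values[0, ja] = np.nan
        t.missing_mask[0, ja] = True
        t.values[1, [ja, jp]] = np.nan
        t.missing_mask[1, [ja, jp]] = True
        out = se.derive_regions(t, schema)
        (js,) = out.column_index(["short_systolic_Septal_radial_strain"])
        assert out.values[0, js] == pytest.approx(6.0)  # mean of available
        assert not out.missing_mask[0, js]
        assert out.missing_mask[1, js]  # all members missing
        strict = se.derive_regions(t, schema, strict_missing=True)
        assert strict.missing_mask[0, js]

    def test_missing_member_column_rejected(self, schema):
        t = blank_schema_table(schema)
        keep = [f for f in t.feature_names if f != "short_systolic_AntSeptum_radial_strain"]
        with pytest.raises(EngineeringError, match="missing member"):
            se.derive_regions(t.restrict(keep), schema)


class TestDetectOutliers:
    def test_tukey_flags_extreme_value(self):
        # class values {1,2,3,4,100}: IQR=2, upper fence 4+3=7 -> 100 flagged
        vals = np.array([[1.0], [2.0], [3.0], [4.0], [100.0], [1.0], [2.0], [3.0]])
        labels = ["WT"] * 5 + ["DB"] * 3
        mask = se.detect_outliers(make_table(vals, labels))
        assert mask[4, 0]
        assert mask.sum() == 1

    def test_inliers_and_constant_not_flagged(self):
        vals = np.array([[1.0], [2.0], [3.0], [4.0], [5.0], [5.0], [5.0], [5.0], [5.0]])
        labels = ["WT"] * 5 + ["DB"] * 4
        mask = se.detect_outliers(make_table(vals, labels))
        assert not mask.any()

    def test_too_few_values_yield_no_flags(self):
        vals = np.array([[1.0], [100.0], [1.0], [2.0], [3.0]])
        labels = ["WT", "WT", "DB", "DB", "DB"]
        mask = se.detect_outliers(make_table(vals, labels))
        assert not mask[:2, 0].any()

    def test_mean_sd_rule(self):
        vals = np.array([[0.0], [0.0], [0.0], [0.0], [0.1], [10.0], [1.0], [1.0], [1.0]])
        labels = ["WT"] * 6 + ["DB"] * 3
        mask = se.detect_outliers(make_table(vals, labels), rule="mean_sd", factor=2.0)
        assert mask[5, 0]
        with pytest.raises(EngineeringError):
            se.detect_outliers(make_table(vals, labels), rule="nope")


class TestImpute:
    def test_per_class_mean_fills_missing(self):
        vals = np.array([[1.0], [2.0], [np.nan], [7.0], [8.0], [9.0]])
        labels = ["WT"] * 3 + ["DB"] * 3
        out, report = se.impute(make_table(vals, labels))
        assert out.values[2, 0] == pytest.approx(1.5)
        assert not out.missing_mask.any()
        assert report.n_imputed == 1
        assert report.missing_counts["f0"]["WT"] == 1

    def test_outlier_cells_replaced_by_clean_mean(self):
        vals = np.array([[1.0], [2.0], [3.0], [5.0], [5.0]])
        labels = ["WT"] * 3 + ["DB"] * 2
        mask = np.zeros_like(vals, dtype=bool)
        mask[2, 0] = True
        out, report = se.impute(make_table(vals, labels), mask)
        assert out.values[2, 0] == pytest.approx(1.5)
        assert report.imputed_cells[0][2] == "outlier"

    def test_pooled_scope_uses_all_clean_values(self):
        vals = np.array([[0.0], [0.0], [2.0], [np.nan]])
        labels = ["WT", "WT", "DB", "DB"]
        out, _ = se.impute(make_table(vals, labels), scope="pooled")
        assert out.values[3, 0] == pytest.approx(2.0 / 3.0)

    def test_no_clean_values_rejected(self):
        vals = np.array([[np.nan], [np.nan], [1.0], [2.0]])
        labels = ["WT", "WT", "DB", "DB"]
        with pytest.raises(EngineeringError, match="no clean values"):
            se.impute(make_table(vals, labels))

    def test_imputation_preserves_scope_mean(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=(12, 6))
        labels = ["WT"] * 6 + ["DB"] * 6
        miss = rng.random((12, 6)) < 0.2
        vals[miss] = np.nan
        t = make_table(vals, labels)
        out, _ = se.impute(t)
        for label in ("WT", "DB"):
            rows = t.class_rows(label)
            for j in range(6):
                clean = t.values[rows, j][~t.missing_mask[rows, j]]
                if clean.size:
                    assert out.values[rows, j].mean() == pytest.approx(clean.mean())


class TestMinMaxScale:
    def test_definition_and_constant_rule(self):
        t = make_table([[2.0, 7.0], [4.0, 7.0], [6.0, 7.0]], ["WT", "WT", "DB"])
        out = se.minmax_scale(t)
        np.testing.assert_allclose(out.values[:, 0], [0.0, 0.5, 1.0])
        np.testing.assert_allclose(out.values[:, 1], 0.0)

    def test_train_fit_extrapolates(self):
        t = make_table([[0.0], [10.0], [12.0]], ["WT", "DB", "DB"])
        out = se.minmax_scale(t, fit_rows=np.array([0, 1]))
        assert out.values[2, 0] == pytest.approx(1.2)

    def test_idempotent(self):
        t = make_table([[2.0], [4.0], [6.0]], ["WT", "WT", "DB"])
        once = se.minmax_scale(t)
        twice = se.minmax_scale(once)
        np.testing.assert_array_equal(once.values, twice.values)

    def test_requires_full_observation(self):
        t = make_table([[np.nan], [1.0]], ["WT", "DB"])
        with pytest.raises(EngineeringError):
            se.minmax_scale(t)


class TestPartitions:
    def test_seventeen_named_partitions(self, partitions_w20):
        assert set(partitions_w20) == set(se.PARTITION_NAMES)
        assert len(partitions_w20) == 17

    def test_septal_membership(self, schema, partitions_w20):
        septal = set(partitions_w20["Septal"].member_features)
        expected = (
            set(schema.segment_features["AntSeptum"])
            | set(schema.segment_features["PostSeptal"])
            | set(schema.region_feature_names("Septal"))
        )
        assert septal == expected

    def test_segment_partition_size(self, partitions_w20):
        assert len(partitions_w20["AntSeptum"].member_features) == 32

    def test_complete_preserves_column_order(self, engineered_w20, partitions_w20):
        table, _ = engineered_w20
        assert partitions_w20["Complete"].member_features == table.feature_names

    def test_coverage_and_disjointness(self, schema, partitions_w20):
        segments = [set(partitions_w20[s].member_features) for s in schema.segments]
        for i in range(len(segments)):
            for j in range(i + 1, len(segments)):
                assert not segments[i] & segments[j]
        union = (
            set(partitions_w20["Segmental"].member_features)
            | set(partitions_w20["Global"].member_features)
            | set(partitions_w20["M-mode"].member_features)
            | set(partitions_w20["PWD"].member_features)
            | {f for r in schema.region_map for f in schema.region_feature_names(r)}
        )
        assert union == set(partitions_w20["Complete"].member_features)
        seg_union = set().union(*segments)
        assert seg_union == set(partitions_w20["Segmental"].member_features)

    def test_missing_schema_features_rejected(self, schema):
        t = blank_schema_table(schema).restrict(schema.all_features[:50])
        with pytest.raises(EngineeringError, match="lacks schema features"):
            se.partition_datasets(t, schema)


def test_normalize_then_average_equals_average_then_normalize(schema):
    """Mass normalization commutes with region averaging (shared per-animal
    divisor), up to float tolerance."""
    spec = se.null_spec(seed=4, missing_rate=0.0, outlier_rate=0.0)
    raw = se.simulate_cohort(schema, spec, timepoint_weeks=20)
    ste = schema.all_ste_segment_features
    a = se.absolutize(raw, ste)
    path1 = se.derive_regions(se.normalize_to_lv_mass(a, ste, schema.lv_mass_feature), schema)
    b = se.derive_regions(a, schema)
    region_feats = [f for r in schema.region_map for f in schema.region_feature_names(r)]
    path2 = se.normalize_to_lv_mass(b, ste + region_feats, schema.lv_mass_feature)
    cols = path1.column_index(region_feats)
    np.testing.assert_allclose(
        path1.values[:, cols], path2.values[:, path2.column_index(region_feats)], atol=1e-12
    )
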