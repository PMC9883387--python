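"""VOC pipeline: censoring, significance screen, normalization chain, PCA."""

import numpy as np
import pandas as pd
import pytest

from fermentomics import (
    VOCTable,
    baseline_shift,
    censor_lod,
    descriptor_assignment,
    mean_center,
    pca_vocs,
    significant_vocs,
    supernormalize_by_class,
)
from fermentomics.volatilome import area_ratio_to_mgkg


def voc_table(values: dict[str, list[float]], classes: dict[str, str] | None = None,
              treatments=None, times=None) -> VOCTable:
    n = len(next(iter(values.values())))
    meta = pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(n)],
        "treatment": treatments or ["HBPA"] * n,
        "time_h": times or [0.0] * n,
        "bio_rep": [i % 2 + 1 for i in range(n)],
        "tech_rep": [1] * n,
    })
    data = pd.concat([meta, pd.DataFrame(values)], axis=1)
    classes = classes or {c: "organic_acid" for c in values}
    return VOCTable(data=data, classes=classes, provenance="raw")


class TestCensorLOD:
    @pytest.mark.parametrize(
        "value,stored,censored,semi",
        [(0.005, 0.01, True, False), (0.02, 0.02, False, True), (0.5, 0.5, False, False)],
    )
    def test_lod_loq_rules(self, value, stored, censored, semi):
        t = censor_lod(voc_table({"c": [value]}))
        assert t.data["c"].iloc[0] == pytest.approx(stored)
        assert bool(t.censored["c"].iloc[0]) is censored
        assert bool(t.semi_quant["c"].iloc[0]) is semi

    def test_negative_value_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            censor_lod(voc_table({"c": [-0.1]}))


class TestSignificantVOCs:
    def test_single_true_effect_detected(self):
        treatments = ["HBPA"] * 4 + ["BC"] * 4
        t = voc_table(
            {
                "hit": [5, 5.01, 5.02, 5.0, 1.0, 1.01, 1.02, 1.0],
                "flat1": [2, 2.01, 2.02, 2.0, 2.0, 2.01, 2.02, 2.0],
                "flat2": [3, 3.02, 3.01, 3.0, 3.01, 3.0, 3.02, 3.0],
            },
            treatments=treatments,
        )
        kept, report = significant_vocs(t, alpha=0.05, group_cols=("treatment",))
        assert kept.compounds == ["hit"]
        assert report.set_index("compound").loc["flat1", "kept"] == False  # noqa: E712

    def test_null_retention_near_alpha(self):
        kept = total = 0
        for seed in range(30):
            local = np.random.default_rng(seed)
            n = 24
            vals = {f"v{i}": local.normal(size=n).tolist() for i in range(100)}
            t = voc_table(vals, classes={f"v{i}": "other" for i in range(100)},
                          treatments=np.repeat(["HBPA", "FOS", "HB", "BC"], 6).tolist(),
                          times=[0.0, 6.0, 18.0] * 8)
            sub, _ = significant_vocs(t, alpha=0.05, group_cols=("treatment",))
            kept += len(sub.compounds)
            total += 100
        assert 0.03 < kept / total < 0.07

    def test_constant_compound_dropped_with_reason(self):
        t = voc_table({"flat": [1.0] * 6, "var": [1, 2, 3, 4, 5, 6.0]},
                      treatments=["HBPA"] * 3 + ["BC"] * 3)
        kept, report = significant_vocs(t, group_cols=("treatment",))
        row = report.set_index("compound").loc["flat"]
        assert not row["kept"] and "constant" in row["reason"]


class TestMeanCenter:
    def test_simple_centering(self):
        t = mean_center(voc_table({"c": [1.0, 2.0, 3.0]}))
        assert t.data["c"].tolist() == [-1.0, 0.0, 1.0]
        assert t.provenance == "centered"

    def test_idempotence(self):
        t = mean_center(voc_table({"c": [1.0, 2.0, 3.0]}))
        again = mean_center(t)
        assert np.allclose(t.data["c"], again.data["c"])

    def test_column_means_vanish_on_random_table(self):
        local = np.random.default_rng(1)
        t = mean_center(voc_table({f"c{i}": local.normal(5, 2, 10).tolist() for i in range(8)}))
        assert (t.values.mean(axis=0).abs() < 1e-12).all()

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError, match="single-sample"):
            mean_center(voc_table({"c": [1.0]}))


class TestSupernormalize:
    def test_per_class_centering_despite_scale_gap(self):
        t = voc_table(
            {"acid": [100.0, 200.0, 300.0], "ket": [0.01, 0.02, 0.03]},
            classes={"acid": "organic_acid", "ket": "ketone"},
        )
        out = supernormalize_by_class(t)
        assert set(out) == {"organic_acid", "ketone"}
        for sub in out.values():
            assert (sub.values.mean(axis=0).abs() < 1e-12).all()
            assert sub.provenance == "supernormalized"

    def test_unit_variance_option(self):
        local = np.random.default_rng(2)
        t = voc_table({f"c{i}": local.normal(0, i + 1, 12).tolist() for i in range(3)})
        out = supernormalize_by_class(t, scale=True)["organic_acid"]
        assert np.allclose(out.values.std(axis=0, ddof=0), 1.0, atol=1e-12)

    def test_unannotated_compound_rejected(self):
        with pytest.raises(KeyError, match="annotation"):
            VOCTable(
                data=voc_table({"c": [1.0]}).data,
                classes={},
            )


class TestBaselineShift:
    def _staircase(self):
        # treatment A +2 units, B +1, blank 0 at the endpoint; zero noise
        treatments = ["HBPA", "HB", "BC"] * 4
        times = [0.0] * 6 + [24.0] * 6
        produced = {"HBPA": 2.0, "HB": 1.0, "BC": 0.0}
        vals = [1.0] * 6 + [1.0 + produced[t] for t in treatments[6:]]
        return voc_table({"c": vals}, treatments=treatments, times=times)

    def test_raw_table_rejected(self):
        with pytest.raises(ValueError, match="normalized"):
            baseline_shift(self._staircase())

    def test_configured_deltas_and_letters_recovered(self):
        shifts = baseline_shift(mean_center(self._staircase()))
        at24 = shifts[shifts.time_h == 24.0].set_index("treatment")
        assert at24.loc["HBPA", "shift"] == pytest.approx(2.0)
        assert at24.loc["HB", "shift"] == pytest.approx(1.0)
        assert at24.loc["BC", "shift"] == pytest.approx(0.0)
        # centered baseline reference row is identically zero
        at0 = shifts[shifts.time_h == 0.0]
        assert np.allclose(at0["shift"], 0.0)

    def test_decay_gives_negative_shift(self):
        t = voc_table({"c": [2.0, 2.0, 0.5, 0.5]}, treatments=["BC"] * 4,
                      times=[0.0, 0.0, 24.0, 24.0])
        shifts = baseline_shift(mean_center(t))
        assert shifts[shifts.time_h == 24.0]["shift"].iloc[0] < 0

    def test_shift_invariance_under_compoundwise_constant(self):
        t1 = self._staircase()
        t2 = t1.with_values(t1.values + 37.0, provenance="raw")
        s1 = baseline_shift(mean_center(t1))
        s2 = baseline_shift(mean_center(t2))
        assert np.allclose(s1["shift"], s2["shift"])

    def test_no_baseline_rejected(self):
        t = voc_table({"c": [1.0, 2.0]}, times=[6.0, 24.0])
        with pytest.raises(ValueError, match="baseline"):
            baseline_shift(mean_center(t))


class TestPCA:
    def test_single_varying_compound_dominates(self):
        t = mean_center(voc_table({"c1": [1.0, 2, 3, 4], "c2": [5.0, 5, 5, 5]}))
        res = pca_vocs(t)
        assert res.proportion_explained[0] == pytest.approx(1.0)

    def test_two_orthogonal_factors_capture_everything(self):
        a = [1.0, 1, -1, -1, 1, 1, -1, -1]
        b = [1.0, -1, 1, -1, 1, -1, 1, -1]
        t = mean_center(voc_table({
            "c1": a, "c2": b, "c3": [x + y for x, y in zip(a, b)],
        }))
        res = pca_vocs(t)
        assert res.proportion_explained[:2].sum() == pytest.approx(1.0)

    def test_duplicated_samples_coincide(self):
        t = mean_center(voc_table({"c1": [1.0, 1.0, 3.0, 3.0], "c2": [0.0, 0.0, 2.0, 2.0]}))
        res = pca_vocs(t)
        assert np.allclose(res.scores.iloc[0], res.scores.iloc[1])

    def test_raw_table_rejected(self):
        with pytest.raises(ValueError, match="normalized"):
            pca_vocs(voc_table({"c1": [1.0, 2.0], "c2": [3.0, 4.0]}))


class TestDescriptors:
    def test_treatment_descriptor_zero_noise(self):
        treatments = ["HBPA"] * 4 + ["FOS"] * 4
        times = [0.0, 6.0, 18.0, 24.0] * 2
        t = voc_table({"c": [5, 5.01, 5.02, 5.03, 1, 1.01, 1.02, 1.03]},
                      treatments=treatments, times=times)
        res = descriptor_assignment(t).set_index("factor")
        assert res.loc["treatment", "significant"]
        assert res.loc["treatment", "descriptor_level"] == "HBPA"

    def test_time_descriptor(self):
        treatments = ["HBPA", "FOS"] * 4
        times = [0.0] * 4 + [24.0] * 4
        t = voc_table({"c": [1, 1.01, 1.02, 1.03, 9, 9.01, 9.02, 9.03]},
                      treatments=treatments, times=times)
        res = descriptor_assignment(t).set_index("factor")
        assert res.loc["time_h", "significant"]
        assert res.loc["time_h", "descriptor_level"] == "24.0"


def test_internal_standard_conversion():
    assert area_ratio_to_mgkg(0.5) == pytest.approx(2.0)
    assert np.allclose(area_ratio_to_mgkg([1.0, 2.0], istd_mg_per_l=4.0), [4.0, 8.0])
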