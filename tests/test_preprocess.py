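"""The GC-MS preprocessing chain, step by step and end to end."""

import numpy as np
import pandas as pd
import pytest

from phenometab import preprocess as pp
from phenometab.matrix import IntensityMatrix, PreprocessReport


def _matrix(values, blanks=None, **meta_extra):
    """Build an IntensityMatrix from a dict feature -> list of leaf values."""
    df = pd.DataFrame(values)
    df.index = [f"S{i}" for i in range(len(df))]
    meta = pd.DataFrame({
        "genotype": "G1", "treatment": "drought", "timepoint": 22,
        "replicate": range(1, len(df) + 1), "is_blank": False,
    }, index=df.index)
    for k, v in meta_extra.items():
        meta[k] = v
    if blanks is not None:
        bdf = pd.DataFrame(blanks)
        bdf.index = [f"B{i}" for i in range(len(bdf))]
        bmeta = pd.DataFrame({
            "genotype": "blank", "treatment": "blank", "timepoint": 22,
            "replicate": range(1, len(bdf) + 1), "is_blank": True,
        }, index=bdf.index)
        for k, v in meta_extra.items():
            bmeta[k] = 1.0 if k != "batch" else "B1"
        df = pd.concat([df, bdf])
        meta = pd.concat([meta, bmeta])
    return IntensityMatrix(df, meta)


# ---- raw normalization ----------------------------------------------------

def test_normalize_raw_unit_factors_identity():
    m = _matrix({"f1": [1.0, 2.0], "f2": [3.0, 4.0]},
                fresh_weight=1.0, is_response=1.0, batch="B1")
    out = pp.normalize_raw(m)
    pd.testing.assert_frame_equal(out.values, m.values.astype(float))


def test_normalize_raw_fresh_weight_proportionality():
    m1 = _matrix({"f1": [10.0]}, fresh_weight=1.0, is_response=1.0, batch="B1")
    m2 = _matrix({"f1": [10.0]}, fresh_weight=2.0, is_response=1.0, batch="B1")
    assert pp.normalize_raw(m2).values.iloc[0, 0] == pytest.approx(
        pp.normalize_raw(m1).values.iloc[0, 0] / 2.0)


def test_normalize_raw_equalizes_batches():
    """A spiked constant feature measured in two batches with different
    detector response ends up with equal batch means (ratio oracle)."""
    vals = {"f1": [10.0, 10.0, 30.0, 30.0], "f2": [4.0, 6.0, 12.0, 18.0]}
    m = _matrix(vals, fresh_weight=1.0, is_response=1.0,
                batch=["B1", "B1", "B2", "B2"])
    out = pp.normalize_raw(m)
    means = out.values["f1"].groupby(m.meta["batch"]).mean()
    assert means["B1"] == pytest.approx(means["B2"], rel=1e-9)


def test_normalize_raw_zero_factor_sample_excluded():
    m = _matrix({"f1": [1.0, 2.0]}, fresh_weight=[1.0, 0.0],
                is_response=1.0, batch="B1")
    out = pp.normalize_raw(m)
    assert out.n_samples == 1


# ---- blank filter ----------------------------------------------------------

def test_blank_filter_strict_twofold_boundary():
    m = _matrix(
        {"exact2x": [20.0, 20.0], "just_over": [20.1, 20.1], "clean": [50.0, 50.0]},
        blanks={"exact2x": [10.0, 10.0], "just_over": [10.0, 10.0],
                "clean": [np.nan, np.nan]},
    )
    out, report = pp.blank_filter(m)
    assert set(out.feature_ids) == {"just_over", "clean"}
    assert report.steps[0].removed == ["exact2x"]


def test_blank_filter_without_blanks_is_skipped():
    m = _matrix({"f1": [1.0, 2.0]})
    out, report = pp.blank_filter(m)
    assert out.n_features == 1
    assert report.steps[0].params.get("skipped") is True


# ---- presence filter --------------------------------------------------------

def test_presence_filter_boundary_at_80_percent():
    n = 100
    vals = {"kept80": [1.0] * 80 + [np.nan] * 20,
            "cut79": [1.0] * 79 + [np.nan] * 21}
    m = _matrix(vals)
    out, _ = pp.presence_filter(m, min_frac=0.8)
    assert set(out.feature_ids) == {"kept80"}


def test_presence_filter_zero_threshold_identity():
    m = _matrix({"f1": [1.0, np.nan, 2.0]})
    out, _ = pp.presence_filter(m, min_frac=0.0)
    assert out.n_features == 1


def test_zero_counts_as_missing():
    m = _matrix({"f1": [0.0] * 5 + [1.0] * 5})
    out, _ = pp.presence_filter(m, min_frac=0.8)
    assert out.n_features == 0


# ---- imputation -------------------------------------------------------------

def test_impute_fifth_of_minimum():
    m = _matrix({"f1": [5.0, np.nan, 15.0], "f2": [10.0, 20.0, np.nan]})
    out = pp.impute_min_fraction(m, frac=0.2)
    assert out.values["f1"].tolist() == [5.0, 1.0, 15.0]
    assert out.values["f2"].tolist() == [10.0, 20.0, 2.0]


def test_impute_no_missing_identity():
    m = _matrix({"f1": [1.0, 2.0, 3.0]})
    out = pp.impute_min_fraction(m)
    pd.testing.assert_frame_equal(out.values, m.values.astype(float))


def test_impute_all_missing_feature_errors():
    m = _matrix({"f1": [np.nan, np.nan]})
    with pytest.raises(ValueError):
        pp.impute_min_fraction(m)


# ---- RSD filter --------------------------------------------------------------

def test_rsd_filter_removes_highest_quarter():
    rng = np.random.default_rng(0)
    base = 100.0
    vals = {}
    for name, rsd in (("a", 0.1), ("b", 0.2), ("c", 0.3), ("d", 0.4)):
        vals[name] = base * (1 + rsd * rng.standard_normal(40))
    m = _matrix(vals)
    out, report = pp.rsd_filter(m, top_frac=0.25)
    assert report.steps[0].removed == ["d"]
    assert set(out.feature_ids) == {"a", "b", "c"}


def test_rsd_filter_zero_fraction_identity():
    m = _matrix({"f1": [1.0, 2.0], "f2": [1.0, 5.0]})
    out, _ = pp.rsd_filter(m, top_frac=0.0)
    assert out.n_features == 2


def test_rsd_filter_tie_broken_by_feature_id():
    m = _matrix({"z_feat": [1.0, 2.0, 3.0], "a_feat": [1.0, 2.0, 3.0],
                 "calm": [10.0, 10.0, 10.001]})
    out, report = pp.rsd_filter(m, top_frac=0.34)  # floor(3*0.34) = 1 removed
    assert report.steps[0].removed == ["a_feat"]


def test_rsd_most_variable_removed_first():
    m = _matrix({"ok": [1.0, 2.0, 3.0], "wild": [1.0, 100.0, 1.0]})
    out, report = pp.rsd_filter(m, top_frac=0.5)
    assert report.steps[0].removed == ["wild"]


# ---- normalization / transforms ----------------------------------------------

def test_median_normalize_values_and_identity():
    m = _matrix({"f1": [1.0, 2.0], "f2": [2.0, 4.0], "f3": [3.0, 6.0]})
    out = pp.median_normalize(m)
    assert out.values.iloc[0].tolist() == [0.5, 1.0, 1.5]
    assert (out.values.median(axis=1) == 1.0).all()


def test_median_normalize_single_feature_all_ones():
    m = _matrix({"f1": [3.0, 7.0]})
    out = pp.median_normalize(m)
    assert (out.values["f1"] == 1.0).all()


def test_log10_transform_values_and_error():
    m = _matrix({"f1": [1.0, 100.0]})
    out = pp.log10_transform(m)
    assert out.values["f1"].tolist() == [0.0, 2.0]
    bad = _matrix({"f1": [1.0, 0.0]})
    with pytest.raises(ValueError, match="f1"):
        pp.log10_transform(bad)


def test_pareto_scale_column_and_identity():
    m = _matrix({"f1": [1.0, 2.0, 3.0]})
    out = pp.pareto_scale(m)
    assert np.allclose(out.values["f1"], [-1.0, 0.0, 1.0])  # sd = 1
    # post-scaling variance equals pre-scaling sd, every feature
    rng = np.random.default_rng(1)
    m2 = _matrix({f"f{i}": rng.gamma(3, 2, 12) for i in range(5)})
    out2 = pp.pareto_scale(m2)
    assert np.allclose(out2.values.var(axis=0, ddof=1), m2.values.std(axis=0, ddof=1))


def test_pareto_scale_constant_column_zeroed():
    m = _matrix({"f1": [4.0, 4.0, 4.0]})
    out = pp.pareto_scale(m)
    assert (out.values["f1"] == 0.0).all()


def test_row_normalize_moments():
    rng = np.random.default_rng(2)
    m = _matrix({f"f{i}": rng.normal(10, 2, 8) for i in range(3)})
    m.values["const"] = 5.0
    out = pp.row_normalize(m)
    assert np.allclose(out.values.drop(columns="const").mean(axis=0), 0, atol=1e-12)
    assert np.allclose(out.values.drop(columns="const").std(axis=0, ddof=1), 1)
    assert (out.values["const"] == 0.0).all()


# ---- pipeline ----------------------------------------------------------------

def test_report_telescoping_enforced():
    report = PreprocessReport()
    report.add("s1", 10, ["a", "b"])
    with pytest.raises(ValueError):
        report.add("s2", 9, [])  # 10 - 2 = 8, not 9


def test_pipeline_telescopes_and_is_per_timepoint_independent(default_study):
    _, matrix, _, _, _ = default_study
    norm = pp.normalize_raw(matrix)
    per_tp = pp.preprocess_pipeline(norm)
    for tp, (scaled, normalized, report) in per_tp.items():
        report.validate()
        assert report.steps[-1].n_out == scaled.n_features
        # sample medians equal one before the log step
        assert np.allclose(normalized.values.median(axis=1), 1.0)
    # processing one timepoint in isolation matches the joint run
    solo_scaled, _, solo_report = pp.preprocess_timepoint(norm.at_timepoint(22))
    pd.testing.assert_frame_equal(solo_scaled.values, per_tp[22][0].values)
    assert solo_report.to_frame().equals(per_tp[22][2].to_frame())


def test_dilution_invariance_of_normalization_chain():
    rng = np.random.default_rng(3)
    m = _matrix({f"f{i}": rng.gamma(4, 50, 10) for i in range(6)})
    scaled1 = pp.pareto_scale(pp.log10_transform(pp.median_normalize(m)))
    dilution = rng.uniform(0.5, 2.0, m.n_samples)
    m2 = IntensityMatrix(m.values.mul(dilution, axis=0), m.meta)
    scaled2 = pp.pareto_scale(pp.log10_transform(pp.median_normalize(m2)))
    assert np.allclose(scaled1.values, scaled2.values, atol=1e-10)


def test_clean_fixture_only_rsd_removes():
    rng = np.random.default_rng(4)
    n_feat = 20
    vals = {f"f{i:02d}": 1000 + 5 * rng.standard_normal(12) for i in range(n_feat)}
    blanks = {f"f{i:02d}": [1.0, 1.0] for i in range(n_feat)}
    m = _matrix(vals, blanks=blanks)
    scaled, _, report = pp.preprocess_timepoint(m)
    by_step = {s.step: s.n_removed for s in report.steps}
    assert by_step["blank_filter"] == 0
    assert by_step["presence_filter"] == 0
    assert by_step["rsd_filter"] == n_feat // 4
    assert scaled.n_features == n_feat - n_feat // 4
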