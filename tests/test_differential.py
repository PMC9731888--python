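import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gclfq.differential import (
    COMPARISONS,
    Comparison,
    Thresholds,
    call_differential,
    differential_table,
    linear_fold_from_log2,
    load_reference_differential,
    nd_status,
    paired_log2_fold_change,
    paired_t_test,
    volcano_table,
)
from gclfq.errors import InputError
from gclfq.quantify import GeneQuantMatrix

T1_VS_T0 = COMPARISONS["T1_vs_T0"]


def test_comparison_validation():
    with pytest.raises(InputError):
        Comparison("bad", "T0_before", "T0_before")
    with pytest.raises(InputError):
        Comparison("bad", "T9", "T0_before")
    assert T1_VS_T0.swapped().numerator == "T0_before"


def test_paired_fold_change_examples(make_log_ifot):
    # 2-subject genes are padded to the 3-subject design with NaN
    log_ifot, design = make_log_ifot({
        "doubles": {"T0": [np.log2(0.001), np.log2(0.002), np.nan],
                    "T1": [np.log2(0.002), np.log2(0.004), np.nan]},
        "flat": {"T0": [-3.0, -4.0, np.nan], "T1": [-3.0, -4.0, np.nan]},
        "mixed": {"T0": [0.0, 0.0, 0.0], "T1": [2.0, -1.0, 2.0]},
    })
    fc = paired_log2_fold_change(log_ifot, design, T1_VS_T0)
    assert fc.at["doubles", "avg_paired_log2fc"] == pytest.approx(1.0)
    assert fc.at["doubles", "n_pairs"] == 2
    assert fc.at["flat", "avg_paired_log2fc"] == pytest.approx(0.0)
    assert fc.at["mixed", "avg_paired_log2fc"] == pytest.approx(1.0)  # mean of {2,-1,2}
    assert fc.at["mixed", "n_pairs"] == 3


def test_paired_fold_change_no_pairs_is_nan(make_log_ifot):
    log_ifot, design = make_log_ifot({"g": {"T0": [np.nan, -3.0], "T1": [-2.0, np.nan]}})
    fc = paired_log2_fold_change(log_ifot, design, T1_VS_T0)
    assert fc.at["g", "n_pairs"] == 0 and np.isnan(fc.at["g", "avg_paired_log2fc"])


def test_paired_t_test_frozen_value_and_conventions(make_log_ifot):
    log_ifot, design = make_log_ifot({
        "g123": {"T0": [0.0, 0.0, 0.0], "T1": [1.0, 2.0, 3.0]},
        "zero": {"T0": [1.0, 1.0, 1.0], "T1": [1.0, 1.0, 1.0]},
        "const_shift": {"T0": [0.0, 0.0, 0.0], "T1": [2.0, 2.0, 2.0]},
        "scaled": {"T0": [0.0, 0.0, 0.0], "T1": [7.0, 14.0, 21.0]},
        "one_pair": {"T0": [0.0, np.nan, np.nan], "T1": [1.0, np.nan, np.nan]},
    })
    p = paired_t_test(log_ifot, design, T1_VS_T0)
    # differences {1,2,3}: t = 2/(1/sqrt(3)) = 3.4641, df = 2; closed form
    # for df=2: P = 1 - t/sqrt(2+t^2) = 0.074180
    assert p["g123"] == pytest.approx(0.074180, abs=1e-6)
    assert p["zero"] == 1.0  # sd = 0, mean = 0 convention
    assert np.isnan(p["const_shift"])  # sd = 0, mean != 0: t undefined
    assert p["scaled"] == pytest.approx(p["g123"])  # t is scale invariant
    assert np.isnan(p["one_pair"])  # < 2 pairs
    # independent check of the non-degenerate case
    ref = stats.ttest_rel([1.0, 2.0, 3.0], [0.0, 0.0, 0.0]).pvalue
    assert p["g123"] == pytest.approx(ref)


def _fc_frame(fc_values, n_pairs=14):
    return pd.DataFrame({
        "avg_paired_log2fc": fc_values,
        "n_pairs": [n_pairs] * len(fc_values),
    }, index=[f"g{i}" for i in range(len(fc_values))])


def test_call_thresholds_boundaries():
    fc = _fc_frame([-1.01, 0.585, 3.0, 0.584, 0.585])
    p = pd.Series([0.008, 0.049, 0.051, 0.001, 0.05], index=fc.index)
    out = call_differential(fc, p, Thresholds())
    assert out.at["g0", "called"] and out.at["g0", "direction"] == "down"
    assert out.at["g1", "called"] and out.at["g1", "direction"] == "up"  # fc boundary inclusive
    assert not out.at["g2", "called"]  # alpha strict
    assert not out.at["g3", "called"]  # below fold threshold
    assert not out.at["g4", "called"]  # P = alpha is not < alpha


def test_min_pairs_blocks_calls():
    fc = _fc_frame([2.0], n_pairs=2)
    p = pd.Series([0.001], index=fc.index)
    out = call_differential(fc, p, Thresholds(min_pairs=3))
    assert not out.at["g0", "called"]


@pytest.mark.parametrize("x,fold", [
    (5.15, 36), (4.25, 19), (6.08, 68), (6.77, 109), (6.91, 120), (4.68, 26),
    (0.0, 1), (-1.01, 2), (-5.15, 36),
])
def test_linear_fold_from_log2(x, fold):
    assert linear_fold_from_log2(x) == fold


def test_volcano_coordinates():
    fc = _fc_frame([-1.18, 0.1, 0.2])
    p = pd.Series([0.0004, 0.01, 1.0], index=fc.index)
    out = call_differential(fc, p)
    tab = volcano_table(out)
    assert tab.at["g0", "x"] == pytest.approx(-1.18)
    assert tab.at["g0", "y"] == pytest.approx(-np.log10(0.0004), abs=1e-3)
    assert tab.at["g0", "called"] and tab.at["g0", "direction"] == "down"
    assert tab.at["g1", "y"] == pytest.approx(2.0)
    assert tab.at["g2", "y"] == pytest.approx(0.0)


def _quant_from_log_ifot(log_ifot, design):
    ifot = (2.0 ** log_ifot).fillna(0.0)
    return GeneQuantMatrix(total_auc=ifot, ibaq=ifot, ifot=ifot,
                           log_ifot=log_ifot, design=design)


def test_nd_status_patterns(make_log_ifot):
    log_ifot, design = make_log_ifot({
        # detected at T0 and T1 in all subjects, never at T2
        "cfhr2_like": {"T0": [-4.0, -4.1], "T1": [-3.0, -3.1], "T2": [None, None]},
        "always": {"T0": [-4.0, -4.0], "T1": [-4.0, -4.0], "T2": [-4.0, -4.0]},
    })
    log_ifot = log_ifot.astype(float)
    quant = _quant_from_log_ifot(log_ifot, design)
    assert not nd_status(quant, T1_VS_T0)["cfhr2_like"]
    assert nd_status(quant, COMPARISONS["T2_vs_T0"])["cfhr2_like"]
    assert nd_status(quant, COMPARISONS["T2_vs_T1"])["cfhr2_like"]
    assert not nd_status(quant, COMPARISONS["T2_vs_T0"])["always"]


def test_antisymmetry_and_base_invariance(make_log_ifot):
    rng = np.random.default_rng(20260103)
    n_sub, n_genes = 8, 40
    values = {
        f"g{i}": {
            "T0": list(rng.normal(-10, 2, n_sub)),
            "T1": list(rng.normal(-10, 2, n_sub)),
            "T2": list(rng.normal(-10, 2, n_sub)),
        }
        for i in range(n_genes)
    }
    log_ifot, design = make_log_ifot(values)
    comp = T1_VS_T0
    fc = paired_log2_fold_change(log_ifot, design, comp)
    fc_sw = paired_log2_fold_change(log_ifot, design, comp.swapped())
    assert np.allclose(fc["avg_paired_log2fc"], -fc_sw["avg_paired_log2fc"])
    p = paired_t_test(log_ifot, design, comp)
    p_sw = paired_t_test(log_ifot, design, comp.swapped())
    assert np.allclose(p, p_sw)
    # switching the log base rescales every difference by a constant, so t
    # statistics and P values are unchanged
    log10_ifot = log_ifot * np.log10(2.0)
    p10 = paired_t_test(log10_ifot, design, comp)
    assert np.allclose(p, p10)


def test_duplicate_subject_sample_rejected(make_log_ifot):
    log_ifot, design = make_log_ifot({"g": {"T0": [0.0], "T1": [0.0]}})
    bad = pd.concat([design, design.iloc[[0]]], ignore_index=True)
    with pytest.raises(InputError, match="multiple samples"):
        paired_log2_fold_change(log_ifot, bad, T1_VS_T0)


# ---------------------------------------------------------------------------
# packaged reference-table regression


@pytest.fixture(scope="module")
def reference():
    return load_reference_differential()


def test_reference_table_shape(reference):
    assert set(reference["comparison"]) == {"T1_vs_T0", "T2_vs_T0", "T2_vs_T1"}
    assert len(reference) == 34 * 3
    cfhr2 = reference[(reference["gene_symbol"] == "CFHR2")
                      & (reference["comparison"] == "T2_vs_T0")]
    assert cfhr2["avg_paired_log2fc"].isna().all()  # printed as ND


@pytest.mark.parametrize("comparison,expected_called", [
    ("T1_vs_T0", 22),
    ("T2_vs_T0", 13),
])
def test_reference_calling_partition(reference, comparison, expected_called):
    """The calling rule reproduces the printed called/not-called partition."""
    sub = reference[reference["comparison"] == comparison].set_index("gene_symbol")
    fc = pd.DataFrame({
        "avg_paired_log2fc": sub["avg_paired_log2fc"],
        "n_pairs": 14,
    })
    out = call_differential(fc, sub["p_value"], Thresholds())
    assert int(out["called"].sum()) == expected_called


def test_reference_apob_rows(reference):
    apob = reference[reference["gene_symbol"] == "APOB"].set_index("comparison")
    assert apob.at["T1_vs_T0", "avg_paired_log2fc"] == pytest.approx(-1.01)
    assert apob.at["T1_vs_T0", "p_value"] == pytest.approx(0.008)
    assert apob.at["T2_vs_T0", "avg_paired_log2fc"] == pytest.approx(-1.18)
    assert apob.at["T2_vs_T0", "p_value"] == pytest.approx(0.0004)


def test_differential_table_end_to_end(default_quant):
    quant, _, truth = default_quant
    de = differential_table(quant, T1_VS_T0)
    assert {"comparison", "avg_paired_log2fc", "linear_fold", "p_value",
            "n_pairs", "called", "direction", "nd", "bh_q"} <= set(de.columns)
    called = de[de["called"]]
    assert (called["avg_paired_log2fc"].abs() >= 0.585).all()
    assert (called["p_value"] < 0.05).all()
    assert not de.loc[de["nd"], "called"].any()
    # spiked genes should dominate the called set
    spiked = truth.spiked.reindex(de.index).fillna(False)
    assert called.index.isin(spiked[spiked].index).mean() > 0.5
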