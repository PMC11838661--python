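import numpy as np
import pandas as pd
import pytest

from dmicrt.dynamics import (
    cov_percent,
    gm_wm_contrast,
    lmm_brain_vs_cgm,
    load_table1,
    load_table2,
    paired_ttest,
    phantom_auc_summary,
    simulate_lmm_study,
    snr_repetitions,
    summarize_table1,
    table2_group_means,
    trapezoid_auc,
)


def test_trapezoid_auc_matches_analytic():
    t = np.linspace(0.0, 10.0, 101)
    assert trapezoid_auc(t, 2.0 * np.ones_like(t)) == pytest.approx(20.0)
    assert trapezoid_auc(t, t) == pytest.approx(50.0, rel=1e-12)
    with pytest.raises(ValueError):
        trapezoid_auc(np.array([0.0, 0.0, 1.0]), np.zeros(3))
    with pytest.raises(ValueError):
        trapezoid_auc(np.array([0.0]), np.array([1.0]))


def test_cov_percent():
    assert cov_percent(np.array([9.0, 10.0, 11.0])) == pytest.approx(10.0)
    with pytest.raises(ValueError):
        cov_percent(np.array([1.0]))


def test_gm_wm_contrast():
    assert gm_wm_contrast(16.13, 12.708) == pytest.approx(26.9, abs=0.1)
    with pytest.raises(ValueError):
        gm_wm_contrast(1.0, 0.0)


def test_snr_repetitions(rng):
    grid = (6, 6, 6)
    signal = np.full(grid, 10.0)
    reps = signal[None] + 0.5 * rng.standard_normal((40, *grid))
    roi = np.ones(grid, dtype=bool)
    snr = snr_repetitions(reps, roi)
    assert snr == pytest.approx(20.0, rel=0.15)
    with pytest.raises(ValueError):
        snr_repetitions(np.ones((3, *grid)), roi)  # identical repetitions


def test_paired_ttest_detects_shift(rng):
    a = rng.normal(5.0, 0.2, size=20)
    shift = 1.0 + rng.normal(0.0, 0.05, size=20)
    res = paired_ttest(a + shift, a)
    assert res["p"] < 1e-6
    assert res["mean_difference"] == pytest.approx(np.mean(shift), abs=1e-9)


def test_table1_contents():
    df = load_table1()
    assert len(df) == 6
    assert df["baseline_cgm_mM"].mean() == pytest.approx(5.43, abs=0.005)
    summary = summarize_table1()
    assert round(summary.means["auc_cgm_mM_min"], 2) == 508.94
    assert summary.means["auc_dmi_mM_min"] == pytest.approx(148.53, abs=0.01)
    assert round(summary.means["auc_ratio"], 2) == 0.29


def test_table2_contents():
    df = load_table2()
    assert len(df) == 72  # 6 subjects x 2 schemes x 3 species x 2 regions
    groups = table2_group_means()

    def mean_of(scheme, species, region):
        row = groups[
            (groups.scheme == scheme)
            & (groups.species == species)
            & (groups.region == region)
        ]
        return float(row["mean_mM"].iloc[0])

    assert mean_of("bSSFP", "glc", "GM") == pytest.approx(2.91, abs=0.0051)
    assert mean_of("bSSFP", "glx", "GM") == pytest.approx(4.05, abs=0.0051)
    assert mean_of("bSSFP", "water", "GM") == pytest.approx(16.13, abs=0.0051)


def test_lmm_exact_recovery_without_variance():
    data = simulate_lmm_study(
        beta0=-1.0, beta1=0.5, re_sd_intercept=0.0, re_sd_slope=0.0,
        noise_sd=0.0, seed=0,
    )
    fit = lmm_brain_vs_cgm(data)
    assert fit.beta0 == pytest.approx(-1.0, abs=1e-6)
    assert fit.beta1 == pytest.approx(0.5, abs=1e-6)
    assert fit.singular  # zero random-effect variance is a boundary fit


def test_lmm_recovery_with_variance():
    data = simulate_lmm_study(seed=11)
    fit = lmm_brain_vs_cgm(data)
    assert fit.n_groups == 6
    assert fit.beta1 == pytest.approx(0.47, abs=0.15)
    assert fit.p_beta1 < 0.01


def test_lmm_input_validation():
    with pytest.raises(ValueError):
        lmm_brain_vs_cgm(pd.DataFrame({"subject": [1], "cgm": [1.0]}))
    one = simulate_lmm_study(n_subjects=1)
    with pytest.raises(ValueError):
        lmm_brain_vs_cgm(one)


def test_phantom_auc_summary_contents():
    df = phantom_auc_summary()
    assert {"species", "tissue", "auc_mM_min", "peak_mM"} <= set(df.columns)
    glc_gm = df[(df.species == "glc") & (df.tissue == "GM")].iloc[0]
    assert glc_gm["auc_mM_min"] > 0
    # GM exceeds WM for the labeled pools
    glc_wm = df[(df.species == "glc") & (df.tissue == "WM")].iloc[0]
    assert glc_gm["auc_mM_min"] > glc_wm["auc_mM_min"]
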