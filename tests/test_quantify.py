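import numpy as np
import pytest

from dmicrt import constants
from dmicrt.params import bssfp_protocol
from dmicrt.quantify import (
    ConcentrationMapSet,
    QuantConstants,
    TissueMasks,
    estimate_concentrations,
    regional_statistics,
    voxel_water_reference,
)
from dmicrt.separation import MetaboliteMapSet
from dmicrt.signals import default_species, quant_correction_factor


def test_water_reference_scaling():
    fr = {"GM": np.array([1.0, 0.0]), "WM": np.array([0.0, 1.0]),
          "CSF": np.array([0.0, 0.0])}
    ref = voxel_water_reference(fr)
    assert ref[0] == pytest.approx(17.2 * 0.78)
    assert ref[1] == pytest.approx(17.2 * 0.65)


def test_masks_threshold_inclusive():
    masks = TissueMasks(
        gm_fraction=np.array([0.59, 0.60, 0.61]),
        wm_fraction=np.array([0.0, 0.0, 0.0]),
    )
    assert list(masks.masks["GM"]) == [False, True, True]


def test_water_self_quantification_identity():
    """Baseline water quantifies exactly to the reference concentration."""
    grid = (3, 3, 3)
    fr = {"GM": np.full(grid, 0.7), "WM": np.full(grid, 0.3),
          "CSF": np.zeros(grid)}
    params = bssfp_protocol(matrix=(12, 12, 11))
    species = [default_species()["water"]]
    amp = np.full(grid, 2.5)  # arbitrary scale cancels in the ratio
    ms = MetaboliteMapSet(maps={"water": amp}, scheme="bSSFP")
    conc = estimate_concentrations(ms, amp, fr, params, species)
    expected = voxel_water_reference(fr)
    assert np.allclose(conc.maps["water"], expected)


def test_metabolite_quantification_corrections():
    """Known amplitude ratio maps back through relaxation/deuteron factors."""
    grid = (2, 2, 2)
    fr = {"GM": np.ones(grid), "WM": np.zeros(grid), "CSF": np.zeros(grid)}
    params = bssfp_protocol(matrix=(12, 12, 11))
    table = default_species()
    species = [table["water"], table["glx"]]
    c_glx = 4.0
    f_w = quant_correction_factor("bSSFP", table["water"], "GM", params)
    f_g = quant_correction_factor("bSSFP", table["glx"], "GM", params)
    ref = 17.2 * 0.78
    water_amp = np.full(grid, 10.0)
    # forward model of the amplitude the scanner would see for c_glx mM
    glx_amp = water_amp * (c_glx / ref) * (f_g / f_w) * (1 / 1) * (1 - 0.4)
    ms = MetaboliteMapSet(maps={"water": water_amp, "glx": glx_amp}, scheme="bSSFP")
    conc = estimate_concentrations(ms, water_amp, fr, params, species)
    assert np.allclose(conc.maps["glx"], c_glx)


def test_noise_floor_masks_voxels():
    grid = (3,)
    fr = {"GM": np.ones(grid), "WM": np.zeros(grid), "CSF": np.zeros(grid)}
    params = bssfp_protocol(matrix=(12, 12, 11))
    species = [default_species()["water"]]
    ms = MetaboliteMapSet(maps={"water": np.array([5.0, 5.0, 5.0])}, scheme="bSSFP")
    baseline = np.array([5.0, 0.05, 5.0])
    conc = estimate_concentrations(
        ms, baseline, fr, params, species, water_noise_floor=0.1
    )
    assert np.isnan(conc.maps["water"][1])
    assert np.isfinite(conc.maps["water"][0])
    assert conc.missing("water")[1]


def test_regional_statistics_drops_nan():
    grid = (4,)
    conc = ConcentrationMapSet(
        maps={"glc": np.array([1.0, 2.0, np.nan, 9.0])}, time_min=70.0, scheme="bSSFP"
    )
    masks = TissueMasks(
        gm_fraction=np.array([1.0, 1.0, 1.0, 0.0]),
        wm_fraction=np.array([0.0, 0.0, 0.0, 1.0]),
    )
    df = regional_statistics(conc, masks)
    gm = df[(df.region == "GM") & (df.species == "glc")].iloc[0]
    assert gm["mean_mM"] == pytest.approx(1.5)
    assert gm["n_voxels"] == 2
    wm = df[(df.region == "WM") & (df.species == "glc")].iloc[0]
    assert wm["mean_mM"] == pytest.approx(9.0)
    assert np.isnan(wm["sd_mM"])


def test_regional_statistics_empty_mask_errors():
    conc = ConcentrationMapSet(maps={"glc": np.zeros(3)}, time_min=0.0, scheme="bSSFP")
    masks = TissueMasks(gm_fraction=np.zeros(3), wm_fraction=np.ones(3))
    with pytest.raises(ValueError):
        regional_statistics(conc, masks)


def test_quant_constants_validation():
    with pytest.raises(ValueError):
        QuantConstants(pure_water_d_concentration_mm=-1.0)
    assert constants.PURE_WATER_D_CONCENTRATION_MM == pytest.approx(17.2, rel=0.05)
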