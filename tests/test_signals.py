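import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dmicrt.params import Scheme, bssfp_protocol, fid_protocol
from dmicrt.signals import (
    LarmorContext,
    bloch_steady_state,
    bssfp_steady_state,
    default_species,
    effective_relaxation,
    quant_correction_factor,
    snr_efficiency_ratio,
    spoiled_fid_signal,
)


def test_on_resonance_closed_form():
    t1, t2, tr, flip = 358.0, 36.0, 23.0, 50.0
    e1, e2 = np.exp(-tr / t1), np.exp(-tr / t2)
    a = np.deg2rad(flip)
    expected = np.sin(a) * (1 - e1) / (1 - (e1 - e2) * np.cos(a) - e1 * e2)
    got = abs(bssfp_steady_state(1.0, t1, t2, tr, 0.0, flip))
    assert got == pytest.approx(expected, rel=1e-12)


def test_spoiled_fid_closed_form():
    t1, tr, flip, t2s = 358.0, 290.0, 86.0, 30.0
    e1 = np.exp(-tr / t1)
    a = np.deg2rad(flip)
    expected = np.sin(a) * (1 - e1) / (1 - e1 * np.cos(a))
    assert abs(spoiled_fid_signal(1.0, t1, tr, flip, t2s, 0.0)) == pytest.approx(
        expected, rel=1e-12
    )
    # decay over the readout
    assert abs(spoiled_fid_signal(1.0, t1, tr, flip, t2s, 30.0)) == pytest.approx(
        expected * np.exp(-1.0), rel=1e-12
    )


def test_bssfp_matches_bloch_iteration_off_resonance():
    for off in (-20.0, -5.0, 0.0, 7.5, 21.7):
        closed = bssfp_steady_state(1.0, 300.0, 60.0, 23.0, 11.5, 50.0, off)
        oracle = bloch_steady_state(300.0, 60.0, 23.0, 11.5, 50.0, off)
        assert abs(closed - oracle) <= 1e-8 * max(abs(oracle), 1e-12)


def test_spoiled_matches_bloch_iteration():
    t1, t2 = 358.0, 36.0
    closed = spoiled_fid_signal(1.0, t1, 290.0, 86.0, t2, 0.0)
    oracle = bloch_steady_state(
        t1, t2, 290.0, 0.0, 86.0, 0.0, phase_alternated=False, spoiled=True
    )
    assert abs(abs(closed) - abs(oracle)) <= 1e-8


@settings(max_examples=30, deadline=None)
@given(
    t1=st.floats(min_value=50.0, max_value=2000.0),
    ratio=st.floats(min_value=0.05, max_value=1.0),
    flip=st.floats(min_value=5.0, max_value=150.0),
)
def test_bssfp_bloch_property(t1, ratio, flip):
    t2 = t1 * ratio
    closed = bssfp_steady_state(1.0, t1, t2, 23.0, 0.0, flip)
    oracle = bloch_steady_state(t1, t2, 23.0, 0.0, flip)
    assert abs(closed - oracle) <= 1e-6 * max(abs(oracle), 1e-9)


def test_relaxation_validation():
    with pytest.raises(ValueError):
        bssfp_steady_state(1.0, 30.0, 60.0, 23.0, 0.0, 50.0)  # T2 > T1
    with pytest.raises(ValueError):
        bssfp_steady_state(1.0, 300.0, 60.0, 23.0, 30.0, 50.0)  # TE > TR


def test_default_species_frequencies():
    species = default_species()
    assert set(species) == {"water", "glc", "glx", "lac"}
    lar = LarmorContext()
    # offsets from the 3.2 ppm bSSFP carrier at 7 T
    assert lar.species_frequency_hz(species["water"], 3.2) == pytest.approx(73.2, abs=0.3)
    assert lar.species_frequency_hz(species["glc"], 3.2) == pytest.approx(32.0, abs=0.2)
    assert lar.species_frequency_hz(species["glx"], 3.2) == pytest.approx(-36.6, abs=0.2)
    assert species["glx"].label_loss_fraction == pytest.approx(0.4)
    assert species["glc"].n_deuterons == 2
    assert species["water"].n_deuterons == 1


def test_effective_relaxation_weighting():
    sp = default_species()["water"]
    fr = {"GM": np.array([1.0, 0.5, 0.0]), "WM": np.array([0.0, 0.5, 0.0]),
          "CSF": np.array([0.0, 0.0, 0.0])}
    t1, t2 = effective_relaxation(sp, fr)
    assert t1[0] == pytest.approx(sp.t1_ms["GM"])
    assert t1[1] == pytest.approx(0.5 * (sp.t1_ms["GM"] + sp.t1_ms["WM"]))
    assert np.isnan(t1[2]) and np.isnan(t2[2])


def test_quant_correction_factor_t0_reference():
    params = bssfp_protocol()
    sp = default_species()["water"]
    f = quant_correction_factor(Scheme.BSSFP, sp, "GM", params)
    expected = abs(
        bssfp_steady_state(1.0, sp.t1_ms["GM"], sp.t2_ms["GM"], 23.0, 0.0, 50.0)
    )
    assert f == pytest.approx(expected, rel=1e-12)
    fid = quant_correction_factor(Scheme.SPOILED_FID, sp, "GM", fid_protocol())
    assert fid == pytest.approx(
        abs(spoiled_fid_signal(1.0, sp.t1_ms["GM"], 290.0, 86.0, sp.t2_ms["GM"], 0.0)),
        rel=1e-12,
    )


def test_snr_efficiency_exceeds_two():
    ratio = snr_efficiency_ratio(bssfp_protocol(), fid_protocol())
    assert ratio > 2.0
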