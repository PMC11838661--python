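import numpy as np
import pytest

from dmicrt.params import bssfp_protocol, fid_protocol
from dmicrt.separation import (
    MetaboliteMapSet,
    SeparationModel,
    crlb_exclude,
    fit_fid_spectra,
    kspace_ideal_separate,
    native_separate,
    separation_conditioning,
    species_dampings,
    voxel_unmix,
)
from dmicrt.signals import default_species


@pytest.fixture(scope="module")
def bssfp_model():
    params = bssfp_protocol(matrix=(12, 12, 11))
    species = [default_species()[n] for n in ("water", "glc", "glx")]
    return SeparationModel.from_protocol(params, species)


def synthetic_kstack(model, grid, rng, dampings=None):
    """Model-consistent Cartesian multi-echo k-space from random species images."""
    n_sp = len(model.species_names)
    images = rng.standard_normal((n_sp, *grid)) + 1j * rng.standard_normal((n_sp, *grid))
    rho_k = np.stack([np.fft.fftshift(np.fft.fftn(img)) for img in images])
    tau = model.tau_map(grid)
    damp = np.zeros(n_sp) if dampings is None else np.asarray(dampings)
    z = (2j * np.pi * model.frequencies_hz - damp) / 1000.0
    kstack = np.zeros((model.echo_times_ms.size, *grid), dtype=complex)
    for n, te in enumerate(model.echo_times_ms):
        for m in range(n_sp):
            kstack[n] += rho_k[m] * np.exp(z[m] * (te + tau))
    return images, kstack


def test_ideal_exact_noiseless(bssfp_model, rng):
    images, kstack = synthetic_kstack(bssfp_model, (12, 12, 11), rng)
    out = kspace_ideal_separate(kstack, bssfp_model, magnitude=False)
    for m, name in enumerate(bssfp_model.species_names):
        err = np.abs(out.maps[name] - images[m])
        assert np.sqrt(np.mean(err**2)) <= 1e-8 * np.sqrt(np.mean(np.abs(images[m]) ** 2))


def test_ideal_conditioning_guard(bssfp_model):
    bad = SeparationModel(
        species_names=("a", "b"),
        frequencies_hz=np.array([10.0, 10.0]),  # identical -> singular
        echo_times_ms=bssfp_model.echo_times_ms,
        revolution_time_ms=bssfp_model.revolution_time_ms,
    )
    kstack = np.ones((5, 8, 8, 8), dtype=complex)
    with pytest.raises(np.linalg.LinAlgError):
        kspace_ideal_separate(kstack, bad)


def test_separation_conditioning_value(bssfp_model):
    cond = separation_conditioning(bssfp_model.frequencies_hz, bssfp_model.echo_times_ms)
    assert 1.0 < cond < 100.0


def test_species_dampings_values():
    species = [default_species()[n] for n in ("water", "glc", "glx")]
    rates = species_dampings(species, 150.0)
    t2_water = 0.5 * (36.0 + 34.0)
    assert rates[0] == pytest.approx(1000.0 * (1.0 / t2_water + 1.0 / 150.0))
    assert np.all(rates > 0)
    with pytest.raises(ValueError):
        species_dampings(species, 0.0)


def test_native_separate_exact_on_model_consistent_samples(bssfp_model, rng):
    """Per-sample separation is exact when data follow the damped basis."""
    from dmicrt.simulate import KSpaceData, model_forward
    from dmicrt.trajectory import build_crt_trajectory

    params = bssfp_protocol(matrix=(12, 12, 11))
    traj = build_crt_trajectory(params)
    grid = (12, 12, 11)
    species = [default_species()[n] for n in ("water", "glc", "glx")]
    damp = species_dampings(species, 150.0)
    # smooth compact images avoid ringing at the unsampled k-space corners
    x, y, z = np.meshgrid(*[np.linspace(-1, 1, n) for n in grid], indexing="ij")
    blob = np.exp(-((x / 0.45) ** 2 + (y / 0.45) ** 2 + (z / 0.45) ** 2))
    images = np.stack([(1.0 + 0.2 * m) * blob for m in range(3)]).astype(complex)
    vd = np.broadcast_to(damp[:, None, None, None], images.shape).copy()
    values = model_forward(images, bssfp_model.frequencies_hz, traj, params,
                           voxel_dampings_per_s=vd)
    out = native_separate(
        KSpaceData(values=values, traj=traj, params=params), bssfp_model,
        dampings_per_s=damp, magnitude=False,
    )
    # adjoint reconstruction has an arbitrary global scale and Hamming blur;
    # compare species ratios at the object centre, which must be exact
    c = (6, 6, 5)
    rec = np.array([out.maps[n][c] for n in bssfp_model.species_names])
    ratios = rec / rec[0]
    expected = np.array([1.0, 1.2, 1.4])
    assert np.allclose(np.abs(ratios), expected, rtol=1e-3)


def test_voxel_unmix_inverts_known_mixing(bssfp_model, rng):
    grid = (4, 4, 3)
    n_sp = 3
    true = rng.standard_normal((n_sp, *grid)) + 1j * rng.standard_normal((n_sp, *grid))
    damp = species_dampings(
        [default_species()[n] for n in ("water", "glc", "glx")], 150.0
    )
    field = rng.uniform(-9, 9, size=grid)
    vd = np.broadcast_to(damp[:, None, None, None], (n_sp, *grid)).copy()
    vd *= rng.uniform(0.8, 1.2, size=(n_sp, *grid))
    # build the per-voxel mixing that the separation stage would produce
    t_ms = bssfp_model.echo_times_ms
    z = (2j * np.pi * bssfp_model.frequencies_hz - damp) / 1000.0
    b = np.exp(np.outer(t_ms, z))
    g0inv_bh = np.linalg.solve(b.conj().T @ b, b.conj().T)
    mixed = np.zeros_like(true)
    for idx in np.ndindex(grid):
        e = np.diag(np.exp(2j * np.pi * field[idx] * t_ms / 1000.0))
        b_true = np.exp(
            np.outer(t_ms, 2j * np.pi * bssfp_model.frequencies_hz / 1000.0)
            - np.outer(t_ms, vd[(slice(None),) + idx] / 1000.0)
        )
        m = g0inv_bh @ e @ b_true
        mixed[(slice(None),) + idx] = m @ true[(slice(None),) + idx]
    rec = voxel_unmix(
        mixed, bssfp_model, basis_dampings_per_s=damp,
        fieldmap_hz=field, voxel_dampings_per_s=vd,
    )
    assert np.max(np.abs(rec - true)) <= 1e-9 * np.max(np.abs(true))


def test_fid_fit_recovers_amplitudes_and_dampings(rng):
    params = fid_protocol(matrix=(12, 12, 11))
    freqs = np.array([73.2, 32.0, -36.6])
    true_amp = np.array([5.0, 1.2, 0.8])
    true_damp = np.array([35.0, 30.0, 32.0])
    t_s = params.echo_times_ms / 1000.0
    fid = sum(
        a * np.exp((2j * np.pi * f - d) * t_s)
        for a, f, d in zip(true_amp, freqs, true_damp)
    )
    amp, crlb, damp, ok = fit_fid_spectra(fid, params.echo_times_ms, freqs)
    assert ok
    assert np.allclose(amp, true_amp, rtol=1e-6)
    assert np.allclose(damp, true_damp, rtol=1e-3)
    assert np.all(np.isfinite(crlb))


def test_fid_fit_nonneg_zero_species(rng):
    params = fid_protocol(matrix=(12, 12, 11))
    freqs = np.array([73.2, 32.0])
    t_s = params.echo_times_ms / 1000.0
    fid = 4.0 * np.exp((2j * np.pi * 73.2 - 33.0) * t_s)
    noisy = fid + 0.05 * (
        rng.standard_normal(t_s.size) + 1j * rng.standard_normal(t_s.size)
    )
    amp, crlb, _, _ = fit_fid_spectra(noisy, params.echo_times_ms, freqs)
    assert amp[0] == pytest.approx(4.0, rel=0.05)
    assert amp[1] >= 0.0
    # absent species gets a much larger relative uncertainty
    assert crlb[1] > crlb[0]


def test_crlb_exclude_thresholding():
    maps = {"glc": np.array([1.0, 2.0, 3.0])}
    crlb = {"glc": np.array([10.0, 50.0, 80.0])}
    ms = MetaboliteMapSet(maps=maps, scheme="bSSFP", crlb_pct=crlb)
    out = crlb_exclude(ms, 50.0)
    assert np.isnan(out.maps["glc"][2])
    # the voxel exactly at the threshold is retained
    assert out.maps["glc"][1] == 2.0
    assert out.excluded_counts["glc"] == 1
    with pytest.raises(ValueError):
        crlb_exclude(MetaboliteMapSet(maps=maps, scheme="bSSFP"), 50.0)
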