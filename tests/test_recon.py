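import numpy as np
import pytest

from dmicrt import constants
from dmicrt.params import bssfp_protocol
from dmicrt.recon import (
    EchoImageStack,
    FieldMap,
    adjoint_dft,
    b0_correct,
    dft_forward,
    downsample_in_kspace,
    estimate_fieldmap_multiecho,
    reconstruct_dft,
    scale_fieldmap_to_deuterium,
)
from dmicrt.simulate import voxel_grid_positions
from dmicrt.trajectory import CRTrajectory, build_crt_trajectory


def cartesian_trajectory(grid):
    """A trajectory whose samples are exactly the Cartesian grid points."""
    nx, ny, nz = grid
    kx, ky, kz = np.meshgrid(
        np.arange(nx) - nx // 2, np.arange(ny) - ny // 2, np.arange(nz) - nz // 2,
        indexing="ij",
    )
    n = kx.size
    ones = np.ones(n)
    return CRTrajectory(
        ring_index=np.zeros(n, dtype=int),
        point_index=np.zeros(n, dtype=int),
        kx=kx.ravel().astype(float),
        ky=ky.ravel().astype(float),
        kz=kz.ravel().astype(float),
        time_offset_ms=np.zeros(n),
        n_averages=np.ones(n, dtype=int),
        n_points_per_ring=1,
        revolution_time_ms=1.0,
        density_weights=ones / n,
        hamming_weights=ones.copy(),
    )


def test_forward_dft_matches_fft(rng):
    grid = (16, 16, 16)
    traj = cartesian_trajectory(grid)
    img = rng.standard_normal(grid) + 1j * rng.standard_normal(grid)
    values = dft_forward(traj, img[None], grid)[0]
    # centred DFT (DC voxel and DC k-sample both at index N//2)
    ref = np.fft.fftshift(np.fft.fftn(np.fft.ifftshift(img))).ravel()
    assert np.max(np.abs(values - ref)) <= 1e-10 * np.max(np.abs(ref))


def test_adjoint_dft_matches_ifft(rng):
    grid = (16, 16, 16)
    traj = cartesian_trajectory(grid)  # uniform weights 1/N
    data = rng.standard_normal((traj.n_samples, 1)) + 1j * rng.standard_normal(
        (traj.n_samples, 1)
    )
    img = adjoint_dft(traj, data, grid)[0]
    ref = np.fft.fftshift(np.fft.ifftn(np.fft.ifftshift(data[:, 0].reshape(grid))))
    assert np.max(np.abs(img - ref)) <= 1e-10 * np.max(np.abs(ref))


def test_forward_adjoint_identity(rng):
    """<A x, w y> == <x, A^H(w y)> on the actual ring trajectory at 16^3."""
    grid = (16, 16, 15)
    traj = build_crt_trajectory(bssfp_protocol(matrix=grid))
    x = rng.standard_normal(grid) + 1j * rng.standard_normal(grid)
    y = rng.standard_normal((traj.n_samples, 1)) + 1j * rng.standard_normal(
        (traj.n_samples, 1)
    )
    lhs = np.vdot(dft_forward(traj, x[None], grid)[0], traj.effective_weights() * y[:, 0])
    rhs = np.vdot(x, adjoint_dft(traj, y, grid)[0])
    assert abs(lhs - rhs) <= 1e-8 * max(abs(lhs), abs(rhs))


def test_reconstruct_point_source(small_bundle):
    """A DC-only object reconstructs to a flat image (delta in k-space)."""
    params = bssfp_protocol(matrix=(12, 12, 11))
    traj = build_crt_trajectory(params)
    from dmicrt.simulate import KSpaceData

    values = np.ones((traj.n_samples, params.n_temporal_points), dtype=complex)
    stack = reconstruct_dft(KSpaceData(values=values, traj=traj, params=params))
    img = stack.images[0]
    centre = img[6, 6, 5]
    assert abs(centre) == pytest.approx(np.abs(img).max(), rel=1e-9)


def test_fieldmap_scaling():
    proton = FieldMap(values_hz=np.full((2, 2, 2), 100.0), nucleus="proton")
    deut = scale_fieldmap_to_deuterium(proton)
    assert deut.nucleus == "deuterium"
    assert np.allclose(deut.values_hz, 100.0 * constants.GAMMA_RATIO_2H_1H)
    with pytest.raises(ValueError):
        scale_fieldmap_to_deuterium(deut)


def test_estimate_fieldmap_from_phase_evolution(rng):
    grid = (6, 6, 5)
    freq = rng.uniform(-8.0, 8.0, size=grid)
    tes = np.array([2.0, 5.5, 9.0, 12.5, 16.0])
    mag = rng.uniform(0.5, 2.0, size=grid)
    echoes = [mag * np.exp(2j * np.pi * freq * te / 1000.0) for te in tes]
    fm = estimate_fieldmap_multiecho(echoes, tes, nucleus="deuterium")
    assert np.max(np.abs(fm.values_hz - freq)) < 1e-9
    assert not fm.ambiguous.any()


def test_b0_correct_roundtrip(rng):
    grid = (6, 6, 5)
    tes = np.array([2.0, 5.5, 9.0])
    images = rng.standard_normal((3, *grid)) + 1j * rng.standard_normal((3, *grid))
    stack = EchoImageStack(
        images=images, grid=grid, voxel_mm=(9.0, 9.0, 17.0), echo_times_ms=tes
    )
    fm = FieldMap(values_hz=rng.uniform(-9, 9, size=grid), nucleus="deuterium")
    corrected = b0_correct(stack, fm)
    restored = b0_correct(corrected, fm, inverse=True)
    assert np.allclose(restored.images, stack.images)
    # the correction actually removes a simulated phase ramp
    phased = EchoImageStack(
        images=images * np.exp(
            2j * np.pi * fm.values_hz[None] * tes[:, None, None, None] / 1000.0
        ),
        grid=grid, voxel_mm=(9.0, 9.0, 17.0), echo_times_ms=tes,
    )
    assert np.allclose(b0_correct(phased, fm).images, images)


def test_b0_correct_requires_deuterium_map(small_bundle):
    stack = EchoImageStack(
        images=np.zeros((2, 4, 4, 4), dtype=complex), grid=(4, 4, 4),
        voxel_mm=(1, 1, 1), echo_times_ms=np.array([1.0, 2.0]),
    )
    fm = FieldMap(values_hz=np.zeros((4, 4, 4)), nucleus="proton")
    with pytest.raises(ValueError):
        b0_correct(stack, fm)


def test_downsample_preserves_constant():
    high = np.full((36, 36, 33), 3.7)
    low = downsample_in_kspace(high, (12, 12, 11))
    assert np.allclose(low, 3.7)


def test_downsample_rejects_upsampling():
    with pytest.raises(ValueError):
        downsample_in_kspace(np.zeros((8, 8, 8)), (16, 16, 16))
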