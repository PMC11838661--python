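"""Forward simulation of multi-echo CRT k-space acquisitions.

Each k-space sample is the superposition over brain voxels and species of

    C(r) (1 - label_loss) N_D  S_scheme(T1, T2; r)
        * exp[(i 2 pi (f_species + B0(r)) - 1/T2*(r, species)) t_abs]
        * exp(-i 2 pi k . r) ,

where ``S_scheme`` is the on-resonance steady-state amplitude per unit
concentration-deuteron (voxel relaxation times are tissue-fraction weighted),
``t_abs`` is the time since excitation of the sample (echo time plus the
within-revolution offset), and ``1/T2* = 1/T2_species + 1/T2'_macroscopic``.
Decay is applied over the full time since excitation for both schemes.
Complex Gaussian noise is divided by sqrt(n_averages); the stored values are
the average-combined acquisition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .params import Scheme, SequenceParams
from .phantom import DigitalPhantom
from .signals import LarmorContext, SpinSpecies, bssfp_steady_state, effective_relaxation, spoiled_fid_signal
from .trajectory import CRTrajectory


@dataclass
class KSpaceData:
    """Complex CRT samples, one row per unique k-space location."""

    values: np.ndarray  # (n_samples, n_temporal)
    traj: CRTrajectory
    params: SequenceParams

    @property
    def scheme(self) -> Scheme:
        return self.params.scheme

    @property
    def echo_times_ms(self) -> np.ndarray:
        return self.params.echo_times_ms

    @property
    def t_abs_ms(self) -> np.ndarray:
        """Time since excitation of every (sample, temporal) value."""
        return self.traj.sample_times_ms(self.echo_times_ms)

    def __post_init__(self) -> None:
        if self.values.shape != (self.traj.n_samples, self.params.n_temporal_points):
            raise ValueError("k-space values do not match trajectory/protocol shape")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("k-space values must be finite")


def voxel_grid_positions(grid, flat: bool = True):
    """Voxel centre positions in fractions of the FOV (DC voxel at index N//2)."""
    axes = [(np.arange(n) - n // 2) / n for n in grid]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    if flat:
        return X.ravel(), Y.ravel(), Z.ravel()
    return X, Y, Z


def species_amplitude_map(
    phantom: DigitalPhantom,
    species: SpinSpecies,
    params: SequenceParams,
    time_min: float,
) -> np.ndarray:
    """Per-voxel signal amplitude (a.u.) of a species at one time point.

    Concentration times visible deuteron content times the on-resonance
    steady-state amplitude for the scheme, with fraction-weighted relaxation.
    """
    conc = phantom.concentration_map(species.name, time_min)
    t1, t2 = effective_relaxation(species, phantom.tissue_fractions)
    mask = phantom.brain_mask
    amp = np.zeros(phantom.grid)
    if not np.any(mask):
        return amp
    if params.scheme is Scheme.BSSFP:
        base = np.abs(
            bssfp_steady_state(
                1.0, t1[mask], t2[mask], params.repetition_time_ms, 0.0,
                params.flip_angle_deg,
            )
        )
    else:
        base = np.abs(
            spoiled_fid_signal(
                1.0, t1[mask], params.repetition_time_ms, params.flip_angle_deg,
                t2[mask], 0.0,
            )
        )
    amp[mask] = (
        conc[mask]
        * (1.0 - species.label_loss_fraction)
        * species.n_deuterons
        * base
    )
    return amp


def species_t2star_map(phantom: DigitalPhantom, species: SpinSpecies) -> np.ndarray:
    """Voxel-wise T2* of a species: species T2 shortened by the macroscopic T2'."""
    _, t2 = effective_relaxation(species, phantom.tissue_fractions)
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = 1.0 / t2 + 1.0 / phantom.t2star_macro_ms
    return 1.0 / rate


def model_forward(
    species_images: np.ndarray,
    frequencies_hz: np.ndarray,
    traj: CRTrajectory,
    params: SequenceParams,
    delta_hz: Optional[np.ndarray] = None,
    voxel_dampings_per_s: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Forward CRT signal model of complex per-species amplitude images.

    ``value(s, n) = sum_r sum_m a_m(r) exp[zeta_m(r) (t_n + tau_s)]
    exp(-i 2 pi k_s . r)`` with ``zeta_m(r) = i 2 pi (f_m + delta(r))
    - R_m(r)`` (angular rates per second, times in ms).  This is the linear
    operator whose approximate inverse the separation stage implements; it is
    used for iterative model-based refinement of the species maps.
    """
    species_images = np.asarray(species_images, dtype=complex)
    n_sp = species_images.shape[0]
    grid = species_images.shape[1:]
    if frequencies_hz.size != n_sp:
        raise ValueError("one frequency per species image required")
    xs, ys, zs = voxel_grid_positions(grid)
    flat = species_images.reshape(n_sp, -1)
    sel = np.flatnonzero(np.any(flat != 0, axis=0))
    values = np.zeros((traj.n_samples, params.n_temporal_points), dtype=complex)
    if sel.size == 0:
        return values
    xs, ys, zs = xs[sel], ys[sel], zs[sel]
    delta = (
        np.zeros(sel.size)
        if delta_hz is None
        else np.asarray(delta_hz, dtype=float).ravel()[sel]
    )
    t_base = params.echo_times_ms
    amps, zrates = [], []
    for m in range(n_sp):
        if voxel_dampings_per_s is None:
            rate = 0.0
        else:
            rate = np.asarray(voxel_dampings_per_s[m], dtype=float).ravel()[sel]
            rate = np.where(np.isfinite(rate), rate, 0.0)
        z = (2j * np.pi * (frequencies_hz[m] + delta) - rate) / 1000.0
        amps.append(flat[m, sel])
        zrates.append(z)
    evol = [
        a[:, None] * np.exp(z[:, None] * t_base[None, :])
        for a, z in zip(amps, zrates)
    ]
    for p in np.unique(traj.point_index):
        psel = traj.point_index == p
        tau = traj.time_offset_ms[psel][0]
        m = np.zeros((sel.size, t_base.size), dtype=complex)
        for ev, z in zip(evol, zrates):
            m += ev * np.exp(z * tau)[:, None]
        phase = np.exp(
            -2j
            * np.pi
            * (
                np.outer(traj.kx[psel], xs)
                + np.outer(traj.ky[psel], ys)
                + np.outer(traj.kz[psel], zs)
            )
        )
        values[psel, :] = phase @ m
    return values


def simulate_kspace(
    phantom: DigitalPhantom,
    traj: CRTrajectory,
    params: SequenceParams,
    species: Sequence[SpinSpecies],
    time_min: float,
    noise_sd: float = 0.0,
    seed: Optional[int] = None,
    larmor: LarmorContext = LarmorContext(),
) -> KSpaceData:
    """Simulate one CRT dataset of the phantom at ``time_min`` after intake."""
    for sp in species:
        for tissue in ("GM", "WM", "CSF"):
            if tissue not in sp.t1_ms:
                raise ValueError(f"species {sp.name} lacks relaxation for {tissue}")
    mask = phantom.brain_mask
    xs, ys, zs = voxel_grid_positions(phantom.grid)
    flat_mask = mask.ravel()
    xs, ys, zs = xs[flat_mask], ys[flat_mask], zs[flat_mask]
    b0 = phantom.b0_map_hz.ravel()[flat_mask]
    n_vox = xs.size

    t_base = params.echo_times_ms
    n_t = t_base.size
    values = np.zeros((traj.n_samples, n_t), dtype=complex)

    if n_vox:
        amps, zrates = [], []
        for sp in species:
            amp = species_amplitude_map(phantom, sp, params, time_min).ravel()[flat_mask]
            t2s = species_t2star_map(phantom, sp).ravel()[flat_mask]
            f_hz = larmor.species_frequency_hz(sp, params.center_frequency_ppm)
            # complex rate per ms
            z = 2j * np.pi * (f_hz + b0) / 1000.0 - 1.0 / t2s
            amps.append(amp)
            zrates.append(z)

        # per-species evolution over the echo/spectral time base
        evol = [
            a[:, None] * np.exp(z[:, None] * t_base[None, :])
            for a, z in zip(amps, zrates)
        ]

        # samples sharing a point index share the within-revolution offset
        for p in np.unique(traj.point_index):
            sel = traj.point_index == p
            tau = traj.time_offset_ms[sel][0]
            m = np.zeros((n_vox, n_t), dtype=complex)
            for ev, z in zip(evol, zrates):
                m += ev * np.exp(z * tau)[:, None]
            phase = np.exp(
                -2j
                * np.pi
                * (
                    np.outer(traj.kx[sel], xs)
                    + np.outer(traj.ky[sel], ys)
                    + np.outer(traj.kz[sel], zs)
                )
            )
            values[sel, :] = phase @ m

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        sigma = noise_sd / np.sqrt(2.0 * traj.n_averages)[:, None]
        values = values + sigma * (
            rng.standard_normal(values.shape) + 1j * rng.standard_normal(values.shape)
        )
    return KSpaceData(values=values, traj=traj, params=params)
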