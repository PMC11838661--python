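"""Concentric-ring k-space trajectory design.

The 3D trajectory is a stack of in-plane concentric rings: at every Cartesian
kz partition, rings of radius 1, 2, ..., floor(Nx/2) (in cycles per FOV) are
traversed once per temporal point, plus a single k=0 sample per partition.
Density-weighted averaging repeats inner rings according to a radial Hamming
window so that the acquisition-noise weighting matches the Hamming
reconstruction filter; the number of repeats per radius is apportioned so the
per-partition total equals the protocol's ring budget (e.g. 107 for the
published bSSFP protocol with an 11-radius 22x22 in-plane matrix).

Coordinates are in cycles/FOV with DC at the matrix centre index ``N//2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List

import numpy as np

from .params import SequenceParams


def hamming_window(x: np.ndarray | float) -> np.ndarray | float:
    """Radial Hamming window, w(0)=1 at the centre, w(1)=0.08 at the edge."""
    x = np.clip(np.abs(x), 0.0, 1.0)
    return 0.54 + 0.46 * np.cos(np.pi * x)


def hamming_averaging_scheme(n_radii: int, n_rings_total: int) -> List[int]:
    """Apportion ring acquisitions across radii proportional to a Hamming window.

    Uses largest-remainder apportionment (every radius gets at least one
    acquisition, the total is hit exactly) followed by a descending sort so
    the averages are monotone non-increasing with radius.
    """
    if n_radii < 1:
        raise ValueError("need at least one radius")
    if n_rings_total < n_radii:
        raise ValueError("ring budget must cover every radius at least once")
    radii = np.arange(1, n_radii + 1, dtype=float)
    w = np.asarray(hamming_window(radii / n_radii), dtype=float)
    quota = n_rings_total * w / w.sum()
    counts = np.maximum(1, np.floor(quota).astype(int))
    # largest-remainder top-up (or trim, if the >=1 floor over-allocated)
    while counts.sum() < n_rings_total:
        frac = quota - np.floor(quota)
        frac[counts > np.floor(quota)] = -1.0  # already topped up
        counts[int(np.argmax(frac))] += 1
    while counts.sum() > n_rings_total:
        candidates = np.where(counts > 1)[0]
        counts[candidates[-1]] -= 1
    counts = np.sort(counts)[::-1]
    return [int(c) for c in counts]


@dataclass
class CRTrajectory:
    """Per-sample k-space coordinates, timing and weights of a CRT scheme.

    One record per unique k-space location; ``n_averages`` counts how often
    the containing ring is acquired.  ``density_weights`` are per acquired
    average (so doubling the averages of a ring halves its per-average
    weight); reconstruction of average-combined data therefore uses
    ``density_weights * n_averages`` as the effective sample weight.
    """

    ring_index: np.ndarray      # int, 0 = the k=0 sample of a partition
    point_index: np.ndarray     # int, position along the ring revolution
    kx: np.ndarray              # cycles/FOV
    ky: np.ndarray
    kz: np.ndarray
    time_offset_ms: np.ndarray  # within one temporal readout
    n_averages: np.ndarray      # int
    n_points_per_ring: int
    revolution_time_ms: float
    density_weights: np.ndarray = field(default=None)  # type: ignore[assignment]
    hamming_weights: np.ndarray = field(default=None)  # type: ignore[assignment]

    @property
    def n_samples(self) -> int:
        return self.kx.size

    @property
    def radius(self) -> np.ndarray:
        return np.hypot(self.kx, self.ky)

    def effective_weights(self) -> np.ndarray:
        """Density x Hamming weight of each average-combined sample."""
        return self.density_weights * self.n_averages * self.hamming_weights

    def sample_times_ms(self, echo_times_ms: np.ndarray) -> np.ndarray:
        """Absolute time (since excitation) of every (sample, temporal) point."""
        return self.time_offset_ms[:, None] + np.asarray(echo_times_ms)[None, :]

    def with_uniform_weights(self) -> "CRTrajectory":
        ones = np.ones(self.n_samples)
        return replace(self, density_weights=ones.copy(), hamming_weights=ones.copy())


def build_crt_trajectory(params: SequenceParams) -> CRTrajectory:
    """Construct the stack-of-rings trajectory for one protocol.

    Per kz partition: a k=0 sample plus rings at radii 1..floor(Nx/2) with
    ``n_points_per_ring`` samples each.  Sample ``p`` on a ring is acquired at
    ``p / n_points_per_ring`` of the revolution time, identically on every
    ring (synchronous angular traversal), so acquisition time within a
    readout depends only on the azimuthal angle.
    """
    nx, ny, nz = params.matrix
    if nx < 4 or ny < 4:
        raise ValueError("in-plane matrix must be at least 4")
    n_radii = nx // 2
    if params.n_rings_total < n_radii:
        raise ValueError(
            f"{params.n_rings_total} ring acquisitions cannot cover "
            f"{n_radii} radii up to the Nyquist radius"
        )
    averages = hamming_averaging_scheme(n_radii, params.n_rings_total)
    n_pts = params.n_points_per_ring
    t_rev = params.revolution_time_ms

    kz_values = np.arange(nz) - nz // 2
    kz_max = max(np.max(np.abs(kz_values)), 1)

    ring_idx, pt_idx, kxs, kys, kzs, navg = [], [], [], [], [], []
    angles = 2.0 * np.pi * np.arange(n_pts) / n_pts
    for kz in kz_values:
        # the single DC sample of this partition
        ring_idx.append(np.array([0]))
        pt_idx.append(np.array([0]))
        kxs.append(np.array([0.0]))
        kys.append(np.array([0.0]))
        kzs.append(np.array([float(kz)]))
        navg.append(np.array([averages[0]]))
        for j in range(1, n_radii + 1):
            ring_idx.append(np.full(n_pts, j))
            pt_idx.append(np.arange(n_pts))
            kxs.append(j * np.cos(angles))
            kys.append(j * np.sin(angles))
            kzs.append(np.full(n_pts, float(kz)))
            navg.append(np.full(n_pts, averages[j - 1]))

    ring_index = np.concatenate(ring_idx).astype(int)
    point_index = np.concatenate(pt_idx).astype(int)
    traj = CRTrajectory(
        ring_index=ring_index,
        point_index=point_index,
        kx=np.concatenate(kxs),
        ky=np.concatenate(kys),
        kz=np.concatenate(kzs),
        time_offset_ms=point_index * (t_rev / n_pts),
        n_averages=np.concatenate(navg).astype(int),
        n_points_per_ring=n_pts,
        revolution_time_ms=t_rev,
    )
    traj.density_weights = density_compensation_weights(traj)
    w_inplane = hamming_window(traj.radius / n_radii)
    w_z = hamming_window(traj.kz / kz_max) if nz > 1 else np.ones(traj.n_samples)
    traj.hamming_weights = np.asarray(w_inplane * w_z)
    return traj


def density_compensation_weights(traj: CRTrajectory) -> np.ndarray:
    """Area-based density compensation, per acquired average.

    Every ring is assigned the annulus bounded midway to its radial
    neighbours (the innermost/DC location gets the central disc), and the
    annular area is split evenly over the samples of the ring and their
    averages.  For sampling that coincides with a uniform Cartesian grid this
    reduces to uniform weights.
    """
    r = traj.radius
    weights = np.empty(traj.n_samples)
    for kz in np.unique(traj.kz):
        part = traj.kz == kz
        radii = np.unique(np.round(r[part], 9))
        if radii.size == 1:
            bounds = np.array([max(radii[0] - 0.5, 0.0), radii[0] + 0.5])
        else:
            mid = 0.5 * (radii[:-1] + radii[1:])
            inner = max(radii[0] - (mid[0] - radii[0]), 0.0)
            outer = radii[-1] + (radii[-1] - mid[-1])
            bounds = np.concatenate([[inner], mid, [outer]])
        for i, radius in enumerate(radii):
            ring = part & (np.round(r, 9) == radius)
            if radius == 0.0:
                area = np.pi * bounds[i + 1] ** 2
            else:
                area = np.pi * (bounds[i + 1] ** 2 - bounds[i] ** 2)
            weights[ring] = area / (ring.sum() * traj.n_averages[ring])
    return weights


def point_spread_function(
    traj: CRTrajectory, axis: int = 0, extent_fov: float = 1.0, n_points: int = 512
) -> tuple[np.ndarray, np.ndarray]:
    """Complex PSF of the weighted trajectory along one image axis.

    Evaluates the density- and Hamming-weighted DFT of a unit point source at
    the origin on a fine line through the image centre; positions are in
    fractions of the FOV.
    """
    x = np.linspace(-extent_fov / 2, extent_fov / 2, n_points)
    k = (traj.kx, traj.ky, traj.kz)[axis]
    w = traj.effective_weights()
    psf = (w[None, :] * np.exp(2j * np.pi * x[:, None] * k[None, :])).sum(axis=1)
    return x, psf
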