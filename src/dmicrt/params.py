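"""Acquisition protocol parameters for bSSFP-CRT and spoiled FID-CRT DMI.

Two factory functions return the published 7 T protocols:

* :func:`bssfp_protocol` - TR 23 ms, flip 50deg (phase cycling factor 2),
  acquisition delay 2 ms, echo spacing 3.5 ms, 5 echo points, 285 Hz receiver
  bandwidth, carrier at 3.2 ppm, 107 ring acquisitions, 80 preparation scans.
* :func:`fid_protocol` - TR 290 ms, flip 86deg, 380 Hz spectral bandwidth,
  96 spectral points, carrier at 4.8 ppm, 43 ring acquisitions.
"""

from __future__ import annotations

import enum
import math
from typing import Optional, Tuple

import numpy as np
from pydantic import BaseModel, model_validator


class Scheme(str, enum.Enum):
    BSSFP = "bSSFP"
    SPOILED_FID = "spoiledFID"


class SequenceParams(BaseModel):
    """Pulse-sequence and sampling parameters for one CRT protocol."""

    scheme: Scheme
    repetition_time_ms: float
    flip_angle_deg: float
    phase_cycle_factor: int = 1
    pulse_duration_ms: float = 1.0
    acquisition_delay_ms: float = 2.0
    echo_spacing_ms: Optional[float] = None  # bSSFP only
    n_temporal_points: int
    receiver_bandwidth_hz: float
    center_frequency_ppm: float
    n_rings_total: int
    n_prep_scans: int = 0
    fov_mm: Tuple[float, float, float]
    matrix: Tuple[int, int, int]

    model_config = {"frozen": True}

    @model_validator(mode="after")
    def _check(self) -> "SequenceParams":
        if min(self.fov_mm) <= 0:
            raise ValueError("FOV must be positive")
        if not (0.0 < self.flip_angle_deg < 180.0):
            raise ValueError("flip angle must lie in (0, 180) degrees")
        for name in ("repetition_time_ms", "pulse_duration_ms", "receiver_bandwidth_hz"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.acquisition_delay_ms < 0:
            raise ValueError("acquisition delay must be non-negative")
        if self.n_temporal_points < 1:
            raise ValueError("need at least one temporal point")
        if min(self.matrix) < 1:
            raise ValueError("matrix entries must be >= 1")
        if self.matrix[0] != self.matrix[1]:
            raise ValueError("in-plane matrix must be square for ring trajectories")
        if self.scheme is Scheme.BSSFP:
            if self.echo_spacing_ms is None or self.echo_spacing_ms <= 0:
                raise ValueError("bSSFP requires a positive echo spacing")
            # the readout bandwidth matches one ring revolution per echo
            if abs(self.receiver_bandwidth_hz * self.echo_spacing_ms / 1000.0 - 1.0) > 0.01:
                raise ValueError(
                    "bSSFP receiver bandwidth must equal 1/echo_spacing within 1%"
                )
            readout = self.acquisition_delay_ms + self.n_temporal_points * self.echo_spacing_ms
            if readout > self.repetition_time_ms:
                raise ValueError("echo train does not fit inside the repetition time")
        return self

    @property
    def temporal_spacing_ms(self) -> float:
        """Spacing between consecutive temporal (echo/spectral) points.

        For bSSFP this is the echo spacing; for spoiled FID the spectral dwell
        time 1/receiver_bandwidth, one ring revolution per spectral point.
        """
        if self.scheme is Scheme.BSSFP:
            assert self.echo_spacing_ms is not None
            return self.echo_spacing_ms
        return 1000.0 / self.receiver_bandwidth_hz

    @property
    def echo_times_ms(self) -> np.ndarray:
        """Start-of-revolution time of each temporal point after excitation."""
        return self.acquisition_delay_ms + np.arange(self.n_temporal_points) * self.temporal_spacing_ms

    @property
    def revolution_time_ms(self) -> float:
        """Duration of one ring revolution (= 1/receiver bandwidth)."""
        return 1000.0 / self.receiver_bandwidth_hz

    @property
    def n_points_per_ring(self) -> int:
        """Samples per ring revolution: angular Nyquist of the outermost ring."""
        return 2 * self.matrix[0]

    @property
    def voxel_mm(self) -> Tuple[float, float, float]:
        return tuple(f / m for f, m in zip(self.fov_mm, self.matrix))

    @property
    def effective_echo_time_ms(self) -> float:
        """Echo time at which separated amplitudes are effectively estimated.

        bSSFP-CRT amplitudes come from a least-squares fit across the echo
        train, so the mean echo time is used; spoiled-FID amplitudes are
        extrapolated to t=0 by the spectral fit.
        """
        if self.scheme is Scheme.BSSFP:
            return float(np.mean(self.echo_times_ms))
        return 0.0


def bssfp_protocol(
    matrix: Tuple[int, int, int] = (22, 22, 21),
    fov_mm: Tuple[float, float, float] = (200.0, 200.0, 192.0),
    n_rings_total: Optional[int] = None,
) -> SequenceParams:
    """The published 7 T bSSFP-CRT protocol (0.75 ml isotropic at 22x22x21)."""
    if n_rings_total is None:
        n_rings_total = _scaled_rings(107, 22, matrix[0])
    return SequenceParams(
        scheme=Scheme.BSSFP,
        repetition_time_ms=23.0,
        flip_angle_deg=50.0,
        phase_cycle_factor=2,
        pulse_duration_ms=1.0,
        acquisition_delay_ms=2.0,
        echo_spacing_ms=3.5,
        n_temporal_points=5,
        receiver_bandwidth_hz=285.0,
        center_frequency_ppm=3.2,
        n_rings_total=n_rings_total,
        n_prep_scans=80,
        fov_mm=fov_mm,
        matrix=matrix,
    )


def fid_protocol(
    matrix: Tuple[int, int, int] = (22, 22, 21),
    fov_mm: Tuple[float, float, float] = (200.0, 200.0, 192.0),
    n_rings_total: Optional[int] = None,
    n_temporal_points: int = 96,
) -> SequenceParams:
    """The published 7 T spoiled FID-CRT protocol at matched resolution."""
    if n_rings_total is None:
        n_rings_total = _scaled_rings(43, 22, matrix[0])
    return SequenceParams(
        scheme=Scheme.SPOILED_FID,
        repetition_time_ms=290.0,
        flip_angle_deg=86.0,
        phase_cycle_factor=1,
        pulse_duration_ms=1.0,
        acquisition_delay_ms=2.0,
        echo_spacing_ms=None,
        n_temporal_points=n_temporal_points,
        receiver_bandwidth_hz=380.0,
        center_frequency_ppm=4.8,
        n_rings_total=n_rings_total,
        n_prep_scans=0,
        fov_mm=fov_mm,
        matrix=matrix,
    )


def _scaled_rings(reference_rings: int, reference_matrix: int, matrix_x: int) -> int:
    """Scale the published ring-acquisition budget to a smaller test matrix."""
    if matrix_x == reference_matrix:
        return reference_rings
    n_radii = matrix_x // 2
    scaled = int(round(reference_rings * n_radii / (reference_matrix // 2)))
    return max(scaled, n_radii)
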