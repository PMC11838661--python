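"""Dynamic digital brain phantom and physiological time courses.

The phantom is a nested-ellipsoid brain: a gray-matter shell around a
white-matter core with a central CSF ventricle, with partial-volume fractions
obtained by supersampling and a seeded low-order lumpy deformation of the
interfaces.  A smooth second-order polynomial B0 field (scaled to a
configurable ppm bound) and a macroscopic T2' map complete the static part.

Metabolite dynamics after oral tracer intake are phenomenological:

* labeled glucose follows a gamma-variate (rapid rise, slow washout) with a
  gray > white matter asymmetry,
* labeled Glx and the deuterated-water pool rise monotonically towards
  saturation,
* interstitial glucose (the CGM trace) rises from a fasted baseline of
  5.43 mM to a peak of 9.21 mM near 48 min before returning to baseline.

Default curve levels are calibrated so that ~70 min after intake the
gray-matter concentrations are ~2.91 mM Glc, ~4.05 mM Glx and ~16.1 mM
deuterated water (white matter: 2.22 / 3.05 / 12.7 mM).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Tuple

import numpy as np
from pydantic import BaseModel

from . import constants

TISSUES = ("GM", "WM", "CSF")

#: fractional tissue water content (literature defaults, configurable)
DEFAULT_WATER_CONTENT = {"GM": 0.78, "WM": 0.65, "CSF": 0.97}


class SpeciesKinetics(BaseModel):
    """Per-tissue kinetic description of one labeled species."""

    shape: str  # "gamma" (rise and washout) or "saturating" (monotone rise)
    level_70min_mm: Dict[str, float]  # concentration reached at t=70 min
    t_peak_min: float = 65.0  # gamma curves
    gamma_exponent: float = 2.0
    tau_min: float = 40.0  # saturating curves
    baseline_mm: Dict[str, float] = {}  # added natural-abundance floor

    def curve(self, tissue: str, times_min: np.ndarray) -> np.ndarray:
        t = np.asarray(times_min, dtype=float)
        target = self.level_70min_mm.get(tissue, 0.0)
        base = self.baseline_mm.get(tissue, 0.0)
        rise = target - base
        if self.shape == "gamma":
            g = _gamma_variate(t, self.t_peak_min, self.gamma_exponent)
            g70 = _gamma_variate(np.array(70.0), self.t_peak_min, self.gamma_exponent)
            vals = base + rise * g / g70
        elif self.shape == "saturating":
            s = 1.0 - np.exp(-np.maximum(t, 0.0) / self.tau_min)
            s70 = 1.0 - np.exp(-70.0 / self.tau_min)
            vals = base + rise * s / s70
        else:
            raise ValueError(f"unknown curve shape {self.shape!r}")
        return np.maximum(vals, 0.0)


class CGMParams(BaseModel):
    baseline_mm: float = 5.43
    peak_mm: float = 9.21
    t_peak_min: float = 48.0
    gamma_exponent: float = 3.0
    noise_sd_mm: float = 0.0


class DynamicsParams(BaseModel):
    """Kinetic parameters of all species plus the CGM sensor trace."""

    species: Dict[str, SpeciesKinetics] = {}
    cgm: CGMParams = CGMParams()
    water_content: Dict[str, float] = dict(DEFAULT_WATER_CONTENT)
    seed: int = 0

    @classmethod
    def default(cls, seed: int = 0) -> "DynamicsParams":
        content = dict(DEFAULT_WATER_CONTENT)
        nat = constants.PURE_WATER_D_CONCENTRATION_MM
        water_base = {t: nat * content[t] for t in TISSUES}
        return cls(
            species={
                "glc": SpeciesKinetics(
                    shape="gamma",
                    level_70min_mm={"GM": 2.91, "WM": 2.22, "CSF": 0.3},
                    t_peak_min=65.0,
                    gamma_exponent=2.0,
                ),
                "glx": SpeciesKinetics(
                    shape="saturating",
                    level_70min_mm={"GM": 4.05, "WM": 3.05, "CSF": 0.2},
                    tau_min=40.0,
                ),
                "water": SpeciesKinetics(
                    shape="saturating",
                    level_70min_mm={"GM": 16.13, "WM": 12.71,
                                    "CSF": water_base["CSF"] + 0.3},
                    tau_min=45.0,
                    baseline_mm=water_base,
                ),
                "lac": SpeciesKinetics(
                    shape="saturating",
                    level_70min_mm={"GM": 0.3, "WM": 0.25, "CSF": 0.05},
                    tau_min=50.0,
                ),
            },
            cgm=CGMParams(),
            water_content=content,
            seed=seed,
        )


def _gamma_variate(t: np.ndarray, t_peak: float, a: float) -> np.ndarray:
    """Gamma-variate normalized to 1 at its peak; zero for t <= 0."""
    t = np.asarray(t, dtype=float)
    x = np.maximum(t, 0.0) / t_peak
    return np.where(t > 0.0, x**a * np.exp(a * (1.0 - x)), 0.0)


def metabolite_timecourses(
    params: DynamicsParams, times_min: np.ndarray
) -> Dict[str, Dict[str, np.ndarray]]:
    """Pure-tissue concentration curves, ``{species: {tissue: mM array}}``."""
    times = np.asarray(times_min, dtype=float)
    return {
        name: {t: kin.curve(t, times) for t in TISSUES}
        for name, kin in params.species.items()
    }


@dataclass
class CGMTrace:
    """Interstitial glucose sensor readings."""

    times_min: np.ndarray
    glucose_mm: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times_min) <= 0):
            raise ValueError("CGM times must be strictly increasing")
        if np.any(self.glucose_mm <= 0):
            raise ValueError("CGM glucose must be positive")


def simulate_cgm_trace(
    params: CGMParams, times_min: np.ndarray, seed: Optional[int] = None
) -> CGMTrace:
    """Simulate a CGM trace: fasted baseline, post-intake peak, return to baseline."""
    times = np.asarray(times_min, dtype=float)
    bump = _gamma_variate(times, params.t_peak_min, params.gamma_exponent)
    glucose = params.baseline_mm + (params.peak_mm - params.baseline_mm) * bump
    if params.noise_sd_mm > 0:
        rng = np.random.default_rng(seed)
        glucose = glucose + rng.normal(0.0, params.noise_sd_mm, size=times.shape)
        glucose = np.maximum(glucose, 0.1)
    return CGMTrace(times_min=times, glucose_mm=glucose)


@dataclass
class DigitalPhantom:
    """Voxelized ground truth: tissue fractions, B0, T2' and dynamics."""

    grid: Tuple[int, int, int]
    voxel_mm: Tuple[float, float, float]
    tissue_fractions: Dict[str, np.ndarray]  # GM/WM/CSF in [0,1], sum <= 1
    b0_map_hz: np.ndarray  # deuterium Hz
    t2star_macro_ms: np.ndarray  # macroscopic (species-independent) T2'
    dynamics: DynamicsParams = field(default_factory=DynamicsParams.default)

    @property
    def brain_mask(self) -> np.ndarray:
        return self.total_fraction > 0.01

    @property
    def total_fraction(self) -> np.ndarray:
        return sum(self.tissue_fractions[t] for t in TISSUES)

    def concentration_map(self, species: str, time_min: float) -> np.ndarray:
        """True concentration map of a species at one time point (mM)."""
        kin = self.dynamics.species[species]
        out = np.zeros(self.grid)
        for tissue in TISSUES:
            level = kin.curve(tissue, np.asarray(time_min))
            out = out + self.tissue_fractions[tissue] * float(level)
        return out

    def true_concentrations(
        self, times_min: np.ndarray
    ) -> Dict[str, Dict[float, np.ndarray]]:
        """Per-species, per-timepoint true concentration maps."""
        return {
            name: {float(t): self.concentration_map(name, float(t)) for t in times_min}
            for name in self.dynamics.species
        }


def build_digital_phantom(
    grid: Tuple[int, int, int] = (22, 22, 21),
    seed: int = 0,
    voxel_mm: Optional[Tuple[float, float, float]] = None,
    b0_ppm_max: float = 0.2,
    t2star_macro_ms: float = 150.0,
    dynamics: Optional[DynamicsParams] = None,
    supersample: int = 3,
) -> DigitalPhantom:
    """Build the deterministic (seeded) nested-ellipsoid brain phantom.

    ``b0_ppm_max`` bounds the magnitude of the polynomial B0 field inside the
    brain (in ppm of the main field; 1 ppm ~ 45.75 Hz for deuterium at 7 T).
    """
    if min(grid) < 8:
        raise ValueError("phantom grid must be at least 8 voxels per axis")
    if voxel_mm is None:
        voxel_mm = (200.0 / grid[0], 200.0 / grid[1], 192.0 / grid[2])
    rng = np.random.default_rng(seed)

    # supersampled normalized coordinates in [-1, 1]
    axes = [
        (np.arange(n * supersample) + 0.5) / (n * supersample) * 2.0 - 1.0
        for n in grid
    ]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    # lumpy radial deformation from a seeded low-order harmonic
    cx, cy, cz = rng.uniform(-0.04, 0.04, size=3)
    lump = 1.0 + 0.05 * np.sin(2.5 * X + cx) * np.cos(2.0 * Y + cy) * np.cos(1.5 * Z + cz)
    rho = np.sqrt((X / 0.88) ** 2 + (Y / 0.88) ** 2 + (Z / 0.84) ** 2) * lump

    brain = rho < 1.0
    ventricle = rho < 0.22
    wm = (rho < 0.62) & ~ventricle
    gm = brain & ~wm & ~ventricle

    def downsample(mask: np.ndarray) -> np.ndarray:
        m = mask.astype(float)
        s = supersample
        return m.reshape(
            grid[0], s, grid[1], s, grid[2], s
        ).mean(axis=(1, 3, 5))

    fractions = {
        "GM": downsample(gm),
        "WM": downsample(wm),
        "CSF": downsample(ventricle),
    }

    # smooth second-order polynomial B0 field, scaled to the ppm bound
    axes_c = [(np.arange(n) + 0.5) / n * 2.0 - 1.0 for n in grid]
    Xc, Yc, Zc = np.meshgrid(*axes_c, indexing="ij")
    coeffs = rng.normal(size=9)
    b0 = (
        coeffs[0] * Xc + coeffs[1] * Yc + coeffs[2] * Zc
        + coeffs[3] * Xc * Yc + coeffs[4] * Xc * Zc + coeffs[5] * Yc * Zc
        + coeffs[6] * (Xc**2 - 0.5) + coeffs[7] * (Yc**2 - 0.5) + coeffs[8] * (Zc**2 - 0.5)
    )
    mask = fractions["GM"] + fractions["WM"] + fractions["CSF"] > 0.01
    peak = np.max(np.abs(b0[mask])) if np.any(mask) else 1.0
    b0 = b0 / peak * b0_ppm_max * constants.ppm_to_hz(1.0)

    return DigitalPhantom(
        grid=tuple(grid),
        voxel_mm=tuple(voxel_mm),
        tissue_fractions=fractions,
        b0_map_hz=b0,
        t2star_macro_ms=np.full(grid, float(t2star_macro_ms)),
        dynamics=dynamics or DynamicsParams.default(seed=seed),
    )
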