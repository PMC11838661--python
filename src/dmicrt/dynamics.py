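"""Dynamic analysis and group statistics for DMI glucose studies.

Operations on metabolite time courses and study tables: trapezoidal areas
under the curve (AUC), coefficients of variation, gray/white-matter contrast,
repetition-based SNR, a linear mixed-effects model relating brain deuterated
glucose to interstitial (CGM) glucose, and group summaries of the bundled
study tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Dict, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats as sps

from .phantom import CGMParams, DynamicsParams, metabolite_timecourses, simulate_cgm_trace


# ---------------------------------------------------------------------------
# bundled study tables
# ---------------------------------------------------------------------------

def load_table1() -> pd.DataFrame:
    """Per-subject study table: demographics, CGM and brain-DMI glucose AUCs."""
    with resources.files("dmicrt.data").joinpath("study_table1.csv").open("r") as fh:
        return pd.read_csv(fh)


def load_table2() -> pd.DataFrame:
    """Per-subject regional concentrations (mM) for both acquisition schemes."""
    with resources.files("dmicrt.data").joinpath("study_table2.csv").open("r") as fh:
        return pd.read_csv(fh)


# ---------------------------------------------------------------------------
# elementary dynamic metrics
# ---------------------------------------------------------------------------

def trapezoid_auc(times_min: np.ndarray, values: np.ndarray) -> float:
    """Trapezoidal area under the curve; times must be strictly increasing."""
    t = np.asarray(times_min, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.ndim != 1 or t.shape != v.shape:
        raise ValueError("times and values must be 1-D arrays of equal length")
    if t.size < 2:
        raise ValueError("need at least two samples for an AUC")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    return float(np.trapezoid(v, t))


def cov_percent(values: np.ndarray) -> float:
    """Coefficient of variation in percent (SD with n-1 over mean)."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 2:
        raise ValueError("need at least two finite values")
    mean = float(np.mean(v))
    if mean == 0.0:
        raise ValueError("mean is zero; CoV undefined")
    return 100.0 * float(np.std(v, ddof=1)) / mean


def gm_wm_contrast(gm_value: float, wm_value: float) -> float:
    """Relative GM-over-WM excess in percent: 100 * (GM / WM - 1)."""
    if wm_value <= 0:
        raise ValueError("WM reference value must be positive")
    return 100.0 * (float(gm_value) / float(wm_value) - 1.0)


def snr_repetitions(maps: np.ndarray, roi: np.ndarray) -> float:
    """SNR from repeated acquisitions of a static object.

    ``maps`` has shape (n_repetitions, *grid).  The SNR is the ROI mean of the
    per-voxel repetition means divided by the ROI mean of the per-voxel
    repetition standard deviations (n-1).  Voxels with zero variation are
    excluded with a warning; identical repetitions everywhere are an error.
    """
    m = np.asarray(maps, dtype=float)
    roi = np.asarray(roi, dtype=bool)
    if m.ndim < 2 or m.shape[0] < 2:
        raise ValueError("need at least two repetitions")
    if roi.shape != m.shape[1:]:
        raise ValueError("ROI shape must match map grid")
    vals = m[:, roi]  # (n_rep, n_roi)
    if vals.shape[1] == 0:
        raise ValueError("empty ROI")
    means = np.mean(vals, axis=0)
    sds = np.std(vals, axis=0, ddof=1)
    nonzero = sds > 0
    if not np.any(nonzero):
        raise ValueError("all repetitions identical; SNR undefined")
    if not np.all(nonzero):
        warnings.warn(
            f"excluding {int(np.sum(~nonzero))} zero-variance voxels from SNR",
            stacklevel=2,
        )
    return float(np.mean(means[nonzero]) / np.mean(sds[nonzero]))


def paired_ttest(a: np.ndarray, b: np.ndarray) -> Dict[str, float]:
    """Two-sided paired t-test between matched measurements."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be matched 1-D arrays")
    res = sps.ttest_rel(a, b)
    return {
        "t": float(res.statistic),
        "p": float(res.pvalue),
        "dof": float(a.size - 1),
        "mean_difference": float(np.mean(a - b)),
    }


# ---------------------------------------------------------------------------
# study summaries
# ---------------------------------------------------------------------------

@dataclass
class StudySummary:
    """Per-subject table plus group mean and SD (n-1) of the key quantities."""

    per_subject: pd.DataFrame
    means: Dict[str, float]
    sds: Dict[str, float]
    n_subjects: int


def summarize_table1(table: Optional[pd.DataFrame] = None) -> StudySummary:
    """Group summary of baselines, AUCs and the brain-to-CGM AUC ratio.

    The per-subject AUC ratio is computed from the subject's own AUCs and
    rounded to two decimals before averaging, matching how per-subject values
    are reported.
    """
    df = load_table1() if table is None else table.copy()
    required = {"subject", "baseline_cgm_mM", "auc_cgm_mM_min", "auc_dmi_mM_min"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"table missing columns: {sorted(missing)}")
    df["auc_ratio"] = (df["auc_dmi_mM_min"] / df["auc_cgm_mM_min"]).round(2)
    keys = ["baseline_cgm_mM", "auc_cgm_mM_min", "auc_dmi_mM_min", "auc_ratio"]
    means = {k: float(df[k].mean()) for k in keys}
    sds = {k: float(df[k].std(ddof=1)) if len(df) > 1 else float("nan") for k in keys}
    return StudySummary(per_subject=df, means=means, sds=sds, n_subjects=len(df))


def table2_group_means(table: Optional[pd.DataFrame] = None) -> pd.DataFrame:
    """Group mean and SD (n-1) per scheme, species and region across subjects."""
    df = load_table2() if table is None else table
    out = (
        df.groupby(["scheme", "species", "region"], as_index=False)
        .agg(
            mean_mM=("mean_mM", "mean"),
            sd_mM=("mean_mM", lambda v: v.std(ddof=1)),
            n_subjects=("subject", "nunique"),
        )
        .sort_values(["scheme", "species", "region"])
        .reset_index(drop=True)
    )
    return out


# ---------------------------------------------------------------------------
# linear mixed-effects model: brain glucose vs CGM glucose
# ---------------------------------------------------------------------------

@dataclass
class LMMResult:
    """Fixed effects and random-effect variances of the brain-vs-CGM model."""

    beta0: float
    beta1: float
    p_beta0: float
    p_beta1: float
    var_random_intercept: float
    var_random_slope: float
    residual_var: float
    converged: bool
    singular: bool
    n_observations: int
    n_groups: int


def lmm_brain_vs_cgm(data: pd.DataFrame) -> LMMResult:
    """Fit brain ~ cgm with per-subject random intercept and slope (REML).

    ``data`` needs columns ``subject``, ``cgm`` and ``brain``.  P-values are
    Wald tests on the fixed effects.  A near-zero random-effects covariance
    is flagged as a singular (boundary) fit rather than an error.
    """
    required = {"subject", "cgm", "brain"}
    missing = required - set(data.columns)
    if missing:
        raise ValueError(f"data missing columns: {sorted(missing)}")
    if data["subject"].nunique() < 2:
        raise ValueError("need at least two subjects for a mixed model")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm("brain ~ cgm", data, groups=data["subject"], re_formula="~cgm")
        fit = model.fit(reml=True, method=["lbfgs", "powell"])
    cov_re = np.asarray(fit.cov_re, dtype=float)
    scale = float(fit.scale)
    # boundary fit: random-effect variance collapses onto (near) zero
    singular = bool(np.min(np.diag(cov_re)) < 1e-8 * max(scale, 1e-12) + 1e-12)
    params = fit.params
    pvalues = fit.pvalues
    return LMMResult(
        beta0=float(params["Intercept"]),
        beta1=float(params["cgm"]),
        p_beta0=float(pvalues["Intercept"]),
        p_beta1=float(pvalues["cgm"]),
        var_random_intercept=float(cov_re[0, 0]),
        var_random_slope=float(cov_re[1, 1]),
        residual_var=scale,
        converged=bool(fit.converged),
        singular=singular,
        n_observations=int(len(data)),
        n_groups=int(data["subject"].nunique()),
    )


def simulate_lmm_study(
    beta0: float = -1.03,
    beta1: float = 0.47,
    n_subjects: int = 6,
    times_min: Optional[np.ndarray] = None,
    re_sd_intercept: float = 0.3,
    re_sd_slope: float = 0.05,
    noise_sd: float = 0.2,
    seed: int = 0,
    cgm: Optional[CGMParams] = None,
) -> pd.DataFrame:
    """Generate a tidy study dataset under the mixed-effects model.

    Each subject gets an interstitial glucose (CGM) trace and brain glucose
    observations ``beta0 + b0_i + (beta1 + b1_i) * cgm + noise``.  With all
    variance parameters zero the fixed effects are recovered exactly.
    """
    rng = np.random.default_rng(seed)
    if times_min is None:
        times_min = np.arange(0.0, 121.0, 10.0)
    times_min = np.asarray(times_min, dtype=float)
    base = cgm if cgm is not None else CGMParams()
    rows = []
    for subj in range(1, n_subjects + 1):
        # per-subject CGM curve: jitter baseline/peak so subjects differ
        params = base.model_copy(
            update={
                "baseline_mm": base.baseline_mm * (1.0 + 0.1 * rng.standard_normal()),
                "peak_mm": base.peak_mm * (1.0 + 0.1 * rng.standard_normal()),
            }
        )
        trace = simulate_cgm_trace(params, times_min)
        b0 = re_sd_intercept * rng.standard_normal()
        b1 = re_sd_slope * rng.standard_normal()
        brain = (
            (beta0 + b0)
            + (beta1 + b1) * trace.glucose_mm
            + noise_sd * rng.standard_normal(times_min.size)
        )
        for t, c, y in zip(times_min, trace.glucose_mm, brain):
            rows.append({"subject": subj, "time_min": t, "cgm": c, "brain": y})
    return pd.DataFrame(rows)


def phantom_auc_summary(
    dynamics: Optional[DynamicsParams] = None,
    times_min: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    """AUCs of the phantom ground-truth metabolite time courses per tissue."""
    dyn = dynamics if dynamics is not None else DynamicsParams.default()
    if times_min is None:
        times_min = np.arange(0.0, 121.0, 5.0)
    times_min = np.asarray(times_min, dtype=float)
    curves = metabolite_timecourses(dyn, times_min)
    rows = []
    for species, per_tissue in curves.items():
        for tissue, values in per_tissue.items():
            rows.append(
                {
                    "species": species,
                    "tissue": tissue,
                    "auc_mM_min": trapezoid_auc(times_min, values),
                    "peak_mM": float(np.max(values)),
                }
            )
    return pd.DataFrame(rows)
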