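# Methods

This document describes the models, algorithms and default parameters used by
`dmicrt`, a simulation and analysis pipeline for dynamic deuterium metabolic
imaging (DMI) of the human brain at 7 T with concentric-ring trajectories
(CRT). The pipeline compares a balanced steady-state free precession readout
(bSSFP-CRT) with a spoiled-FID readout (FID-CRT).

## 1. Signal models (`dmicrt.signals`)

### bSSFP steady state

The on-resonance bSSFP steady-state transverse magnetization is obtained by
solving the 3x3 fixed-point equation of the alternating-pulse sequence
exactly:

```
M_ss = (I - E R(alpha) P(phi))^-1  (I - E) M0
```

where `E = diag(E2, E2, E1)`, `E1 = exp(-TR/T1)`, `E2 = exp(-TR/T2)`,
`R(alpha)` is the excitation rotation and `P(phi)` precession by the
off-resonance phase `phi = 2*pi*df*TR` plus the alternating RF phase `pi`.
The signal is evaluated at the echo time by propagating the post-pulse state
through precession and T2 decay. A brute-force Bloch iteration (explicit
pulse-by-pulse time stepping, run for `max(ceil(25*max(T1,T2)/TR), 400)`
excitations so the final excitation has phase `+alpha`) serves as an
independent oracle; the closed-form solution agrees with it to better than
1e-6 relative error across the physiological parameter range.

### Spoiled FID

The spoiled (Ernst) steady state is

```
S(t) = M0 * sin(alpha) * (1 - E1) / (1 - E1 cos(alpha)) * exp(-t/T2*)
```

with `t` the time since excitation. Perfect spoiling is assumed.

### Species and relaxation

Four deuterated species are modelled: water (4.8 ppm), glucose (Glc, 3.9
ppm), glutamate+glutamine (Glx, 2.4 ppm) and lactate (Lac, 1.3 ppm).
Chemical-shift frequencies are referenced to the acquisition carrier (3.2 ppm
for bSSFP-CRT, 4.8 ppm for FID-CRT) at the deuterium Larmor frequency of
45.7 MHz. T1/T2 values per tissue are tabulated in `data/species.csv`.
Apparent T2* combines species T2 with a macroscopic decay constant
T2' (default 150 ms): `1/T2* = 1/T2 + 1/T2'`.

### SNR efficiency

The per-unit-time SNR efficiency of each readout is
`S(TE) * sqrt(T_acq_fraction / TR)`. With aqueous-phantom relaxation values
(T1 = T2 = 350 ms, T2* = 30 ms) the bSSFP/FID efficiency ratio evaluates to
about 2.6, consistent with the greater-than-twofold advantage expected for
deuterium's favourable T2/T1 ratio.

## 2. Trajectory design (`dmicrt.trajectory`)

A 3D stack-of-rings CRT is used: `Nz` Cartesian partitions, each holding
concentric rings with `2*Nx` points per ring traversed synchronously. Ring
radii are the `Nx/2` Cartesian radial bins. The number of repetitions
(averages) per radius follows a Hamming window apportioned by the
largest-remainder method over the total ring budget (107 rings for bSSFP-CRT
at the 22x22x21 matrix, giving [19, 18, 16, 14, 12, 9, 7, 5, 3, 2, 2] from
centre to edge; 43 rings for FID-CRT). Density-compensation weights are
proportional to the annular area of each radial bin; reconstruction weights
are the product of density compensation, the number of averages and a
separable 3D Hamming apodization. For matrices smaller than the protocol
matrix, the ring budget is scaled proportionally.

Each TR acquires all rings of one (partition, radius, average) set at
`n_temporal` temporal points (5 echoes at TE = 2, 5.5, 9, 12.5, 16 ms for
bSSFP-CRT; 96 FID points at 380 Hz for FID-CRT). The per-ring readout
bandwidth is 285 Hz (bSSFP), so each sample within a ring has a distinct
acquisition time offset `tau` — this intra-ring timing is carried through
simulation and separation exactly.

## 3. Digital phantom (`dmicrt.phantom`)

An ellipsoidal brain (semi-axes 0.88/0.88/0.84 of the half-FOV, with a
seeded +-5% lumpy modulation) is partitioned into GM, WM and CSF fractions:
a CSF core, a WM annulus and a GM shell with smooth sigmoidal transitions,
plus seeded spatial texture. Water content is 0.78 (GM), 0.65 (WM), 0.97
(CSF). A smooth random B0 map bounded by +-0.2 ppm and a macroscopic T2'
map are generated from the same seed.

Metabolite dynamics after oral [6,6'-2H2]glucose intake are phenomenological
gamma-variate (Glc) and saturating-exponential (Glx) curves calibrated so
that at t = 70 min GM concentrations are Glc 2.91 mM, Glx 4.05 mM and water
16.13 mM (water rises slowly from natural abundance, 17.2 mM x water
content). Glx carries a 40% label-loss factor in quantification. A
capillary-glucose (CGM) trace is modelled as baseline 5.43 mM with a
gamma-variate excursion peaking at 9.21 mM near 48 min.

## 4. Simulation (`dmicrt.simulate`)

For each species, the complex amplitude per voxel is the steady-state signal
model evaluated with tissue-fraction-weighted relaxation, scaled by
concentration. The k-space signal at sample `n`, temporal point `s` is the
exact discrete Fourier sum over voxels with per-sample phase evolution
`exp(i*2*pi*(f_species + B0(r))*(t_n + tau_s))` and apparent-T2* damping at
the true per-voxel rate. Complex white noise with standard deviation
`noise_sd / sqrt(n_averages)` is added per sample. The linear forward
operator `model_forward` reproduces this simulation exactly for given
amplitude maps, which enables model-based iterative refinement during
separation.

## 5. Reconstruction (`dmicrt.recon`)

Reconstruction uses the exact (weighted) adjoint non-uniform DFT onto the
centred Cartesian grid (DC voxel at index N//2), with Hamming apodization
and density compensation in the weights. On Cartesian test trajectories the
transform matches `fftshift(fft(ifftshift(.)))` to machine precision and
satisfies the weighted adjoint identity `<Ax, Wy> = <x, A*y>`.

B0 correction uses an image-domain sandwich: reconstruct each temporal point,
multiply by `exp(-i*2*pi*B0(r)*t_s)`, and re-project with the forward DFT.
The deuterium field map is obtained either from the phantom ground truth or
by multi-echo phase fitting of the water-dominated echoes, scaled from the
proton field by the gyromagnetic ratio.

## 6. Metabolite separation (`dmicrt.separation`, `dmicrt.pipeline`)

Species separation is performed natively in k-space: every sample `(n, s)`
has the model phase `exp(i*2*pi*f_m*(t_n + tau_s))` and relaxation damping
`exp(-R2*_m*(t_n + tau_s))`, giving a per-sample mixing matrix whose damped
least-squares inverse yields species k-space channels that are then
reconstructed by the adjoint DFT. Basis damping rates come from literature
T2 values (GM/WM mean) plus T2' for bSSFP, or from a variable-projection
non-negative fit of the DC-sample FID for FID-CRT.

Two corrections follow:

1. **Per-voxel unmixing** (`voxel_unmix`): the global mixing matrix is
   re-evaluated per voxel with the local field offset and tissue-fraction
   weighted damping rates, and the small residual cross-talk left by the
   global inverse is removed voxel-wise.
2. **Model-based refinement**: with `A` the exact linear forward operator
   and `P` the approximate inverse above, amplitude maps are refined by a
   preconditioned Landweber iteration `a <- a + P(y - A a)/g`, where the
   scalar gain `g = Re<P A a0, a0> / <a0, a0>` normalizes the un-normalized
   adjoint. Two iterations (the default, `refine_iterations=2`) reduce
   GM concentration bias to below 1% at the full protocol matrix.

Amplitude uncertainty is propagated through the damped least-squares
covariance; a Cramer-Rao-style percentage bound (`crlb_pct`) supports
exclusion of unreliable voxels (default threshold 50%).

## 7. Quantification (`dmicrt.quantify`)

Metabolite amplitude maps are referenced to the baseline (t = 0) water map:

```
C_m = S_m / S_w(0) * F_w / F_m * N_w / N_m * C_ref / (1 - loss_m)
```

where `F` is the steady-state signal per unit magnetization evaluated at the
excitation (t = 0 amplitude referencing — the separation returns amplitudes
extrapolated to zero readout time, so only the steady-state factors differ
between species), `N` the number of labile deuterons (water 2, Glc 2 at
position 6,6', Glx 1), `loss` the label-loss fraction (0.4 for Glx) and
`C_ref = 17.2 mM x water content` the tissue water reference. Regional
statistics use inclusive tissue masks (fraction >= 0.6).

## 8. Dynamics and statistics (`dmicrt.dynamics`)

Time curves are summarized by trapezoidal AUC, coefficient of variation,
GM/WM contrast and repetition-based SNR. Group comparisons use paired
t-tests. The association between brain Glc and capillary glucose is
modelled with a linear mixed-effects model (random intercept and slope per
subject, REML), with boundary (singular) fits flagged. Bundled six-subject
study tables provide reference group means (e.g. AUC_CGM 508.94 mM min,
AUC_DMI 148.53 mM min, ratio 0.29; bSSFP GM means Glc 2.91, Glx 4.05,
water 16.13 mM).

## 9. Noise calibration

Image-domain SNR is defined on the first temporal point of the weighted
adjoint reconstruction: brain-mean magnitude divided by the analytic noise
standard deviation `sigma * sqrt(sum_s w_s^2 / n_avg_s)` propagated through
the adjoint weights. `noise_sd_for_snr` inverts this to choose the k-space
noise level for a target SNR.

## 10. Limitations

- The bSSFP model uses the on-resonance pass-band signal; the banding
  profile across off-resonance is captured in the steady-state solve used
  for separation basis functions but no intra-voxel frequency dispersion
  across the band is modelled.
- B0 correction removes inter-echo phase accrual at the temporal-point
  level; residual intra-readout (within-ring) B0 blurring is not
  deblurred.
- Metabolite kinetics are phenomenological curve shapes calibrated to
  reported concentrations, not a kinetic-compartment model.
- Relaxation is single-compartment per tissue class; no exchange or
  multi-exponential decay.
- Coil sensitivity is uniform; no parallel-imaging or motion effects.
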