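# Methods

This note documents the models, defaults and numerical choices behind the
package, and what the synthetic validation does and does not establish.

## Saturation-transfer forward model

Z-spectra are simulated with the Bloch–McConnell equations for water
coupled to one (optionally more) exchanging solute pool.  Each pool
contributes three magnetization components; exchange couples every solute
pool to water with solute→water rate k and water→solute rate f·k
(detailed balance, f = pool proton fraction).  Continuous-wave saturation
of amplitude ω₁ = 2π·γ·B1 is applied for the pulse duration at each
offset; the readout is treated as an instantaneous sample of water Mz,
normalized by the unsaturated signal.  Echo-train signal evolution during
the readout is not modeled.

The affine system dM/dt = A·M + b is embedded homogeneously
(d[M;1]/dt = [[A,b],[0,0]]·[M;1]) and propagated by eigendecomposition of
the augmented matrix, batched over offsets — an exact matrix-exponential
time evolution from thermal equilibrium, not a steady-state shortcut.
A dense `expm` fallback guards ill-conditioned eigenbases.  Agreement
with an independent ODE integration is ~1e-11 at 1 s, and with the
closed-form steady state <1e-9 once saturation is long enough for the
slowest eigenmode (~1.6 s⁻¹ at ±3 ppm for water T1 = 1.8 s) to decay;
at the protocol's 1 s pulse the spectrum is deliberately pre-steady-state,
as in the acquisition it emulates.

Default pools (all configurable):

| parameter | water | glutamate amine |
| --- | --- | --- |
| chemical shift | 0 ppm | +3.0 ppm |
| exchange rate | — | 5500 s⁻¹ |
| T1 / T2 | 1.8 s / 40 ms | 1.0 s / 10 ms |

Tissue classes override the water T1/T2 (hippocampus 1.9 s / 50 ms).
The amine exchange rate is the literature-typical physiological value;
note that at 7 T it is comparable to the 3 ppm shift (2π·900 Hz), so the
apparent MTRasym peak of the forward model coalesces toward ~2 ppm even
though the pool sits at 3.0 ppm — the slow-exchange limit (k ≲ 1000 s⁻¹)
peaks at the pool position, and the tests check pool placement there.

## Contrast calibration and the observed water frame

The proton fraction needed to produce a target GluCEST percentage is
obtained by a bracketed root-find on the forward model (the map
fraction→contrast is strictly increasing at fixed power).  One subtlety:
fast exchange shifts the *apparent* water resonance by a small,
pool-dependent amount (~1e-3 ppm at a 5 % contrast), and the
B0-corrected pipeline centers each voxel on the WASSR-observed dip, not
on the nominal water frame.  Calibration therefore evaluates the forward
contrast at ±3 ppm relative to the observed dip center (re-estimated
between root-find rounds until self-consistent).  Without this the
corrected pipeline shows a systematic ≈0.06 pp offset; with it,
noiseless hippocampal ROI means recover their targets to <0.01 pp.

## Digital phantom and cohort generation

The phantom is a single 2-D slice (matching the single-slice protocol):
a circular brain containing two elliptical hippocampal ROIs (~107 voxels
each at 64×64).  Tissue parameters are regional constants
(brain 1800/45 ms, ADC 0.75e-3 mm²/s, CBF 120; hippocampus 1900/50 ms,
0.80e-3, 150 mL/100 g/min — literature-typical rodent values at 7 T),
optionally jittered per animal (2 % relative SD).  B0 and B1 maps are
random low-order polynomial surfaces scaled to ±0.15 ppm and ±5 %.

Cohorts draw each animal's hippocampal contrast target from
N(group mean, between-animal SD) and calibrate a fraction per animal and
tissue class.  Noise is additive Gaussian on magnitude images at a stated
fraction of mean S0 (default 1 %; high-SNR approximation, no Rician
floor).  Seeding: one master seed, per-animal child seeds via
`numpy.random.SeedSequence.spawn`, so identical seeds give bit-identical
cohorts.

For speed, voxelwise spectra are generated by evaluating a dense
Bloch–McConnell base spectrum per (tissue class, B1 bin) — B1 quantized
at 0.005, offset grid 0.05 ppm (0.01 ppm for WASSR) — and sampling it at
each voxel's offsets shifted by its B0 (monotone cubic interpolation).
This is numerically equivalent to per-voxel evolution because a static
field offset enters the model only as a shift of the offset axis;
measured deviation from exact per-voxel simulation is <1e-3 in Z and
<0.03 pp in contrast.  Base spectra are cached across animals.  The
large replicate study (power analysis) uses a 32×32 phantom with a
0.1 ppm / 0.01-B1 grid — ROI-mean statistics are insensitive to these
resolutions.

What the phantom does *not* emulate: partial-volume mixing at ROI
boundaries, motion, coil-profile shading beyond a smooth proton-density
map, macromolecular MT background (a third pool is supported but off by
default), k-space/readout artifacts, and atlas-space anatomy.  Passing
recovery tests therefore demonstrates correctness of the analysis chain
under the stated physics, not robustness to those real-world effects.

## B0 mapping (WASSR)

Default estimator: the direct-saturation dip is near-Lorentzian, so
1/(1 − Z) is near-quadratic in offset over the dip core; the center is
the vertex of a weighted quadratic fit to the 7 samples nearest the
current estimate, iterated 4 times (weights (1−Z)², the delta-method
variance of 1/(1−Z)).  Noiseless accuracy ~1e-4 ppm; at SNR 50 the 95th
percentile error is ~0.011 ppm (the error statistic quoted for noisy
data is the 95th percentile, since single-voxel outliers are unbounded
under noise).  A model-free maximum-symmetry-center search (coarse grid,
frozen-support fine grid, parabolic refinement) is available via
`method="symmetry"`; it floors at ~5e-3 ppm noiseless because
finite-pulse sidelobes alias into the 0.05 ppm sampling, which is why it
is not the default.  Voxels whose dip lies within two steps of the sweep
boundary are flagged invalid rather than extrapolated.

## B1 mapping and correction

Relative B1 comes from the double-angle identity
S(60°)/(2·S(30°)) = cos(30°·b1) with the ratio clamped to [−1, 1];
zero-signal voxels are invalid.  Contrast correction uses a
forward-model lookup: the two-pool asymmetry is precomputed on a B1 grid
(0.7–1.3, 13 nodes) at a reference fraction, and each voxel's observed
±3 ppm asymmetry is scaled by asym(1)/asym(b1) (linear interpolation in
b1).  The correction is applied to the +3 ppm sample, keeping −3 ppm as
the reference, after B0 re-sampling.  Residual error from using a single
reference fraction across tissues is <0.01 pp over the working range.
A simple 1/b1 linear scaling is available as a fallback and recorded in
output metadata.  B0 re-sampling uses shape-preserving (monotone cubic)
interpolation to avoid overshoot near the water dip; voxels are grouped
by B0 quantized at 0.002 ppm so the interpolation vectorizes (bin width
configurable, 0 = exact per voxel).  Offsets falling outside a voxel's
shifted support are NaN at that offset only.

## Asymmetry mapping

GluCEST (%) = 100·(M₋₃ − M₊₃)/M₋₃ per voxel; voxels with
M₋₃ ≤ 0.01·S0 are flagged invalid (guards CSF/background divisions), and
invalidity from any field map propagates — no silent fill.  The
ROI-averaged MTRasym curve averages per-voxel ratios, so its value at
3 ppm equals the ROI mean of the map by construction.

## Relaxometry

Models: I = I0(1 − C·e^(−TR/T1)) (C absorbs incomplete inversion,
bounds [0.5, 2.5]; T1 bounds [50, 10000] ms), I = I0·e^(−TE/T2),
I = I0·e^(−b·ADC).  Monoexponential fits initialize from a weighted
log-linear solve (weights y², the delta-method variance of log y) and
refine with a vectorized damped Gauss–Newton over all voxels; the
recovery model uses the same scheme with two starts (default and
half-T1), keeping the better fit.  Flat signals (T1/T2 unidentifiable)
and fits pinned at the T1 bounds are flagged unconverged; non-positive
decay samples are excluded pointwise.  Noiseless recovery at the
protocol's TR/TE/b/TI lists is exact to machine precision.

FAIR CBF uses the standard T1-difference formula
CBF = λ·(1/T1_sel − 1/T1_ns)·6000 mL/100 g/min (T1 in s; λ = 0.9 mL/g,
configurable), with apparent T1s fitted from the slice-selective and
non-selective inversion-recovery series (signed signals, C ≈ 2).  The
vendor-side reconstruction the protocol used is not public, so this
model substitution is flagged in the fit metadata.

## MRS quantification

A deliberately transparent stand-in for commercial linear-combination
packages: basis spectra are sums of pseudo-Voigt lines (HWHM 0.02 ppm,
η = 0.5) at literature positions for Glu, Gln, NAA, Cr, Cho, mIns and
Tau, with amplitudes proportional to proton counts; the fit is bounded
linear least squares (metabolite coefficients ≥ 0, free polynomial
baseline of order 2) over 4.3–0.3 ppm.  Water scaling converts
coefficients to μmol/g via the unsuppressed water reference; the tissue
water constant (43.3 mol/L-equivalent) cancels between synthesis and
fitting, so no absolute-unit claim is made beyond self-consistency.
Uncertainties are Cramér–Rao-style relative SDs from the linear-model
covariance at the residual noise level.  Noise for validation studies is
chosen so the Glu coefficient's CRLB-style relative SD is 5 %.  No
macromolecule model, lineshape estimation or eddy-current compensation.

## ROI statistics

Left/right ROI means are computed over valid voxels only (empty ROIs are
errors); the bilateral average is (left+right)/2 exactly.  MRS
concentrations are measured in the right hippocampus only, following the
acquisition geometry, and enter the comparison as-is.  Normality is
screened with the Lilliefors-corrected Kolmogorov–Smirnov test (the
population mean/SD are estimated from the sample; plain KS would be
anticonservative); groups are compared with a two-sided independent
t-test, equal-variance by default with a Welch switch, both recorded in
the output.

## Known limitations and error budget

* Noise rectification: at 1 % image noise the corrected cohort means
  carry a small group-dependent bias of ~±0.04 pp (nonlinearity of the
  asymmetry ratio and of the B0-error response); negligible against the
  between-animal SDs (0.44/0.81 pp) but visible in high-precision
  noiseless-vs-noisy comparisons.
* Statistical power: with group means 5.02/3.67, SDs 0.44/0.81 and
  n = 12/group, the exact noncentral-t power of the equal-variance test
  at α = 0.001 is 0.875; replicate studies should not expect p < 0.001
  in ≥95 % of draws under these conditions, and the package's replicate
  report quotes the 95th percentile of p for exactly this reason.
* The B1 correction assumes the two-pool forward model; for real data
  with unknown exchange parameters the linear fallback bounds the
  correction error instead.
* Problem sizes in the validation studies (64×64 single-cohort runs,
  32×32 replicate power runs, 50-spectrum MRS batches) were chosen as
  the smallest sizes at which ROI statistics are stable; all are
  configurable.
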