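# Methods

## Signal models

A voxel of hydrating polymer matrix is modelled as two exchanging proton
pools with distinct transverse relaxation: a *short* component (water bound
to or exchanging with the polymer, T₂S of a few ms) and a *long* component
(freer water in clusters, T₂L of tens to hundreds of ms). The two
acquisitions sample complementary windows of the decay envelope
S(t) = A_S·e^(−t/T₂S) + A_L·e^(−t/T₂L):

* the CPMG train (MSME; TE 6.5 ms, 32 echoes, to 208 ms) starts after the
  short pool has largely decayed and is fitted with the two-parameter
  monoexponential S₀·e^(−t/T₂L);
* the short-TE series (BLIP; 3, 4, … 12 ms) resolves the fast decay, over a
  window across which the long pool is nearly constant, and is fitted with
  A_S·e^(−t/T₂S) + A_L. The baseline A_L therefore *is* the long-component
  amplitude, and both amplitudes are taken exclusively from this fit. The
  approximation error from treating e^(−t/T₂L) as 1 over 3–12 ms is a few
  percent of A_L for T₂L ≳ 100 ms and is accepted.

Longitudinal relaxation is treated as a single pool (one T₁ per voxel, as
expected when T₁ ≫ T₂ in a binary polymer–water system) and mapped from an
inversion-recovery FISP series via the ideal magnitude model
|A·(1 − 2·e^(−TI/T₁))|, TI = 400 + 160·k ms. No finite-TR or readout
corrections are applied.

Component naming is by model — the BLIP exponential is "short", the MSME
decay / BLIP baseline is "long" — never by sorting fitted values.

## Fitting

All fits are per-pixel nonlinear least squares with the Levenberg–Marquardt
algorithm (`scipy.optimize.least_squares`, analytic Jacobians).
Initialisation: log-linear regression of the positive samples for the
monoexponential; (last sample, first − last, span/3) for the
short-decay-plus-baseline model; the null-point heuristic T₁ ≈ TI_min/ln 2
for inversion recovery.

LM is unconstrained, so plausibility bounds are enforced afterwards:
estimates outside T₂S ∈ [1, 50] ms, T₂L ∈ [5, 2000] ms,
T₁ ∈ [10, 10000] ms, or amplitudes outside [0, 3 × max observed intensity]
set `converged = False` and the pixel is excluded from the validity mask.
The T₂S lower bound reflects the sampling resolution — with a first echo at
3 ms, decays faster than ~1 ms are not resolvable, and at the study's noise
level fits demanding them are noise artifacts with arbitrarily large
amplitudes. The 3× amplitude cap discards the heavy tail of such artifacts;
both cuts matter because radial profiles average *fitted parameters*, and a
bin mean is only as good as its worst accepted fit. Failed pixels are
flagged and excluded, never interpolated.

No Rician bias correction is applied by default; an optional correction
subtracting (π/2)·σ² in quadrature is available
(`relaxometry.rician_bias_correct`).

## Masking, recentering, profiling

The analysis mask thresholds the first BLIP echo at background median +
k·MAD-spread (k = 3; background from image-border pixels), keeps the largest
connected component (ignoring components under 9 px) and fills holes, so the
low-signal core stays inside the mask. The tablet is shifted to the grid
center by an integer translation of the mask centroid — no interpolation, so
decay curves are unaltered.

Radial profiles average each fitted parameter over annular bins (default bin
width = one pixel) restricted to a 60° pie sector; pixels enter bins by the
radius of their center, without area weighting. The sector orientation is
either explicit or chosen automatically as the wedge whose mask boundary has
minimal radial variance — a reproducible surrogate for manually picking an
undistorted piece of tablet. The profile additionally carries the
Gaussian-blurred (σ = 2 px) first-echo intensity as an auxiliary channel;
blurring suppresses per-pixel noise by ~7× and makes this the most reliable
detectability signal for the weak core.

## Layer classification and fronts

Walking outward, bins are labelled by amplitude behaviour:

| region | rule |
|---|---|
| unhydrated | not detectable (blurred first-echo intensity ≤ 1.3 × noise floor) |
| minimally hydrated | detectable; A_L below presence threshold; flat; A_T < 50 % of gel level |
| interface 1 | A_L absent; A_S (or A_T) rising steeper than 1.0 /mm (relative to gel level) |
| interface 2 | A_L present (> 15 % of gel level); relative slopes above 0.35 /mm |
| gel | both components; slopes within tolerance |

The noise floor defaults to 0.6 a.u. and is re-anchored per study at the
measured background level of the blurred first-echo image (the histogram's
noise mode), so the same rules work at any simulated noise level. Profiles
are smoothed with a 5-bin moving average before slope estimation (raw
profiles are kept for front positions); NaN gaps are filled from the nearest
informative bins so gradients see no spurious steps. The per-bin label
sequence is regularised by a 3-bin median filter, merging of runs shorter
than 2 bins into their outer neighbour, and a cumulative maximum over the
region order, which guarantees contiguous, outward-ordered runs. Unhydrated
and minimally hydrated cores are mutually exclusive at one time point; when
an unhydrated core exists, stray minimally-hydrated bins are promoted to
interface 1.

Fronts: **penetration** = inner edge of the interface-1 run (where the steep
total-amplitude gradient begins); **full hydration** = radius of the maximum
binned A_S, searched over the interface bins (the peak is their boundary by
definition), plateau ties resolved to the innermost bin; **total
gelification** = interface-2/gel boundary; **apparent erosion** = outer edge
of the outermost bin with pixels and detectable signal. Ordering
(penetration ≤ full hydration ≤ total gelification ≤ apparent erosion) is
enforced by a running maximum; missing layers yield absent fronts. Front
evolution is tabulated as displacement from the 4.5 mm dry radius.

## Histogram modes

For the low-intensity analysis the first-echo image is blurred (σ = 2 px)
and histogrammed over [0, 25 % of the fully-hydrated level] in 64 bins; the
fully-hydrated reference is the median blurred intensity over the outer gel
annulus of the mask (1–5 px from the mask edge). Modes are prominence-
filtered local maxima (≥ 5 % of the peak count after 3-bin smoothing): the
lowest-intensity mode is the noise mode, the next distinct one the
tablet-center mode; a unimodal histogram reports the center mode absent.

## The phantom generator

The generator emulates a single coronal slice of a 9 mm tablet as a disc of
four concentric material zones over a 15 mm field of view (default matrix
256, i.e. 59 µm pixels; analyses in the tests and the reproduction script
use a 128 matrix / 117 µm as the package's default study size). Layer
endpoint parameters (a.u. / ms):

| zone | A_S | T₂S | A_L | T₂L | T₁ |
|---|---|---|---|---|---|
| core, HPMC 400 (≥ 1 h) | 1.8 | 3.6 | 0 | – | 900 |
| core, HPMC 10000 (≥ 1 h) | 1.3 | 3.8 | 0 | – | 900 |
| interface-1 outer edge | 6.0 | 8 | 0 | – | 500 |
| gel (= interface-2 outer edge) | 1.5 | 20 | 4.5 | 150 | 800 |

At 0.5 h the core is undetectable and simulated as zero signal (noise only),
not as an ultra-short decay. Interface layers interpolate linearly in radius
between the adjacent zones, which yields the characteristic profiles: A_S
rising steeply across interface 1 while A_T ramps up, then the amplitude
crossing across interface 2 with A_T constant at 6.0, and a T₁ profile with
an interior minimum. The core T₂ of 3.6/3.8 ms is the *effective* fitted
value of the solid-like zone; it reproduces the observed echo-time
asymmetries (visible at a 3 ms echo, gone at 6.5 ms; a tablet-center
histogram mode in the short-TE image only).

Boundary radii move as smooth √t interpolations of the observed front
behaviour — the true water-uptake kinetics between sampled time points are
not known, so these are qualitative trajectories, not fits:

* penetration front: 4.5 − 1.0·√t mm (both grades; the inner fronts evolve
  alike),
* interface-1 width 0.4 mm; interface-2 width 0.55 mm (HPMC 400) / 0.35 mm
  (HPMC 10000),
* apparent erosion: 4.5 + 0.8·√t (HPMC 400) / 4.5 + 1.0·√t (HPMC 10000).

Hence the firm gel layer is thicker for the high-viscosity grade at every
time, grows with time, and its inner boundary moves opposite to the outer
one — the qualitative behaviour the front tracker must recover. Times much
beyond 3 h exhaust the core and are rejected.

Noise is Rician: the magnitude of (signal + complex Gaussian), with the
default channel σ = 0.6/√(π/2) ≈ 0.479 a.u., chosen so the background
magnitude mean is 0.6 a.u. against a fully hydrated signal of ≈ 6 a.u.
A clipped-Gaussian option exists for unit tests. Identical (spec, schedule,
seed) produce bit-identical stacks. The default tablet center sits ~2–3 px
off the grid center (sub-pixel) so recentering is always exercised.

What the phantom does **not** emulate: diffusion, flow, B₀/B₁
inhomogeneity, slice profile, k-space artifacts, stimulated echoes in the
CPMG train, tablet deformation (layers are perfectly concentric, so the
automatic sector choice is arbitrary rather than necessary), inter-sequence
amplitude calibration differences, or 3D geometry. Tests passing on
phantoms therefore validate the estimation and classification machinery
under controlled conditions, not robustness to real-scanner artifacts or
distorted tablets.

## Numerical and design choices

* MSME's fitted amplitude S₀ is kept as a diagnostic (`s0_msme`) only;
  amplitudes in all downstream analysis come from the BLIP fits.
* MSME/FISP fits are run only where the BLIP fit converged — other pixels
  are outside the validity mask regardless, and the skipped fits are the
  slowest (noise-dominated) ones.
* A_T = A_S + A_L is computed pointwise from the fitted maps, so the
  identity holds exactly on the validity mask by construction.
* Degenerate inputs: an all-zero or constant decay, a signal-free profile,
  an empty mask, or a histogram with no counts are flagged (converged=False,
  degenerate segmentation, warning, absent modes) rather than guessed at.
* The pipeline records per-time-point failures and continues; outputs are
  written with fixed float formatting and checksummed in a manifest, so
  identical configuration and inputs reproduce runs byte-identically.

## Known limitations

* The A_S/A_L decomposition is poorly conditioned per pixel when T₂S
  approaches the 3–12 ms window length (gel-like voxels) at the default
  noise; bin means of accepted fits are upward-biased for A_S there. The
  classifier is calibrated on phantoms to be robust to this, but the
  per-pixel split should not be over-interpreted at low SNR — consistent
  with treating the parametric core values as effective quantities.
* Region rules are threshold-based; the defaults are calibrated for the
  preset phantoms' geometry and noise and exposed as configuration
  (`SegmentationThresholds`) for other regimes.
* T₂L from the monoexponential MSME fit is biased low where the short
  component still contributes at 6.5 ms; it is reported as fitted, matching
  the model definition.
* Raw vendor data formats (Bruker ParaVision) are out of scope; stacks
  enter as TIFF/NIfTI with JSON schedule sidecars.
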