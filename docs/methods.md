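# Methods

## Imaging model

`qobm` models an epi-mode quantitative phase imager of the oblique
back-illumination (qOBM) family. Light multiply scattered inside thick
tissue re-illuminates the focal plane from below; four fiber-coupled LEDs
placed obliquely (two opposing pairs along x and y) make that effective
illumination asymmetric, which converts phase gradients into intensity
contrast. The package does not model the tissue light transport itself:
the effective source of each arm is a parametric offset Gaussian in pupil
coordinates,

    S(u) = exp(-|u - c|^2 / (2 sigma^2)),
    c = offset_frac * f_c along the arm axis,   sigma = width_frac * f_c,

with `f_c = NA/lambda` the pupil cutoff. Defaults `offset_frac = 0.8`,
`width_frac = 0.35` give strong, well-conditioned phase contrast across
the 0.1–0.7 `f_c` band; they are not calibrated to any particular tissue,
and both are exposed per arm in the configuration. Negative arms are
lattice reflections of their positive partners, so opposing pairs are
mirror images sample for sample, exactly.

The pupil is an ideal unaberrated circle (`|u| <= f_c`). Under the
weak-object approximation `t = exp(-mu + i*phi) ~ 1 - mu + i*phi`, the
partially coherent image spectrum of one arm is

    I_hat(u) = B delta(u) + H_abs(u) mu_hat(u) + H_ph(u) phi_hat(u),

with `B = sum S|P|^2`, `Gamma(u) = sum_u' S(u') P*(u') P(u'+u)`,
`H_abs = -(Gamma(u) + Gamma*(-u))` and `H_ph = i(Gamma(u) - Gamma*(-u))`,
all as discrete sums over the frequency lattice (the pupil is zero outside
the lattice; grid resolution is the only source of discretization error).
For the real pupil and real source weights used here, `Gamma` is real,
which makes `H_ph(0)` exactly zero — constant phase offsets are
unobservable — and enforces the Hermitian symmetry that keeps
reconstructed phase maps real. `Gamma` is evaluated with zero-padded FFT
correlations; unit tests pin it to a literal double-loop evaluation at
1e-10 relative.

Conventions: frequencies in cycles/um on the `numpy.fft` lattice, phase
in radians, `phi > 0` for refractive index above background.

## Forward simulation

`simulate_intensities` applies the linear model per arm and optionally
Poisson shot noise at `photon_scale` photons per pixel at the background
level (default 10,000; camera exposure is otherwise unmodeled, and no
read noise is added — second-order at these levels). Depth stacks are
simulated slice by slice with no defocus cross-talk; the default slice
spacing is 1.5 um, typical of a qOBM depth scan.

An Abbe-sum reference simulator (incoherent sum of coherent images over
discrete source points, exact transmittance) bounds the linearization
error: on default weak phantoms the two agree to ~0.2–0.3% relative RMS
(the acceptance check requires < 1%). `truncate_source` restricts both
paths to the same strongest source samples (200 per arm) so the
comparison isolates linearization, not source sampling. The Abbe shift is
circular on the lattice while the WOTF sums are linear; the two
conventions coincide whenever `f_c < 1/(4 * pixel_um)`, which holds at
the 0.25 um/pixel settings used for that comparison.

## Reconstruction

The measurement chain is the standard DPC one: per axis,
`D = (I_a - I_b)/(I_a + I_b)` (pixels with vanishing sum are zeroed and
counted), then a single joint Tikhonov solve over both axes,

    phi_hat = (Hx* Dx_hat + Hy* Dy_hat) / (|Hx|^2 + |Hy|^2 + alpha),

with `H = (H_ph,a - H_ph,b)/(B_a + B_b)` per axis. Joint inversion rather
than per-axis deconvolution + averaging gives isotropic frequency
coverage. `alpha` defaults to 1e-3 for noisy data and 1e-4 for noiseless
work; no apodization, low-frequency inpainting or DC restoration is
applied — the mean phase is genuinely unobservable and is reported as 0.
For mirror-pair arms the noiseless weak-object sum `I_a + I_b` is exactly
`B_a + B_b`, so the only round-trip error is the Tikhonov shrinkage
`alpha/(|H|^2 + alpha)`; at `alpha = 1e-4` the band (0.1–0.7 `f_c`) RMSE
is ~0.01% of peak on 256x256 phantoms (acceptance bound: < 2%).

## Synthetic tissue phantom

`generate_phantom` emulates one en-face section of fresh tissue:
non-overlapping nucleus disks (radius uniform in 3–6 um by default) with
a smooth dome profile peaking at `nucleus_phase`, a zero-mean Gaussian
background texture smoothed to 1 um and rescaled to
`background_texture_sd`, and a few small bright inclusions (0.6 rad)
standing in for lipid droplets. Defaults put the field in the regime the
technique is motivated by: *fresh* nuclei barely exceed the cytoplasmic
texture (peak 0.15 rad vs texture SD 0.10 rad), so whole-image phase
variance is texture-dominated and nuclear CNR is ~1. Placement is
rejection-sampled with a bounded attempt budget; infeasible packings
raise with the achieved count. A phantom with max |phase| > 1 rad or
absorption > 0.2 is flagged `nonlinear` in its metadata.

The acetowhitening transform is deliberately minimal: nucleus phase is
multiplied by `nuclear_gain` (default 1.8), background phase is mixed
toward its global mean with weight `homogenization` (default 0.7; a
local-mean variant is selectable), inclusions are left unchanged by
default, and geometry/labels/absorption are untouched so fresh/stained
pairs stay pixel-aligned — real tissue deforms under staining, which is
precisely why the simulator keeps geometry fixed. With these defaults the
transform reproduces the qualitative staining signature: whole-image
phase SD drops (~0.099 -> ~0.059 rad on reconstructed 128x128 fields)
while nuclear CNR rises (~0.95 -> ~5.2), and CNR is monotone in the gain.
The magnitudes are free parameters, not calibrated to tissue — no
absolute refractive-index shift is available to calibrate against.
Nuclear shrinkage, red-blood-cell lysis and tissue densification are not
modeled.

What passing tests therefore show: the reconstruction chain is exact
under its own model, the linearization is valid at tissue-like phase
levels, and the *direction* of the acetowhitening statistics matches
observation. They do not validate absolute phase values in real tissue,
penetration-depth effects, or any learned virtual-staining step.

## Statistics

`phase_std` is the per-image sample SD (n-1), computed over the whole
field for group comparisons (no masking). `nuclear_cnr` is
(mean nucleus - mean background)/background SD on label masks.
`welch_ttest` implements the unequal-variance statistic with
Welch–Satterthwaite degrees of freedom and a two-sided p from the
Student-t CDF; a pooled-variance flag exists. Pairwise group p-values are
raw by default (Bonferroni optional). Calibration is verified by
simulation: type-I rate at nominal 0.05 stays inside the 95% binomial
band over hundreds of seeded null replicates, and power at the default
simulated staining effect saturates at 1.0 with 50 images per group.

## Problem sizes and reproducibility

Config defaults target 512x512 fields at 0.25 um/pixel with 12 nuclei.
Replicate-heavy computations use scaled-down fields chosen as a
deliberate accuracy/throughput trade: the group experiment runs 50 fields
per group at 128x128 (0.5 um/pixel, 8 nuclei of 2.5–4.5 um), and power
replicates use 64x64 fields (3 nuclei); the effects measured are far from
threshold at these sizes. All randomness derives from one root seed via
SHA-256 stage names (`stage_seed`), so a run is reproduced bit-for-bit by
its seed; the pipeline writes a manifest with SHA-256 checksums of every
output.

## Known limitations

- The effective-source model is phenomenological; obliquity and width in
  real tissue depend on depth and scattering properties.
- 2D only: no 3D transfer function, no defocus coupling between z-slices,
  no penetration-depth physics.
- The weak-object model degrades beyond ~1 rad phase excursions; the
  phantom flags but does not prevent that regime.
- Absolute phase levels of the phantom are plausible but uncalibrated.
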