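# Methods

## Scope

`guancest` reimplements the quantitative core of a creatine-weighted CEST
(GuanCEST) group study in Parkinson's disease as a reusable pipeline:
Z-spectrum quantification of the guanidino (~2 ppm) and amide (~3.5 ppm)
peaks by polynomial-plus-Lorentzian (PLOF) decomposition, dual-flip-angle T1
mapping, atlas-ROI aggregation with a hemisphere rule and outlier filtering,
and the group/severity statistics (Student's t, Kendall tau-b, ANCOVA).
Because the underlying clinical scans are not redistributable, validation is
by parameter recovery on a calibrated synthetic cohort: the generator is a
first-class, tested module whose defaults encode the study conditions, and
every analysis claim the package makes is something the pipeline recomputes
from generated data at run time.

Out of scope by design: scanner reconstruction, inter-image registration
(inputs are assumed co-located in one space; the phantom is generated in
that space), B1 inhomogeneity, Bloch–McConnell integration, and
MTRasym/APTw-style analyses.

## Forward model

A voxel's Z-spectrum is a pure Lorentzian pool sum,

    Z(dw) = 1 − Σ_p A_p (G_p/2)² / ((G_p/2)² + (dw − d_p)²) + eps,

with pools for direct water saturation (0 ppm), semisolid MT (−2.3 ppm,
FWHM 30 ppm), aliphatic NOE (−1.6 ppm, FWHM 3 ppm), guanidino (+2.0 ppm,
FWHM 0.5 ppm) and amide (+3.5 ppm, FWHM 0.6 ppm), and eps ~ N(0, 0.002) on
the normalized signal.  The schedule is the study's 53-offset list (200 ppm
unsaturated reference, then 8 to −2.2 ppm in 0.2 ppm steps) with B1 = 0.8 uT
and tsat = 0.95 s carried as provenance.  Chemical shifts are standard
literature values; they are not stated in the clinical protocol and are
config-exposed.

Two geometry choices are deliberately stylized rather than Bloch–McConnell
derived.  First, the direct-water line is narrow (FWHM 0.2 ppm).  A wide
water line makes the downfield background strongly non-polynomial across the
fit window; since the package's fitting stage (and the study's) models that
background as a low-order polynomial, a forward model with a broad water
tail is not invertible by *any* polynomial-background method — peak
amplitudes absorb the model error.  With the narrow line the combined
water+MT+NOE background over the fit window is cubic to within a few 1e-4,
so recovery tests measure the pipeline, not an arbitrary model mismatch.
Second, peak widths are fixed and known to the fitter through tight bounds
(below).  Both choices mean the phantom validates the estimation machinery
under its own assumptions; they do not demonstrate robustness to in-vivo
lineshape deviations, B1 variation, or fat/motion artifacts.

## PLOF quantification

Given a normalized spectrum (reference-divided, reference point removed,
sorted downfield-first) the B0 shift is estimated by fitting one Lorentzian
to the direct-saturation dip over |dw| <= 1 ppm and centering the axis on
its fitted center (the protocol has no separate field map); a flat spectrum
yields a warning and zero shift.

The decomposition then proceeds in three steps over the fit window
(default 1.4–5.0 ppm):

1. **Background**: least-squares polynomial of order 3 in dw, fitted to the
   window points outside the two peak-exclusion bands (1.6–2.4 and
   3.1–3.9 ppm), on a centered/scaled abscissa for conditioning.
2. **Peaks**: the residual r = background − z is fitted with two bounded
   Lorentzians (centers 2.0 ± 0.3 and 3.5 ± 0.3 ppm; widths 0.4–0.6 and
   0.5–0.7 ppm; amplitudes 0–0.1), trust-region least squares with analytic
   Jacobians.
3. **Joint refinement (variable projection)**: for fixed peak parameters the
   optimal background is the linear projection of z + peaks onto the
   polynomial space, so the peaks are re-optimized against the projection
   residual.  This is the converged form of "refit the background after
   subtracting the fitted peaks": plain alternation between steps 1 and 2
   stalls at a biased fixed point when peak wings leak into the background
   anchor points, whereas the projected problem reaches the joint optimum
   (exactly recovering noise-free single-peak spectra).

Amplitudes are reported in % of the normalized signal — the raw PLOF
amplitude, with no T1/B1 scaling, matching how the reported values are
expressed.  Non-convergent voxels are flagged, excluded from ROI means, and
counted in the run report.

Numerical behavior with generator defaults: noise-free recovery bias is
−0.04 % (guanidino) and +0.01 % (amide) at 1.8 %-scale amplitudes (≤ 2.3 %
relative); with zero-amplitude peaks the fitted amplitudes stay below
0.05 %; at the study noise level the per-voxel estimate has SD ≈ 0.28 % and
replicate-mean bias below 5 % relative.  The window, bands, order and bounds
are all config-exposed; the tight width bounds are an identifiability
requirement — a flexible-width Lorentzian and a polynomial are nearly
collinear over a ~4 ppm window at voxel SNR.

## T1 mapping

Two-point DESPOT1: with y_i = S_i/sin(a_i), x_i = S_i/tan(a_i) the SPGR
signal equation is linear with slope E1 = exp(−TR/T1); two flip angles
(5°/30°, TR 25 ms) determine the line exactly and T1 = −TR/ln(slope).
Voxels with slope outside (0, 1) are flagged invalid (air/noise), never
raised.  Flip angles are nominal — the protocol has no B1 map.  T1 maps are
computed and stored but do not enter the CEST metric, mirroring how the
protocol acquires them without stating a downstream use.

## Cohort and effect calibration

Clinical covariates are truncated normals at the reported group means/SDs
(age, disease duration ≥ 0.5 y, MDS-UPDRS parts I–IV ≥ 0 rounded to
integers, LEDD ≥ 0, MoCA clipped to [0, 30], BDI-II ≥ 0), sex Bernoulli at
the reported 12F/13M and 10F/14M proportions, affected side Bernoulli(0.5)
(not reported).  Note that truncation shifts moments: the sampler's own
distribution (scipy truncated normal) is the oracle the calibration tests
check against, and for strongly truncated scales (BDI-II) the post-truncation
mean is well above the nominal one.  Hoehn–Yahr is a deterministic cut of
the motor-score z-score at (−0.8, 0.97, 1.7) → stages 1–4, reproducing the
reported median 2 and range (1; 4).

Regional truth (in %, guanidino/amide): the caudate carries the reported
healthy-control baseline 1.82 and a patient shift of −0.15, so the patient
population mean at the cohort-average motor score is the reported 1.67.
Other subcortical baselines sit in a plausible 1.58–1.95 band with a small
non-significant patient shift (−0.03); cortical baselines are uniformly
lower than every subcortical value (the reported floor effect).  The amide
channel is null everywhere except the caudate, whose baseline 1.72 and
shift −0.12 reproduce the reported (non-significant) amide difference.
Severity coupling: TH-IML and TH-LN carry −0.01 %/point in linear mode; in
copula mode the latent correlation is rho = sin(tau·pi/2) with tau = −0.44
(TH-IML) and −0.39 (TH-LN), so the population Kendall tau equals the target
by the Gaussian-copula identity.  Between-subject SD is 0.20 (guanidino)
and 0.32 (amide), matching the scale of the reported group SDs
(0.16/0.26 and 0.35/0.29); with these, the caudate guanidino difference is
significant at the study size with ~70 % probability and the amide
difference with only ~20–25 % — i.e. the calibrated generator reproduces
the reported significance pattern as the *typical* outcome of a cohort
draw, not a certainty, which is exactly what a p = 0.023 vs p = 0.18 pair
of findings means.

## Phantom

Regions are rectangular blobs (default 5×6×7 voxels) on a lattice, mirrored
across the midline with distinct left/right label codes (right = left + 100),
plus a hemisphere-less CSF blob; anatomy is explicitly schematic — only
topology (distinct, mirrored, non-touching regions) matters to the pipeline.
Both hemispheres carry identical truth (laterality effects out of scope).
Gray-matter voxels get the subject's regional spectra scaled by M0 = 1000,
structural intensity 100 and a per-region T1 drawn from 1200–1600 ms; CSF
gets a near-pure water spectrum, structural intensity 10 (below the default
CSF threshold of 0.25 × robust max) and T1 = 4000 ms; air is zero.

## ROI aggregation and statistics

ROI means use converged voxels only.  Hemisphere rule: controls average both
hemispheres (voxel-count-weighted); patients use the hemisphere
contralateral to the clinically affected side.  Outliers: Tukey fences
(quartiles ± 1.5 IQR, multiplier config-exposed) per region per group across
subjects, applied exactly once — the rule is not idempotent if quartiles are
recomputed after removal, and single application matches the analysis
pipeline it reproduces.  Exclusion is per region, never whole-subject, and
always reported.  Composites (thalamus, basal ganglia, deep gray matter) are
voxel-count-weighted means of members, which equals the union-ROI mean
exactly.  The group-difference map pools the contralateral hemisphere of
each patient into a hemisphere template (mirroring left-affected subjects),
reflects it, subtracts from the control average, masks CSF by intensity
thresholding and min–max normalizes to [0, 1]; a constant difference warns
and returns zeros.

Statistics: pooled-variance two-sided Student's t (Welch optional);
Kendall tau-b by explicit pair counting with tie corrections (p from the
tie-adjusted normal approximation; exact null distribution for untied
n ≤ 10); ANCOVA as OLS of the region value on severity, age and sex
(F = 0/M = 1) via statsmodels, with per-sex fitted lines at a fixed age.  No
multiple-comparison correction is applied to primary outputs (regions are
pre-selected); ANCOVA is run only for regions whose severity correlation is
significant, mirroring the analysis being reproduced.

## Problem sizes and determinism

The imaging reproduction runs the default 25-patient/24-control cohort on a
caudate-only phantom (~210 voxels per hemisphere, 52-point spectra,
~20k voxel fits, a few minutes on one core); region-value-level experiments
use n = 2500 (copula/Kendall) and n = 2000 (linear/ANCOVA) patients.  All
randomness flows from explicit integer seeds through `numpy` SeedSequence
spawning, so cohorts, phantoms and result tables are bit-identical across
runs with the same seed; every on-disk run writes its resolved configuration
and provenance beside the outputs.

## Known limitations

The generator and the fitter share the Lorentzian lineshape family and the
peak-width priors, so recovery results certify the estimation code, not
in-vivo accuracy.  No Bloch–McConnell saturation physics, B0/B1 field maps
beyond the dip-centering correction, partial-volume effects, registration
error, or Rician noise.  The per-voxel amplitude estimate is noisy at the
study SNR (SD ≈ 0.28 % per voxel) and mildly right-skewed, which inflates
ROI means by a few hundredths of a percent; ROI averaging keeps this well
inside the reproduction tolerances but single-voxel values should not be
over-interpreted.
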