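# guancest

Creatine-weighted CEST (GuanCEST) MRI quantification and group statistics,
with a calibrated synthetic cohort simulator.

## The problem

Creatine is the brain's short-term energy buffer, and impaired bioenergetics
is a core feature of Parkinson's disease, but no routine imaging method maps
creatine in vivo.  GuanCEST MRI detects the guanidinium protons of creatine
(and of arginine side chains) ~2 ppm downfield of water: selectively
saturated solute protons exchange with water and depress the water signal,
and the depth of the resulting dip in the Z-spectrum (normalized water
signal vs. saturation offset) scales with solute concentration.  The amide
peak at ~3.5 ppm serves as a mobile-protein control channel — if amide is
unchanged, a guanidino change is attributable to creatine rather than
protein content.

This package implements the full analysis chain for such a study:

- **PLOF quantification** (`zspectrum_fitting`): normalize by the 200 ppm
  reference, center the direct-saturation dip (B0), fit a polynomial
  background over a downfield window with the peak bands excluded, fit the
  residual with two bounded Lorentzians
  `L(dw) = A (G/2)² / ((G/2)² + (dw − d)²)`, and refine background and peaks
  jointly by variable projection.  GuanCEST/amideCEST are the Lorentzian
  amplitudes in % of the normalized signal.
- **T1 mapping** (`t1_mapping`): closed-form two-point DESPOT1 from a
  5°/30° SPGR pair (TR 25 ms).
- **ROI pipeline** (`roi_pipeline`): per-hemisphere ROI means over converged
  voxels; controls average hemispheres while patients use the hemisphere
  contralateral to the clinically affected side; Tukey-fence outlier
  removal per region per group; composite (union-ROI) regions; CSF masking
  by intensity thresholding; a min–max-normalized group-difference map.
- **Statistics** (`stats`): pooled Student's t, Kendall tau-b with tie
  handling, ANCOVA of region signal on motor severity (MDS-UPDRS-III)
  adjusted for age and sex.
- **Synthetic cohort** (`synthetic_data`): clinical covariates drawn from
  the study's reported demographics, per-region truth with calibrated group
  shifts and severity couplings (linear or Gaussian-copula, where
  Kendall tau = (2/pi)·arcsin(rho)), and a mirrored digital phantom whose
  voxels carry multi-pool Lorentzian Z-spectra over the study's 53-offset
  schedule, plus the SPGR pair.

The target quantities the defaults are calibrated to: caudate GuanCEST
1.82 % (controls) vs 1.67 % (patients), caudate amideCEST 1.72 % vs 1.60 %
(a non-significant difference), Kendall tau = −0.44 between thalamic
internal-medullary-lamina GuanCEST and motor score, and an ANCOVA slope of
−0.01 %/point.

## Worked example

Region-value-level experiments run in seconds:

```python
from guancest.reproduce import severity_kendall_experiment, ancova_slope_experiment

print(severity_kendall_experiment(seed=42, n_patients=2500))
# {'tau_b': -0.44890967133336235, 'p': 2.848773078788721e-243, 'n': 2500}

print(ancova_slope_experiment(seed=11, n_patients=2000))
# {'beta_severity': -0.00917757926916568, 'p_severity': 1.1898403846424079e-132, 'n': 2000}
```

The first simulates 2 500 patients whose internal-medullary-lamina signal is
coupled to their motor score through a Gaussian copula and recovers the rank
correlation (−0.449, target −0.44) with the package's own tau-b
implementation.  The second simulates 2 000 patients in linear mode and
recovers the severity slope (−0.0092 %/point, target −0.01) from the ANCOVA
adjusted for age and sex.

Group means as reported can also be checked directly from summary
statistics:

```python
import numpy as np
from guancest.stats import two_sample_ttest

def with_moments(mean, sd, n, seed):
    x = np.random.default_rng(seed).normal(0, 1, n)
    x = (x - x.mean()) / x.std(ddof=1)
    return mean + sd * x

r = two_sample_ttest(with_moments(1.82, 0.16, 24, 0), with_moments(1.67, 0.26, 25, 1))
print(f"t = {r.t_stat:.3f}, df = {r.df:.0f}, p = {r.p_two_sided:.4f}")
# t = 2.420, df = 47, p = 0.0194
```

i.e. the caudate group difference is significant at the cohort size, while
the same construction on the amide summaries (1.72 ± 0.35 vs 1.60 ± 0.29)
gives p ≈ 0.2.

## Command line

A full on-disk run (simulate → fit → analyze) with the default
configuration:

```bash
guancest all --out run1 --seed 42
```

writes the cohort CSV, per-subject NIfTI volumes (4-D CEST, SPGR pair,
structural channel), the label volume and offset sidecar, fitted
GuanCEST/amideCEST/T1/QC maps, region tables, t-test/Kendall/ANCOVA result
CSVs, the normalized difference map, a run report listing every exclusion,
and the resolved configuration.  `guancest simulate/fit/analyze` run the
stages separately; `--config cfg.yaml` overrides any default.

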