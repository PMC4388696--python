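# divlayers

Quantitative analyses of layered protein structures at the bacterial division
site, from single-molecule localization microscopy (PALM / iPALM) data.

The *E. coli* divisome is organised as a stack of concentric protein layers at
midcell: membrane-proximal FtsZ protofilament clusters, the FtsZ-binding
protein ZapA at a similar radius, a more internal ZapB layer, and
chromosome-anchored MatP clusters near the nucleoid. Mapping these layers
means extracting quantitative geometry from sparse, noisy molecular
coordinates. `divlayers` packages the complete analysis chain for this kind of
study, together with ground-truth synthetic-data generators that emulate each
measurement's statistical structure, so that every estimator can be validated
by parameter recovery.

## What it computes

* **Ring morphometry** — per-cell band width *w* (FWHM of a Gaussian fitted
  to the long-axis localization density, with the localization precision
  removed in quadrature) and ring diameter *d* (distance between the two most
  distal peaks of the short-axis projection, with a blur-bias correction);
  Welch comparisons between strains and an OLS line relating the diameters of
  two co-imaged species, whose x-intercept halved is the radial separation of
  the layers.
* **Two-color colocalization** — least-squares affine channel registration
  from fiducial-bead control points, and the coordinate-based
  cross-correlation "apparent displacement": the short-axis displacement Δ
  maximising

  C(Δ) = (1 / n₁n₂) Σᵢ Σⱼ exp(−[(xᵢ−xⱼ)² + (yᵢ−yⱼ−Δ)²] / 2h²).

* **iPALM axial positions** — coverslip-surface z from a Gaussian fit to a
  surface-dye channel, per-cell mean z of in-box molecules above it, and
  species-to-species displacements with a label-size uncertainty budget
  (√(s₁² + s₂²)).
* **Radial placement models** — threshold/connected-component cluster
  detection, cluster displacements along the cell axes, and two models for
  the distribution of projected short-axis displacements r′ = |r cos φ|:
  a Gaussian-radius model fitted by seeded simulation on a (μ_r, σ_r) grid,
  and a uniform-disk model with the analytic projected density
  f(r′) = 4/(πR²)·√(R² − r′²) and closed-form moments (mean 2R/3,
  sd R/√18).
* **FRAP turnover** — bleach-ratio screening, two-ROI normalization,
  single-exponential recovery fitting (τ½ = ln 2 / k) on the averaged trace,
  and a bootstrap standard error over traces.
* **Expression calibration** — integrated fluorescence → copies per cell →
  fraction of total (wild-type + fusion) protein via a reference fusion of
  known expression fraction.

The fitted analyses follow a model/results pattern: construct a model object
from data (`FrapRecoveryModel`, `RadialProjectionModel`,
`DiameterCorrelation`), call `fit()`, and read estimates, uncertainties and a
`summary()` from the results object.

## Worked example

```python
import numpy as np
from divlayers import (RingSimParams, simulate_ring_band, measure_band_width,
                       measure_band_diameter, summarize_ring_geometry,
                       FrapSimParams, simulate_frap)
from divlayers.frap import FrapRecoveryModel

# 54 synthetic cells with a 115 nm-wide, 689 nm-diameter ring,
# 600 molecules each, 20 nm localization precision
rng = np.random.default_rng(0)
cells = [simulate_ring_band(RingSimParams(), seed=int(rng.integers(2**31)))
         for _ in range(54)]
geom = summarize_ring_geometry([measure_band_width(c) for c in cells],
                               [measure_band_diameter(c) for c in cells])
print(geom)

# 59 FRAP traces at a 19.8 s recovery half-time, fitted with a bootstrap SE
traces = simulate_frap(FrapSimParams(halftime=19.8, n_traces=59), seed=0)
print(FrapRecoveryModel(traces).fit(n_boot=300, seed=1).summary())
```

prints

```
w = 118 ± 1 nm, d = 684 ± 2 nm (n = 54)

FRAP single-exponential recovery fit
  traces (accepted)   : 59 (0 rejected by bleach-ratio screen)
  rate k (1/s)        : 0.0345
  half-time (s)       : 20.1
  amplitude A         : 0.747
  bootstrap se (s)    : 0.3 (300 resamples)
```

i.e. the morphometry recovers the generating ring geometry (width 115 nm,
diameter 689 nm) to a few nanometres across 54 cells, and the FRAP pipeline
recovers the generating half-time within its bootstrap error. The same
recoveries are exercised at tighter tolerances in the test suite.

A `divlayers` command-line tool exposes the generators and analyses
(`divlayers simulate ring --seed 1 --out ring.csv`,
`divlayers morph width ring.csv`, `divlayers frap-fit traces.csv`,
`divlayers quant fraction ...`; see `divlayers --help`).

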