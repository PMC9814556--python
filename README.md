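# chromspect

Unsupervised deconvolution and spectral fingerprinting of full-spectrum
(time × wavelength) HPLC chromatograms.

Portable liquid chromatography with a broadband UV–vis detector records an
absorbance surface A(t, λ) rather than a single-wavelength trace. That extra
dimension makes two things possible that a conventional detector cannot do:

* **resolve hidden peaks** — species whose elution profile is entirely
  overlapped by neighbours, so they never produce an apex or a pure spectrum
  of their own;
* **identify species by spectral shape alone**, independent of retention
  time, which matrix effects routinely shift in field samples.

`chromspect` implements the full chemometric chain for mixtures of UV-active
analytes such as polycyclic aromatic hydrocarbons (PAHs):

1. **Peak detection** on a monitoring channel (default 230 ± 2 nm), with a
   robust noise estimate and 10%-of-apex flank times.
2. **Species counting** in congested windows: unit-norm timepoint spectra →
   PCA → K-means for k = 1…k_max, the count chosen at the elbow (maximum
   discrete second difference) of the within-cluster sum-of-squares curve.
3. **Gaussian elution modelling**: a channel is Σⱼ aⱼ·exp(−(t−Rtⱼ)²/2σⱼ²);
   retention times and widths are fitted jointly across wavelength channels
   (σ is a physical property of elution, not of wavelength). A retention
   time that drifts with the monitoring wavelength is diagnostic of an
   under-counted window — a hidden species.
4. **MCR-AR** (multivariate curve resolution by alternating regression):
   the Beer–Lambert bilinear factorisation D ≈ C·Sᵀ solved by alternating
   non-negative least squares, initialised from flank spectra (rising/
   trailing 10% timepoints for the outer species, the fitted Rt row for
   hidden ones). Recovers each species' spectrum and concentration profile.
5. **Fingerprint classification**: reference spectra are interpolated to a
   common grid, Savitzky–Golay smoothed (order 5, ±4.5 nm), differentiated
   once (cancelling baseline offsets), variance-projected, and classified by
   a shrinkage linear discriminant; inconclusive posteriors fall through to
   an r² tiebreak against candidate reference curves. Similarity is reported
   as r² and as a discrete Fréchet distance on doubly normalised curves.

A synthetic-data module generates spectra, reference libraries and full
chromatograms with the statistical structure the analysis assumes
(bilinear mixing, Gaussian elution, additive noise, baseline drift),
including canned hidden-peak scenarios with ground truth.

## Worked example

```python
import numpy as np
from chromspect import (
    hidden_peak_scenario, train_fingerprint_model, run_pipeline, PipelineConfig,
)

# three co-eluting species; the middle one never shows an apex of its own
chrom, truth = hidden_peak_scenario(seed=1)
model = train_fingerprint_model(truth["library"])
table, artifacts = run_pipeline(chrom, model, PipelineConfig(min_separation_min=0.05))
print(table[["retention_time", "species", "posterior", "r2", "deconvolved"]].round(3))
```

prints

```
   retention_time   species  posterior     r2  deconvolved
0           5.856  hidden_A      0.462  0.964         True
1           5.999  hidden_B      0.788  0.994         True
2           6.144  hidden_C      0.469  0.959         True
```

Only two apexes are visible on the detection channel, but the window's
spectra cluster into three species; the shared-Rt Gaussian fit places the
hidden component at 5.999 min (truth: 6.000), and the MCR-AR-deconvolved
spectrum matches the generating spectrum at r² = 0.994. The `deconvolved`
flag marks rows whose spectrum came from curve resolution rather than
from an apex timepoint.

The same flow is available from the shell:

```bash
chromspect --seed 1 simulate --scenario three --out chrom.csv --truth-out truth.json
chromspect --seed 0 library --n-species 24 --model-out model.json
chromspect run --chromatogram chrom.csv --model model.json --out peaks.tsv
```

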