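# shearfret

Spatio-temporal analysis of ratiometric FRET biosensor imaging in single
adherent cells under fluid shear stress.

## The problem

Genetically encoded FRET biosensors report a protein interaction as the
intensity ratio of two emission channels (an ECFP donor around 475 nm and a
yellow acceptor around 535 nm, excited at 420 nm). In flow-chamber
experiments a cell is imaged once per minute in both channels; applying
laminar shear stress changes the whole-cell ratio by tens of percent and can
redistribute the signal between the edge of the cell facing the flow
(*upstream*) and the opposite edge (*downstream*). Quantifying that response
takes a fixed chain of image operations, and the polarity question — is the
signal at 30 min significantly different between the two cell ends? — takes
a defined statistical protocol. This package implements that chain as a
tested library for experimenters analyzing two-channel time-lapse TIFF
stacks, and for anyone who wants to validate the protocol on synthetic data
with known ground truth.

## The method

For each frame of a donor/FRET stack:

1. **Background**: the mean intensity of the four image corners (8 × 8 px
   windows) is subtracted from each channel, clamping at zero.
2. **Despeckle**: a 3 × 3 median filter removes impulse noise.
3. **Segmentation**: Otsu threshold on the nonzero donor intensities, keep
   the largest 4-connected component, fill holes.
4. **Ratiometry**: per-pixel ratio `R = I_FRET / I_ECFP` over the mask
   (pixels with donor signal below a noise floor are excluded and counted).
5. **Whole-cell series**: the mean of the per-pixel ratios, normalized by
   its pre-stimulus mean, so a response reads directly as a fractional
   change.
6. **Flow-axis profile**: the cell is cut into 50 equal-width slabs along
   the flow direction; bin *i* carries the percentage
   `p_i = 100 · Σ_{x∈bin i} R(x) / Σ_x R(x)`, with bin 1 the downstream
   extreme and bin 50 the upstream extreme. Each bin's trace is normalized
   by its own pre-stimulus mean, and the profiles stack into a 50 × T
   spatio-temporal map.
7. **Polarity**: per cell, the first five and last five normalized bins are
   averaged into a downstream and an upstream value at 30 min after flow
   onset; across n replicate cells a two-tailed two-sample t-test (Welch by
   default) calls polarity at p < 0.05.

A synthetic-data module generates two-channel stacks from a known forward
model — elliptical cell, exponential ratio decay `1 − d·(1 − e^(−t/τ))`
after stimulus onset, a linear flow-axis gradient of amplitude `g`, Poisson
photon noise, Gaussian read noise, background offset, optional
photobleaching — so every stage of the pipeline can be verified against
closed-form ground truth.

## Worked example

```python
from shearfret import (FretPolarityModel, GroundTruth, cohort_polarity_test,
                       generate_cohort, generate_stack)

# one synthetic cell: 25% ratio decay, downstream-shifted gradient g = 0.3
truth = GroundTruth(decay_amplitude=0.25, gradient_slope=0.3, seed=7)
stack, _ = generate_stack(truth, n_frames=41)
res = FretPolarityModel(stack).fit()
print(res.summary())
```

```
FRET polarity analysis
======================================================
frames                   41  (interval 60 s, onset frame 10)
baseline FRET/donor      1.2004
normalized plateau       0.7491  (-25.1% change from baseline)
downstream (bins 1-5)    1.1457  at last frame
upstream  (bins 46-50)   0.8804  at last frame
mean mask area           3498 px
mean background (donor)  100.05
======================================================
```

The fitted baseline (1.2004) matches the generator's ratio baseline of 1.2,
the plateau of 0.7491 recovers the simulated 25% decrease, and the
downstream bins sit above the upstream bins because the gradient tilts the
ratio toward the flow exit. An eight-cell cohort then makes the polarity
call:

```python
cells = generate_cohort(GroundTruth(decay_amplitude=0.25, gradient_slope=0.3),
                        8, master_seed=7, n_frames=41)
results = [FretPolarityModel(s).fit() for s, _ in cells]
pol = cohort_polarity_test(results, time_after_onset_s=1800.0)  # 30 min
print(pol.down_mean, pol.up_mean, pol.p_value, pol.polar)
# 1.1521  0.8471  9.4e-16  True
```

`res.save("out/")` writes `series.csv`, `profiles.csv`, `map.csv`,
`ratio.tif`, figures, the effective config, and an audit log. The same
pipeline is scriptable from a shell:

```bash
shearfret simulate --out sim --seed 7 --n-cells 8 --frames 41
shearfret analyze --donor sim/cell_00/donor.tif --fret sim/cell_00/fret.tif \
                  --meta sim/cell_00/meta.yaml --out run_00
shearfret cohort-test --runs run_00 --runs run_01 ... --time-point 30m
```

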