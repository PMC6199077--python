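# nanopillar

Quantitative analysis of mechano-bactericidal nanopillar surfaces — the
"black silicon" family of etched silicon pillar forests that kill bacteria by
rupturing their membranes.  The package is aimed at surface scientists and
image analysts who need to turn micrographs, height maps and plate counts
into comparable numbers per surface: pillar density, characteristic spacing,
spectral regularity, roughness, and bactericidal efficiency.

Because such studies rarely ship raw images, the package includes a
first-class synthetic generator with known ground truth, so every estimator
can be validated end to end: patterns are sampled at realistic densities
(8–11 tips/µm²), hard-core excluded areas (~150 nm) and characteristic
neighbour spacings (~300–400 nm), rendered as SEM-like micrographs and
AFM-like height fields, and paired with simulated plate-count assays.

## What it computes

- **Pair-correlation function** `g(R) = ρ(R)/ρ₀` of tip positions, where
  ρ(R) is the mean tip density at distance R from a typical tip and ρ₀ the
  overall density, so g → 1 at large R.  The estimator bins all pair
  distances into 20-nm annuli with Ripley's isotropic edge correction;
  `first_peak` locates the characteristic spacing with parabolic sub-bin
  interpolation.  Neighbour-count distributions within a cutoff (default
  500 nm) quantify local crowding.
- **Tip detection** with a from-scratch three-layer backpropagation
  perceptron (12×12-pixel patches × 3 colour channels → 432 inputs, 24
  hidden, 2 logistic outputs for the classes E "empty" and P "pillar tip"),
  trained online on 7 hand-picked patches per class augmented 72-fold
  (24 rotations × rescales to 90/100/110 %), then slid over the calibrated
  micrograph; tips are local response maxima pruned to a minimum separation.
- **Tiled averaged-FFT spectra**: mean magnitude spectrum over 512×512-px
  tiles displaced by 100 px, radially averaged to magnitude vs wave number
  q = 2π/R (nm⁻¹), with halo-ring peak localisation.
- **Surface metrology**: area-wise Ra and Rq, the Abbott–Firestone bearing
  curve (fraction of the area at or above each height level), and the pillar
  aspect ratio height / tip width.
- **Bactericidal efficiency**: per replicate,
  `(control CFU − surface CFU) / (area × incubation time)` in
  cells·min⁻¹·cm⁻², summarised as mean ± SEM with a two-tailed paired
  Student's t test.
- **Pipeline**: a JSON-configured end-to-end run per surface plus a
  comparison table with Spearman rank correlations of efficiency against
  each topographic parameter.

## Worked example

```sh
python examples/01_pattern_and_pair_correlation.py
```

```
generated 1000 tips -> density 10.00 /um^2
first g(R) peak at R = 305.9 nm (g = 4.48)
g(R) is 0 inside the excluded area: True
mean neighbours within 500 nm: 6.34
```

The generator was asked for 10 tips/µm² with a 306-nm characteristic
spacing on a 10×10 µm field; the estimated density matches, g(R) vanishes
inside the 150-nm hard core, and the recovered first peak (305.9 nm) is the
preferred tip-to-tip distance.  The detector chain closes the loop from
pixels back to statistics:

```sh
python examples/02_detect_tips_with_mlp.py
```

```
ground truth: 275 tips on 5x5 um (11.0 /um^2)
training set after augmentation: {'E': 504, 'P': 504}
final training loss: 2.57e-05
detected 274 tips -> density 11.51 /um^2
precision 1.000, recall 0.996 (match radius = 110 nm tip width)
```

The remaining examples cover the FFT halo (`03`), roughness/bearing/
viability (`04`) and the three-surface comparison pipeline (`05`).  A thin
CLI mirrors the library (`nanopillar synth|tips|stats|spectral|topo|
viability|pipeline ...`); see `nanopillar --help`.

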