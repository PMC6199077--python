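# Methods

This note documents the models behind each module, the defaults and why
they were chosen, what the synthetic generator does and does not emulate,
and the numerical details that matter for reproducibility.

## Synthetic tip patterns

Nanopillar tips on etched silicon behave like a hard-core point process with
short-range order: each pillar excludes an area around itself (pillars that
nucleate closer lean together and fuse into bundles), and neighbours show a
preferred spacing of roughly 300–400 nm at densities of 8–11 tips/µm².

`generate_pattern` samples this in three steps, all on a torus (periodic
boundaries) so the pattern stays statistically homogeneous up to the field
edge:

1. **Dart throwing**: `round(density × area)` points are placed by
   sequential rejection with minimum distance `exclusion_radius`
   (default 150 nm).  Densities above the random-sequential-adsorption
   saturation (≈ 0.547·4/(π d²), i.e. ~31 µm⁻² at d = 150 nm) raise an
   error naming the limit.
2. **Spacing relaxation** (optional, default on at 306 nm): every pair
   closer than the target spacing is pushed apart toward it with damped
   Jacobi updates (η = 0.35, 120 iterations).  This concentrates
   neighbour distances at the spacing and is what produces a
   pair-correlation first peak *at* the requested value.  Lloyd-type
   centroidal relaxation was rejected: it drives patterns toward hexagonal
   order with spacing √(2/(√3 ρ)) ≈ 340 nm at 10 µm⁻², which cannot place
   the peak at 306 nm at that density.
3. **Jitter and bundling**: Gaussian positional noise (default σ = 10 nm),
   then optional bundle merging — with probability `bundle_prob`, pairs
   closer than 1.5× the exclusion radius are replaced by their midpoint,
   mimicking leaning pillar pairs that a detector counts once.  The hard
   core is re-enforced afterwards, so every returned pattern satisfies
   min pairwise distance ≥ `exclusion_radius` exactly.

All randomness flows from the single spec seed through one `numpy`
Generator; stream order is darts → jitter → bundling (the relaxation is
deterministic).  Identical specs give bitwise-identical patterns.

**Ordering strength.** The default relaxation is strong: it reproduces the
target peak position to within ~1 nm across seeds, at the cost of a peak
height (g ≈ 4.5) larger than on real surfaces, whose first peaks are modest
(g ≈ 1.5–2).  Weaker relaxation (≤ 12 iterations with 30–40 nm jitter)
matches the realistic peak heights but lets the peak position scatter by
±25 nm.  Position fidelity was preferred because the characteristic spacing
is the recovery target; the trade-off is documented here rather than hidden.

## Rendering

SEM-like micrographs place one isotropic Gaussian blob per tip (FWHM =
physical tip width, default 110 nm) on a constant background with additive
Gaussian noise, clipped to the 8-bit range.  Default calibration is
10 nm/px — a free parameter, since magnification alone does not fix it; it
resolves a 110-nm tip over ~11 px and a 10×10 µm field as 1000×1000 px.
Charging, edge brightening, tilt projection and the conical pillar body are
not modelled.

AFM-like height maps draw per-pillar summit heights from
Normal(mean, sd) truncated at zero (defaults 836.8 ± 91.2 nm, the tallest
surface class observed) and render each pillar as a Gaussian cap of lateral
scale 60 nm combined by maximum, so an isolated summit equals its drawn
height exactly and the baseline is 0.  Tip convolution and scan-line noise
are not modelled, so absolute Ra/Rq of real AFM scans are not reproduced —
only their invariants (Rq ≥ Ra, bearing-curve shape) are meaningful.

Viability tables apply multiplicative Gaussian noise (CV default 10 %) to
the true means (inoculum for controls, inoculum × (1 − kill) for surfaces),
rounded and clipped at zero.  Multiplicative noise keeps kill = 1 at exactly
zero surface counts and leaves the efficiency estimator unbiased, which the
test suite verifies over 200 simulated assays.

## Pair-correlation estimator

g(R) is estimated as the edge-corrected pair density in annuli of width
20 nm (default) divided by ρ₀ = N/area.  Each ordered pair (i → j) at
distance d is weighted by the inverse fraction of the circle of radius d
around i inside the rectangular field (Ripley's isotropic correction).  For
d ≤ min(width, height)/2 — enforced as `r_max` precondition — at most two
adjacent edges cut the circle and the closed form

    exterior = Σ_edges 2·arccos(t/d) − Σ_adjacent max(0, α + β − π/2)

is exact.  Raw (unweighted) pair counts are kept alongside g and are tested
for exact equality against brute-force enumeration of all pairs.  ρ₀ from
the empirical density satisfies the large-R normalisation under edge
correction; a large-R plateau fit was rejected as needlessly model-bound.
Defaults (bin 20 nm, r_max 1000 nm, peak search beyond 100 nm) resolve a
~306-nm peak while keeping well over 10 pairs per bin at study densities.

`first_peak` returns the first local maximum above 1 beyond `min_R`, with
the vertex of the parabola through the three neighbouring bins (the offset
is clipped to ±half a bin; a plateau falls back to the bin centre).  No
qualifying bin yields an explicit no-peak result (`None`).

Neighbour counts use minus sampling: only tips at least `cutoff` from every
edge are counted (unbiased), all tips count as neighbours.  The
density-shift comparison checks first-order stochastic dominance of the two
empirical count CDFs.

## Spectral analysis

`tiled_fft` averages the unnormalised FFT magnitude of every 512×512 tile
on a 100-px stride grid anchored top-left; partial tiles are discarded.
Magnitude (not power) is averaged, matching typical FFT-display pipelines;
no apodization window is applied by default (a Hann option exists).  The DC
pixel of the averaged spectrum is replaced by the mean of its 8 neighbours
for display parity; the original value is retained so Parseval's identity
per tile remains checkable.  Radial averaging bins |q| uniformly up to the
Nyquist wave number π/pixel_size with q = 2π·(cycles/px)/pixel_size.

The 2π reciprocal convention (R = 2π/q) is fixed because it reproduces the
printed pairing of a 306-nm spacing with q ≈ 0.020 nm⁻¹.  Note the reported
halo range 0.016–0.021 nm⁻¹ corresponds under this convention to 299–393 nm,
not 330–390 nm; the quoted low-end scale is inconsistent with the
convention and is not silently reconciled.

**Known limitation (intentionally failing check).**  A point pattern whose
g(R) first peak sits at 306 nm at 10 tips/µm² necessarily has its
structure-factor ring near q₁ ≈ 0.022 nm⁻¹: for dense 2-D packings
q₁·r₁ ≈ 7 rather than 2π.  Measured directly on the generated patterns the
ring sits at 0.0220 (point S(q)) and 0.0215–0.0227 (tiled FFT of the
render) — just above the 0.016–0.021 window reported for the real surfaces,
which is only reachable from patterns ordered at the 330–390 nm scale
(e.g. a 360-nm-spacing pattern gives 0.0198–0.0201).  The blob form factor
(FWHM ≈ tip width) cannot pull the product peak below 0.021 without burying
the ring under the low-q envelope.  The acceptance test asserting the
window on the 306-nm pattern is therefore expected to fail and is left in
place with this analysis; the adjacent consistency checks (2π/R_peak within
0.020 ± 0.002; |q_halo − 2π/R_peak| ≤ 0.002) pass.

`halo_peak` takes the magnitude maximum beyond `q_min` (default 0.008 nm⁻¹,
excluding the tile-scale envelope) with parabolic interpolation; a maximum
at the window edge is reported as "no halo".

## Tip detector

Architecture 432–24–2 (12×12 px × 3 channels; grayscale feeds the same
value to all three channels), logistic activations, squared-error loss
against targets [1,0] (E) and [0,1] (P).  Unstated training details were
fixed as: weights ~ Uniform(−0.5, 0.5) from the seed, learning rate 0.1,
online updates (one backpropagation per pattern), patterns reshuffled each
epoch, and "N forward passes per picture" read as N epochs over the
augmented set.  Augmentation: 24 equidistant rotation angles × rescales to
90/100/110 %, bilinear interpolation with reflective padding, resampled to
12×12 — 72 variants per base patch, 504 per class from the canonical 7.
The analytic gradient is verified against central finite differences at
1e-5 relative tolerance.

Scanning normalises the whole image to [0,1] by global min–max (a fixed,
reproducible choice), evaluates every stride-th window and records the P
output.  Detection takes 8-neighbourhood local maxima above threshold 0.5
and greedily keeps the highest-response candidates at least one tip width
(110 nm) apart, mirroring how leaning pillar bundles are counted as single
objects.  Response-map coordinates are window centres; the reported field
extent is the scanned region, so densities are computed over the area that
was actually examined.

At study conditions (11 tips/µm², 10 nm/px, noise σ = 8 gray levels) the
full chain — 7+7 patches, 120 epochs, stride-1 scan of a 5×5 µm field —
recovers density within a few percent with F1 ≥ 0.99 against ground truth.
The reduced epoch count and field size keep the check to seconds; they are
the package's standard validation problem size.

## Metrology and viability

Ra/Rq are area-wise mean-absolute and RMS deviations from the mean plane
(line-wise evaluation is not implemented); an optional first-order plane
subtraction exists and is off by default since synthetic maps are level.
The bearing curve is the height-exceedance fraction on levels descending
from one step above the summit (fraction 0) to the minimum (fraction 1).
The pillar aspect ratio is height / tip width, which reproduces all three
published example pairs within rounding (8.4, 6.0, 8.8).

Efficiency is (control − surface)/(area × time) per replicate
(dilution-scaled if a dilution column is present), summarised as
mean ± SEM; negative replicates are flagged, not truncated, to avoid upward
bias.  The paired t test delegates to `scipy.stats.ttest_rel` with
degenerate inputs intercepted: identical samples → (t = 0, p = 1); constant
non-zero differences → an explicit error result, since t is undefined at
zero variance.  Significance is reported at the conventional p < 0.05.

## Pipeline

A run is one JSON document with a namespaced block per stage; unknown keys
are rejected (pydantic, `extra="forbid"`) and every random stage carries an
explicit seed, making runs deterministic — reports contain no timestamps,
so identical configs yield byte-identical `report.json`.  Provenance
(config hash, seeds, package version) is embedded per surface.  Stage
timings go to a JSON-lines run log; failures abort with the stage name.
By default statistics run on ground-truth tips (`detector.enabled=false`);
enabling the detector inserts the train–scan–detect chain.  Rank
correlations between efficiency and each topographic parameter use
Spearman's ρ, with zero-variance metrics flagged and reported as undefined.
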