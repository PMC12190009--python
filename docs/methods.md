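# Methods

This note documents the models and procedures each module implements, the
parameters that matter with their defaults, what the synthetic generators
do and do not emulate, and the numerical choices made where the design was
open.

## Lifetime fitting (`flim`)

**Model.** A photon-decay histogram is modelled per bin (at bin centres
t) as `μ(t) = A1·e^(−t/τ1) + A2·e^(−t/τ2) + b`, with the convention
**τ1 ≥ τ2 everywhere in the package** (components are relabelled after
fitting, so the result is invariant to swapping any start point). Because
the integral of an exponential over a uniform bin is itself proportional
to the bin-centre exponential, fitting at bin centres introduces no
discretisation bias in the lifetimes; only the amplitudes absorb a known
`2τ·sinh(w/2τ)/w` factor.

**Objective.** Poisson negative log-likelihood by default (the correct
counting-noise model); Poisson-weighted least squares (`weighted_lsq`) is
retained for parity with vendor software and is exactly
scale-equivariant on noiseless data. Optimisation is L-BFGS-B in
log-parameters with analytic gradients, five starts (one seeded by a
log-linear fit to the final third of bins, τ2 at τ1/3; four jittered),
and box constraints keeping lifetimes inside
`[bin_width/2, 20 × window]` — a lifetime far beyond the acquisition
window is not identifiable from the data and the bound prevents ridge
run-away at low photon counts. Non-convergence is reported
(`converged=False`), never silent.

**Conventions and gates.** The tension readout is the *longer* lifetime
τ1; when it does not also carry the higher amplitude the result is
flagged `amplitude_order_violated` rather than reinterpreted. Fits are
gated at 1000 photons per ROI (100 per binned pixel in maps): below
that, two-component fits are effectively unidentifiable. A fit with
τ1/τ2 < 1.2 or either amplitude below 1% of the total is flagged
`effectively_monoexponential`. No instrument-response deconvolution is
applied by default; an exponentially-modified-Gaussian model
(`biexp_model(..., irf_sigma)`) is available for synthetic data with a
Gaussian IRF. Measured histograms are integer counts, but the container
accepts real-valued counts so exact model-expected histograms can flow
through the same fitting path for validation.

**Known behaviour.** The τ1 estimator is noisy and slightly right-skewed
at low counts (relative SD ≈ 3% at 10⁵ photons for the 6 ns/2 ns, 60/40
mixture, worse below); per-pixel maps at ≤10⁴ photons should be
summarised with medians. Acquisition defaults (12.5 ns window, 0.05 ns
bins) are package choices typical of diode-laser TCSPC at 80 MHz-class
windows, not protocol facts.

## ER morphometry (`er_morph`)

**8-bit conversion** is a linear min–max rescale to 0..255 with
half-to-even rounding; a constant image maps to all zeros and logs a
degenerate-input warning.

**Rényi threshold.** For a threshold t the histogram splits into
background (≤ t) and foreground (> t); the single-α criterion maximises
the sum of the two classes' Rényi entropies
`H_α = ln(Σ pᵢ^α)/(1−α)` (Shannon/Kapur at α→1) over all 256 candidate
levels, ties broken toward the lower level. The default `three_alpha`
mode combines the thresholds at α ∈ {½, 1, 2} with the
Sahoo–Wilkins–Yeager weighting used by the common ImageJ plugin; when
the three agree the combination reduces to that threshold.

**Segmentation.** `double_renyi` (default): one threshold separates ER
from background, a second — computed on the intensity histogram *within*
the ER mask — separates the brighter sheets from tubules. Because an
entropy threshold always splits a histogram, even a unimodal one, the
sheet class is accepted only if the split sits in a genuine valley: the
lightly smoothed ER histogram between the threshold and the upper mode
must dip below half of both class peaks; otherwise the ER is labelled
all-tubule. The alternative `renyi_plus_thickness` strategy calls sheet
any ER structure locally wider than `width_cutoff_px` (seeds from the
Euclidean distance transform at depth > cutoff/2, grown back out).
After thresholding, connected components smaller than `min_object_px`
(default 8 px) are removed from the ER mask and sub-threshold sheet
fragments revert to tubule — the standard particle-size cleanup; every
resolvable ER structure spans far more than 8 px at confocal sampling.

**Profiles.** Three bands of width 56 px (kept in pixels; the physical
width follows from the pixel size) run from the nuclear envelope along
fixed directions to the cell boundary or image edge; `"auto"` places
them at 120° spacing starting from the cell's long axis (second-moment
principal axis). The sheet percentage denominator is the ER pixels *of
that band* (the per-segment reading of the protocol sentence). ER area
fraction is ER pixels within the cytoplasm mask over cytoplasm pixels.

## Cytoskeleton (`cytoskeleton`)

Orientation is axial data (θ ≡ θ+180°), so statistics operate on doubled
angles. Display convention: after rotating the cell's long axis to
vertical, 0° is vertical and 90° horizontal with the fold
`min(φ, 180−φ)`; the unfolded [0,180) orientation is kept internally for
statistics, since folding before doubling would conflate ±45°.

The estimator is the structure tensor with Gaussian smoothing σ = 2 px
(configurable): the minor eigenvector gives the texture direction, the
eigenvalue contrast `(λmax−λmin)/(λmax+λmin)` the coherence weight.
Dispersion is the circular standard deviation of doubled angles
`√(2(1−R))`, halved back to the fiber-angle scale and reported in
degrees: 0 for parallel fields, `≈40.51°` (the closed-form R→0 limit)
for a uniform axial distribution; coherence weighting is the default.
Near-isotropic cell masks (axis ratio < 1.05) have no long axis and
raise a degeneracy error instructing a manual angle. Intensity density
is Σ intensity / mask area, per px and per µm².

## Interactions (`interactions`)

**Manders.** Thresholded form: `M1 = Σ ch1 over (ch2 > t2) / Σ ch1` and
symmetrically M2, with Otsu, fixed, or zero thresholds recorded in the
result; channel swap exchanges (M1, M2) exactly.

**ER-on-mitochondria map.** Mitochondria mask from its channel
threshold; ER normalised to its per-image maximum and sampled on the
mask; the summary is the mean normalised ER intensity over the mask.

**Contact extent.** Traces are densified to ≤ 1 nm spacing; the gap at
each point of trace A is the distance to the nearest sampled point of
trace B (KD-tree; with ≤1 nm sampling the vertex-vs-segment error is
below the reporting tolerance). "Reciprocal distance" is enforced by
requiring the nearest partner point to be itself within the cutoff, so
one-sided overhangs cannot inflate extent (a single-sided mode exists
for sensitivity checks). Maximal runs with gap ≤ `max_gap` (default
30 nm) and arc length ≥ `min_run` (default 10 nm, suppressing
single-point grazes) become contact sites; runs separated by
out-of-cutoff stretches stay distinct. Note the measured gap is the
true point-to-curve distance: for steeply sloped gap profiles it is
smaller than the vertical gap, so analytic profile fixtures should keep
slopes shallow (as TEM membrane pairs do).

**Cortical ER classes.** Lumen width < cutoff → thin, ≥ cutoff → wide
(boundary wide); default cutoff 30 nm, configurable — the thin/wide
distinction is qualitative in the source material.

**Puncta.** Threshold (Otsu default), drop components smaller than
`min_voxels` (default 4), count connected components at 6- or
26-connectivity (default 26). A stack blank after thresholding counts 0.

## Assays (`assays`)

SOCE: F0 is the mean over the final 60 s before readdition (window
configurable); the statistic is `max F after readdition / F0` (`F/F0`
default; `dF/F0` available). Optional pre-smoothing: a 3-point median
for spike-like artefacts, or a 3-point moving average, which also
shrinks the upward bias a max over broadband noise incurs; defaults to
none, which is exact on clean traces. DNA normalisation is elementwise
division; XBP1 splicing ratio is `s/(u+s)` with total defined as u+s.

## Synthetic generators (`synthetic`)

Every generator is a pure function of (parameters, seed) through one
`numpy.random.default_rng`; fixtures regenerate bit-for-bit and carry a
`SyntheticTruth` with all parameters (units in key names).

* **Decays**: total photons Poisson(n); arrivals exponential with the
  component chosen Bernoulli(frac1) — frac1 is the *photon* fraction, so
  the mixture mean arrival is `frac1·τ1+(1−frac1)·τ2`; optional Gaussian
  IRF jitter; uniform background; arrivals outside the window truncated
  with the realised fraction recorded.
* **ER cells**: disk nucleus, disk cell; 1–3 px tubules random-walk
  outward from stratified launch angles (real ER fills the cytoplasm
  without the angular clumping of independent directions); sheet blobs
  added until the realised sheet fraction reaches its target — default
  perinuclear 6–14 px blobs; the `"uniform"` placement instead centres
  small blobs on tubule pixels at bit-reversed angular quantiles, making
  the sheet *share* of local ER the same in every direction (the
  radially-uniform condition the profile tests exercise). Intensities
  take three levels (20/100/220 by default, the separable worked-example
  levels) plus Gaussian noise (σ = 8).
* **Membrane pairs**: trace A straight, trace B at the prescribed gap
  (constant / linear / sinusoid); the analytic extent is the closed-form
  measure of {gap ≤ cutoff} with sinusoid crossings from `arcsin` roots.
* **Fibers**: axial angles from a von Mises on doubled angles; rendered
  analytically with a Gaussian cross-section (σ = 1.5 px) — no
  rasterisation staircase, so images carry their stated orientations
  without aliasing bias.
* **Puncta**: rejection-sampled sphere centres with a minimum
  separation; failure names the violated constraint.
* **SOCE traces**: 5 s sampling; baseline through the Ca²⁺-free wash
  (5 min) and store depletion (30 min); after readdition a
  double-exponential transient scaled so its sampled maximum equals the
  stated peak exactly.

**What the generators do not emulate** — and hence what passing tests do
not show about real data: no optics beyond the Gaussian fiber/IRF
widths (no PSF, no SIM reconstruction artefacts), no photobleaching or
motion, no spectral bleed-through between channels, no vendor file
formats, piecewise-ideal morphologies (disk nuclei, straight fibers,
spherical puncta). Recovery results demonstrate the *estimators* are
correct and unbiased under their stated noise models, not that the
pipeline is robust to every real-world artefact.

## Pipeline and I/O

Configs are pydantic-validated and YAML round-trippable; defaults carry
the protocol constants (56 px band width, 30 nm contact gap, 40 nm
sensor gap, 5 s SOCE sampling). All manifest paths are checked up front
and a missing file aborts naming every absent path. Images travel as
float32 TIFF with a JSON description (channel names, pixel size, z-step;
masks as extra `mask:`-prefixed channels); a manifest pixel size
overrides file metadata with a logged warning. Reports (CSV + JSON) use
fixed float formatting and contain no timestamps, so a rerun of the same
config and inputs is byte-identical; the provenance block records the
config hash, package version and seed.

## Problem sizes used in tests

Monte-Carlo suites are sized to keep the full test run in tens of
seconds while leaving clear statistical margin: 200 decays at 10⁵
photons for the recovery median (estimator SD ≈ 3% → median SE ≈ 0.3%),
60 decays per photon level for the RMSE trend, 10 seeds for image-level
recoveries, 20 for threshold/puncta oracles, 8×8 pixels at 10⁵ photons
for the map-vs-pooled comparison, and a 5-cell cohort for end-to-end
determinism.
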