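# Methods

`patchstoich` implements the quantitative analysis of single-molecule
fluorescence imaging of membrane-receptor assemblies: molecule counting by
photobleach-calibrated intensity ("stoichiometry"), detection of an oligomer
periodicity in those counts, and second-order spatial statistics (Ripley's
K/L/H) of super-resolved puncta. This note records the models, the parameter
choices, the numerical decisions, and what the synthetic validation does and
does not demonstrate.

## Imaging model and the synthetic generator

The generator (`patchstoich.synthetic`) emulates the statistical structure
the analysis assumes, with known ground truth:

* **Foci.** Each assembly is an immobile, diffraction-limited focus rendered
  as a pixel-integrated 2D Gaussian (PSF FWHM 180 nm, i.e. sigma ≈ 76.4 nm;
  53 nm pixels, so sigma ≈ 1.44 px). Its integrated intensity in frame *t*
  is (surviving fluorophores) × *I*₁, with *I*₁ = 100 counts the unitary
  single-fluorophore brightness.
* **Photobleaching.** Each fluorophore bleaches irreversibly in a single
  step with constant per-frame probability *p* (default 0.03), so bleach
  frames are geometric with mean 1/*p*. No blinking or maturation effects —
  the counting model assumes unitary, irreversible steps.
* **Noise.** Pixel values are Poisson(signal + background) plus Gaussian
  read noise. Defaults: background 1.0 count/px, read noise sd 0.5 counts.
  With *I*₁ = 100 counts this puts a lone fluorophore at matched-filter SNR
  ≈ 17 (≈ 6 under the disk-sum convention), consistent with an instrument
  that demonstrably detects single GFPs at ~40 nm localization precision.
  Background and read noise are deliberately low relative to *I*₁; higher
  backgrounds degrade single-fluorophore calibration first.
* **Geometry.** Assemblies are placed uniformly with a minimum separation of
  480 nm. The candidate de-duplication radius of the detector is 8 px =
  424 nm, so closer assemblies are unresolvable *by construction* of the
  detection rule; 480 nm keeps the ground truth recoverable while remaining
  denser than typical puncta spacing in the imaged cells.
* **Point patterns.** Uniform-random (homogeneous Poisson/CSR),
  jittered square lattice (isotropic Gaussian jitter of rms = half the
  spacing, i.e. per-axis sd a/(2√2)), and Thomas parent/offspring clusters
  (parents simulated on a buffered window to avoid edge depletion).
* **Traces.** Piecewise-constant intensity schedules with additive Gaussian
  noise, for validating the step-detection chain in isolation.

What the generator does **not** emulate: emitter diffusion, 3D PSF
structure, EMCCD excess noise, fluorophore blinking/maturation, cellular
autofluorescence gradients, or irregular cell boundaries. Passing the
synthetic validation therefore shows the *algorithms* are correct and
well-calibrated under the stated model, not that real data meet that model.

## Spot detection and localization

Candidates are strict local maxima within an 8-px-radius disk that exceed
the mean of their 17×17 neighbourhood. Each candidate is refined by
iterated Gaussian masking (mask sd fixed at the PSF sigma; convergence
tolerance 0.01 px, at most 50 iterations): the centroid is the mask-weighted
mean of background-subtracted pixel positions, re-centred until fixed. On
noiseless spots this localizes to < 0.01 px and agrees with a full nonlinear
least-squares Gaussian fit.

**Background.** The local background is a 4-sigma-clipped mean of the window
pixels outside the detection disk (sd likewise from the clipped set). A
plain annulus mean is biased upward whenever a neighbouring focus leaks into
the 17×17 window — in crowded fields this depressed integrated intensities
by tens of percent — while a median is biased at low Poisson counts;
sigma-clipping removes neighbour flux and stays unbiased for the skewed
background distribution.

**Intensity.** The focus intensity is the background-subtracted pixel sum
inside the 8-px disk (the disk captures > 1 − 10⁻⁷ of the PSF mass).

**SNR and threshold.** The SNR definition is an analysis choice exposed in
the configuration (`snr_method`):

* `matched` (default): PSF-weighted amplitude estimate divided by its
  background-noise sd — the optimal linear detector for a known PSF. A
  single fluorophore sits near SNR 17, while blank-frame noise maxima reach
  only ~8.
* `disk_sum`: integrated intensity / (bg sd × √n_disk). Its noise floor is
  set by the whole 201-pixel disk plus background-estimate variance; on
  blank frames its false positives overlap the single-fluorophore signal, so
  no threshold can deliver both low false positives and single-molecule
  recall. Retained for comparison.

The default threshold (8.0) was calibrated with
`calibrate_snr_threshold` on 2000 simulated blank 256×256 frames to keep
false positives below one per 100 frames (measured: ~0.1/100). A cheap
peak-height prefilter (3 robust sigma above the local mean) skips mask fits
that could never pass; it affects speed only.

## Track linking

A focus in frame *t* links to at most one focus in frame *t*+1. A pair is
admissible iff the fractional area overlap of the two detection disks
(radius = PSF FWHM, centred on each centroid) lies in 75–100 % and the
intensity ratio lies in 50–200 %. "Overlap" is interpreted as equal-disk
area intersection normalized by one disk's area (a centre-distance gate is
available); there is no gap closing — adjacent frames only. Ambiguities are
resolved greedily by decreasing overlap, then intensity-ratio closeness to
1, then lexicographic order, so linking is fully deterministic and the
result is a partition of all foci.

For immobile emitters, a missed link (localization jitter, or a large bleach
step tripping the ratio gate) splits one assembly into co-located track
fragments; the pipeline collapses fragments within half a PSF FWHM of an
earlier-starting track before any counting. This de-duplication is
appropriate only for immobile-emitter data and is a pipeline step, not part
of the linking operation.

## Molecule counting

**Initial intensity.** Each track's first min(5, length) intensities are fit
by ordinary least squares against frame index and extrapolated to the first
laser-exposed frame; a positive slope (impossible under photobleaching)
falls back to the plain mean. Tracks of length 1 have no initial intensity.
Only tracks starting within the first 10 frames of exposure contribute
stoichiometries — later tracks undercount because part of the assembly has
already bleached.

**Single-fluorophore brightness *I*₁.** Two independent estimates:

* *modal post-bleach*: the knee is the first frame where total
  background-corrected intensity falls below 25 % of its initial value
  (config-exposed); focus intensities from frames past the knee are pooled
  and the KDE mode (Silverman bandwidth unless overridden) is *I*₁.
* *step intervals*: intensity traces are read out at fixed track positions,
  smoothed with the Chung–Kennedy filter and segmented into plateaus; the
  KDE mode of downward plateau steps is *I*₁. Only steps whose pre-step
  plateau is below 6 × min_step (≈ 3 molecules) are used: early in a bright
  trace molecules bleach faster than the filter window resolves, and merged
  cascade drops otherwise bias the mode upward by ~30 %.

Both require at least 10 supporting foci/steps; on generator defaults they
agree within a few percent and each lands within ~5 % of the true *I*₁.

**Chung–Kennedy filter.** Output_t combines the means of the W (= 5)
samples strictly before and strictly after *t*, weighted by
(window variance)^(−p) with p = 2; truncated windows at the trace ends;
equal weights if both variances vanish. A zero-variance window dominates
entirely, which preserves noiseless steps exactly. Step detection thresholds
the two-sided window difference of the filtered trace at min_step/2,
locates each step at the largest single-sample drop within a candidate run,
takes plateau levels as raw-trace medians between change points, and merges
plateaus whose difference is below min_step (default 0.5 × *I*₁).

**Stoichiometry distribution.** S = I₀ / *I*₁ per track; the population is
summarised as a Gaussian KDE of kernel sd 0.6 molecules — the total
uncertainty of a single-molecule intensity, so structure narrower than 0.6
molecules is not considered resolved.

## Periodicity

The oligomer periodicity is the modal nearest-neighbour interval of the
sorted stoichiometries, quoted from a Gaussian KDE (sd 0.6 molecules) over
the intervals, with the error
0.6 × √(mean(S)/n_extrap) / n_under_peak (n_extrap = 5 extrapolation
points; n_under_peak = intervals within ±0.6 of the peak; the alternative
reading with the count inside the square root is also reported).

Two refinements make the estimator usable outside the sparse regime, both
config-exposed and both reducing to the plain sorted-value method when every
underlying stoichiometry level holds at most one track:

1. **Peak intervals** (default). Intervals are taken between the local
   maxima of the stoichiometry KDE rather than between raw sorted values.
   With several tracks per level, within-level spacings shrink raw intervals
   far below the true period (the literal estimator's mode collapses toward
   zero); KDE peak positions remain unbiased level estimates. In the sparse
   regime each value is its own peak and the two coincide. The literal form
   is available via `intervals_from="values"` (with sub-resolution intervals
   below the kernel width excluded).
2. **Harmonic disambiguation.** When neighbouring levels merge (measurement
   noise grows with S), their apparent spacing doubles. If the interval
   density at half the modal interval reaches 60 % of the peak density, the
   half is quoted as the fundamental — the standard octave correction of
   period estimation.

In the multi-cell pipeline the headline periodicity pools the tracks of all
cells (pooling sharpens the low-stoichiometry peaks that carry the period);
per-cell estimates are reported alongside. On nine simulated cells of
dimeric (2k-mer) assemblies the pooled estimate is ~2.0–2.2 molecules;
individual realizations scatter by roughly ±0.3.

## Spatial statistics

**Binarization.** Puncta images are scaled to 8 bits and thresholded by the
conjunction of the global Otsu threshold and a per-pixel Otsu threshold in a
disk of radius 25 px; objects below 4 px are removed. Objects are 8-connected
components with intensity-weighted centroids and circularity 4πA/P² using a
Crofton perimeter (small discrete objects can marginally exceed 1).

**Ripley K/L/H.** K(r) = (A/n²) Σ_i Σ_{j≠i} e_ij 1(d_ij ≤ r), L = √(K/π),
H = L − r. The default edge correction is the isotropic (circle-coverage)
correction, computed by sampling 72 angles of each pair's circle against the
ROI (rectangle or binary cell mask); `"none"` is retained and matches a
brute-force double loop exactly. The A/n² normalization (rather than
A/(n(n−1))) follows the convention used for these curves. The default radius
grid runs from 0 to min(10 µm, half the equivalent ROI radius) in 20 nm
steps; radii beyond the validity range are truncated with a warning.

**Modal clustering gradient.** Gradients between adjacent points of a
gradient grid (every 5th point of the H grid, 100 nm at defaults) are
summarised as the KDE mode with kernel width 0.001 (dimensionless; r and H
in µm). Radii with K = 0 are excluded — there H(r) = −r by construction and
the repeated exact −1 gradients would dominate the narrow kernel. On the
native 20 nm grid the per-step pair increments are Poisson-sparse and the
CSR modal gradient was biased to −0.04; at 100 nm the CSR mean is −0.002
(2 SE 0.014 over 100 patterns).

**Nearest-neighbour distance.** The argmin of H over the maximal initial
contiguous negative region. Leading positive values below one grid step are
treated as curve resolution (a single anomalously close pair can push the
very first radii marginally above zero); a genuine rise before any negative
excursion leaves the distance undefined, which is reported as such.
Per-condition summaries average over cells (mean ± SEM).

**Photobleach correction of z-stacks.** Plane k is scaled by exp(k/τ) with
τ from an OLS line through log(mean intensity) of a repeated-acquisition
reference series; an increasing reference has no admissible fit and errors;
a flat reference yields the identity.

## Statistics

The Brunner–Munzel test compares two samples via the relative effect
P(X<Y) + ½P(X=Y), with midranks for ties and a t reference with Welch-type
degrees of freedom (scipy's implementation); an exact small-sample variant
enumerates the studentized statistic over all group relabelings. Zero rank
variance (all ties or complete separation) raises an explicit error rather
than returning NaN. Empirical type-I error at n = 20/20 over 5000 null
replicates is ~0.052. Families of planned comparisons use the Bonferroni
level α/n (0.05/5 = 0.01 for the five study comparisons). The
stoichiometry split comparison partitions values into S < 15 and S ≥ 15.

## Problem sizes used in validation

The test suite and `scripts/acceptance.py` use: nine 256×256 cells × 300
frames with ~50 assemblies each for end-to-end recovery; five 192×192 cells
× 250 frames for calibration consistency; 300 blank 256×256 frames for the
false-positive rate; 100 CSR patterns (plus a 199-simulation envelope) of
~200 points on a 10×10 µm window for the spatial calibration; and 5000
null replicates for the test calibration. These sizes give stable
statistics while keeping a full run in minutes on one core.

## Known limitations

* The stoichiometry noise grows roughly with √S (shot noise and the
  stochastic bleach path during the five extrapolation frames), so
  individual levels are resolved only for small assemblies; the periodicity
  rests on the low-stoichiometry part of the distribution.
* The modal-gradient statistic is a dense-cluster summary of few values and
  is only sign-reliable when clustering acts on scales comparable to the
  analysis window (as in the imaged cells); compact clusters make H peak
  and decline, and the mode can land in the declining branch.
* The interval-KDE periodicity is upward-biased when levels merge; harmonic
  disambiguation removes the factor-two failures but ±0.3-molecule scatter
  between realizations remains.
* Track de-duplication assumes immobile emitters; diffusing-emitter data
  would require gap-closing assignment, which is out of scope.
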