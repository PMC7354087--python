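# Methods

This note documents the measurement models, the defaults and why they were
chosen, what the synthetic generators do and do not emulate, and the
numerical decisions a maintainer would otherwise have to reverse-engineer.

## Mean linear intercept (stereology)

The estimator measures airspace chords along a grid of parallel test
lines laid over a binary tissue mask. A chord is a maximal run of air
pixels along one line; its length is the run length times the pixel size.
Two filters apply:

* **Border-clipped runs are discarded.** A run touching the field border
  is right-censored — its true length is unknown — and keeping it would
  bias Lm downward, increasingly so for small fields. The original
  grid-overlay protocol is silent on this; discarding is this package's
  documented choice.
* **Minimum chord length, default 10 µm.** Sub-resolution slivers between
  touching septa are noise, not alveoli.

Averaging is hierarchical and unweighted: chords pool into a field mean
(horizontal and vertical grids together, which cancels orientation bias on
isotropic tissue), field means average into a section mean, section means
into the subject Lm. Pooling all chords instead would weight fields by
their chord counts; with heterogeneous emphysema that lets a single
airspace-rich field dominate a subject. The hierarchical rule is the
conservative reading of "average of per-field measurements" and matches
how multi-section designs are usually summarized. Fields with no surviving
chord are dropped from the average; a subject in which no field yields a
chord gets an explicit `undefined` flag rather than an exception.

Defaults: 5 fields per section, field edge 600 µm (a 20×-objective
capture), line spacing 50 µm — dense enough for stable estimates, sparse
enough that adjacent lines are weakly correlated. All are parameters.
Field placement is a systematic lattice with seeded random offset;
candidate fields intersecting the exclusion mask (bronchioles, vessels
over 50 µm, non-airway structures — supplied as a mask, never detected
automatically) are dropped, and up to ten lattice offsets are tried before
the section is declared short of clean fields (a warning) or unusable (an
error).

Exactness guarantees: at one-pixel line spacing on a whole mask the chord
multiset equals an independent run-length scan exactly; doubling the pixel
size doubles every chord exactly; a parallel-septa grating with period P
and septum width S yields horizontal chords of exactly P − S.

## Leukocyte focus counting

Foci are connected components of the graph linking cell centroids closer
than a linking radius, implemented with a KD-tree plus sparse connected
components; a component is a focus only if it has **at least 21** members
(the strict "more than 20 cells" rule). The 25 µm default radius is about
two leukocyte diameters; it is an operational reconstruction of visual
scoring — no published proximity rule exists — and is exposed everywhere
as a parameter. Densities are n_foci × 20 / area_mm², and a subject's
value is the mean over its sections.

## CT densitometry

HU calibration is the standard two-point affine map: measured water mean →
0 HU, measured air mean → −1000 HU, then a clamp to [−1000, 1000]
mirroring reconstruction limits. Water-only calibration (as done on the
scanner) fixes one anchor; the air anchor is the HU definition itself.
The map is exactly invariant to any affine distortion of raw intensities
provided the references are re-measured on the distorted data — this is a
property test.

Mean lung HU is the arithmetic mean over the supplied VOI, optionally
intersected with a parenchyma window, default [−900, −100] HU, which
drops bone/soft tissue (> −100) and trachea-like pure air (< −900). The
published analyses do not state whether their mean used a threshold; both
modes are provided (`lung_window=None` uses the full VOI). The VOI is an
input mask; anatomical landmarking is out of scope.

Longitudinal series are summarized as percent change on the **raw signed
values**: for a lung moving from −357 to −399.1 HU the change is +11.8%,
because the baseline is negative. This convention is deliberate and
prominent; magnitude-based alternatives flip the sign.

## T2 ratios

Lung and kidney region means are normalized by the arm-muscle mean in the
same slice. The ratio cancels global scanner gain exactly (another
property test). An empty muscle ROI is an error; a missing kidney ROI
yields an absent kidney ratio, not zero.

## Exact nonparametric statistics

All tests condition on the observed midrank pattern and enumerate the
permutation distribution:

* Mann–Whitney: all C(n₁+n₂, n₁) rank assignments for pooled n ≤ 20;
  two-sided p = min(1, 2 × smaller tail), the convention used by common
  biostatistics packages — under complete separation p = 2/C(n₁+n₂, n₁).
  Larger samples use the normal approximation with tie and continuity
  corrections (cross-checked against scipy).
* Wilcoxon signed-rank: zero differences dropped, then all 2ⁿ sign
  patterns via a generating-function convolution over doubled (integer)
  midranks, exact for n ≤ 20.
* Kruskal–Wallis: tie-corrected H with a χ²(k−1) reference; exact label
  enumeration for pooled n ≤ 10.
* Spearman: Pearson correlation of midranks; exact permutation p for
  n ≤ 9 (all n! permutations), Student-t approximation otherwise.

A consequence worth knowing: the two-sided exact Mann–Whitney test at
n = 5 v 5 only attains p-values of the form 2k/252, so its true type-I
error at α = .05 is exactly 8/252 ≈ 0.032 — conservative. A one-sided
test at the same α would reject at rate 12/252 ≈ 0.048. The package's
null-simulation test documents the two-sided behavior.

No multiplicity correction is applied anywhere, matching the analysis
style the package reproduces.

## Synthetic data: what it emulates, and what it does not

**Alveolar sections.** The foam morphology is a Voronoi tessellation of a
Poisson point process whose cell boundaries are dilated to the septal
thickness; emphysema removes a fraction f of the shared walls. Removal
follows a single seeded permutation of the wall list, so the removed sets
are nested in f and the true mean chord is strictly increasing in f at
fixed seed. Walls are removed individually (the two cells are *not*
transitively merged): merging percolates at moderate f and produces
implausible giant airspaces, whereas individual removal at f = 0.15 gives
roughly the +16–20% Lm shift seen in smoke-exposed animals. The true mean
chord of a foam has no closed form; it is established by an exhaustive
one-pixel chord scan of the whole mask with the same border and
minimum-length rules as the estimator. Defaults: 55 µm seed spacing, 8 µm
septa, 2 µm pixels — mouse-lung scale at 20×. Masks are noise-free binary
by design: segmentation of stained slides is upstream of this package's
boundary, so a green test establishes estimator correctness, not
robustness to segmentation error.

**Leukocyte patterns.** Each focus is a disc of radius 50 µm holding ≥ 21
cells, resampled until internally connected at the detector's default
25 µm linking radius; focus centers keep mutual gaps of several linking
radii and background cells (default 0.5/mm², far below chaining density)
are excluded from a margin around foci. Recovery of the injected count is
therefore a generator postcondition, and the recovery test validates the
detector, not placement luck. Real infiltrates are not disc-shaped and do
sit near vessels; none of that is modeled.

**CT volumes.** A true-HU phantom (water 0, air −1000, lung at the chosen
level, body +40) is pushed through a hidden affine gain (0.5–2) and
offset (±200), seeded, so calibration is a real, exactly invertible step.
Noise is additive Gaussian in HU units. No beam hardening, rings, gating
or anatomy. The single integer label map encodes the VOI as code 6
*inside* the lung (lung = codes {1, 6}), since one code per voxel cannot
express overlapping regions.

**MR slices.** Flat-intensity ROIs (lung, kidney, muscle) plus Gaussian
noise; nothing of RARE contrast physics is simulated — the target of the
tests is the ratio arithmetic, not the sequence.

**Study generator.** Default design mirrors a three-cohort smoke-exposure
study: control (n = 4), smoke-exposed (n = 5), smoke + macrolide (n = 5);
3 sections/subject, 5 fields/section, scans at weeks 0, 6, 8, 10, 12.
Group effect levels sit at the published medians (focus densities
1.1/10.98/5.147 per 20 mm²; week-12 lung HU −384.9/−399.5/−377.3; a
~27% T2 elevation in the smoke group; Lm scale 1.2 for smoke, 0.95 for
treated). Between-subject variability is *not* reported anywhere for these
cohorts; CVs of 3–5% (and 4 HU between subjects) were chosen once so that
n = 4–5 group separations are achievable, and are not tuned further. A
per-subject latent severity couples Lm upward, lung HU downward and T2
upward (coupling 0.7), giving the cross-modality correlation panel a known
sign. HU trajectories interpolate linearly through the week-0 and week-6
anchors. Everything is written as plain TIFF/CSV/NIfTI plus a manifest,
and identical (design, seed) reproduce the tree byte-for-byte.

## Numerical and degenerate-input decisions

* Seeds: every generator and the field sampler accept a seed;
  sub-streams derive from `SeedSequence` spawn keys, so adding a subject
  never perturbs another subject's data.
* Ties: midranks everywhere; enumeration tails use an absolute tolerance
  of 1e-9 when comparing permutation statistics to the observed one.
* All-identical two-group data: p = 1 with a `degenerate` flag, never a
  division by zero. Zero-variance Spearman input: `undefined` flag.
* |rho| = 1 beyond the exact-n range: the t approximation degenerates;
  the no-tie permutation value 2/n! is substituted.
* Tissue-only fields are dropped from Lm averages; an all-tissue subject
  is flagged, not raised, so one solid section cannot abort a cohort run.
* The estimator facades (`LinearInterceptEstimator`, `FocusDetector`,
  `HUCalibrator`) follow scikit-learn conventions (constructor parameters,
  fitted attributes with trailing underscores, `fit`/`transform`/
  `fit_predict`) so they compose with sklearn tooling; the module-level
  functions wrap them.

## Known limitations

* Lm is computed on air runs only; tissue-intercept variants and
  shrinkage corrections are not implemented.
* The focus definition is a geometric reconstruction of a visual count;
  concordance with human scoring on real slides is untested here.
* The synthetic cohorts cannot validate biology — only that each
  measurement recovers what the generator put in, at the stated noise.
* Exact enumeration is O(C(n, n₁)); beyond pooled n = 20 the tests switch
  to approximations without warning beyond the `exact=False` flag.
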