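# Methods

## Model

Let a cohort of lesions be reduced to centroid points in a common template
space, and let a label atlas partition the template's foreground into k
regions (possibly merged groups of finer labels).  Under the null
hypothesis that every foreground voxel carries equal metastatic risk, the
number of lesions falling in region g is Binomial(n, p0(g)) with

    p0(g) = V(g) / Σ V(g'),

where V(g) is the region's volume and n the number of lesions assigned to
any tested region.  The observed proportion p(g) = count(g)/n is compared to
p0(g) with the one-sample proportion z-statistic

    Z = (p − p0) / sqrt(p0 (1 − p0) / n),

two-tailed P = 2(1 − Φ(|Z|)), and Bonferroni control of family-wise error:
significance at P ≤ α/k.  Regions significant with Z > 0 are called HIGHER
risk, with Z < 0 LOWER.

Assumptions worth making explicit:

- **Independence across lesions.** Multiple lesions from one patient are
  treated as independent draws.  Cohorts in this literature average ~5
  lesions per patient, so the effective sample size is somewhat smaller than
  n; P-values are anti-conservative to that extent.
- **No spatial correlation beyond region membership**; the multinomial null
  is exact only for point centroids, and a centroid is a point regardless of
  lesion size.
- **Normal approximation.** The z-test is a large-sample approximation to
  the binomial.  Results carry `approximation_warning=True` when
  n·p0 < 5 or n·(1−p0) < 5; `exact_binomial_p` / `risk_table(exact=True)`
  provide the exact two-sided binomial P (minimum-likelihood definition) for
  those regions.  No continuity or finite-population correction is applied,
  because the plain statistic is the one used throughout this literature.

### Choice of n

n is the number of lesions assigned to tested regions, not the cohort
total: lesion centroids can fall in unlabeled tissue (background, CSF) and
are excluded from both numerator and denominator.  The packaged reference
cohort has 1,033 lesions of which 1,026 are inside the coarse parcellation;
its printed observed rates are consistent only with n = 1,026.

### Multiplicity family k

`k_rois` defaults to the number of tested groups.  It is overridable
because published analyses sometimes correct across a larger family than
one table shows (the reference cohort corrects across 53 ROIs spanning two
atlases plus manual structures, giving the threshold 0.05/53 ≈ 9.434e-4).
The composition of such a family is configuration, not something the
package can derive.

## Pipeline geometry

- **Coordinates.** World coordinates are mm in the template's native
  orientation (RAS assumed); voxel indices are 0-based; the voxel-to-world
  map is the NIfTI affine.  Plain-text 4×4 transforms are world-mm →
  world-mm; scaled-voxel dialects (FLIRT `.mat`) must be converted upstream.
- **Mask resampling** is pull/backward: each candidate target voxel center
  is inverse-mapped and takes the occupancy of its nearest source voxel
  (half-away-from-zero rounding).  Pull resampling cannot introduce holes.
  A transform that leaves zero occupied target voxels raises a degenerate-
  result error rather than returning an empty mask.
- **Centroids** are unweighted means of occupied voxel centers, computed
  *after* transformation (the alternative — transforming native-space
  centroids — differs sub-voxel; one order had to be fixed).
- **Assignment** is nearest-voxel: round the centroid's continuous voxel
  coordinate per axis (halves away from zero); background or out-of-bounds
  → UNASSIGNED, a valid outcome counted separately.  An optional snap mode
  (`snap_radius_mm` > 0) reassigns background centroids to the nearest
  labeled voxel within a radius; it is off by default because the default
  rule is what reproduces published unassigned counts without inventing a
  radius.
- **A lesion is a label, not a connected component** (manual delineations
  may be deliberately disconnected); per-label connected-component
  splitting is available behind a flag.
- **Frequency map**: closed-ball membership on voxel centers (distance ≤
  diameter/2, default 20 mm), counts accumulated over lesions.
- **Risk map**: every voxel of a region carries the region's z; background
  is NaN (z = 0 is a legal value, so 0 cannot mark background).

## Synthetic data

The generator instantiates the per-voxel equal-risk null and perturbs it
with per-group risk multipliers: lesion centers are drawn categorically
over foreground voxels with weight proportional to the group multiplier,
and masks are digital balls around the centers.  Sampling per voxel (rather
than per region, then uniformly within) makes hit probabilities exactly
volume-proportional under the null for any region shape.

Atlas primitives are boxes and ellipsoids with closed-form volumes;
`make_slab_atlas` builds whole-voxel slab partitions whose volume fractions
are exact, which the calibration studies use so that expected rates carry
no digitization error.  Digitized ellipsoid volumes agree with 4/3·π·abc to
within ~2% when the smallest semi-axis spans ≳10 voxels.

What the generator does **not** emulate: anatomy-shaped regions, MRI
intensities, segmentation error, registration error beyond the affine
family tested, or within-patient clustering of lesions.  Green synthetic
tests therefore validate the *computational* pipeline and the *statistical*
calibration, not robustness to real-world delineation or registration
noise.

## Study conditions used by tests and the acceptance script

- **Regression**: the packaged published tables (10 coarse regions,
  n = 1,026, k = 53; 22 printed fine-parcellation rows).  Recomputed
  z-scores match printed values within |Δz| ≤ 0.02 except two rows whose
  printed cells are internally inconsistent (tagged in the fixture: the
  precentral-gyrus expected rate, and the amygdala/Heschl z at two-decimal
  rate rounding); those are asserted as flagged discrepancies.
- **Null calibration**: 8 slab regions with volume fractions
  (.20, .15, .15, .15, .12, .10, .08, .05) — chosen so the exact binomial
  level of the nominal-5% z-test is within 0.4 percentage points of 5% for
  every region — n = 1,026 lesions per replicate, 2,000 multinomial
  replicates.  Per-region type-I error must sit within 3 Monte-Carlo SEs of
  0.05.
- **Recovery**: 25 equal slabs, two merged into a "hot" group (volume
  fraction 0.08) with multiplier 3.0; n = 2,000 lesions per replicate, 200
  replicates through the full voxel pipeline (sampling → centroids →
  assignment → testing).  The hot group must be flagged HIGHER in ≥ 95% of
  replicates with every other region flagged in ≤ 10%.
- **Geometry**: frequency maps checked voxel-for-voxel against brute-force
  distance enumeration on a 64³ grid; forward-then-inverse resampling of a
  digital ball over 100 random affines (±10° rotations, ±5 mm translations,
  ±5% scales) must return the centroid within 1 mm on a 1 mm grid.

These problem sizes keep the full suite and the acceptance script each
around half a minute on one CPU while leaving the replicate counts large
enough for the stated Monte-Carlo tolerances.

## Known limitations

- Orientation handling is the caller's job: inputs must already live on (or
  be mapped into) the template's axes; no header-based reorientation is
  attempted.
- Probabilistic atlases must be reduced to hard maximum-probability labels
  upstream.
- The proportion test ignores per-patient clustering and spatial
  autocorrelation; FDR or permutation alternatives are out of scope.
- TSV floats are written at 6 significant digits for byte-stable reruns;
  raster outputs keep native precision.
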