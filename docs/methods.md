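# Methods

## Coordinate model

The template grid has 13 × 13 holes at a 5 mm pitch; column letters A–M map to
x indices 0–12 left to right and row numbers 1–13 to y indices 0–12 (the
handedness of printed reports is not standardised; this package fixes one and
documents it here).  Each hole is sampled by two stacked 20 mm needles; z runs
cranio-caudally with z = 0 at the apical (India-inked) end of the apex needle,
apex covering [0, 20) mm and base [20, 40) mm as abutting, non-overlapping
intervals.  Coarse voxel (i, j, k) is the 5 × 5 × 1 mm block at
x ∈ [5i, 5i+5), y ∈ [5j, 5j+5), z ∈ [k, k+1); its centre
(5i+2.5, 5j+2.5, k+0.5) is the "grid site" where the recorded histology is
anchored.  The fine grid is the lattice of sample points at 0.5 mm steps
(130 × 130 × 80); with these spacings every coarse voxel centre is exactly a
fine lattice point, so "re-sampling at the template grid sites" is an exact
array lookup rather than an interpolation with its own error.

## Coarse map and CCL counting

Each core's cancer segments are painted into its (x, y) column; a z section is
labelled when a segment covers at least half of it (0.5 mm of a 1 mm voxel).
Two counting rules for discontinuous foci are implemented exactly as defined
clinically: *separate* (segments are the reported foci; CCL = Σ lengths) and
*cumulative* (a single segment from first-focus start to last-focus end).  The
merged cumulative segment needs a Gleason score, which reporting conventions
do not define; we assign primary = the pattern with the largest
focus-length-weighted abundance (each focus contributes its length to its
primary pattern; ties toward the higher grade) and secondary = the highest
other pattern present.  The longest single segment is kept alongside the
scalar CCL so both readings of "maximum CCL" (longest focus vs per-mode sum)
remain computable.

## Lesion delineation

Lesions are 26-connected components of cancer voxels in index space on the
anisotropic blocks — voxels sharing a face, edge or corner belong to one
lesion, and grade labels are ignored for connectivity (heterogeneity is a
per-lesion property assessed afterwards).  Ids are assigned in ascending order
of each component's lexicographically first voxel, making the labelling a pure
function of the voxel set.  Since cumulative counting only adds voxels inside
existing columns' gaps, its components can only merge: lesion counts under
cumulative CCL never exceed those under separate CCL.

## Fine reconstruction and the preservation constraint

For each Gleason pattern p ∈ {3, 4, 5} a binary indicator (1 where the voxel's
score contains p) and a cancer-presence indicator are trilinearly interpolated
from coarse voxel centres to the fine lattice (fields are 0 outside the
sampled support) and convolved with an isotropic Gaussian of standard
deviation σ (zero-padded boundaries, kernel truncated at 4σ, mass-conserving
away from the volume boundary).  A fine voxel "reads" pattern p when its
smoothed indicator is ≥ 0.5, and reads cancer when presence ≥ 0.5.

σ is the reconstruction's single free parameter.  It is tuned by bisection
(default tolerance 0.05 mm, search cap 5 mm = one grid pitch) to the *largest*
value for which re-sampling the smoothed fields at every sampled grid site
reproduces the recorded histology: (a) cancer/benign status, and (b) at
cancer sites, the set of patterns read equals the voxel's recorded score
patterns.  The unsmoothed interpolation interpolates its nodes, so σ = 0
always satisfies the constraint and the search is well defined; preservation
is treated as monotone in σ, which holds in practice because violations are
produced by cumulative mass displacement.  Choosing the largest preserving σ
(maximal smoothness subject to fidelity) is this package's reading of
"tuned"; an alternative check mode ("primary") validates only the argmax
pattern against the recorded primary.  The pattern-set mode is the default
because it is the only self-consistent one at σ = 0: a 3+4 voxel has both
indicators at 1, so an argmax with ties broken toward the higher grade would
reject the identity reconstruction.  Note the constraint is intrinsic as well
as relational: a thin lesion (a single 5 × 5 × 1 mm block is a 0.025 ml
lesion) caps σ at well under 1 mm on its own, because larger kernels erode
its peak below the 0.5 threshold — tuning therefore adapts per patient,
typically returning 0.9–1.1 mm for cohorts with small lesions and the full
cap for patients with no cancer.

## Virtual needles and hotspots

A virtual needle is the z column of the fine map at one sampling-plane
coordinate (0.5 mm pitch — the discordance distances of interest are not
multiples of the 5 mm template pitch, so the search runs on the fine plane).
Per lesion (fine voxels are attributed to the nearest coarse cancer voxel's
lesion, Euclidean in mm):

* **CCL on a track** integrates the 0.5-level set of the presence field with
  piecewise-linear sub-voxel crossings.  On indicator columns this equals
  0.5 mm × voxel count; on smoothed fields it varies continuously, which
  removes spurious 0.5 mm-quantisation plateaus that would otherwise create
  large artificial ties for the maximum and inflate hotspot sets.
* The **volume hotspot set** is all columns attaining the lesion's maximal
  CCL (to 10⁻⁶ mm); its representative z is the midpoint of the cancer run.
* The **grade hotspot set** is all columns whose track reads the lesion's
  maximal pattern; its representative z is the centroid of the maximal-grade
  voxels on the track.
* **Concordance** is set intersection, not representative-point equality: the
  clinical question is whether *a* needle at the maximum-CCL coordinate
  captures the maximum grade, and tie-breaking to single points would invent
  discordance.  For discordant lesions the 3-D hotspot distance is the
  minimal Euclidean distance between volume points (x, y, z_ccl) and grade
  points (x, y, z_grade).  Tertiary patterns recorded in foci are stored but
  excluded from hotspot grading by default.

Lesion volume is the coarse block count × 0.025 ml; all published volume
quantiles in this setting are multiples of 0.025 ml, identifying the block as
the volume quantum.

## Heterogeneity criteria and summaries

A lesion's composition is the set of Gleason scores over its coarse voxels.
Primary criterion ("grades"): heterogeneous iff more than one distinct ordered
score (3+4 vs 4+3 counts).  Secondary criterion ("score"): scores with equal
totals are identified (3+4 ≡ 4+3), so heterogeneity needs two distinct total
scores.  Score-heterogeneity implies grades-heterogeneity.  Homogeneous
lesions are inherently concordant; the per-lesion Gleason score tabulated in
summaries is the highest ordered score present (the tabulation rule is not
standardised; this one is conservative and recorded here).  Proportions carry
Wald 95% CIs with z = 1.96 exactly — the unique standard binomial interval
consistent with the conventional "k (p±h%)" table cells this mirrors — and
displayed percentages round half away from zero (percent to integer,
half-width to one decimal).  Quantiles use linear interpolation between order
statistics; the rule is recorded in summary metadata because printed IQRs
cannot discriminate quantile conventions.

## Synthetic cohorts: what they emulate, and what they do not

Ground truth is a fine-lattice pattern volume; sampling reads it along needle
tracks and reports contiguous cancer runs as foci with primary = most
abundant pattern in the run (ties toward the higher grade), secondary =
highest other pattern — the standard biopsy convention.  Run endpoints are
quantised at 0.25 mm.  Rebuilding the coarse map from sampled records
reproduces the truth's cancer status and pattern content at every grid site
(sampling invents no information), a tested invariant.

* **Lesions** are axis-aligned ellipsoids — the simplest geometry with a
  controllable hotspot offset; geometry enters the pipeline only through grid
  samples, so irregular real lesion shapes differ mainly in producing
  plateaued CCL profiles and larger hotspot sets.
* **Heterogeneous lesions** are single-pattern bodies with a spherical focus
  of the next grade.  In free-placement cohorts the focus radius is 3.6 mm
  (> 2.5·√2) so at least one template needle always samples it — otherwise a
  planted heterogeneous lesion could masquerade as homogeneous and bias
  planted rates; consequently heterogeneous lesions are drawn from the upper
  size range (0.6–4 ml) so the focus fits.  Real heterogeneity also rises
  with lesion size, but the correlation here is a construction, not an
  empirical calibration.
* **Mixed-score homogeneous lesions** (e.g. every core reading 3+4) put the
  secondary pattern in a mid-chord band sized per column (40% of the chord,
  at least one voxel; columns under 1.5 mm chord trimmed), so *every*
  possible core read returns exactly the planted score.  Lesions are confined
  to a single needle depth window so chords are never split across two cores
  (a split sub-run could read a partial score).  The focus z centre coincides
  with the lesion z centre: per-focus grading records which patterns a core
  contains, not where along the core, so an off-centre z position would be
  unrecoverable from the report format — a genuine limitation of core-level
  pathology that the generator makes explicit.
* **Discontinuous foci** are emulated at reporting level: with probability
  0.1 per eligible run (≥ 5 mm), a 1–3 mm central band is re-attributed to
  benign tissue, splitting the run into two foci only when both parts retain
  the run's full pattern set.  This exercises the separate-vs-cumulative
  logic without altering grade composition.
* **Cohort defaults** (94 patients, Poisson(2) lesions per patient, 24%
  heterogeneous, 23% of heterogeneous foci placed discordantly, per-patient
  elliptical gland footprints of ~40 sampled holes ≈ 80 cores): chosen once
  to match the scale and rates of the pilot-cohort setting this pipeline
  addresses.  Lesion volumes are log-uniform on 0.03–4 ml, bracketing the
  clinically observed range rather than matching its (unpublished) shape; the
  synthetic volume median is therefore larger than typical clinical medians,
  and planted discordant distances (focus offsets 6.6–11.6 mm minus the
  footprint radius) are somewhat shorter than clinically reported medians.
  Passing tests on these cohorts show the *pipeline* recovers planted
  geometry and rates; they do not certify the clinical numbers themselves.
* **Phantom cohorts** for hotspot-recovery scoring are grid-aligned: lesion
  centre and focus centre sit exactly on template holes (offsets 0/5/10/15 mm,
  multiples of the pitch), the lesion straddles z = 20 mm so both needle
  depths sample the focus, and the focus radius is 2.5 mm (half the pitch) so
  exactly one hole samples it and the reconstructed grade footprint's
  0.5-level edge falls at the planted boundary.  The closed-form truth
  separation is max(0, offset − r_focus).  Grid alignment isolates
  reconstruction error from sampling-phase error; free-placement cohorts
  carry the additional ±half-pitch quantisation real lesions would.

## Numerical choices and degenerate inputs

Bisection tolerance 0.05 mm on σ; kernel truncation 4σ; painting threshold
exactly half a voxel (≥ 0.5 − 10⁻⁹ mm to absorb float error); argmax ties in
the fallback fine label volume break toward the higher grade (conservative
for hotspot grading); hotspot CCL ties within 10⁻⁶ mm join the maximum set.
All-benign patients yield zero lesions, empty reports and σ = σ_max (nothing
constrains smoothing); empty record lists yield an all-`no_tissue` map.
Cohort generation, sampling and the CLI are deterministic given their seeds.

## Problem sizes used by the test and acceptance runs

The shipped suites use a 20-patient cohort for preservation/monotonicity
properties, 50 phantoms per offset for hotspot recovery, 1000 random
10 × 10 × 10 maps for the connectivity oracle, and a 94-patient cohort plus
25 phantoms per offset in `scripts/acceptance.py` — sizes chosen to keep a
full from-scratch reproduction in the minutes range on one core while leaving
binomial error well inside the tested margins.

## Known limitations

Cores are assumed exactly on their nominal grid (no deformation, registration
or needle-placement error); lesion clustering knows only 26-connectivity
(adjacent but clonally independent tumours merge); tertiary patterns do not
enter hotspot grading by default; the synthetic generator models no clinical
covariates (PSA, age) and no imaging; and multi-needle targeting yield is out
of scope.
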