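# Methods

`lesionmap` implements a lesion–outcome analysis pipeline for temporal lobe
epilepsy (TLE) surgery cohorts. The question it serves is whether the spatial
pattern of a surgical resection — in particular the resected fraction of
specific mesiotemporal structures such as the piriform cortex subregions,
hippocampus, amygdala and entorhinal cortex — is associated with complete
postoperative seizure freedom (ILAE class I) as opposed to any persisting
seizures or auras (classes II–VI). Because clinical MRI cohorts of this kind
are not redistributable, the package ships a synthetic cohort generator that
reproduces the statistical structure the analyses assume, including an exact
null, so every inferential guarantee can be demonstrated end to end.

## Data model

All volumes — pre/postoperative T1-like images, integer atlas labels, binary
resection masks — live on one shared voxel grid with a common world affine
(NIfTI-1 on disk; masks as uint8, labels as int32). Registration and brain
shift correction are deliberately out of scope: the generator emits
everything aligned, and real data are accepted whenever they arrive on a
common grid. The cohort table is a TSV with one row per subject
(`subject_id, sex, laterality, surgery, lesion, ilae_class,
follow_up_years, mask_path, pre_path, post_path`); the binary outcome is
`ilae_class == 1`.

## Synthetic cohorts

**Atlas.** `make_atlas` paints geometric parcels (ellipsoids/slabs) for ten
bilateral regions — three piriform subregions (frontal, anterior,
dorsotemporal), hippocampal head/body/tail, amygdala, entorhinal cortex,
temporal neocortex and white matter — on an even-first-dimension grid, and
mirrors the left hemisphere exactly, so the mid-sagittal plane falls between
voxel columns and left/right homologues have identical voxel counts. The
default grid is 48×56×48 at a nominal 2 mm spacing; a radius floor keeps
every region at ≥ 20 voxels down to 24³ grids. Small seeded jitter of parcel
centers and radii makes atlases vary across seeds without breaking symmetry.

**Resections.** `simulate_resection` grows a connected mask from a
mesiotemporal seed (the amygdala centroid, so spread runs anterior to
posterior) within a surgery-specific accessible territory: ATLR reaches the
temporal neocortex and frontal piriform, SAHE and tailored resections stay
mesial, lesionectomies are smaller still; white matter within a small
dilation margin bridges the parcels. Voxels are rank-ordered by distance
from the seed and the `extent` parameter is the retained distance quantile,
so a subject's masks are nested in extent and ATLR masks are larger than
SAHE masks in expectation at equal extent. The distance metric is randomly
anisotropic per subject (log-normal axis weights; `growth_anisotropy_sd`,
default σ = 0.35) and the seed jitters by ±2 voxels. This emulates
surgical variability in the direction of
spread and is load-bearing for the statistics: without it, a voxel's
resection status would be an almost deterministic function of surgery type
and overall volume, and no voxelwise signal could survive adjustment for
those covariates.

**Images.** `simulate_images` assigns each tissue a mean T1-like intensity
(white matter 110, grey structures 80, background 15 in arbitrary units),
subtracts a cavity `drop` (default 40) inside the resection mask, and adds
independent Gaussian noise (default `noise_sd = drop/8 = 5`) to the pre and
post images. In the noise-free limit the voxelwise difference equals the
drop exactly on resected voxels — the delineation stage is provably exact
there.

**Outcomes.** `simulate_outcomes` draws ILAE class 1 vs 2 from a logistic
model: logit P(ILAE I) = intercept + Σ region effects + Σ covariate effects.
Region effects are per unit fraction resected, or — with
`region_threshold` set — per the binary split `fraction > threshold`
(the log-odds contrast between subjects whose region was and was not
substantially resected). Covariates may enter as sex (female = 1), surgery
(ATLR = 1), lesion (HS = 1) and z-scored total resection volume. An
all-zero region-effect map is the exact global null: outcome independent of
resection topography. The default cohort configuration mirrors the
published validation cohort's margins (n = 305; 205 HS + ATLR; laterality
170 left / 135 right; seizure-free marginal 188/305), and a discovery-style
configuration (n = 28, 22 SAHE / 3 ATLR / 3 tailored, intercept
logit(12/28)) is provided for calibration studies. Extent distributions per
surgery are Beta laws (ATLR (5,3), SAHE (3,4), lesionectomy (3.5,4),
tailored (3,3.5)), chosen so that the amygdala and entorhinal cortex are
largely removed, the hippocampus partially (tail last), the temporal
piriform subregions variably, and the frontal piriform — outside mesial
reach — essentially never, the qualitative coverage ordering these
surgeries produce; no source cohort reports extent distributions, so these
are stated defaults, not fits.

Reproducibility: one master seed; each subject and operation derives an
independent substream by hashing `(master seed, subject id, operation)`, so
outputs do not depend on generation order, and regenerating a cohort with
the same config and seed reproduces the TSV byte for byte.

## Resection delineation

Pre and post images are rescaled so their within-brain median equals a
common target (default 100). A voxel becomes a resection candidate when its
normalized intensity drop `pre − post` exceeds a tissue-specific cutoff:
`wm_threshold` on white-matter parcels, `gm_threshold` elsewhere (defaults
both 20, i.e. half the default cavity drop). Background voxels are never
candidates, so masks stay within the labelled brain. Candidates are closed
morphologically (ball radius 1) and components below
`min_component_voxels = 10` are discarded — this cleanup replaces the
manual mask correction an interactive workflow would apply. A helper
proposes a cutoff as the midpoint between the two most prominent modes of
the smoothed within-brain difference histogram, for data where the drop is
unknown. Per-parcel mean intensities are tabulated for QC (empty parcels
are flagged, not dropped), and a per-subject QC row records candidate voxel
count, retained components and final volume in µl.

Exact recovery in the noise-free limit holds whenever the drop exceeds both
cutoffs *with cleanup disabled* (no closing, minimum component 1): closing
can add voxels at concavities of the true cavity, so the exactness claim and
test use the cleanup-free parameters. At the default noise level the
delineated masks agree with the simulated truth at Dice ≈ 0.99.

## Regional volumetrics

`percent_resected` is 100·|resection ∩ ROI|/|ROI| (empty ROIs are an
error). `RegionOutcomeModel` assembles, per subject, the ipsilateral
percent resected of a region family mirroring the published eight-test
design — frontal, dorsotemporal and anterior piriform, whole piriform,
hippocampus, entorhinal, amygdala, plus overall resection volume in µl —
and `fit` compares ILAE I vs II–VI groups per quantity with a permutation
t-test, correcting the family with Benjamini–Hochberg FDR (q = 0.05; the
family is exactly the set of quantities in one call, never implicit).

The permutation test permutes group labels and recomputes the two-sample
statistic — pooled-variance by default (this matches the √(1/n₁+1/n₂)
structure linking the published t and d columns), Welch optional. The
Monte-Carlo p uses the add-one convention p = (1 + #{|t\*| ≥ |t|})/(B + 1),
valid and never zero; ties count against rejection (a relative tolerance of
10⁻⁹ in the comparison makes tie handling robust to floating-point noise).
When C(n, n₁) ≤ B the test enumerates all relabelings instead; the
enumeration includes the identity assignment, so the smallest attainable
two-sided p is 3/(C(n, n₁)+1). Zero variance in both groups with equal
means yields t = 0, p = 1 rather than an error. Both Cohen's d (pooled-SD,
n₁+n₂−2 denominator) and the conversion d = t·√(1/n₁+1/n₂) are provided;
the published table is consistent with the conversion for six of its eight
rows and with neither formula for the remaining two, so the package exposes
both and leaves the discrepancy documented rather than resolved.

## Voxel-based lesion-outcome mapping

At every testable voxel, seizure freedom is regressed on that voxel's
resection status (0/1) plus covariates — sex, z-scored overall resection
volume, surgery type (ATLR vs other), lesion type (HS vs other) — by
maximum-likelihood logistic regression; constant covariate columns are
dropped with a warning. A voxel is testable when it is resected in at least
`min_per_cell` subjects and spared in at least as many (default 10); the
sources state no inclusion rule, so this one is explicit and configurable.
The Wald z map is thresholded two-sided at the cluster-forming p (default
0.001, z ≈ 3.29), supra-threshold voxels are grouped into sign-homogeneous
connected components (26-connectivity by default; 6 and 18 available —
connectivity changes cluster counts, hence exposed), and each cluster's
mass is the sum of |z| over its voxels (the simpler of the two common mass
definitions; excess mass above threshold is not used). Family-wise error is
controlled by permutation: the outcome vector is shuffled across subjects
(Manly-style; exact under exchangeability of outcomes, approximate when
covariates and outcome are dependent), the full model is refit at every
voxel, the largest cluster mass over both signs is recorded, and
p_FWE = (1 + #{max-mass\* ≥ mass})/(B + 1). OR maps are e^β.

Separation (e.g. a voxel resected exactly in the seizure-free subjects) is
flagged, not estimated: a fit that fails to converge or runs past |β| = 15
is excluded with a QC count, and contributes z = 0 during permutation.

Two pooling modes reproduce the published designs: `split_by_laterality`
analyses left- and right-operated subgroups separately;
`flip_and_pool` mirrors right-hemisphere masks across the mid-sagittal
voxel plane ((i,j,k) → (Nₓ−1−i,j,k); involutive, volume-preserving,
requires an even first dimension) and pools everyone in a single
left-hemisphere analysis, optionally restricted to hippocampal sclerosis.

### Numerical strategy

All per-voxel fits share the covariate block, so they are solved by one
batched damped-Newton routine (direction-preserving trust region of 4
log-odds units per step; coordinate-wise clipping is avoided because it can
cycle), warm-started from the covariate-only fit, with voxels sharing an
identical resection pattern fitted once. Observed maps are fit in float64
to tolerance 10⁻⁸. During permutation the routine first computes
closed-form efficient-score z statistics from the covariate-only fit and
gives the full Wald refit only to voxels whose |score z| reaches 85% of the
cluster-forming threshold; in these designs the Wald z never exceeds the
score z (Hauck–Donner shrinkage), so the screened null maxima are identical
to exhaustive refitting — the test suite asserts agreement with the
unscreened path (retained behind `screen=False`) to 10⁻⁹. A tiny ridge
(10⁻⁹ in float64) keeps the Newton system solvable under separation without
materially biasing estimates (the closed-form 2×2 agreement test at 10⁻⁶
bounds the effect).

## Calibration and recovery studies

The `calibration` module is the package's own evidence, shared by the test
suite and `scripts/acceptance.py`; the sizes below are the package's
standard desk-scale study sizes.

* **Type-I error, volumetrics** — 500 discovery-style null cohorts
  (n = 28), 1000 permutations each; the raw-p rejection fraction at
  α = 0.05 pooled over the family's non-degenerate tests (quantities
  constant in both groups yield the vacuous p = 1 and are not counted)
  should sit in [0.03, 0.07]. Measured: 0.054.
* **FWER, voxel mapping** — 200 null cohorts (n = 100, 32³ grid, mixed
  ATLR/lesionectomy), 500 permutations; the fraction of repetitions with
  any cluster at p_FWE ≤ 0.05 should sit in [0.02, 0.09]. Measured: 0.025.
* **Recovery** — 50 cohorts (n = 300, 32³ grid) with a −3 log-odds
  contrast for resecting more than half the posterior hippocampus
  (body + tail, ≈ 100 voxels), extents drawn from a U-shaped Beta(0.3, 0.3)
  emulating the selective-vs-extended dichotomy, and growth anisotropy
  raised to σ = 0.9 (strongly heterogeneous surgical trajectories, which
  decouple posterior coverage from overall volume — without this the
  volume covariate absorbs the voxelwise signal). Significant clusters
  (p_FWE ≤ 0.05, 250 permutations) should cover ≥ 50% of the planted
  region, and the hippocampus should attain the family's smallest raw p
  (ties at the permutation floor broken by |t|), each in ≥ 90% of runs.
  Measured: 0.98 and 1.00.
* **Delineation** — exact recovery noise-free; Dice ≥ 0.90 at the default
  noise (measured ≈ 0.996).

What passing these studies does and does not show: the generator produces
piecewise-constant tissue intensities, geometric parcels and
single-component cavities — no bias fields, no registration error, no
longitudinal brain shift, no anatomical variability beyond parcel jitter.
Calibration under this null therefore validates the *inference machinery*
(permutation validity, FWER control, oracle-exact components), not
robustness to real-MRI artifacts, which the out-of-scope preprocessing
(registration, bias correction, parcellation) would have to address.

## Degenerate inputs and conventions

Empty ROIs, single-class outcomes, all-zero atlases, invalid extents,
non-positive brain medians, rank-deficient designs (reported with the
collinear column names) and ILAE values outside 1–6 raise typed errors;
empty filter results and constant covariates warn. Voxel indices are
reported 0-based (ijk), world coordinates via the affine; 1 mm³ = 1 µl.
Percent values are stored at full precision and rounded only for display
(medians 1 dp, t and d 2 dp). All randomized outputs are fully determined
by (configuration, seed).

## Known limitations

The generator's resection geometry is convex-ish and single-seeded; real
cavities can be multifocal and registration-distorted. The permutation
scheme permutes outcomes, not residuals, so covariate-outcome dependence
makes FWER control approximate. The score-test screen's validity
(|Wald| ≤ |score|) is verified for binary predictors in these designs, not
proven universally; the exhaustive path exists for verification. Published
cohort-level medians and odds-ratio maps depend on non-redistributable
images and are out of reach by design — the package reproduces the
analysis machinery and its printed summary-statistic relationships, not
those cohort-specific values.
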