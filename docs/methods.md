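# Methods

This note documents the models, conventions and numerical choices behind
strucnet, in the spirit of the methods documentation of the established
simulation and statistics packages in this field.

## Node schema and data model

The default schema has 83 nodes: the 34 Desikan–Killiany cortical
parcels per hemisphere (68), seven subcortical gray structures per
hemisphere — thalamus, caudate, putamen, pallidum, hippocampus,
amygdala, accumbens — (14), and the brainstem. Node order is fixed by
the schema and never inferred from file headers: every permutation-based
procedure in the package relies on subject matrices being aligned
row-for-row. Connectome matrices are dense (83×83 is small), symmetric,
zero-diagonal and integer; violations are rejected at construction.
Synthetic studies at other sizes use a generic schema whose first half
of nodes is labeled left-hemisphere and second half right.

## Synthetic cohort generator

The generator defines the study conditions under which the pipeline is
validated; it emulates a two-group diffusion-MRI connectome study, not
the MRI physics.

*Template.* A single mean-NOS template per cohort. The binary topology
is a stochastic block model: nodes within a hemisphere are split into
contiguous ~12-node modules; the connection-probability ratio
within-module : within-hemisphere : cross-hemisphere is 1 : 0.35 : 0.12
with an additional exp(−0.3·d) decay in module distance, rescaled to hit
the requested mean density and resampled until the graph is connected
and within 10% relative of the target density. This topology places the
resulting weighted graphs in the small-world regime (γ > 1, λ ≈ 1), as
observed for real structural connectomes. Edge means are lognormal with
default (μ, σ) = (5.0, 0.8) — median ≈ 150 streamlines, central 95%
range ≈ 30–700 — matching the tens-to-hundreds NOS scale of reported
connectome edge tables.

*Subjects.* Each subject's matrix is round(template ⊙ ε) with
independent lognormal multipliers ε of mean exactly 1 (μ = −σ²/2) and
coefficient of variation 0.5. Reported control-group NOS dispersions in
comparable studies have sd/mean between roughly 0.4 and 1.1 with a
median near 0.6; cv = 0.5 reproduces edge-level t statistics of 3–4 for
a 37% group deficit at n ≈ 41/42, the regime of interest. Rounding is
round-half-to-even; negatives are clipped to zero, so every generated
NOS is a nonnegative integer. With a zero effect the two groups are
exchangeable draws by construction.

*Planted effect.* A multiplicative deficit (1 − δ) on a connected edge
set in the case group, default δ = 0.37 on seven edges over seven
left-hemisphere nodes (medial orbitofrontal cortex, putamen, pallidum,
amygdala, entorhinal cortex, insula, temporal pole) — a realistic shape
for a focal structural deficit. An optional larger deficit for
"medicated" cases supports subgroup analyses. Default group sizes are
41/42 with a 29/41 medicated fraction.

*Clinical scores.* Y-BOCS (total, obsession, compulsion), OCI-R and BDI
are normal draws at typical moderately-ill OCD means and s.d., clipped
to instrument bounds (Y-BOCS total further clipped to the 15–36 range of
a case cohort). With `association='linear'` each score is
r·z(feature) + √(1−r²)·noise on the standardized per-subject mean NOS
over the planted edges, giving population correlation r (slightly
attenuated by clipping).

*What the generator does not model:* spatial autocorrelation between
edges, site/scanner effects, age/sex covariates, volume–NOS coupling,
and registration or tracking artifacts. Passing tests therefore
establish the statistical machinery (error control, recovery, metric
correctness), not robustness to those real-data complications.

## Tractography

The tensor fit is ordinary log-linear least squares of
ln S = ln S₀ − b gᵀDg, requiring one b=0 volume and ≥6 non-collinear
gradients; voxels with any non-positive signal are invalidated (FA = 0).
FA uses the normalized-variance eigenvalue formula; the principal
direction is the leading eigenvector.

Tracking is a voxel-grid FACT scheme. Seeds lie on a fixed centered
sub-voxel lattice (8 seeds = the 2×2×2 ±0.25 grid; the lattice doubles
one axis at a time, so doubling seeds exactly doubles every streamline
count on a deterministic field). Each seed is grown bidirectionally; a
step moves one voxel length along the current voxel's principal
direction *from the voxel center*, so propagation is a deterministic
function of the voxel sequence and sub-voxel seed position contributes
multiplicity only. Eigenvector sign is axial: at each step the
orientation forming the acute angle with the incoming direction is used,
and the angle criterion compares |cos| against cos(45°) with a 1e-12
slack so an exact-threshold angle does not terminate. Termination checks
at the prospective next voxel, in order: grid exit, parcel label
(reached_label), mask exit, FA < 0.1, angle > 45°. Streamline endpoints
claim the first labeled voxel they enter; a streamline contributes one
NOS count when its two endpoints lie in distinct parcels.

Phantoms provide ground truth: a straight high-FA (0.7) bundle joining
two end parcels; the same bundle interrupted by an FA = 0.05 slab; two
orthogonal non-interacting bundles in separate slabs; and a "curved"
bundle whose direction field alternates ±turn/2 about the bundle axis so
the inter-voxel axial angle equals the configured turn everywhere — below
45° streamlines pass through, above it every streamline stops at its
first step by the angle rule. (A progressively rotating field cannot
produce the all-angle behavior: voxels with near-transverse directions
would exit the mask before violating the angle criterion.)

## Thresholding

"Present" means weight > 0 after pruning — existence, never magnitude.
The τ comparison count/n ≥ τ is evaluated in exact rational arithmetic
(τ parsed through its decimal string, so 0.6 is exactly 3/5 and an edge
present in 6 of 10 subjects is retained). The two-step variant zeroes
sub-threshold edges within each group first and recomputes presence on
that output for the pooled step; reading the two steps sequentially is
the default, with `step2_on='raw'` exposing the alternative (the
published descriptions are ambiguous on this point). Masks are monotone
across the sweep: the keep set at a higher τ is always a subset of the
keep set at a lower τ.

## NBS

Pooled-variance t (not Welch), df = n₁ + n₂ − 2, matching the canonical
NBS formulation; zero-variance edges get t = 0 with a warning and can
never enter a component. Contrasts are one-sided per direction by
default (a two-sided mode halves the primary p per tail). Component size
is edge count (extent); the intensity variant is out of scope. The
p-value estimator (1 + k)/(1 + K) includes the observed labeling so p
never reaches zero and is exact-level conservative. When the number of
distinct group relabelings is ≤ K the null is enumerated exhaustively
(identity included) with a warning. The permutation engine computes all
edge t statistics per shuffle with one matrix product per block of 250
permutations and extracts the max component by union-find over the (few)
suprathreshold edges, which keeps 500-permutation runs at the 83-node
scale near 0.1 s.

## Graph metrics and null models

Onnela clustering with global max-weight normalization is the common
toolbox convention for weighted undirected clustering; it is invariant
to uniform weight rescaling. The length transform is 1/w (standard for
streamline-count networks), so uniform rescaling w → cw scales distances
by 1/c and leaves λ invariant. Unreachable pairs are excluded from
path-length means with a loud warning naming their count — a
degenerate-input policy, since thresholded networks are expected to be
connected; a graph with no edges is an error. Degree-preserving
randomization performs 10 double-edge swap attempts per edge
(Maslov–Sneppen), with weights traveling on their edges, so both the
binary degree sequence and the weight multiset are preserved exactly. γ
and λ normalize by ensemble means over (by default) 1000 such networks.

## Group statistics

Permutation tests use the difference of group means, two-sided, with the
(1 + k)/(1 + K) estimator, switching to exhaustive enumeration when all
relabelings number at most K. FDR is Benjamini–Hochberg, applied within
each metric family across the 83 nodes (strength, clustering, path
length are separate families); the four global metrics are standalone
tests. Correlations default to Pearson with Spearman by flag;
zero-variance features are skipped with a warning and the FDR family is
all (feature, score) pairs.

## Pipeline

One top-level seed spawns independent per-stage seeds through numpy's
SeedSequence, so stage results are reproducible individually and
end-to-end runs are bit-identical given config + seed. Stage failures
abort with the stage name. The report lists each significant component's
edges with per-group mean ± s.d. and t, the metric comparison and
correlation tables, the sweep table (one row per τ), and the full
configuration with its digest.

## Problem sizes used in validation

The test suite and acceptance script size their simulations to run on a
single CPU in tens of seconds while keeping the reference design where
it matters: false-positive-rate estimation uses 200 exchangeable
41/42-subject cohorts at 500 permutations; planted-effect recovery uses
25 replicates at 1000 permutations; null-model checks use 100–150 random
networks instead of the 1000 a production analysis would use (the
ensemble mean is stable to ~1% at that size); oracle comparisons use
graphs of ≤ 12 nodes where brute-force enumeration is exact.

## Known limitations

The tracker is a voxel-level FACT simplification (center-to-center
steps, no sub-voxel interpolation) intended for validated synthetic
fields, not raw scanner data; robust tensor fitting, eddy/motion
correction and probabilistic tractography are out of scope. The
generator's independence assumptions make its null conservative relative
to spatially correlated real data. FDR family choices (per metric vs
pooled) and the NBS p-value and sidedness conventions are documented
defaults, configurable where the literature is ambiguous.
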