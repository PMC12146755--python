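# Methods

This note documents the models, estimators and numerical conventions
behind `spanflex`, the design choices that were genuinely open, and what
the synthetic-data generator does and does not emulate.

## Containers and units

All coordinates are stored in Angstrom (the PDB native unit); every
reported spacing and dispersion is converted to nanometres at the
reporting boundary, and angles are reported in degrees. A
`WeightedEnsemble` holds states in weight-table order with weights
renormalized to sum to 1 (renormalization is idempotent; raw MultiFoXS-style
weights are accepted). Weight tables are two columns (label, weight),
tab- or comma-separated, with `#` comments. A multi-model PDB maps
MODEL/ENDMDL records to states in file order, keyed by model number; a
list of single-model files is keyed by file stem.

## Weighted quantiles

The weighted median and quartiles interpolate linearly between the
midpoints of consecutive cumulative-weight spans: sort values, give value
v_k the span (c_{k-1}, c_k] of the cumulative weight, and evaluate the
piecewise-linear function through the points (c_k − w_k/2, v_k), clamped
at the extremes. This estimator reproduces the two anchor cases any
definition must satisfy — a single value is every quantile of itself, and
two equal-weight values 1 and 3 have median 2 — and is continuous in the
quantile level. Duplicating every state with halved weights moves the
interpolation knots slightly, so quantiles are estimator-level (not
bit-exact) invariant under aggregation; the RMS dispersion metrics below
are exactly invariant.

## Superposition and spacings

States are superposed by the Kabsch algorithm (SVD of the cross-covariance,
determinant-corrected to a proper rotation) fitting each state's reference
selection onto the **first** state's reference selection. The first state
— the first row of the weight table — is a deterministic, documented
target; order invariance holds for all order-free statistics. Fewer than
3 reference atoms, or a collinear reference, raises a rank error because
the rotation is under-determined.

Landmark spacings are centroid-to-centroid Euclidean distances. The
paratope tip defaults to the annotated CDR3-apex residue's Cα; membrane
anchors default to the Cα atoms of the last three ordered residues of the
annotated chain (three residues damp terminal disorder). Both are plain
selection expressions (`CHAIN[:RES-RANGE[:ATOM]]`, comma-separated unions),
so single-atom or multi-atom landmark conventions are a configuration
choice, not code.

Tilt angles use the domain's longest principal axis (largest-eigenvalue
eigenvector of the positional covariance), folded to the acute angle
against the head→tail axis unit vector, because a principal axis is
parameter-free and sign-ambiguous. When the top two covariance eigenvalues
agree within 1% the axis is ill-defined: the state is flagged and a
warning emitted, but the (unstable) angle is still reported rather than
silently dropped.

## Flexibility metrics

All dispersion measures are weighted RMS quantities (they compose with the
analytic two-state checks: CoM displaced by d at equal weights gives d/2;
rotations of ±θ give θ):

- **CoM flex** (nm): √(Σᵢ wᵢ‖cᵢ − c̄‖²), cᵢ the mass-weighted center of the
  domain in state i and c̄ the weighted mean. Masses come from an element
  lookup; unknown elements fall back to carbon with a warning.
- **Rotational flex** (deg): each state's domain orientation relative to
  state 1 is extracted by a centered Kabsch fit; the mean orientation is
  the principal eigenvector of Σᵢ wᵢ qᵢqᵢᵀ over unit quaternions (the
  outer product is sign-invariant, so the double cover needs no special
  handling); the reported value is √(Σᵢ wᵢ θᵢ²) with θᵢ ∈ [0°, 180°] the
  geodesic angle from the mean.
- **Effective disorder** (nm·deg): the literal product CoM flex ×
  rotational flex, a single per-domain disorder score. A true Shannon
  entropy of the state weights, −Σ wᵢ ln wᵢ in nats ∈ [0, ln n], is
  computed by `weight_entropy` and always reported under that separate
  name; the two are never conflated.

Metrics are computed per domain plus a whole-molecule row (every atom as
one body), since either convention is defensible and reporting both costs
one extra row.

## Coarse-grained SAXS

The Debye engine uses uniform form factors f = 1 (one bead per Cα, or
every atom), sinc-summed over all pairs, with sinc(0) := 1 and
I(0) = n². There is no excluded-volume or hydration-layer term: the
package's claims are comparative (rigid vs flexible, mixture recovery),
not absolute-intensity parity with atomistic predictors, and the
simplification is what makes desk-scale oracle tests (closed-form two-bead
curve, naive double-loop sums) exact. Pairwise work is chunked over q to
bound memory.

The Guinier fit is an iteratively windowed linear fit of ln I vs q²:
fit, recompute the window from q·Rg ≤ qrg_max (default 1.3, the standard
data-analysis rule), refit until the window stabilizes; a window
oscillating between two sizes settles deterministically on the tighter
one, and a window below 5 points or a non-negative slope is an error.
Note the Guinier approximation itself is biased for compact globular
particles — for an ideal sphere the recovered Rg is ≈1.8% high at
qRg ≤ 1.3 and ≈1.1% high at qRg ≤ 1.0 — so the analytic-sphere validation
(Rg → √(3/5)·R) is run at qRg ≤ 1.0 while 1.3 remains the default for
data.

The dimensionless Kratky transform is x = qRg, y = x²·I(q)/I(0); an ideal
globular (Gaussian) curve peaks at (√3, 3/e) and a point scatterer gives
the flexible-limit parabola y = x². One caveat discovered while building
the generator: for an *extended* articulated molecule, increasing hinge
flexibility compacts the average conformation, which can lower the
dimensionless-Kratky amplitude even though disorder rose. The
flexibility-raises-amplitude signature is therefore exercised as the
textbook contrast (compact globular particle vs flexible chain ensemble),
and flexibility ranking between same-architecture ensembles is left to
the ensemble-model metrics above.

χ uses the closed-form optimal scale c = Σ(IₑIₘ/σ²)/Σ(Iₘ²/σ²) and the
1/M normalization (M = number of fitted points); only relative χ
comparisons are meaningful, so the convention is declared rather than
matched to any external code. Models are interpolated linearly in q onto
the experimental grid; fewer than 5 overlapping points is an error.
Missing experimental σ columns are imputed as 3% of I (configurable).

## Multistate selection

For each ensemble size N = 1..N_max (N_max ≤ 5, pool ≤ 50 — exhaustive
enumeration is the documented regime), every size-N subset is fitted and
the lowest-χ subset kept. Because the global scale and the normalized
weights enter the residual only through their products, the joint
nonnegative-weights-plus-scale problem is solved exactly by a single
nonnegative least squares on unnormalized coefficients (weights =
coefficients / sum, scale = sum); this is the fixed point the alternating
scheme would converge to, obtained in one step. Ties are broken
deterministically: smaller N, then lexicographic label order (subsets are
enumerated in that order and replacement requires strict improvement).

Subset recovery is only well-posed when pool members are mutually
distinguishable at the experimental noise level; `prune_pool` provides a
greedy max-min pruning by pairwise χ distinctness for building such pools,
and the size error on oversized pools points to it.

## Synapse-image statistics

Footprints are connected components above an Otsu (or fixed) threshold
with a minimum area in µm²; quantification is per component (one row per
contact, matching per-contact violin plots). Background is estimated
outside the union of all cell masks dilated by a configurable margin
(default 2 µm), which keeps the contact halo out of the background and
guarantees mask/background disjointness. Pearson correlation is the plain
sample correlation over mask pixels, requiring ≥10 pixels and nonconstant
channels — an undefined correlation is reported as missing, never coerced
to 0. Normalized levels are (mask mean − background mean)/reference
scale, where the reference scale is the batch median of the same raw
quantity over an explicitly declared reference condition; a global gain
applied to the whole batch therefore cancels. No deconvolution,
flat-field or bleed-through correction is applied.

## Synthetic-data generator

Templates are ordered rigid domains — rods (gentle helices whose end
beads sit on the axis and whose lateral pattern is mirror-symmetric in z,
so the principal axis coincides with the geometric axis) and blobs
(stratified Fibonacci balls) — of 2–7 domains with radii 1–3 nm, joined
by hinges. Per state and non-rigid joint, a hinge angle is drawn uniformly
in [−κ, +κ] and a twist over the joint's twist range; domains downstream
rotate rigidly about the hinge point. Raw uniform draws are scaled by the
joint limits, so ensembles at different κ share randomness for a given
seed and dispersion is deterministically monotone in κ. A κ override sets
both the hinge half-angle and the twist half-range to κ, making κ = 0 the
exact rigid limit. Weights are uniform or symmetric-Dirichlet. The
default engager-like preset has four domains (antigen · binder arm ·
hinge/Fc · second arm) with a rigid antigen–binder joint, mirroring the
convention of superposing on the antigen-arm complex; hinge half-angles
default to 40° (a moderately flexible hinge), and the stacked-domain
geometry lands anchor spacings in the 15–17 nm range typical of large
formats.

Generated coordinates are quantized to 0.001 Å — exactly the PDB
coordinate field precision — so the written multi-model PDB *is* the
ground truth and the simulate → write → read → measure round trip is
exact (≤1e-6 nm) rather than limited by format truncation.

SAXS experiments are weighted Debye mixtures with multiplicative Gaussian
noise σ(q) = noise_fraction·I(q); a noiseless curve writes the default 3%
imputed σ column so χ remains defined. Synapse images plant
non-overlapping circular contacts with a smooth radial enrichment;
`colocalized` shares the enrichment between channels, `segregated` splits
it into complementary angular sub-domains, and `excluded` depletes a
uniformly bright second channel inside the contact. Counts are Poisson
with peak signal snr², giving peak signal-to-noise ≈ snr.

What the generator does **not** emulate: linker energetics, sterics or
self-avoidance (states may clash), atomistic side chains and realistic
form factors, correlated SAXS noise, beamline q-range artifacts, optical
point-spread functions, bleed-through, or uneven illumination. Passing
tests therefore demonstrate correctness of the estimators and the
pipeline plumbing on idealized articulated data, not robustness to every
artifact of real beamline or microscope data.

## Problem sizes and determinism

The test suite and the acceptance script run on deliberately desk-scale
problems: ensembles of 100–200 states (~84 beads each), SAXS grids of
80–600 points, pools of 10 candidates from 30, images of 256²–512² pixels
with ≤10 contacts, and 20-seed replicate sweeps — sizes at which the
brute-force oracles (double-loop Debye sums, explicit quantile scans,
SVD cross-checks) are themselves fast. Every sampler takes an explicit
seed; identical inputs are bit-identical across runs, and
`scripts/acceptance.py` derives all its sub-seeds from the single `--seed`
argument.

## Known limitations

- Selection expressions are chain/residue/atom-name based; no automatic
  chain or domain inference from sequence, and no mmCIF reading.
- The Debye engine's absolute intensities are not comparable to
  hydration-aware predictors; only relative/comparative use is supported.
- Tilt angles assume the domain has a well-defined long axis; the 1%
  eigenvalue-gap flag is a heuristic.
- Exhaustive subset selection scales combinatorially; pools beyond 50
  members must be pruned first.
- Per-contact image statistics assume 2D TIRF-like data; no 3D stacks,
  tracking, or phenotype classification.
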