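# Methods

This note documents the models implemented in `kernem`, the choices made
where the design was genuinely open, and what the synthetic experiments do
and do not demonstrate.

## Emission model and projector

Data are modelled as independent Poisson counts per line of response (LOR):
`y_i ~ Poisson([P λ]_i + s_i)`, with `λ` the activity image, `P` the system
model and `s` an additive expectation for scatter and randoms. The
projector is a 2-D parallel-beam discrete Radon transform assembled once as
a sparse matrix: each voxel centre is projected onto the radial axis of
each angle and deposited into the two neighbouring bins with linear
interpolation weights. Scanner resolution is an isotropic Gaussian
(default FWHM 4.4 mm, FWHM = 2√(2 ln 2)·σ) applied in **image space**
inside the projector; the adjoint applies the same blur after
back-projection. Because the blur uses zero-padding (a symmetric operator)
and the geometric part is an explicit matrix, `back_project` is the exact
adjoint of `forward_project` — the inner-product identity holds to ~1e-15
and is enforced at 1e-6 in the tests, since every EM convergence argument
relies on it. A sinogram-space resolution model was considered and
rejected: the image-space form keeps the adjoint exact and is the common
practical choice.

Attenuation can be supplied as a per-voxel linear-attenuation map and is
applied as a multiplicative sinogram factor `exp(-∫μ)`; it is off by
default because the simulation study needs only a self-consistent model,
not vendor-grade corrections.

Ordered subsets partition the angles with stride `n_subsets`
(interleaving maximises angular coverage per subset); the subsets are
disjoint, balanced and cover all angles.

`simulate_counts` rescales the noiseless projection of the ground truth so
its total equals `total_counts`, adds the additive term (default: a flat
sinogram carrying 30% of the true counts), and draws Poisson counts with a
caller-supplied seed. Expected total counts are therefore
`total_counts + sum(additive)` by construction.

## Kernel representation

The activity is expanded as `λ_j = Σ_f k_jf α_f` over a sparse
neighbourhood. For every voxel, candidates are the voxels in a square
window of half-width `max(patch_radius, 1)` (configurable); the
`n_neighbors` candidates with the nearest patch features are kept, the
centre voxel always included, ties broken by voxel index so the operator
is fully deterministic. Features are the `(2r+1)²` patch intensities
divided by the image's global standard deviation; this normalisation makes
the intensity scales σ_m, σ_p (default 0.1) meaningful across images of
arbitrary dynamic range. The anatomical weight is the product of an
intensity Gaussian (σ_m) and a spatial Gaussian (σ_dm, voxel units,
default 3); the functional kernel repeats the construction on the current
coefficient iterate (σ_p, σ_dp) over the *same* sparsity pattern, and the
hybrid kernel is the elementwise product. Defaults (n = 3, σ_m = σ_p =
0.1, σ_dm = σ_dp = 3, patch radius 1) follow the most frequently optimal
values reported for this algorithm family on patient data; all are plain
configuration.

Two conventions are not settled in the literature and are explicit
options here:

- **Row normalisation** (default on): each kernel row sums to 1, so the
  expansion preserves counts and maps constant coefficient images to
  constant activity. All degenerate-limit identities in the tests
  (self-only kernel = identity; hybrid with flat functional factor = K_m)
  hold exactly under this convention.
- **Functional feature source** (default: the coefficient image α, which
  is what the update iterates); using λ = Kα instead is a one-line
  configuration change.

## Reconstruction algorithms

All three algorithms share one multiplicative EM update on α restricted to
the active subset, with `K = I` for OSEM, `K = K_m` (fixed) for KEM and
`K⁽ⁿ⁾ = K_m·K_p⁽ⁿ⁾` for HKEM. α is initialised to 1 everywhere. The
functional factor is rebuilt before every subset update by default (the
finest cadence consistent with the per-update kernel index); a
once-per-full-iteration cadence is available and behaves
indistinguishably on the desk-scale phantom. OSEM stores a 5 mm Gaussian
post-filtered copy of every per-iteration image (hence "OSEM+G"); the
filter uses reflective boundaries and preserves total mass to 1e-6.

Numerical policy: ratio denominators carry ε = 1e-10; voxels with zero
sensitivity (outside every active LOR) are frozen at their current value
rather than raising — this cannot bias supported voxels. Nonnegativity of
α and λ is preserved by the multiplicative form. MLEM (one subset)
monotonically increases the Poisson log-likelihood, which is asserted over
50 iterations on matched-model data; no such guarantee exists for HKEM
(the kernel changes between updates), and none is claimed.

There is no convergence-based stopping rule: a fixed iteration budget is
run and the *comparison* iteration is chosen afterwards as the one with
the highest cohort true-positive count (earliest on ties). The desk-scale
default budget is 7 subsets × 4 iterations on a 64×64 grid at 3 mm voxels
with 63 angles — small enough that a three-algorithm, 40-subject cohort
reconstructs in seconds, while the full-scale setting (21 subsets, 10
iterations) remains a configuration choice.

## Synthetic phantom

One subject is a 2-D axial abdominal slice with: a hot spine (activity 3×
blood — NaF is a bone tracer, and the spine is the dominant spill-in
hazard), an aneurysmal aorta (disc of diameter 35–65 mm for positives,
18–26 mm for controls; its wall annulus is ROI T), a normal-calibre aorta
segment (wall = ROI A), and the vena cava (ROI B). Blood and vessel walls
have activity 1, background 0.5. Positive subjects carry 1–3 calcified
lesions: discs of radius 3 mm clipped into the wall annulus at
rejection-sampled angles (mutually separated, never inside the
spine-margin exclusion zone), with activity contrast drawn uniformly from
2–4× the wall. Controls carry no lesions, so their maximum truth activity
in T equals that in A exactly. Wall voxels within 6 mm of the spine are
excluded from T, as an analyst would do to avoid spill-in.

The guidance image is a noiseless CT-like map (background 20, lumen 45,
wall 55, spine 400, arbitrary units) at the PET grid. Crucially, each
lesion is visible on CT (intensity 150) only with probability 0.5:
NaF-avid microcalcification is frequently below CT resolution, and this is
precisely the case where anatomy-only guidance cannot help. This one
parameter controls the division of labour between the two kernels — for
CT-visible lesions KEM and HKEM perform alike; for CT-invisible lesions
only the functional factor preserves the lesion edge, and HKEM recovers
measurably more uptake (verified per-subject in the test suite).

What the phantom does **not** emulate: 3-D geometry (and hence realistic
ROI A/B sizes), anatomical texture and CT noise, respiratory motion,
inter-subject variability of background and blood activity, attenuation,
and scanner-specific corrections. Passing cohort-level tests therefore
demonstrates internal consistency of the algorithms and pipeline under a
controlled, favourable geometry — not clinical performance.

## Quantification and statistics

TBR_max and the percentage increase follow the definitions above; both
are invariant to positive rescaling of the image, so no SUV calibration is
needed (an optional linear scaling exists for interface completeness).
Classification uses the strict >25% rule. The coefficient of variation
(population SD / mean) is computed over the blood-pool ROI B by default —
the reference region is uniform by construction; the region is
configurable since conventions differ. The kernel-parameter sweep rule
selects, among candidates within a relative CoV band (default ±10%) of a
reference, the one with the highest TBR, ties to the earliest candidate.

Cohort statistics are all two-sided at the 95% level: paired t-tests on
per-subject increases for each algorithm pair; ROC analysis with the
operating point fixed at the 25% rule (higher increase = more positive)
and AUC variance/comparison by DeLong's structural-components method
(implemented with midranks and validated against brute-force placement
counting and jackknife variances); Pearson correlation between aneurysm
diameter and increase over the positive subjects; and a logistic
regression of positivity on TBR_max(T) after down-sampling the majority
class to balance, reporting Wald errors, residual deviance and the
probability-0.5 classification threshold −β₀/β₁. Perfect separation — the
common case on this clean synthetic cohort, where reconstructed TBR
separates classes — is flagged as a non-converged fit with no estimates
rather than reported as huge coefficients. No multiple-testing correction
is applied across the three pairwise tests, matching common practice for
a three-way algorithm comparison; the logistic accuracy is in-sample and
labelled as such.

## Known limitations

- The projector is 2-D; the API keeps geometry per-axis so a 3-D
  extension is mechanical, but none is provided.
- HKEM has no convergence guarantee; with very small σ_p the functional
  kernel degenerates towards the identity in noisy flat regions,
  trading noise suppression for edge preservation.
- Sensitivity orderings between algorithms on a 30-positive cohort move
  by single subjects between noise realisations; the continuous
  comparisons (paired t-tests on increase) are the statistically stable
  readout at this cohort size.
- NIfTI stores voxel spacing in 32-bit floats; spacings that are not
  exactly representable round-trip to float32 precision.
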