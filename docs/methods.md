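# Methods

## Superimposition

Shapes are 72-point 2D configurations. GPA centers each configuration,
scales it to unit centroid size (full Procrustes; no further tangent-space
projection), and alternates rotate-to-consensus with consensus
re-estimation until the consensus moves by less than 1e-10 per
coordinate (max 100 iterations; hitting the cap flags the result as
non-converged rather than raising). Rotations are proper (no
reflections); mirroring appears only inside the asymmetry score. The
final consensus is the exact coordinate-wise mean of the aligned
coordinates. A GPA solution is defined only up to one joint rotation of
the whole sample; every downstream quantity (distances, projections,
asymmetry) is invariant to that rotation, and the invariance tests
compare solutions modulo a joint rotation rather than pinning an
arbitrary canonical orientation.

`procrustes_distance` is the partial Procrustes distance: both shapes at
unit centroid size, optimal rotation, root-summed-squared point
distance. It is exactly symmetric and is the distance used for
averageness.

## Semilandmark sliding

Sliding minimizes thin-plate-spline bending energy against the current
consensus. The TPS kernel is U(r) = r² log r²; the bending-energy matrix
is the upper-left block of the inverse of the bordered kernel system, so
it is symmetric, PSD, and annihilates affine fields. Each semilandmark
moves only along its local tangent, estimated by the central difference
of its two curve neighbors (anchors included); the optimal slide amounts
solve one small linear system per configuration, which can only lower
the quadratic energy. A semilandmark whose neighbors coincide is held
fixed with a warning. Three slide↔realign cycles are run by default; the
digitizing software behind this study design does not publish its
iteration counts, so these defaults are the package's own and are
exposed as parameters.

## Shape cues

- **AVRG**: Procrustes distance from the face to its sex-specific GPA
  consensus (separate GPA per sex). Higher = more distinctive.
- **SShD**: faces of both sexes are pooled in one GPA; with male and
  female mean shapes m and f, the score is the projection of the face
  onto the unit vector (m − f)/‖m − f‖, centered on the midpoint
  (m + f)/2. The default sign makes higher scores more male-like; the
  source analyses describe both conventions in different places, so a
  `sign="female"` switch flips it and outputs label the convention.
  Because all downstream variables are standardized, the projection
  scale cannot affect any standardized coefficient.
- **FA**: the configuration is mirrored (x negated), bilateral labels
  are swapped, and the mirror is re-superimposed by translation and
  rotation only (sizes agree by construction). The score is the summed
  squared distance over all 72 points: exactly 0 for perfect bilateral
  symmetry, and invariant to rigid motion of the input. The refit makes
  the score reflect shape asymmetry rather than orientation artifacts; a
  `refit=False` option scores the literal mirrored difference.
  Asymmetry is computed on GPA-aligned coordinates.
- **BMI** = weight / height².

The 72-point scheme itself (which indices are semilandmarks, which pair
across the midline) is study-specific and not publicly tabulated; the
shipped default scheme is a synthetic stand-in — 4 midline fixed
landmarks, 16 bilateral fixed pairs, and 6 bilateral curve pairs with 3
semilandmarks each — with the same bookkeeping structure, loadable from
JSON for real digitizing layouts.

## Rating statistics

Rater exclusions: age outside 18–50 (inclusive bounds retained),
non-target group, self-reported non-heterosexual (when the column is
present), same-sex rater–face pairs. Known-person skips stay in the
table as missing ratings and never enter means. ICC(3,k) is the two-way
mixed, consistency, average-of-k-raters coefficient
(MS_faces − MS_error)/MS_faces, computed per (rater group × stimulus
sex) dataset; faces with any missing cell are dropped listwise, the
formulation the complete-matrix ANOVA assumes. How the original analyses
treated skips inside ICC matrices is unstated; listwise deletion is this
package's documented choice.

## Path analysis

The model is a recursive DAG over standardized (mean 0, variance 1,
n−1 denominator) face-level variables: age precedes BMI, which precedes
FA, then AVRG and SShD, with attractiveness (the face's mean rating in
one rater group) as the sole sink; all forward edges are present. For a
recursive system with independent errors, maximum likelihood factors
into per-equation OLS, so each edge coefficient is the standardized
partial regression coefficient of the child on that parent (equal to the
Pearson correlation when the parent is the only one). Asymptotic t-based
p-values are reported for reference only.

Primary inference is the permutation "robust" p-value: each of n_perm
(default 10,000) iterations independently permutes the rows of every
variable, destroying all associations while preserving marginals, refits
the whole system, and records all coefficients; the p-value is
(1 + #{|β*| ≥ |β_obs|}) / (n_perm + 1), two-sided, with the +1 correction
so p is never 0. The randomization unit is not pinned down by the study
description; permuting every column is the default and a
`scheme="response-only"` alternative permutes each equation's response
instead. One integer seed drives the whole run.

The unit of analysis is the face (mean attractiveness per rater group),
giving six fits: 3 rater groups × 2 stimulus sexes. Individual ratings
appear only in the mixed models.

## Mixed models

Per stimulus sex: `rating ~ (age + bmi + avrg + sshd + fa) * group` with
correlated random intercept + slopes per rater (raters nested in group)
and a random intercept per face; predictors standardized over the
modeling table's rows; AVN is the reference level. Estimation is REML
with Satterthwaite denominator df, delegated to R's lmerTest (with
multcomp's `glht` for single-step pairwise group contrasts, both on the
group main effects and on each predictor × group slope family) — the
standard, well-validated machinery for exactly this model class. The
module owns the specification, marshalling, and parsing; a
`random_slopes=False` option drops to intercept-only random structure
for small datasets. Singular (boundary) fits are reported as-is, never
auto-simplified: with a generator whose raters share slopes exactly, the
slope variances are legitimately 0 and correlations hit ±1. multcomp's
single-step p-values integrate a multivariate t numerically with Monte
Carlo; the worker script fixes the R seed so repeated fits are
bit-identical.

## Synthetic cohorts

The generator is the package's stand-in for the photographed sample, and
its defaults are the study conditions: 60 male and 33 female faces, ages
truncated-normal 21.1 ± 1.85 in 18–33 (men) and 21.8 ± 4.21 in 18–40
(women); BMI 21.5 ± 2.3 correlated 0.35 with age; heights/weights on
plausible young-adult Vietnamese scales. Shape space is built from a
bilaterally symmetric template plus:

- a deterministic symmetric dimorphism field (jaw width, brow height,
  eye aperture) scaled so the sex means are separated by d = 0.04
  Procrustes units (men at +d/2, women at −d/2) — a realistic
  facial-dimorphism magnitude for a low-dimorphism population;
- 8 orthonormal symmetric basis deformations with sds 0.012·0.85^k
  (individual variation an order of magnitude above the noise floor);
- symmetric age- and BMI-linked deformation directions (0.008 and 0.010
  shape units per sd);
- iid per-coordinate asymmetry noise, sd 0.0025 — the only symmetry
  breaker, hence the ground truth for FA;
- along-curve semilandmark jitter, sd 0.004 — digitizing arbitrariness
  that sliding is designed to remove;
- a random rigid motion and scale (800–1200 units) into "pixel" space.

Raters: per group and stimulus sex, the published sample sizes (124/86
AVN, 67/47 CZVN, 104/64 CZE raters for male/female stimuli). A rater's
latent judgment is intercept (4.0, rater sd 0.8) + preference weights on
the standardized cues + Gaussian noise (sd 0.9), discretized by rounding
to the nearest scale point (equally spaced half-integer cut points,
clipped to 1–7). Default weights: male stimuli avrg −0.45 / sshd −0.35
(CZE −0.55 / −0.30), female stimuli avrg −0.60 / age −0.50 (CZE −0.70 /
−0.45) — averageness dominant everywhere and weighted more by the CZE
group, the qualitative pattern this design probes. The generating
weights are in latent-rating units; the implied *standardized* path
coefficients are larger (the response sd is smaller than 1), so recovery
tests compare fitted coefficients against an oracle refit that replaces
the response with the noiseless weighted cue composite.

What the generator does **not** emulate: skin color and texture cues
(deliberately out of scope), non-linear cue use, rater-specific weight
variation, heavy-tailed or ordinal-threshold response styles, and any
correlation between asymmetry and the covariates. Passing tests
therefore demonstrate that the pipeline measures what this generative
model injects — not that real faces satisfy the model.

## Numerical and design notes

- The SShD axis is estimated on the same sample it scores, so the
  projected male–female gap carries a positive bias of the order of the
  mean-difference sampling noise; recovery tests therefore use a
  cross-fitted gap (axis from half of each sex, gap from the other
  half), which is unbiased. The same-sample bias also means the sexes'
  scores separate slightly even with zero injected dimorphism.
- ICC(3,k) = 1 − 1/F has a heavy negative tail under the null
  (independent ratings), so null checks bound its median and mean, not
  its extremes.
- Permutation-calibration and recovery simulations run at reduced but
  statistically adequate sizes: 200 replicates × 1,000 permutations for
  uniformity of the null p-value (KS at α = 0.01 per edge), 100 seeds at
  the study's cohort size for sign recovery, 3 cohorts of 500 faces for
  magnitude bias (≤10%).
- Degenerate inputs fail loudly and early: zero-size configurations,
  duplicated TPS kernel points, constant columns under standardization,
  rank-deficient path designs, empty post-filter rating tables.

## Limitations

- 2D frontal-view shape only; no 3D, no texture or color.
- FA is a single summed score; directional vs fluctuating asymmetry are
  not decomposed.
- The mixed models treat the 1–7 response as linear, as in the source
  analysis; ordinal models are out of scope.
- The path models report direct standardized coefficients only — no
  latent variables, fit indices, or mediation decompositions.
- Requires R (lmerTest/multcomp) at runtime for the mixed models; all
  other functionality is pure Python.
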