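# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `pteromorph`.

## Landmark scheme and mirroring

The ventral-cranium template has 19 fixed landmarks and four semilandmark
curves — the snout contour (8 semilandmarks between landmarks 1 and 19),
the outer (19→18) and inner (7→9) outlines of the zygomatic arch (18
each), and the closed outline of the fourth upper premolar (18) — for 81
points one-sided. Landmarks 1, 10, 11, 13 and 14 are treated as
mid-sagittal. Landmarks 2 (incisor-socket midpoint) and 12 (pterygoid
apophysis) sit near but not necessarily on the midline, so they are
excluded from the default midline set; the set is configurable.

Mirroring reflects all non-midline points across the total-least-squares
line through the midline landmarks (the first principal axis of their
scatter), giving 2·81 − 5 = 157 bilateral points. Reflection conjugates
correctly with rigid motions of the input, so digitization orientation is
irrelevant. Building the bilateral structure this way removes spurious
asymmetry that one-sided digitization plus independent left/right
placement would introduce.

## Superimposition

GPA centres every configuration, scales it to unit centroid size, and
iterates rotate-to-mean / re-mean until the mean displacement falls below
`tol = 1e-10` (at most 200 iterations; non-convergence is an error that
carries the last change). Rotations are constrained to det +1 —
reflections are a genuine hazard for bilateral configurations and are
never allowed, in fitting or in distances.

Semilandmark sliding minimises thin-plate-spline bending energy. With
reference X (the current mean) and bending-energy matrix L_k (the
upper-left block of the inverse of the bordered TPS system with kernel
U(r) = r² log r²), each semilandmark of specimen Y moves by t_j along its
unit tangent u_j; the vector t solves the normal equations of the
quadratic form, jointly over all semilandmarks:

    t = −(Uᵀ(I₂⊗L_k)U)⁻¹ Uᵀ(I₂⊗L_k)(y − x)

Because this is the exact minimiser over the tangent subspace, bending
energy never increases, and affine deformations cost zero by
construction. Tangents are central differences of the specimen's own
curve neighbours; open-curve end semilandmarks use their bounding fixed
landmark as a neighbour, and the premolar outline wraps around. Sliding
is interleaved with the alignment iterations (up to 10 rounds) against
the iterated mean; a `sliding_reference="grand"` flag slides against the
initially converged mean instead, since published descriptions rarely say
which was used.

Shape distances are full Procrustes distances computed directly on the
aligned unit-size coordinates after an optimal rotation; no separate
tangent-space projection is applied. At the scale of cranial variation in
this clade (Procrustes distances of order 10⁻²) the curvature of shape
space is negligible relative to every test tolerance except the exact
two-point identity, where it appears at second order.

## Morphospace

PCA operates on species means (the analysis unit throughout the
comparative stages), via SVD of the centred flattened coordinates. Null
axes are dropped so explained variance sums to 1; each axis is oriented
so its largest-magnitude loading is positive, making output deterministic
across platforms and input orderings. Axis endpoint shapes are the mean
displaced by the extreme observed scores along the loading vector.

## Comparative models

**Covariance.** Under Brownian motion, Cov(tip i, tip j) is the depth of
their most recent common ancestor. Pagel's λ multiplies the off-diagonal
entries (equivalently: rescales internal branches while preserving tip
depths); λ is estimated by maximum likelihood on the residuals of the
*non-phylogenetic* least-squares fit of the full model, a single λ shared
across coordinate columns with per-column profiled rates, by bounded
scalar optimisation on [0, 1] (tolerance 1e-6, both endpoints checked).
The estimate is then applied to every reported fit. Estimating λ per
model is supported by calling `estimate_lambda` on each model's residuals,
but the shared full-model estimate is the default workflow.

**Procrustes PGLS.** Response and design are premultiplied by C^(−1/2)
(symmetric inverse square root). Sums of squares are sequential (type I),
in the order the formula states — diet before size before interaction —
computed as differences in summed squared residuals between nested
models. F per term is (SS/df)/(SS_res/df_res). Significance uses RRPP:
the reduced model's residuals (in the transformed space) are row-permuted,
added back to the reduced fitted values, and the term's F recomputed; the
p-value is the fraction of `n_perm` arrangements (observed included,
default 1000) with F at least as large, and Z = (ln F_obs − mean ln
F_perm)/sd ln F_perm. The same permutation indices are shared across
terms within an iteration. With a star phylogeny the whole construction
reduces exactly to a non-phylogenetic Procrustes ANOVA, which the tests
verify against explicit nested least-squares fits.

**Interaction rule.** A conditional protocol — include diet×size only if
size ~ diet is significant — coexists uneasily with reporting a full
diet×size table when the size model is not significant. The pipeline
exposes `interaction = always | auto | never`; `always` is the default so
that the full factorial table is produced, `auto` implements the
conditional rule.

**Dispersion and allometry.** Pairwise diet comparisons use each group's
mean residual distance from its mean (RMS behind a flag) on the
GLS-transformed residuals of the group-means model, with a group-label
permutation null; singleton groups are excluded with a warning.
Allometric regression scores project the transformed, centred shapes onto
the fitted shape-on-log-size regression vector; a zero vector (no
allometry) is flagged and yields zero scores.

## Disparity and the richness null

Shape disparity of a species set is the sample Procrustes variance:
per-species Procrustes distances d_i to the group mean shape (rescaled to
unit size), summarised as D = Σd_i²/(n−1). The (n−1) denominator is fixed
by the two-species case, where the sample variance equals half the
squared inter-species distance; a mean-absolute-distance statistic is
available via `disparity_stat="mean_abs"`. Size disparity is the sample
variance of log centroid sizes. Species occupying several biomes count in
each; a biome with fewer than two occupants is undefined and flagged, and
two-occupant biomes (the savanna, richness 2) are flagged low-power but
still computed.

The null model draws, for each richness k from 2 to the maximum observed
richness, `n_rep = 1000` uniform without-replacement samples from the
full species pool and records their disparity. One-sided p-values use the
add-one convention p = (#extreme + 1)/(n_rep + 1), so p is never exactly
zero and the observed arrangement counts as a replicate; "outside the
95% of the expected distribution" is implemented as p ≤ 0.05 on the
stated side (upper for tropical biomes I, II, II/III; lower for temperate
and boreal V, VI, VIII), with the reverse tail always reported. A
least-squares regression of null disparity on richness summarises the
expected richness–disparity relationship.

The across-biome ANOVA treats per-species distances as observations with
biome as a one-way factor; species in several biomes enter once per
biome. This inflates nominal df slightly when ranges overlap heavily, but
matches how per-biome distance plots are drawn; the choice is logged.

## Synthetic data generator

The generator emulates the study system, not cranial anatomy. Species
mean shapes start from a smooth synthetic half-cranium (the built-in
template geometry), to which three additive components are applied in the
flattened coordinate space:

* **Phylogenetic drift**: Brownian deviations drawn on a pure-birth
  (Yule) tree of depth 1, covariance λ_true·C, with total variance
  `sigma_bm` per unit depth spread evenly over coordinates;
* **Diet effects**: one displacement per diet category along random unit
  directions orthogonalised against the similarity subspace (translation,
  scale, rotation) and each other, so superimposition cannot absorb them
  and their variance contributions are separable;
* **Allometry**: `allometry_slope` × (log CS − mean log CS) along another
  orthonormal direction.

Specimens add iid Gaussian coordinate noise (`specimen_noise_sd`) to the
species mean, are scaled to the species' centroid size, and then receive
nuisance transforms — rotation U(0, 2π), translation U(−10, 10)², scale
LogNormal(0, 0.2) — that GPA must undo. Log sizes are normal within diet
with broad overlap between categories. Biome occupancy sorts species by a
latent tropicality score with per-biome jitter (sd 0.15): tropical biomes
take the top-scoring species at the requested richness, temperate the
bottom, reproducing the overlap structure in which wide-ranging species
occupy several same-pole biomes.

Default conditions match the study sample: 35 species, specimen counts
resampled from the published per-species N column (151 specimens in
total), per-biome richness {I: 26, II: 17, II/III: 2, V: 14, VI: 8,
VIII: 11}; for smaller pools the richness scales proportionally. The
effect magnitudes (`sigma_bm = 1e-4`, diet displacement 0.0032–0.0063,
`allometry_slope = 0.013`, log-size means 3.85–4.05 with sd 0.25–0.30)
were calibrated once so that the generated data reproduce the published
effect structure — diet explaining roughly 30% of among-species shape
variance, size roughly 13%, and a weak (~20%, non-significant at n = 35)
diet–size association — and are not tuned further. Diets are assigned
balanced across the five informative categories; the `NoInfo` category
of the real table exists only in the shipped metadata, where the
comparative stage drops such species automatically.

What the generator does *not* emulate: realistic cranial anatomy,
digitization/camera error models, within-species allometry, correlated
(non-isotropic) specimen noise, and diet-dependent evolutionary rates.
Passing tests therefore demonstrate statistical correctness of the
machinery under the assumed generative model, not anatomical realism.

## Numerical choices and degenerate inputs

* GPA tolerance 1e-10 on mean displacement; max 200 iterations; up to 10
  sliding rounds.
* Rank-deficient (collinear) configurations, coincident reference points
  in the TPS system, singular covariances, and zero centroid sizes raise
  typed errors naming the offending objects.
* λ-transformed covariances are Cholesky-factored per likelihood
  evaluation; a singular candidate gets likelihood −∞ rather than an
  exception during optimisation.
* Permutation p-values always count the observed arrangement, so they lie
  in (0, 1]; F statistics are compared with a 1e-12 slack to make ties
  deterministic across platforms.
* The add-one Monte Carlo p gives p_upper + p_lower ≥ 1 (the observed
  value sits in both tails).

## Test problem sizes

The statistical suites run at sizes chosen to make their Monte Carlo
bounds sharp while keeping the default test run fast: λ recovery uses 50
seeds × 50-tip trees × 20 residual columns; PGLS power uses 50 seeds of
30-species datasets through GPA and the estimated-λ fit (coordinates
compressed by an exact rank-preserving rotation before permutation);
type-I calibrations use 200 null simulations of 16–30 rows with 199
permutations; the null-test coverage check uses a 20-species pool,
999-replicate null, and 1000 simulated biomes.

## Known limitations

* 2D ventral view only; no 3D superimposition or missing-landmark
  estimation.
* Brownian motion (λ-rescaled) is the only evolutionary model; no OU or
  early-burst alternatives, and a single λ is shared across coordinates.
* Disparity is not phylogenetically corrected, matching the published
  design, and the richness null treats the sampled pool as the universe.
* The two-species savanna biome yields a defined but very low-power test.
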