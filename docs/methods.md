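# Methods

This note documents the models and procedures `wingshape` implements,
the numerical choices behind them, what the synthetic-data generator
does and does not emulate, and the known limitations. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## 1. Wing geometry: chord profiles and moment radii

A wing is an ordered simple polygon with designated base and apex
points. The wing axis is the base→apex chord (not a PCA axis): span
position r is measured along it, and the wing length R is the base–apex
distance. The wing is partitioned into `n_strips` equal-width strips
perpendicular to the axis; the chord of strip i is its area divided by
the strip width. Strip areas are computed analytically — the cumulative
area left of each strip boundary is a per-edge Green's-theorem integral
with the integration limit clipped at the boundary — so there is no
polygon-clipping approximation; the only discretization is the
piecewise-constant chord itself, whose moment-radius error is
O(1/n_strips²) on smooth outlines (convergence-tested against closed
forms for the rectangle, both triangles, and Beta profiles).

The profile object stores the n+1 strip edges r̂ ∈ [0,1] and the n
per-strip normalized chords ĉ = (strip area/width)/(S/R). With that
pairing the rectangle-rule integral ∫ĉ dr̂ equals 1 exactly (up to float
rounding), and the moment integrals ∫ĉ r̂ᵏ dr̂ use the exact polynomial
integral of r̂ᵏ within each strip. The k-th moment radius is
r̂ₖ = (∫ĉ r̂ᵏ dr̂)^{1/k}; k = 2 is the RSM. Power-mean monotonicity
guarantees r̂₁ ≤ r̂₂ ≤ r̂₃ for any non-negative profile, and the radii are
invariant under rigid motion and uniform scaling (the computation runs
in the axis frame, so this holds to machine precision).

Defaults: `n_strips = 500`. Area lying beyond the base or apex along the
axis (impossible for the synthetic outlines, rare in practice) is
excluded from S; the profile then describes the in-span part of the
wing. A scanned-image adapter traces a single-component binary mask by
marching squares; mask coordinates are treated as y-up Cartesian (no
image-row flip — the moment radii are reflection-invariant, and callers
who need oriented landmarks flip explicitly).

## 2. Geometric morphometrics

**GPA.** Configurations are centered, scaled to unit centroid size and
rotated (SVD Procrustes, reflections disallowed by default since all
wings come from one body side) onto a running consensus — the mean of
the aligned specimens, renormalized each round. Convergence is declared
when the consensus root-mean-square change drops below `tol = 1e-10`
(`max_iter = 100`); non-convergence raises an error carrying the
descent history. The total Procrustes sum of squares is recorded every
iteration and is non-increasing.

**Sliding semilandmarks.** Each flagged point may slide along its
tangent, estimated as the chord between its two index-neighbors
(endpoints use their single adjacent chord). The slide amount is the
projection of the consensus residual on the tangent — the minimizer of
the specimen-to-consensus Procrustes distance, which is the criterion
used here (not minimum bending energy). Sliding alternates with
re-superimposition against the consensus of the current iteration. Two
guards keep the procedure well-behaved: a slide that fails to reduce the
specimen's distance after renormalization is rolled back, and sliding
runs only during the first `slide_iterations = 10` rounds. The second
guard exists because the minimized-distance criterion leaves the
position of the consensus semilandmarks along their own curve
unidentified (a gauge direction): fully iterated sliding creeps along
that direction indefinitely instead of converging. Displacements are far
below digitizing noise after a few rounds; the remaining rounds are
plain GPA, which converges geometrically.

**Shape variables.** Residuals from the consensus are orthogonally
projected onto the tangent space at the consensus (removing the two
translation, one rotation and one scaling directions) and expressed in
an orthonormal basis: 2(k−3) partial-warp columns — eigenvectors of the
consensus bending-energy matrix (the k×k upper-left block of the
inverse bordered TPS system), ordered by decreasing eigenvalue, each
contributing an x and a y score — plus the 2 uniform columns, the
affine deformations of the consensus (shear and anisotropic stretch)
orthogonalized against the similarity directions. For k = 12 landmarks
this gives exactly 20 variables; a pure affine deformation loads only on
the uniform columns; the basis reconstructs the tangent-projected
residuals exactly and preserves total variance. Species-mean shapes are
computed by averaging aligned coordinates and re-projecting through the
same basis (the alternative — averaging shape variables — differs only
through the tangent projection of the means and was not taken).

**TPS grids and shape scores.** Deformation grids solve the interpolating
thin-plate spline (kernel U(r) = r² log r²) via the bordered system;
landmark images are exact to solver precision, and near-collinear
configurations raise an explained error. Allometric shape scores follow
the regression-projection construction: each aligned coordinate is
regressed on the covariate and specimens are projected onto the unit
regression vector, retaining residual variation along that direction.

## 3. Comparative statistics

Species are the unit of replication: per-taxon × wing arithmetic means
of the RSM and log centroid size feed every model. Fore- and hindwings
run as separate analysis lanes (they do not form a common functional
surface in odonates), sharing one tree and one joint GPA.

* **Size regressions** — OLS of RSM on log centroid size (degree 1) and
  on size + size² (degree 2); with 37 species the overall F carries
  (1, 35) and (2, 34) df.
* **MANCOVA** — shape variables against wing (fixed factor) and RSM
  (covariate), Wilks' Λ with Rao's F per term, interaction omitted by
  default; with 20 variables and 74 species×wing means the covariate
  test has (20, 52) df. When a small study leaves fewer error df than
  responses, the pipeline uses the leading shape variables (ordered by
  bending energy) and records how many.
* **Coloration GLM** — RSM ~ coloration group (6 levels) + size + size²,
  each term adjusted for all others (Type II partial SS; with no
  interactions in the model this equals "adjusted for everything else").
  With 37 taxa the error df is 29. Interactions can be included and
  removed stepwise (least significant first at α = 0.05).
* **Non-allometric residuals** — residuals of the quadratic size
  regression; mean zero and orthogonal to {1, size, size²} by
  construction; the size-corrected RSM used for the coloration analysis.
* **Independent contrasts** — Felsenstein's recursion (ancestral value =
  branch-length-weighted mean; parent branch extended by v₁v₂/(v₁+v₂));
  polytomies are a hard error rather than silently resolved. Contrast
  pairs are positivized on the predictor (the through-origin fit is
  invariant to the flips), regressed through the origin with
  (1, n_contrasts − 1) df, and R² is reported about the origin with the
  about-the-mean value alongside. The through-origin slope is
  algebraically the GLS slope under the Brownian tip covariance
  (verified to 1e-8 on random trees). Branch-length transforms (log,
  sqrt, exp — the latter after rescaling tree height to 1, so the map is
  scale-free) support the standard adequacy diagnostic, the correlation
  of |contrast| with its standard deviation.
* **Phylogenetic ANOVA** — conventional one-way F at the tips, with a
  null distribution from `n_sim` Brownian-motion simulations on the
  study tree; the rate defaults to the REML-style estimate from
  contrasts (mean squared standardized contrast), overridable. The
  p-value is (b + 1)/(n_sim + 1); the plain proportion is available via
  a flag. Type-I error at α = 0.05 is verified to sit in [0.03, 0.07]
  over 500 null replicates.

P-values for parametric tests come from the F distribution with the
stated df; no small-sample corrections are applied.

## 4. The synthetic study generator

The generator emulates the statistical structure of a museum-specimen
study of ~37 territorial calopterygid taxa (5–10 specimens per taxon,
both wings) without asserting any real parameter values.

* **Tree**: a Yule (pure-birth) tree grown to n tips, one extra waiting
  time appended so no terminal branch is zero, rescaled to unit height.
  Topologies are redrawn until the smaller root-child subtree holds at
  most `max_basal_fraction = 0.15` of the tips: the emulated study
  system has a basal lineage of a few taxa (a genus), and the raw-scale
  hump that motivates the whole analysis only exists when the offset
  clade is a small leverage group rather than half the family.
* **Sizes**: log centroid size evolves by Brownian motion
  (σ² = 0.0625 on the height-1 tree → tip SD 0.25, i.e. roughly a
  2–3-fold size range) from a root value of 4.0 log-mm; the basal clade
  is shifted by `basal_size_shift = −0.9`, making it distinctly the
  smallest — as the basal genus is in the emulated system.
* **RSM**: intercept 0.56 at root size, slope −0.06 per log-size unit,
  basal-clade offset −0.045, residual SD 0.008 per wing (the scale of
  the residual variance printed in comparable species-level analyses).
  These defaults were calibrated, by the simulation study the acceptance
  property prescribes, so that the generator actually produces its
  defining scenario: the quadratic term is selected on raw species means
  and the contrast slope is significantly negative in ≈87% of 300
  replicates (the acceptance threshold is 80%).
* **Geometry**: per-specimen chord profiles are Beta(α, β) densities
  with α + β = 4 — a modeling convenience, not a biological claim, chosen
  because the Beta second moment is closed-form, giving an exact oracle
  for every downstream RSM (√0.3 for Beta(2,2), worst-case cohort error
  < 0.01% at default resolution). Outlines are symmetric polygons
  realizing those profiles (aspect ratio 5.5; wing length 0.55·e^{log size}
  mm, hindwings 5% shorter); 12 landmarks sit at fixed perimeter
  fractions with isotropic digitizing noise (SD 0.15 mm), two of them
  flagged as semilandmarks.
* **Coloration groups**: a uniform random draw from 1..6 per taxon
  (independent of the RSM, so the coloration GLM and phylogenetic ANOVA
  operate under their null), optionally linking the basal clade to
  group 1.

What this does **not** emulate: vein topology, pigment imagery,
asymmetric (cambered) planforms, digitizing landmarks tied to actual
vein intersections, measurement error correlated between wings of one
specimen, and any non-Brownian evolutionary process. Passing tests
therefore demonstrate the correctness of the computational chain under
a known generative model, not the biological realism of that model.

## 5. Problem sizes and numerical choices

The shipped study size (37 taxa, ~530 specimens, 500 strips, 400-vertex
outlines, 1000 BM simulations) keeps a full pipeline run at ~15 s on one
CPU; the test suite's replicate studies use 8–20 taxa and 100–500
simulations, sizes chosen so the whole suite exercises every stage in
well under a minute of compute per module. Tolerances: GPA consensus
1e-10; TPS interpolation checked at 1e-10; contrast/GLS equivalence at
1e-8; closed-form RSM at 1e-3 for 500 strips. Ties in the basal-clade
definition (equal root-child sizes) resolve to the first child.
Degenerate inputs — zero-area outlines, coincident base/apex, coincident
landmarks, constant covariates, singular TPS systems, polytomies,
zero-length log-transformed branches — raise typed, explained errors
rather than propagating NaNs.

## 6. Known limitations

* Procrustes-distance sliding is capped (see §2); datasets whose
  semilandmarks carry most of the shape signal may prefer
  bending-energy sliding, which is not implemented.
* The MANCOVA reports Rao's F approximation for Wilks' Λ; exactness
  holds for the 1- and 2-df hypothesis cases used here.
* The exponential branch-length transform is one member of a family the
  literature leaves unspecified; the height-1 rescaling makes it
  scale-free but other conventions exist.
* Contrast R² is reported both about the origin (primary) and about the
  mean, since published through-origin analyses differ in convention.
* The generator draws specimen-level variation independently per wing
  and specimen; real fore/hind pairs of one animal are correlated.
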