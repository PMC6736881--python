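# Methods

`paleoshape` implements a phylogenetic-morphometric inference chain for 3D
cranial landmark data: superimposition and symmetrization of landmark
configurations, maximum-likelihood reconstruction of ancestral shapes under
Brownian motion on a dated phylogeny, rendering of the reconstructed
ancestors as warped meshes, ordination-based comparison of fossils against
the reconstructions, and mesh surface-deviation spectra.  This note records
the models, the parameters that matter, and the design choices made where
the design was genuinely open.

## Superimposition

Generalized Procrustes Analysis (GPA) removes translation, scale and
rotation: each configuration is centred, scaled to unit centroid size, and
rotated to the running consensus; the consensus is the re-normalized mean.
Iteration stops when the summed squared residual changes by less than
1e-10 (cap 100 iterations; non-convergence warns with the last change —
typical for samples of very dissimilar shapes, whose Procrustes mean is
poorly determined).  Rotations come from an SVD with a determinant
correction so reflections are never applied: anatomical chirality is
preserved.  After convergence the consensus is put in a canonical
principal-axis orientation with per-axis sign fixing, which makes the
output independent of specimen input order.  For an exactly bilaterally
symmetric consensus the sign of the left–right axis is a true tie;
pipeline stages that re-run GPA internally (semilandmark sliding)
therefore re-anchor each new frame to the previous consensus.

Analyses run on the Procrustes shape coordinates directly; no tangent-space
projection is applied.  In the small-variation regime of cranial data the
difference is far below the effects studied, and omitting the projection
keeps scores and back-rotated shapes in one coordinate system.

## Bilateral symmetry

The symmetric component of object symmetry averages each configuration
with its reflected-and-relabelled copy.  All originals and copies are
aligned in one joint GPA, then each specimen's two copies are re-fitted
pairwise by ordinary Procrustes before averaging.  The pairwise refit
matters: it makes the average exactly invariant under the induced
reflection–relabelling (the optimal rotation satisfies the involution
property), so the output is object-symmetric to machine precision rather
than approximately.  The operation is idempotent.

The midsagittal plane used for mirroring (and for mirror-based imputation)
is the least-squares plane through the midline landmarks; "mirroring onto
the other side" admits several plane definitions, and this one is the
package's choice.

## Missing landmarks

Two-stage imputation: (1) a missing landmark whose bilateral partner is
preserved is filled by reflecting the partner across the fitted midline
plane; (2) remaining gaps are filled by a thin-plate spline fitted from a
complete template onto the preserved landmarks and evaluated at the
template's missing positions.  Provenance (observed / mirrored / tps) is
recorded per landmark.  Reconstruction quality depends strongly on how
close the template is to the specimen's own population mean; with a
population-mean template and the default noise level, reconstruction error
at imputed landmarks stays below the within-population landmark standard
deviation (tested on simulated fossils with analysis-D preservation).

## Thin-plate splines

3D TPS with kernel U(r) = r and a full affine part, solved through the
standard bordered system; interpolation at controls is exact (<1e-8) and
coplanar or duplicated controls raise an error naming the offending
points.  The bending-energy matrix is the negated upper-left block of the
inverse bordered matrix: the 3D biharmonic energy corresponds to the
kernel −r, while the interpolant itself is invariant to the kernel's sign,
so the reported energy is the conventional non-negative one and vanishes
exactly on affine maps.

## Semilandmark sliding

Curve semilandmarks slide along the central-difference tangent of their
chain neighbours; surface semilandmarks slide in the least-squares tangent
plane of their declared neighbour set.  Displacements are the closed-form
minimizer of the TPS bending energy between the specimen and the
consensus (the default criterion, matching the standard practice of the
tool family used for such data; minimized Procrustes distance to the
consensus is available as an alternative).  Chain endpoints and fixed
landmarks never move; degenerate tangents leave the landmark unmoved with
a warning.  Each iteration recomputes the consensus and re-runs GPA;
3 iterations is the default (the number is not prescribed anywhere, and
the objective decreases monotonically within each iteration, so more
iterations change little).  Slid surface points are *not* re-projected
onto an actual mesh surface — the package operates on landmarks, with
meshes optional; this is a documented limitation.  Sliding is applied
before symmetrization when both are requested.

The synthetic-data generator plants no arbitrary-spacing artefacts, so the
end-to-end synthetic studies run with sliding off; sliding is exercised
directly on constructions where it matters (re-parameterized arcs, where
it removes >95% of the spurious shape distance).

## Dated trees and Brownian-motion ancestral states

A chronogram is a fully resolved rooted tree with branch lengths in ka;
tips may be non-contemporaneous (fossil terminals sit at their own ages and
simply have shorter root-to-tip paths).  Star trees (a deliberate
polytomy) are available via an explicit constructor for reference cases;
file input rejects unresolved trees.

All computation runs through shared-path covariance matrices
C[i,j] = path length from the root to the MRCA of tips i and j.  For one
trait y, the root state is the GLS mean a = (1'C⁻¹1)⁻¹1'C⁻¹y, and every
other internal node is the same formula on the tree re-rooted at that node
(computed via patristic distances: C_v[i,j] = (d(v,i)+d(v,j)−d(i,j))/2).
Re-rooted GLS reproduces the joint maximum-likelihood node states (checked
against direct numerical maximization and against an independent R
implementation).  The rate is the ML estimator
σ̂² = (y−1a)'C⁻¹(y−1a)/N by default — "maximum likelihood" being the
stated method — with the REML variant (divide by N−1) as an option; the
REML option reproduces the confidence intervals of the reference R
implementation exactly, the ML default gives intervals narrower by a
factor √((N−1)/N).  Node variance is σ̂²·(1'C_v⁻¹1)⁻¹ and the 95%
envelope is ±1.96 standard errors.  Under a uniform rescaling of all
branch lengths the estimates are invariant; the per-ka rate scales
inversely and the structural factor linearly, so node variances computed
from re-estimated rates are invariant too.

Ancestral *shapes* are obtained by running the estimator jointly over all
non-zero principal components of the taxon mean shapes (the PCs are
uncorrelated, so per-trait estimation is exact) and back-rotating each
node's score vector into landmark space.  Only the display uses the first
three PCs; the estimation always carries all of them.  Back-rotated
ancestors are re-scaled to unit centroid size before any comparison
analysis — distances are shape-space distances and the method provides no
ancestor size.

### Preset hypothesis trees

Four built-in chronograms describe genus-*Homo* hypotheses: an early-Homo
outgroup (H. habilis, H. georgicus, H. ergaster), a structured Neandertal
clade (Early (Near-East (South-Europe, West-Europe))), an early H. sapiens
terminal, and 21 extant human populations.  Anchors: modern–Neandertal
common ancestry at 600 ka, Neandertal clade root at 300 ka, modern clade
root at 305 ka, deepest extant split at 260 ka, and an out-of-Africa at
90 ka for the Sahul populations (hypothesis h1) or a single out-of-Africa
at 75 ka (h2); h1b/h2b drop the Khoisan and Pygmy populations (San,
Khoikhoi, Bayaka, Mbuti).  Fossil terminal ages are chronology-range
midpoints averaged per taxon (e.g. early Neandertals 195 ka, early
H. sapiens 100 ka, H. habilis 1800 ka).  Node ages between the anchors
(the African population ladder, the Eurasian sub-structure, outgroup
attachment at 2000/1900/1800 ka) are not fixed by any single published
number; the values used are one defensible arrangement and are defined in
one place (`paleoshape.phylo`) for inspection or replacement.  They matter
only through C, and every downstream statistic is computed from the tree,
never hard-coded.

## Phylogenetic signal

The multivariate K statistic generalizes Blomberg's K to p traits:

    K = [tr(S'S) / tr(S'C⁻¹S)] / [(tr C − N(1'C⁻¹1)⁻¹)/(N−1)],  S = Y − 1a.

K = 1 exactly on a unit-branch star tree and averages ≈1 for data
simulated under Brownian motion on any tree.  Significance comes from
permuting tip rows (999 permutations by default; a seed is mandatory);
p = (1 + #{K_perm ≥ K_obs})/(1 + n_perm).  Note that within-population
sampling noise attenuates K below 1 even for perfectly Brownian
population means — visible in the synthetic studies, where mean-shape K is
≈0.5–0.7 with p ≪ 0.05.

## Comparison analyses A–D

Each analysis restricts the template to the landmarks preserved in a
target fossil and re-runs GPA from scratch on the restricted
configurations (subsetting aligned coordinates is *not* equivalent and is
not done).  On the canonical 780-landmark template the subsets hold 255
(A, full skull), 148 (B, calvarium, no facial curves), 112 (C) and 181 (D)
landmarks; other template sizes scale proportionally.  The exact member
lists on the synthetic template are deterministic evenly spaced selections
per landmark role — the real study's per-landmark lists are not published,
so the synthetic subsets reproduce the counts and the role composition,
not the anatomy.  Specimens whose preservation defined an analysis are
excluded where the study excluded them: Florisbad from B, Omo II and LH18
from C.  The early-Homo outgroup is excluded from all comparison analyses.

Between-group PCA: PCA of the g unweighted group mean shapes centred on
the mean of means; individuals and ungrouped ("passive") specimens — the
vLCAs and fossils — are projected onto the axes.  Axis signs are
canonicalized (largest-magnitude loading positive) so scores are
bit-reproducible.  Euclidean distance tables among group means and passive
points are taken in the full (g−1)-dimensional between-group score space,
where group means reproduce their full-space distances exactly; per-group
Procrustes-distance distributions (min, quartiles, max) supply the boxplot
summaries, and 90% confidence ellipses use each group's score covariance
with a 2-dof chi-square radius.

## Surface deviation

For every vertex of a test mesh, the signed distance to a reference
surface: mode `nearest_point` projects onto the exact closest point of any
reference triangle (vectorized exact point-triangle projection; zero-area
faces dropped at load); mode `corresponding_vertex` uses the same-index
vertex and requires shared vertex provenance (per-vertex nearest-point
distances are then never larger).  The sign follows the reference's
barycentrically interpolated outward vertex normal: positive = outside.
No ICP or other registration is performed — meshes are expected to be
pre-aligned by the landmark pipeline.  Reports carry the maximum and mean
positive and negative distances, the standard deviation, the maximum
absolute value, and a 50-bin fixed-width histogram.

## Synthetic data generator

The generator emulates the study structure: a bilaterally symmetric
skull-like template on an ellipsoid (semi-axes 70 × 90 × 65 mm) with 56
fixed landmarks (≈⅓ on the midline), 116 curve semilandmarks in mirrored
facial arcs and 608 surface semilandmarks in mirrored pairs on the
calvarial region; population mean shapes evolving by Brownian motion on a
preset chronogram (every coordinate independently, variance = rate ×
branch length); individuals as isotropic Gaussian scatter around their
population mean; and five LMP fossil stand-ins branching off the modern
clade root with extra drift, masked by the preservation pattern of the
analysis shaped on them.  Defaults: rate 0.002 mm²/ka per coordinate and
within-population sd 1.0 mm — chosen so that, on a ~2000 mm-centroid-size
cranium, between-population shape distances come out at a few hundredths
of a Procrustes unit with clearly separable populations, the regime of
real cranial data; 10 individuals per extant population and study-sized
fossil taxa (2–3 specimens).  All randomness flows from one seed;
regeneration is bit-identical.

What the generator does *not* emulate: correlated (anatomically
structured) within-population variation, digitization spacing artefacts,
allometry, and measurement error concentrated on curves.  Passing tests
therefore demonstrate correctness of the inference machinery under its own
model assumptions, not robustness to the full messiness of digitized
crania.

Shapes are not re-normalized during simulation: Brownian motion runs in
raw coordinate space, size variation emerges, and GPA removes it
downstream — matching how the estimator will see real data.

## Numerical and degenerate-input choices

- Procrustes fits require ≥4 landmarks of rank ≥2; rank-deficient input
  raises rather than silently fitting.
- TPS needs ≥5 non-coplanar, duplicate-free controls.
- The sliding linear system is solved with an SVD-based least-squares
  solve, so collinear tangent directions cannot blow up.
- Covariance solves use Cholesky factorization and fail loudly on
  non-positive-definite matrices.
- Ties in the canonical-orientation sign convention (exactly symmetric
  shapes) are resolved arbitrarily but deterministically for identical
  input bytes.

## Known limitations

- Ancestral-node uncertainty is per-PC (axis-aligned envelopes); the full
  covariance between PCs at a node is not propagated.
- Internal-node estimates at nodes outside a rearranged clade change
  slightly when the clade's internal topology changes (the clade enters
  through its aggregated covariance); "locality" holds only approximately.
- bgPCA with many groups and few individuals per group can overstate group
  separation; the package reports the ordination as the study design
  prescribes and leaves that caveat to the analyst.
- The comparison analyses' synthetic landmark subsets match counts and
  composition, not anatomical identity.
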