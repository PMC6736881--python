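# paleoshape

Phylogenetic modelling of 3D cranial shape: from landmark configurations
and a dated phylogeny to maximum-likelihood ancestral ("virtual last
common ancestor", vLCA) shapes with confidence envelopes, warped ancestor
meshes, between-group ordination of fossils against the reconstructions,
multivariate phylogenetic signal, and mesh surface-deviation spectra.

The package is aimed at geometric morphometricians and
palaeoanthropologists who want to ask: *given a hypothesis about the
phylogeny of a group (here, genus* Homo*), what cranial shape does the
model predict for an ancestral node, and which real fossils resemble that
prediction?*

## The model

Specimens are k×3 landmark configurations (mm).  Generalized Procrustes
Analysis (GPA) removes position, scale and orientation (proper rotations
only); bilateral asymmetry is removed by the symmetric component of object
symmetry; semilandmarks on curves and surfaces may slide to minimize
thin-plate-spline bending energy against the consensus.  Taxon mean shapes
are decomposed by PCA, and each principal component is treated as a
continuous character evolving by Brownian motion on a dated tree with
shared-path covariance **C** (C_ij = root-to-MRCA path length, ka).  The
ancestral state at the root is the GLS estimate

    â = (1′C⁻¹1)⁻¹ 1′C⁻¹ y,   σ̂² = (y − 1â)′C⁻¹(y − 1â) / N,

and every other internal node is the same formula on the tree re-rooted at
that node (equivalent to the joint ML node states).  Node variances
σ̂²·(1′C_v⁻¹1)⁻¹ give 95% confidence envelopes.  The ancestral PC scores
are rotated back into landmark space and a reference mesh is TPS-warped
into the reconstructed configuration.  Phylogenetic signal uses the
multivariate K statistic with a tip-permutation test.

Four dated genus-*Homo* hypothesis trees are built in (`h1`, `h2`, `h1b`,
`h2b`: with/without an early out-of-Africa at 90 ka, with/without the
Khoisan and Pygmy populations), and a synthetic-data module generates
skull-like, bilaterally symmetric landmark datasets with known truth at
every node for end-to-end validation.

## Worked example

```python
import paleoshape as ps

# simulated study: 780-landmark template, BM on hypothesis h1,
# 10 individuals per extant population, known true shapes at every node
ds = ps.make_dataset(preset="h1", rate=0.002, within_sd=1.0, n_extant=10, seed=7)

study = ps.vlca_study(ds.individuals, ds.tree, scheme=ds.scheme)
err = ps.root_recovery_error(study, ds.true_node_shapes[ds.tree.root_id])
print(f"PC1-3 variance: {100*study.pca.explained_variance_ratio_[:3].sum():.1f}%")
print(f"root vLCA error (Procrustes units): {err['procrustes_distance']:.4f}")
print(f"tip dispersion (Procrustes units):  {err['tip_dispersion']:.4f}")

k = ps.kmult(study.tree, study.pca.scores_, n_perm=999, seed=7,
             taxa=study.pca.labels_)
print(f"Kmult = {k.K:.3f}, p = {k.p_value:.3f}")

comp = ps.comparison_study(ds, study, analyses=("A",))
print(comp["A"].nearest.round(4))
```

Output:

```
PC1-3 variance: 58.8%
root vLCA error (Procrustes units): 0.0113
tip dispersion (Procrustes units):  0.0183
Kmult = 0.537, p = 0.001
                nearest_group  distance
passive
vLCA_n0      Neandertal_Early    0.0230
vLCA_n14        EarlyHsapiens    0.0197
Florisbad          EastAfrica    0.0184
OmoII             NorthAfrica    0.0202
LH18              NorthAfrica    0.0204
KNM-ES11693       SouthEurope    0.0175
Irhoud1                   San    0.0176
```

Reading it: the estimated root shape sits closer to the truth (0.0113)
than the terminal taxa are spread around their mean (0.0183), so the
reconstruction adds information beyond "use the average".  The
phylogenetic signal of the mean shapes is highly significant (p = 0.001)
but K < 1, as expected when within-population sampling noise dilutes a
Brownian between-population pattern.  In the analysis-A ordination the
fossil stand-ins — generated as drifted relatives of the modern clade
root — project nearest to modern-human populations, with shape distances
of ~0.02 Procrustes units, the magnitude typical of between-population
cranial differences.

A command-line driver wraps the same pipeline:

```sh
paleoshape simulate --preset h1 --seed 7 --out run/
paleoshape align    --data run/ --out run/aligned
paleoshape vlca     --data run/ --tree h1 --out run/vlca
paleoshape signal   --data run/ --tree h1 --seed 7 --out run/signal
```

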