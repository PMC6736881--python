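"""From aligned specimens to virtual last common ancestor (vLCA) shapes.

Population mean shapes (one per terminal taxon) are decomposed by PCA; the
uncorrelated PC scores are treated as continuous characters and their
ancestral states estimated under Brownian motion on the dated tree; each
node's score vector is rotated back into landmark space, and a reference
mesh can be TPS-warped into the ancestral configuration.  The ordination of
tips, nodes and tree edges (the phylomorphospace) is exported as plain
tables for plotting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .geometry import AlignedSample, LandmarkConfiguration
from .phylo import AncestralEstimate, Chronogram, bm_ancestral_states
from .tps import tps_apply, tps_fit


def population_mean_shapes(
    sample: AlignedSample, grouping: dict[str, str] | None = None
) -> dict[str, np.ndarray]:
    """Arithmetic mean of aligned coordinates per group, unit centroid size.

    ``grouping`` maps specimen id to taxon label; by default each config's
    ``group`` attribute is used.  Every group must be non-empty.
    """
    groups: dict[str, list[np.ndarray]] = {}
    for c in sample.configs:
        g = grouping.get(c.specimen_id) if grouping is not None else c.group
        if g is None:
            continue
        groups.setdefault(g, []).append(c.coords)
    if not groups:
        raise ValueError("no grouped specimens")
    out = {}
    for g, arrs in groups.items():
        m = np.mean(arrs, axis=0)
        m = m - m.mean(axis=0)
        s = np.sqrt((m**2).sum())
        if s == 0:
            raise ValueError(f"group {g!r} has degenerate mean shape")
        out[g] = m / s
    return out


class ShapePCA(BaseEstimator, TransformerMixin):
    """PCA of vectorized landmark configurations, keeping all non-zero PCs.

    Fits on an (n, k, 3) or (n, 3k) array; components are rows of an
    orthonormal matrix, so full-dimension scores preserve pairwise Euclidean
    distances between shapes exactly.

    Attributes
    ----------
    mean_ : ndarray (3k,)
    components_ : ndarray (q, 3k)
    explained_variance_ : ndarray (q,)
    explained_variance_ratio_ : ndarray (q,)
    scores_ : ndarray (n, q)
    labels_ : list of str or None
    """

    def __init__(self, tol: float = 1e-12):
        self.tol = tol

    @staticmethod
    def _flatten(X) -> np.ndarray:
        arr = np.asarray(X, dtype=float)
        if arr.ndim == 3:
            arr = arr.reshape(arr.shape[0], -1)
        if arr.ndim != 2:
            raise ValueError(f"expected (n, k, 3) or (n, d), got {arr.shape}")
        return arr

    def fit(self, X, y=None, labels: list[str] | None = None):
        arr = self._flatten(X)
        n = arr.shape[0]
        if n < 3:
            raise ValueError("shape PCA needs at least 3 shapes")
        self.n_landmarks_ = arr.shape[1] // 3
        self.mean_ = arr.mean(axis=0)
        centered = arr - self.mean_
        u, s, vt = np.linalg.svd(centered, full_matrices=False)
        keep = s > self.tol * max(s[0], 1.0)
        keep &= np.arange(s.size) < n - 1
        self.components_ = vt[keep]
        self.singular_values_ = s[keep]
        self.explained_variance_ = s[keep] ** 2 / (n - 1)
        total = self.explained_variance_.sum()
        self.explained_variance_ratio_ = self.explained_variance_ / total
        self.scores_ = centered @ self.components_.T
        self.labels_ = list(labels) if labels is not None else None
        return self

    def transform(self, X) -> np.ndarray:
        arr = self._flatten(X)
        return (arr - self.mean_) @ self.components_.T

    def inverse_transform(self, scores: np.ndarray) -> np.ndarray:
        scores = np.atleast_2d(np.asarray(scores, dtype=float))
        return scores @ self.components_ + self.mean_

    def to_landmarks(self, scores: np.ndarray) -> np.ndarray:
        """Back-rotate a score vector into a k x 3 landmark configuration."""
        flat = self.inverse_transform(scores)
        return flat.reshape(-1, self.n_landmarks_, 3).squeeze(0) if flat.shape[0] == 1 else flat.reshape(flat.shape[0], self.n_landmarks_, 3)

    @property
    def n_components_(self) -> int:
        return self.components_.shape[0]


def shape_pca(mean_shapes: dict[str, np.ndarray]) -> ShapePCA:
    """PCA over a taxon -> shape mapping; row order follows dict order."""
    labels = list(mean_shapes)
    arr = np.stack([mean_shapes[g] for g in labels])
    return ShapePCA().fit(arr, labels=labels)


@dataclass
class VirtualAncestor:
    """Ancestral shape at one internal node, back-rotated to landmarks."""

    node_id: str
    landmarks: np.ndarray  # (k, 3), raw back-rotation
    scores: np.ndarray  # (q,)
    estimate: AncestralEstimate
    mesh: object | None = None

    @property
    def ci_envelope(self) -> np.ndarray:
        """Per-PC 95% confidence interval, rows (lo, hi)."""
        return self.estimate.ci95

    @property
    def unit_landmarks(self) -> np.ndarray:
        """Landmarks re-centred and scaled to unit centroid size."""
        c = self.landmarks - self.landmarks.mean(axis=0)
        return c / np.sqrt((c**2).sum())

    def as_configuration(self) -> LandmarkConfiguration:
        return LandmarkConfiguration(self.node_id, self.unit_landmarks)


def ancestral_shapes(
    tree: Chronogram, pca: ShapePCA, taxa: list[str] | None = None, method: str = "ML"
) -> dict[str, VirtualAncestor]:
    """Estimate every internal node's shape from PC scores under Brownian motion.

    The PCA's rows must correspond to the tree's tips; ``taxa`` (or
    ``pca.labels_``) gives the mapping.  All non-zero PCs are carried through
    the estimation and back-rotated jointly.
    """
    if taxa is None:
        taxa = pca.labels_
    if taxa is None:
        raise ValueError("taxon labels required (fit ShapePCA with labels or pass taxa)")
    missing = set(taxa) ^ set(tree.tip_labels)
    if missing:
        raise ValueError(f"tips and PCA rows do not match; offenders: {sorted(missing)}")
    estimates = bm_ancestral_states(tree, pca.scores_, taxa=taxa, method=method)
    out = {}
    for node_id, est in estimates.items():
        lm = pca.to_landmarks(est.values)
        out[node_id] = VirtualAncestor(node_id, lm, est.values.copy(), est)
    return out


def warp_reference(reference_mesh, reference_landmarks: np.ndarray, target) -> object:
    """TPS-warp a reference mesh into an ancestral landmark configuration.

    ``target`` may be a :class:`VirtualAncestor` or a k x 3 array.  Every
    mesh vertex is mapped by the spline fitted on
    ``reference_landmarks -> target landmarks``; faces are unchanged.
    """
    import trimesh

    tgt = target.landmarks if isinstance(target, VirtualAncestor) else np.asarray(target, float)
    ref = np.asarray(reference_landmarks, dtype=float)
    if ref.shape != tgt.shape:
        raise ValueError(f"landmark count mismatch: {ref.shape} vs {tgt.shape}")
    t = tps_fit(ref, tgt)
    verts = tps_apply(t, np.asarray(reference_mesh.vertices, dtype=float))
    return trimesh.Trimesh(vertices=verts, faces=np.asarray(reference_mesh.faces), process=False)


@dataclass
class Phylomorphospace:
    """Plain-table description of the ordination of tips, nodes and edges."""

    tip_points: pd.DataFrame  # index: tip label; columns PC<i>
    node_points: pd.DataFrame  # index: node id
    edges: list[tuple[str, str]]
    ellipses: pd.DataFrame  # index: node id; columns PC<i> 1.96*sqrt(var) semi-axes

    def plot(self, pcs: tuple[int, int] = (0, 1), ax=None):
        """Quick matplotlib rendering: tips, nodes, edges, 95% ellipses."""
        import matplotlib.patches as mpatches
        import matplotlib.pyplot as plt

        cx, cy = (self.tip_points.columns[p] for p in pcs)
        if ax is None:
            _, ax = plt.subplots()
        pts = pd.concat([self.tip_points, self.node_points])
        for a, b in self.edges:
            ax.plot(pts.loc[[a, b], cx], pts.loc[[a, b], cy], color="0.6", lw=0.8, zorder=1)
        ax.scatter(self.tip_points[cx], self.tip_points[cy], s=18, zorder=3)
        ax.scatter(self.node_points[cx], self.node_points[cy], s=28, marker="s", zorder=3)
        for nid, row in self.node_points.iterrows():
            w, h = 2 * self.ellipses.loc[nid, cx], 2 * self.ellipses.loc[nid, cy]
            ax.add_patch(
                mpatches.Ellipse((row[cx], row[cy]), w, h, fill=False, ec="0.3", lw=0.6, zorder=2)
            )
        ax.set_xlabel(cx)
        ax.set_ylabel(cy)
        return ax


def phylomorphospace(
    tree: Chronogram,
    pca: ShapePCA,
    ancestors: dict[str, VirtualAncestor],
    pcs: tuple[int, ...] = (0, 1, 2),
) -> Phylomorphospace:
    """Project tips and estimated ancestors into the chosen PCs.

    Nodes sit at their ancestral scores; each node carries axis-aligned 95%
    confidence semi-axes ``1.96 * sqrt(variance)`` per displayed PC; edges
    follow the tree topology.
    """
    q = pca.n_components_
    for p in pcs:
        if p >= q:
            raise ValueError(f"requested PC {p} but only {q} components exist")
    cols = [f"PC{p + 1}" for p in pcs]
    taxa = pca.labels_
    tip_points = pd.DataFrame(
        pca.scores_[:, list(pcs)], index=pd.Index(taxa, name="tip"), columns=cols
    )
    node_ids = list(ancestors)
    node_points = pd.DataFrame(
        np.stack([ancestors[n].scores[list(pcs)] for n in node_ids]),
        index=pd.Index(node_ids, name="node"),
        columns=cols,
    )
    ellipses = pd.DataFrame(
        np.stack([1.96 * np.sqrt(ancestors[n].estimate.variances[list(pcs)]) for n in node_ids]),
        index=node_points.index,
        columns=cols,
    )
    edges = [(p, c) for p, c, _ in tree.edges()]
    return Phylomorphospace(tip_points, node_points, edges, ellipses)
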