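"""Comparative analyses A-D: landmark subsets, between-group PCA, distances.

Each analysis restricts the template to the landmarks preserved in a target
fossil, re-runs GPA on the restricted configurations, and ordinates the
individuals by between-group PCA (bgPCA): a PCA of the unweighted group mean
shapes onto which individuals and ungrouped ("passive") specimens — the
vLCAs and fossils — are projected.  Euclidean distance tables among group
means and passive specimens, and Procrustes-distance distributions per
group, summarize the phenetic relationships.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .geometry import AlignedSample, procrustes_distance
from .scheme import LandmarkScheme

# per-analysis landmark counts on the canonical 780-landmark template; other
# template sizes get proportionally scaled subsets
_ANALYSIS_COUNTS = {"A": 255, "B": 148, "C": 112, "D": 181}
_CANONICAL_TOTAL = 780
# deterministic composition of each subset over landmark roles
_ANALYSIS_MIX = {  # fractions of the subset drawn from (fixed, curve, surface) pools
    "A": (0.22, 0.24, 0.54),  # full skull
    "B": (0.14, 0.0, 0.86),  # calvarium only (no facial curves)
    "C": (0.14, 0.29, 0.57),  # calvarium and face
    "D": (0.13, 0.25, 0.62),  # calvarium and face
}
_ANALYSIS_EXCLUSIONS = {"A": [], "B": ["Florisbad"], "C": ["OmoII", "LH18"], "D": []}


@dataclass
class AnalysisSpec:
    """Landmark subset and specimen exclusions for one comparison analysis."""

    name: str
    landmark_indices: np.ndarray
    excluded_specimens: list[str] = field(default_factory=list)

    @property
    def n_landmarks(self) -> int:
        return int(self.landmark_indices.size)


def _even_subset(pool: np.ndarray, count: int) -> np.ndarray:
    count = min(count, pool.size)
    if count <= 0:
        return pool[:0]
    pos = np.unique(np.round(np.linspace(0, pool.size - 1, count)).astype(int))
    while pos.size < count:  # fill collisions from the remaining pool
        rest = np.setdiff1d(np.arange(pool.size), pos)
        pos = np.sort(np.concatenate([pos, rest[: count - pos.size]]))
    return pool[pos]


def make_analysis_spec(name: str, scheme: LandmarkScheme) -> AnalysisSpec:
    """Landmark subset for analysis ``A``/``B``/``C``/``D`` on a scheme.

    On the canonical 780-landmark template the subsets have exactly the
    sizes 255 (A, full skull), 148 (B, calvarium), 112 (C) and 181 (D);
    other template sizes scale proportionally.  Selection is deterministic
    (evenly spaced within each landmark-role pool).
    """
    if name not in _ANALYSIS_COUNTS:
        raise ValueError(f"unknown analysis {name!r}; choose from {sorted(_ANALYSIS_COUNTS)}")
    total = int(round(scheme.n_landmarks * _ANALYSIS_COUNTS[name] / _CANONICAL_TOTAL))
    total = max(total, 8)
    f_fix, f_cur, f_sur = _ANALYSIS_MIX[name]
    fixed, curve, surface = scheme.fixed_indices, scheme.curve_indices, scheme.surface_indices
    n_fix = min(int(round(total * f_fix)), fixed.size)
    n_cur = min(int(round(total * f_cur)), curve.size)
    n_sur = min(total - n_fix - n_cur, surface.size)
    chosen = [
        _even_subset(fixed, n_fix),
        _even_subset(curve, n_cur),
        _even_subset(surface, n_sur),
    ]
    idx = np.sort(np.concatenate(chosen))
    short = total - idx.size
    if short > 0:  # top up from whatever pool has spare landmarks
        rest = np.setdiff1d(np.arange(scheme.n_landmarks), idx)
        idx = np.sort(np.concatenate([idx, rest[:short]]))
    return AnalysisSpec(name, idx, list(_ANALYSIS_EXCLUSIONS[name]))


class BetweenGroupPCA(BaseEstimator, TransformerMixin):
    """PCA of unweighted group mean shapes with projection of individuals.

    ``fit(X, groups)`` computes the g group means, centres them on the mean
    of means, and extracts up to g-1 orthonormal axes; ``transform``
    projects any specimen (grouped or passive) onto those axes.  Axis signs
    are canonicalized (largest-magnitude loading positive) so scores are
    reproducible bit-for-bit for identical input.

    Attributes
    ----------
    group_labels_ : list of str
    group_means_ : ndarray (g, d)
    components_ : ndarray (g-1, d)
    explained_variance_ratio_ : ndarray (g-1,)
    scores_ : ndarray (n, g-1)   training individuals' scores
    group_mean_scores_ : ndarray (g, g-1)
    """

    @staticmethod
    def _flatten(X) -> np.ndarray:
        arr = np.asarray(X, dtype=float)
        if arr.ndim == 3:
            arr = arr.reshape(arr.shape[0], -1)
        return arr

    def fit(self, X, groups):
        arr = self._flatten(X)
        groups = np.asarray(groups)
        labels = list(dict.fromkeys(groups.tolist()))  # first-appearance order
        if len(labels) < 2:
            raise ValueError("bgPCA needs at least 2 groups")
        means = np.stack([arr[groups == g].mean(axis=0) for g in labels])
        grand = means.mean(axis=0)
        centered = means - grand
        u, s, vt = np.linalg.svd(centered, full_matrices=False)
        keep = min(len(labels) - 1, int((s > 1e-12 * max(s[0], 1.0)).sum()))
        comp = vt[:keep]
        # canonical sign: largest-|loading| coordinate positive per axis
        for j in range(comp.shape[0]):
            i = np.argmax(np.abs(comp[j]))
            if comp[j, i] < 0:
                comp[j] = -comp[j]
        self.group_labels_ = labels
        self.group_means_ = means
        self.grand_mean_ = grand
        self.components_ = comp
        ev = s[:keep] ** 2 / max(len(labels) - 1, 1)
        self.explained_variance_ = ev
        self.explained_variance_ratio_ = ev / (s**2 / max(len(labels) - 1, 1)).sum()
        self.scores_ = (arr - grand) @ comp.T
        self.group_mean_scores_ = centered @ comp.T
        return self

    def transform(self, X) -> np.ndarray:
        return (self._flatten(X) - self.grand_mean_) @ self.components_.T


@dataclass
class BgPCAResult:
    """Between-group PCA scores for groups, individuals and passive specimens."""

    estimator: BetweenGroupPCA
    group_labels: list[str]
    group_mean_scores: np.ndarray
    scores: np.ndarray
    individual_labels: list[str]
    individual_groups: list[str]
    passive_scores: np.ndarray
    passive_labels: list[str]

    @property
    def variance_fractions(self) -> np.ndarray:
        return self.estimator.explained_variance_ratio_


def bgpca(
    individuals,
    groups: list[str],
    passive=None,
    passive_labels: list[str] | None = None,
    individual_labels: list[str] | None = None,
) -> BgPCAResult:
    """Run a between-group PCA; individuals carry group labels, passive do not.

    All configurations must come from one common GPA restricted to the same
    landmark subset.
    """
    est = BetweenGroupPCA()
    arr = est._flatten(individuals)
    est.fit(arr, groups)
    if individual_labels is None:
        individual_labels = [f"ind_{i}" for i in range(arr.shape[0])]
    if passive is None:
        pscores = np.zeros((0, est.components_.shape[0]))
        passive_labels = []
    else:
        parr = est._flatten(passive)
        pscores = est.transform(parr)
        if passive_labels is None:
            passive_labels = [f"passive_{i}" for i in range(parr.shape[0])]
    return BgPCAResult(
        estimator=est,
        group_labels=est.group_labels_,
        group_mean_scores=est.group_mean_scores_,
        scores=est.scores_,
        individual_labels=list(individual_labels),
        individual_groups=list(groups),
        passive_scores=pscores,
        passive_labels=list(passive_labels),
    )


def euclidean_distance_table(result: BgPCAResult) -> pd.DataFrame:
    """Pairwise Euclidean distances among group means and passive specimens.

    Distances are taken in the full (g-1)-dimensional between-group score
    space, where group means reproduce their full-space distances exactly.
    """
    labels = list(result.group_labels) + list(result.passive_labels)
    pts = np.vstack([result.group_mean_scores, result.passive_scores])
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    return pd.DataFrame(d, index=labels, columns=labels)


def nearest_groups(result: BgPCAResult) -> pd.DataFrame:
    """For each passive specimen, the nearest group mean and its distance."""
    table = euclidean_distance_table(result)
    rows = []
    for lab in result.passive_labels:
        sub = table.loc[lab, result.group_labels]
        rows.append({"passive": lab, "nearest_group": sub.idxmin(), "distance": sub.min()})
    return pd.DataFrame(rows).set_index("passive")


def group_confidence_ellipses(result: BgPCAResult, pcs=(0, 1), level: float = 0.90) -> pd.DataFrame:
    """Per-group confidence ellipses of the individual scores on two bg axes.

    Returns centre, semi-axes and orientation from each group's score
    covariance with a 2-dof chi-square radius at the given level.
    """
    from scipy.stats import chi2

    r = np.sqrt(chi2.ppf(level, df=2))
    if result.scores.shape[1] <= max(pcs):
        raise ValueError(
            f"requested axes {pcs} but only {result.scores.shape[1]} bg axes exist"
        )
    rows = []
    groups = np.asarray(result.individual_groups)
    for g in result.group_labels:
        pts = result.scores[groups == g][:, list(pcs)]
        centre = pts.mean(axis=0)
        if pts.shape[0] < 3:
            rows.append({"group": g, "cx": centre[0], "cy": centre[1],
                         "a": 0.0, "b": 0.0, "angle_deg": 0.0})
            continue
        cov = np.cov(pts.T)
        vals, vecs = np.linalg.eigh(cov)
        rows.append({
            "group": g,
            "cx": centre[0],
            "cy": centre[1],
            "a": r * np.sqrt(max(vals[1], 0.0)),
            "b": r * np.sqrt(max(vals[0], 0.0)),
            "angle_deg": float(np.degrees(np.arctan2(vecs[1, 1], vecs[0, 1]))),
        })
    return pd.DataFrame(rows).set_index("group")


def procrustes_distance_report(
    sample: AlignedSample, reference_ids: list[str], groups: dict[str, str] | None = None
) -> pd.DataFrame:
    """Distance distributions from each reference specimen to every group.

    For each reference (a vLCA or fossil present in the common GPA) the
    Procrustes distances to all individuals of each group are summarized as
    min, quartiles, median and max — the numbers behind group-comparison
    boxplots.
    """
    ids = {c.specimen_id: c for c in sample.configs}
    missing = [r for r in reference_ids if r not in ids]
    if missing:
        raise KeyError(f"references not in the aligned sample: {missing}")
    rows = []
    for ref in reference_ids:
        refc = ids[ref]
        per_group: dict[str, list[float]] = {}
        for c in sample.configs:
            g = groups.get(c.specimen_id) if groups is not None else c.group
            if g is None or c.specimen_id == ref:
                continue
            per_group.setdefault(g, []).append(procrustes_distance(refc, c))
        for g, dists in per_group.items():
            q = np.percentile(dists, [0, 25, 50, 75, 100])
            rows.append({
                "reference": ref, "group": g, "n": len(dists),
                "min": q[0], "q1": q[1], "median": q[2], "q3": q[3], "max": q[4],
            })
    return pd.DataFrame(rows)


def pairwise_reference_distances(sample: AlignedSample, reference_ids: list[str]) -> pd.DataFrame:
    """Scalar Procrustes distances between the named specimens."""
    ids = {c.specimen_id: c for c in sample.configs}
    n = len(reference_ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = procrustes_distance(ids[reference_ids[i]], ids[reference_ids[j]])
    return pd.DataFrame(d, index=reference_ids, columns=reference_ids)
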