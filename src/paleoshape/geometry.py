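"""Landmark superimposition: Procrustes fits, GPA, shape distance, symmetry.

Coordinates are k x 3 matrices in mm.  Generalized Procrustes Analysis (GPA)
removes translation, scale (to unit centroid size) and rotation (proper
rotations only — anatomical chirality is preserved), yielding Procrustes
shape coordinates and a consensus.  The symmetric component corrects for
bilateral asymmetry by averaging every specimen with its reflected and
relabelled copy after joint alignment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .scheme import LandmarkScheme


class MissingLandmarkError(ValueError):
    """An operation requiring complete configurations met missing landmarks."""


class DegenerateConfigurationError(ValueError):
    """Configuration is rank-deficient or too small for a Procrustes fit."""


@dataclass
class LandmarkConfiguration:
    """A single specimen's landmark coordinates with a missing-data mask."""

    specimen_id: str
    coords: np.ndarray
    missing: np.ndarray | None = None
    group: str | None = None
    provenance: np.ndarray | None = None  # per-landmark: observed|mirrored|tps

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError(f"coords must be k x 3, got {self.coords.shape}")
        k = self.coords.shape[0]
        if self.missing is None:
            self.missing = np.zeros(k, dtype=bool)
        else:
            self.missing = np.asarray(self.missing, dtype=bool)
            if self.missing.shape != (k,):
                raise ValueError("missing mask length must equal landmark count")
        if not np.all(np.isfinite(self.coords[~self.missing])):
            raise ValueError("non-finite coordinates at landmarks not flagged missing")
        if self.provenance is None:
            prov = np.array(["observed"] * k, dtype=object)
            prov[self.missing] = "missing"
            self.provenance = prov

    @property
    def n_landmarks(self) -> int:
        return self.coords.shape[0]

    @property
    def is_complete(self) -> bool:
        return not self.missing.any()

    def copy(self) -> "LandmarkConfiguration":
        return LandmarkConfiguration(
            self.specimen_id,
            self.coords.copy(),
            self.missing.copy(),
            self.group,
            self.provenance.copy(),
        )


@dataclass
class AlignedSample:
    """Result of a GPA: aligned unit-size configurations plus the consensus."""

    configs: list[LandmarkConfiguration]
    consensus: np.ndarray
    centroid_sizes: np.ndarray
    n_iterations: int
    converged: bool = True

    def coords_array(self) -> np.ndarray:
        """Stack aligned coordinates into an (n, k, 3) array."""
        return np.stack([c.coords for c in self.configs])

    @property
    def specimen_ids(self) -> list[str]:
        return [c.specimen_id for c in self.configs]

    @property
    def groups(self) -> list[str | None]:
        return [c.group for c in self.configs]


# ---------------------------------------------------------------------------
# elementary quantities
# ---------------------------------------------------------------------------

def centroid_size(config: LandmarkConfiguration | np.ndarray) -> float:
    """Centroid size: sqrt of summed squared landmark distances to the centroid.

    Raises
    ------
    MissingLandmarkError
        If the configuration has missing landmarks (impute first).
    """
    if isinstance(config, LandmarkConfiguration):
        if not config.is_complete:
            raise MissingLandmarkError(
                f"{config.specimen_id}: {int(config.missing.sum())} missing landmarks; "
                "impute before computing centroid size"
            )
        x = config.coords
    else:
        x = np.asarray(config, dtype=float)
    c = x - x.mean(axis=0)
    return float(np.sqrt((c**2).sum()))


def _center_and_scale(x: np.ndarray) -> np.ndarray:
    c = x - x.mean(axis=0)
    s = np.sqrt((c**2).sum())
    if s == 0.0:
        raise DegenerateConfigurationError("configuration has zero centroid size")
    return c / s


def optimal_rotation(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Proper rotation R (det +1) minimizing ||a - b R||_F for centered a, b."""
    u, _, vt = np.linalg.svd(b.T @ a)
    d = np.sign(np.linalg.det(u @ vt))
    if d == 0:
        d = 1.0
    corr = np.ones(a.shape[1])
    corr[-1] = d
    return u @ np.diag(corr) @ vt


def ordinary_procrustes(
    a: LandmarkConfiguration | np.ndarray,
    b: LandmarkConfiguration | np.ndarray,
    allow_scale: bool = True,
) -> tuple[np.ndarray, float]:
    """Ordinary Procrustes fit of ``b`` onto ``a``.

    Translates, optionally scales, and rotates ``b`` (proper rotation only)
    to minimize the summed squared differences to ``a``.  The returned
    distance is the Procrustes distance between the two shapes, i.e. the
    residual norm after both are scaled to unit centroid size.

    Returns
    -------
    aligned_b : ndarray (k, 3)
        ``b`` superimposed on ``a`` (in ``a``'s frame, a's size if
        ``allow_scale``).
    distance : float
    """
    xa = a.coords if isinstance(a, LandmarkConfiguration) else np.asarray(a, float)
    xb = b.coords if isinstance(b, LandmarkConfiguration) else np.asarray(b, float)
    if isinstance(a, LandmarkConfiguration) and not a.is_complete:
        raise MissingLandmarkError("first configuration has missing landmarks")
    if isinstance(b, LandmarkConfiguration) and not b.is_complete:
        raise MissingLandmarkError("second configuration has missing landmarks")
    if xa.shape != xb.shape:
        raise ValueError(f"shape mismatch {xa.shape} vs {xb.shape}")
    if xa.shape[0] < 4:
        raise DegenerateConfigurationError("need at least 4 landmarks in 3D")

    za, zb = _center_and_scale(xa), _center_and_scale(xb)
    if min(np.linalg.matrix_rank(za), np.linalg.matrix_rank(zb)) < 2:
        raise DegenerateConfigurationError("rank-deficient configuration (collinear landmarks)")

    rot = optimal_rotation(za, zb)
    distance = float(np.linalg.norm(za - zb @ rot))

    # full superimposition of raw b into a's frame
    ca, cb = xa - xa.mean(0), xb - xb.mean(0)
    if allow_scale:
        sa = np.sqrt((ca**2).sum())
        sb = np.sqrt((cb**2).sum())
        cb = cb * (sa / sb)
    aligned = cb @ rot + xa.mean(0)
    return aligned, distance


def procrustes_distance(
    a: LandmarkConfiguration | np.ndarray, b: LandmarkConfiguration | np.ndarray
) -> float:
    """Square-root of summed squared coordinate differences of two aligned shapes.

    Both inputs must come from a common GPA (unit centroid size, common
    orientation); no further fitting is done here.
    """
    xa = a.coords if isinstance(a, LandmarkConfiguration) else np.asarray(a, float)
    xb = b.coords if isinstance(b, LandmarkConfiguration) else np.asarray(b, float)
    if xa.shape != xb.shape:
        raise ValueError(f"shape mismatch {xa.shape} vs {xb.shape}")
    return float(np.linalg.norm(xa - xb))


# ---------------------------------------------------------------------------
# Generalized Procrustes Analysis
# ---------------------------------------------------------------------------

def _canonical_orientation(consensus: np.ndarray) -> np.ndarray:
    """Rotation taking the consensus to a canonical principal-axis frame.

    Makes GPA output independent of specimen input order: the consensus is
    rotated onto its principal axes, each axis signed so that its
    largest-magnitude coordinate is positive, with a determinant fix to stay
    a proper rotation.
    """
    c = consensus - consensus.mean(axis=0)
    _, _, vt = np.linalg.svd(c, full_matrices=False)
    r = vt.T  # columns: principal axes
    y = c @ r
    signs = np.ones(3)
    for j in range(3):
        i = np.argmax(np.abs(y[:, j]))
        signs[j] = np.sign(y[i, j]) or 1.0
    r = r * signs
    if np.linalg.det(r) < 0:
        r[:, 2] = -r[:, 2]
    return r


class GeneralizedProcrustes(BaseEstimator, TransformerMixin):
    """Generalized Procrustes Analysis as a scikit-learn style transformer.

    ``fit`` runs the iterative superimposition on an (n, k, 3) array (or a
    list of complete :class:`LandmarkConfiguration`); ``transform`` maps raw
    configurations into the fitted consensus frame (center, unit-scale,
    rotate to ``consensus_``).

    Parameters
    ----------
    tol : float
        Convergence threshold on the change in summed squared residuals.
    max_iter : int
        Iteration cap; non-convergence raises a warning, never silent.
    scale : bool
        Rescale every configuration to unit centroid size (shape analysis).

    Attributes
    ----------
    consensus_ : ndarray (k, 3)
        Mean shape, unit centroid size, canonical principal-axis orientation.
    centroid_sizes_ : ndarray (n,)
        Original centroid sizes in mm.
    n_iterations_ : int
    converged_ : bool
    """

    def __init__(self, tol: float = 1e-10, max_iter: int = 100, scale: bool = True):
        self.tol = tol
        self.max_iter = max_iter
        self.scale = scale

    @staticmethod
    def _as_array(X) -> tuple[np.ndarray, list[LandmarkConfiguration] | None]:
        if isinstance(X, np.ndarray):
            arr = np.asarray(X, dtype=float)
            if arr.ndim != 3 or arr.shape[2] != 3:
                raise ValueError(f"expected (n, k, 3) array, got {arr.shape}")
            return arr, None
        configs = list(X)
        for c in configs:
            if not c.is_complete:
                raise MissingLandmarkError(
                    f"{c.specimen_id} has missing landmarks; impute before GPA"
                )
        ks = {c.n_landmarks for c in configs}
        if len(ks) > 1:
            raise ValueError(f"inconsistent landmark counts: {sorted(ks)}")
        return np.stack([c.coords for c in configs]), configs

    def fit(self, X, y=None):
        arr, _ = self._as_array(X)
        n = arr.shape[0]
        if n < 2:
            raise ValueError("GPA needs at least two configurations")

        sizes = np.empty(n)
        z = np.empty_like(arr)
        for i in range(n):
            c = arr[i] - arr[i].mean(axis=0)
            s = np.sqrt((c**2).sum())
            if s == 0:
                raise DegenerateConfigurationError(f"specimen {i} has zero centroid size")
            sizes[i] = s
            z[i] = c / s if self.scale else c

        consensus = z[0].copy()
        prev_ss = np.inf
        change = np.inf
        converged = False
        it = 0
        for it in range(1, self.max_iter + 1):
            for i in range(n):
                z[i] = z[i] @ optimal_rotation(consensus, z[i])
            consensus = z.mean(axis=0)
            consensus = consensus - consensus.mean(axis=0)
            cs = np.sqrt((consensus**2).sum())
            if cs == 0:
                raise DegenerateConfigurationError("degenerate consensus")
            if self.scale:
                consensus = consensus / cs
            ss = float(((z - consensus) ** 2).sum())
            change = abs(prev_ss - ss)
            if change < self.tol:
                converged = True
                break
            prev_ss = ss
        if not converged:
            warnings.warn(
                f"GPA did not converge in {self.max_iter} iterations "
                f"(last change {change:.3e}); results may be inaccurate",
                RuntimeWarning,
                stacklevel=2,
            )

        r = _canonical_orientation(consensus)
        consensus = (consensus - consensus.mean(0)) @ r
        for i in range(n):
            z[i] = z[i] @ r
            # final rotation pass against the canonical consensus
            z[i] = z[i] @ optimal_rotation(consensus, z[i])

        self.consensus_ = consensus
        self.aligned_ = z
        self.centroid_sizes_ = sizes
        self.n_iterations_ = it
        self.converged_ = converged
        return self

    def transform(self, X) -> np.ndarray:
        arr, _ = self._as_array(X)
        out = np.empty_like(arr)
        for i in range(arr.shape[0]):
            c = arr[i] - arr[i].mean(axis=0)
            if self.scale:
                c = c / np.sqrt((c**2).sum())
            out[i] = c @ optimal_rotation(self.consensus_, c)
        return out

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X).aligned_


def gpa(sample, tol: float = 1e-10, max_iter: int = 100, scale: bool = True) -> AlignedSample:
    """Run GPA on a list of configurations; convenience wrapper.

    Returns an :class:`AlignedSample` carrying aligned unit-size
    configurations, the consensus, original centroid sizes and the
    iteration count.
    """
    est = GeneralizedProcrustes(tol=tol, max_iter=max_iter, scale=scale)
    arr, configs = est._as_array(sample)
    est.fit(arr)
    if configs is None:
        configs = [
            LandmarkConfiguration(f"specimen_{i}", arr[i]) for i in range(arr.shape[0])
        ]
    out = [
        LandmarkConfiguration(c.specimen_id, est.aligned_[i], group=c.group)
        for i, c in enumerate(configs)
    ]
    return AlignedSample(
        configs=out,
        consensus=est.consensus_,
        centroid_sizes=est.centroid_sizes_,
        n_iterations=est.n_iterations_,
        converged=est.converged_,
    )


# ---------------------------------------------------------------------------
# bilateral symmetry
# ---------------------------------------------------------------------------

def reflect_relabel(coords: np.ndarray, scheme: LandmarkScheme) -> np.ndarray:
    """Mirror a configuration: negate x and swap left/right landmark labels."""
    out = coords.copy()
    out[:, 0] = -out[:, 0]
    return out[scheme.partner()]


def midline_plane(coords: np.ndarray, scheme: LandmarkScheme, missing=None):
    """Least-squares midsagittal plane through the midline landmarks.

    Returns ``(point, normal)``; the normal is the smallest principal axis of
    the midline point cloud.
    """
    idx = np.array(scheme.midline, dtype=int)
    if missing is not None:
        idx = idx[~np.asarray(missing)[idx]]
    if idx.size < 3:
        raise ValueError("need at least 3 preserved midline landmarks to fit the plane")
    pts = coords[idx]
    centroid = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - centroid, full_matrices=False)
    normal = vt[-1]
    return centroid, normal / np.linalg.norm(normal)


def reflect_across_plane(points: np.ndarray, point: np.ndarray, normal: np.ndarray) -> np.ndarray:
    d = (points - point) @ normal
    return points - 2.0 * np.outer(d, normal)


def symmetric_component(sample, scheme: LandmarkScheme, **gpa_kwargs) -> AlignedSample:
    """Symmetric component of bilateral (object) symmetry.

    Each specimen is paired with its reflected-relabelled copy; all originals
    and copies are jointly aligned by GPA, then each specimen's two aligned
    copies are averaged after a final pairwise refit, which makes the output
    exactly object-symmetric.  The averaged configurations are re-unified in
    a closing GPA.
    """
    configs = list(sample.configs) if isinstance(sample, AlignedSample) else list(sample)
    if not scheme.symmetry_pairs and not scheme.midline:
        raise ValueError("scheme declares no symmetry structure")
    n = len(configs)
    doubled = []
    for c in configs:
        if not c.is_complete:
            raise MissingLandmarkError(f"{c.specimen_id}: impute before symmetrization")
        doubled.append(c)
        doubled.append(
            LandmarkConfiguration(
                c.specimen_id + "/mirror", reflect_relabel(c.coords, scheme), group=c.group
            )
        )
    joint = gpa(doubled, **gpa_kwargs)
    sym_configs = []
    for i in range(n):
        orig = joint.configs[2 * i].coords
        mirr = joint.configs[2 * i + 1].coords
        # pairwise refit: optimal alignment of the mirror onto the original
        # makes the average invariant under the induced reflection-relabelling
        mirr = mirr @ optimal_rotation(orig, mirr)
        avg = 0.5 * (orig + mirr)
        avg -= avg.mean(axis=0)
        avg /= np.sqrt((avg**2).sum())
        sym_configs.append(
            LandmarkConfiguration(configs[i].specimen_id, avg, group=configs[i].group)
        )
    if n >= 2:
        out = gpa(sym_configs, **gpa_kwargs)
    else:
        out = AlignedSample(sym_configs, sym_configs[0].coords.copy(), np.ones(1), 0)
    out.centroid_sizes = (
        sample.centroid_sizes
        if isinstance(sample, AlignedSample)
        else np.array([centroid_size(c) for c in configs])
    )
    return out


def asymmetry_residual(coords: np.ndarray, scheme: LandmarkScheme) -> float:
    """Norm of the difference between a configuration and its best-fit mirror."""
    m = reflect_relabel(coords, scheme)
    zc, zm = _center_and_scale(coords), _center_and_scale(m)
    return float(np.linalg.norm(zc - zm @ optimal_rotation(zc, zm)))
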