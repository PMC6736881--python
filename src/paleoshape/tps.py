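"""Thin-plate-spline interpolation in 3D.

Uses the radial kernel U(r) = r (the 3D biharmonic fundamental solution up
to sign) with a full affine part, solved through the standard bordered
linear system

    | K  P | | W |   | V |
    |      | |   | = |   |      P = [1 | X],
    | P' 0 | | A |   | 0 |

giving exact interpolation at the control points and a smooth extension
elsewhere.  The same machinery supplies the bending-energy matrix used by
semilandmark sliding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg


class SingularTPSError(ValueError):
    """Control points are degenerate (coplanar or duplicated)."""


def _u(r: np.ndarray) -> np.ndarray:
    return r


def _kernel_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    d = np.sqrt(((a[:, None, :] - b[None, :, :]) ** 2).sum(-1))
    return _u(d)


def _check_controls(source: np.ndarray) -> None:
    m = source.shape[0]
    if m < 5:
        raise SingularTPSError(f"need at least 5 control points, got {m}")
    d2 = ((source[:, None, :] - source[None, :, :]) ** 2).sum(-1)
    np.fill_diagonal(d2, np.inf)
    dup = np.argwhere(d2 < 1e-20)
    if dup.size:
        i, j = dup[0]
        raise SingularTPSError(f"duplicated control points {i} and {j}")
    c = source - source.mean(axis=0)
    s = np.linalg.svd(c, compute_uv=False)
    if s[-1] < 1e-10 * max(s[0], 1.0):
        raise SingularTPSError("control points are (nearly) coplanar")


@dataclass
class TPSTransform:
    """Fitted thin-plate spline mapping ``control_source`` onto ``control_target``."""

    control_source: np.ndarray
    control_target: np.ndarray
    weights: np.ndarray  # (m, 3) kernel coefficients
    affine: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,)

    def __call__(self, points: np.ndarray) -> np.ndarray:
        return tps_apply(self, points)


def tps_fit(source: np.ndarray, target: np.ndarray) -> TPSTransform:
    """Fit an exactly interpolating 3D thin-plate spline.

    Raises
    ------
    SingularTPSError
        On coplanar or duplicated control points (named in the message).
    """
    source = np.asarray(source, dtype=float)
    target = np.asarray(target, dtype=float)
    if source.shape != target.shape or source.ndim != 2 or source.shape[1] != 3:
        raise ValueError(f"source/target must both be m x 3, got {source.shape}, {target.shape}")
    _check_controls(source)
    m = source.shape[0]

    k = _kernel_matrix(source, source)
    p = np.hstack([np.ones((m, 1)), source])
    lhs = np.zeros((m + 4, m + 4))
    lhs[:m, :m] = k
    lhs[:m, m:] = p
    lhs[m:, :m] = p.T
    rhs = np.zeros((m + 4, 3))
    rhs[:m] = target
    try:
        sol = scipy.linalg.solve(lhs, rhs)
    except scipy.linalg.LinAlgError as err:  # pragma: no cover - guarded above
        raise SingularTPSError(f"singular TPS system: {err}") from err
    weights = sol[:m]
    translation = sol[m]
    affine = sol[m + 1 :].T  # rows act on columns of points
    return TPSTransform(source.copy(), target.copy(), weights, affine, translation)


def tps_apply(t: TPSTransform, points: np.ndarray) -> np.ndarray:
    """Evaluate a fitted spline at arbitrary points (n x 3)."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    k = _kernel_matrix(pts, t.control_source)
    out = k @ t.weights + pts @ t.affine.T + t.translation
    return out.reshape(np.shape(points))


def bending_energy_matrix(source: np.ndarray) -> np.ndarray:
    """Bending-energy matrix B (m x m) of a control configuration.

    For a spline from ``source`` to targets ``Y`` (m x 3), the bending
    energy is ``trace(Y' B Y)``; B is the upper-left block of the inverse of
    the bordered system matrix, negated so the form is positive
    semidefinite (the 3D biharmonic energy kernel is -r while the
    interpolant itself is kernel-sign invariant).  B annihilates affine
    targets, so rigid motions and scalings cost nothing.
    """
    source = np.asarray(source, dtype=float)
    _check_controls(source)
    m = source.shape[0]
    k = _kernel_matrix(source, source)
    p = np.hstack([np.ones((m, 1)), source])
    lhs = np.zeros((m + 4, m + 4))
    lhs[:m, :m] = k
    lhs[:m, m:] = p
    lhs[m:, :m] = p.T
    inv = np.linalg.inv(lhs)
    b = -inv[:m, :m]
    return 0.5 * (b + b.T)


def bending_energy(source: np.ndarray, target: np.ndarray) -> float:
    """Bending energy of the spline mapping ``source`` onto ``target``."""
    b = bending_energy_matrix(source)
    y = np.asarray(target, dtype=float)
    return float(np.trace(y.T @ b @ y))
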