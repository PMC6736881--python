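"""Vertex-wise surface deviation between two triangulated meshes.

For every vertex of a test mesh, the signed distance to a reference surface
is computed either to the exact closest point on any reference triangle
(``nearest_point`` mode) or to the same-index reference vertex
(``corresponding_vertex`` mode, requiring shared vertex provenance).  The
sign follows the reference's outward normal: positive means the test vertex
lies outside the reference surface.  Distances are in the mesh's units (mm
throughout the pipeline) and are summarized as a histogram plus maximum /
mean positive and negative distances and the standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class DeviationReport:
    """Per-vertex signed deviations with histogram and summary statistics."""

    per_vertex: np.ndarray  # (n,) signed mm
    bin_edges: np.ndarray  # (n_bins + 1,)
    counts: np.ndarray  # (n_bins,)
    stats: dict[str, float]  # max_pos, max_neg, mean_pos, mean_neg, sd

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"vertex": np.arange(self.per_vertex.size),
                             "signed_distance_mm": self.per_vertex})


def _clean_mesh(mesh):
    """Vertices, faces and vertex normals with zero-area faces dropped."""
    v = np.asarray(mesh.vertices, dtype=float)
    f = np.asarray(mesh.faces, dtype=int)
    if v.size == 0 or f.size == 0:
        raise ValueError("empty mesh")
    if f.max() >= v.shape[0]:
        raise ValueError("face indices out of range")
    cross = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
    area2 = np.linalg.norm(cross, axis=1)
    keep = area2 > 1e-14 * max(float(area2.max()), 1.0)
    f = f[keep]
    if f.size == 0:
        raise ValueError("mesh has no non-degenerate faces")
    # area-weighted vertex normals (outward if the mesh is consistently wound)
    fn = cross[keep]
    vn = np.zeros_like(v)
    for c in range(3):
        np.add.at(vn, f[:, c], fn)
    norms = np.linalg.norm(vn, axis=1)
    norms[norms == 0] = 1.0
    vn = vn / norms[:, None]
    return v, f, vn


def _closest_point_triangles(p: np.ndarray, a, b, c):
    """Closest points on triangles (a, b, c) to each point p; vectorized.

    All arrays are (m, 3) for one point against m triangles.  Returns the
    closest points (m, 3) and barycentric coordinates (m, 3).  Standard
    region-classification algorithm; exact up to floating point.
    """
    ab = b - a
    ac = c - a
    ap = p - a
    d1 = (ab * ap).sum(1)
    d2 = (ac * ap).sum(1)
    bp = p - b
    d3 = (ab * bp).sum(1)
    d4 = (ac * bp).sum(1)
    cp = p - c
    d5 = (ab * cp).sum(1)
    d6 = (ac * cp).sum(1)

    va = d3 * d6 - d5 * d4
    vb = d5 * d2 - d1 * d6
    vc = d1 * d4 - d3 * d2

    m = a.shape[0]
    bary = np.empty((m, 3))
    denom_all = va + vb + vc
    denom_all[denom_all == 0] = 1.0
    v = vb / denom_all
    w = vc / denom_all
    bary[:, 0] = 1.0 - v - w
    bary[:, 1] = v
    bary[:, 2] = w

    # vertex regions
    reg_a = (d1 <= 0) & (d2 <= 0)
    reg_b = (d3 >= 0) & (d4 <= d3)
    reg_c = (d6 >= 0) & (d5 <= d6)
    # edge regions
    t_ab = np.divide(d1, d1 - d3, out=np.zeros(m), where=(d1 - d3) != 0)
    reg_ab = (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    t_ac = np.divide(d2, d2 - d6, out=np.zeros(m), where=(d2 - d6) != 0)
    reg_ac = (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    t_bc = np.divide(d4 - d3, (d4 - d3) + (d5 - d6), out=np.zeros(m),
                     where=((d4 - d3) + (d5 - d6)) != 0)
    reg_bc = (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)

    for cond, bary_val in (
        (reg_bc, np.stack([np.zeros(m), 1 - t_bc, t_bc], axis=1)),
        (reg_ac, np.stack([1 - t_ac, np.zeros(m), t_ac], axis=1)),
        (reg_ab, np.stack([1 - t_ab, t_ab, np.zeros(m)], axis=1)),
        (reg_c, np.tile([0.0, 0.0, 1.0], (m, 1))),
        (reg_b, np.tile([0.0, 1.0, 0.0], (m, 1))),
        (reg_a, np.tile([1.0, 0.0, 0.0], (m, 1))),
    ):
        bary[cond] = bary_val[cond]

    closest = bary[:, 0:1] * a + bary[:, 1:2] * b + bary[:, 2:3] * c
    return closest, bary


def deviation(test, reference, mode: str = "nearest_point", n_bins: int = 50) -> DeviationReport:
    """Signed surface deviation of ``test`` against ``reference``.

    Parameters
    ----------
    test, reference : trimesh.Trimesh (or anything with vertices/faces)
        Pre-aligned meshes; no registration is performed here.
    mode : {"nearest_point", "corresponding_vertex"}
        Exact closest point on any reference triangle (default), or
        per-index vertex distance for meshes with shared vertex provenance.
    n_bins : int
        Fixed-width histogram bins spanning [min, max] of the distances.
    """
    tv, _, _ = _clean_mesh(test)
    rv, rf, rvn = _clean_mesh(reference)

    if mode == "corresponding_vertex":
        if tv.shape[0] != rv.shape[0]:
            raise ValueError(
                f"corresponding_vertex mode needs equal vertex counts "
                f"({tv.shape[0]} vs {rv.shape[0]})"
            )
        delta = tv - rv
        d = np.linalg.norm(delta, axis=1)
        sign = np.sign((delta * rvn).sum(1))
        sign[sign == 0] = 1.0
        signed = d * sign
    elif mode == "nearest_point":
        dist = np.empty(tv.shape[0])
        a, b, c = rv[rf[:, 0]], rv[rf[:, 1]], rv[rf[:, 2]]
        for i, p in enumerate(tv):
            cp, bary = _closest_point_triangles(
                np.broadcast_to(p, (rf.shape[0], 3)), a, b, c
            )
            d2 = ((p - cp) ** 2).sum(1)
            j = int(np.argmin(d2))
            dist[i] = np.sqrt(d2[j])
            n_interp = (bary[j, :, None] * rvn[rf[j]]).sum(0)
            nn = np.linalg.norm(n_interp)
            if nn > 0:
                n_interp = n_interp / nn
            s = np.sign(((p - cp[j]) * n_interp).sum())
            dist[i] *= s if s != 0 else 1.0
        signed = dist
    else:
        raise ValueError(f"unknown mode {mode!r}")

    lo, hi = float(signed.min()), float(signed.max())
    if hi - lo < 1e-9:  # (near-)constant deviations still need finite bins
        lo, hi = lo - 0.5, hi + 0.5
    counts, edges = np.histogram(signed, bins=n_bins, range=(lo, hi))
    pos = signed[signed > 0]
    neg = signed[signed < 0]
    stats = {
        "max_pos": float(pos.max()) if pos.size else 0.0,
        "max_neg": float(neg.min()) if neg.size else 0.0,
        "mean_pos": float(pos.mean()) if pos.size else 0.0,
        "mean_neg": float(neg.mean()) if neg.size else 0.0,
        "sd": float(signed.std()),
        "max_abs": float(np.abs(signed).max()),
    }
    return DeviationReport(per_vertex=signed, bin_edges=edges, counts=counts, stats=stats)


def colormapped_ply(test, report: DeviationReport, path) -> None:
    """Write the test mesh with per-vertex signed deviation as vertex colour."""
    import trimesh

    v = np.asarray(test.vertices, dtype=float)
    f = np.asarray(test.faces, dtype=int)
    d = report.per_vertex
    span = max(abs(d.min()), abs(d.max())) or 1.0
    x = (d / span + 1) / 2  # 0..1, 0.5 = zero deviation
    colors = np.zeros((v.shape[0], 4), dtype=np.uint8)
    colors[:, 0] = np.clip(2 * x, 0, 1) * 255
    colors[:, 2] = np.clip(2 * (1 - x), 0, 1) * 255
    colors[:, 1] = (1 - np.abs(2 * x - 1)) * 255
    colors[:, 3] = 255
    mesh = trimesh.Trimesh(vertices=v, faces=f, vertex_colors=colors, process=False)
    mesh.export(path, file_type="ply", encoding="ascii")
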