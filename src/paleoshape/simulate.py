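"""Synthetic tree-structured landmark data with known ground truth.

The generator emulates the structure of the study sample: a skull-like,
bilaterally symmetric landmark template on an ellipsoid (56 fixed landmarks,
116 curve semilandmarks on the face, 608 surface semilandmarks on the
calvaria by default); population mean shapes evolving by Brownian motion on
a dated tree; individual specimens as isotropic Gaussian scatter around
their population mean; and fossil stand-ins with preservation masks shaped
like the comparison analyses A-D.  Every quantity is reproducible from a
single seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .compare import make_analysis_spec
from .geometry import LandmarkConfiguration
from .phylo import Chronogram, build_hypothesis
from .scheme import ROLE_CURVE, ROLE_FIXED, ROLE_SURFACE, LandmarkScheme

# ellipsoid semi-axes of the template cranium, mm (x: left-right, y:
# anterior-posterior, z: inferior-superior)
_SEMI_AXES = np.array([70.0, 90.0, 65.0])


def _on_ellipsoid(theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Points on the template ellipsoid from spherical angles."""
    x = np.sin(phi) * np.cos(theta)
    y = np.sin(phi) * np.sin(theta)
    z = np.cos(phi)
    return np.column_stack([x, y, z]) * _SEMI_AXES


def make_template(
    k_fixed: int = 56,
    n_curves: int = 4,
    curve_len: int = 29,
    n_surface: int = 608,
    seed: int = 0,
) -> tuple[LandmarkScheme, np.ndarray]:
    """Bilaterally symmetric skull-like template on an ellipsoid.

    Defaults reproduce the canonical proportions: 56 fixed landmarks, 116
    curve semilandmarks (4 facial curves of 29) and 608 surface
    semilandmarks on the calvaria, 780 in total.  Curves come in mirrored
    left/right pairs (``n_curves`` must be even), surface points in mirrored
    pairs, and fixed landmarks split between the midline and mirrored pairs.
    The scheme's symmetry pairing is exact by construction.
    """
    if n_curves % 2:
        raise ValueError("n_curves must be even (mirrored curve pairs)")
    if n_surface % 2:
        raise ValueError("n_surface must be even (mirrored point pairs)")
    if k_fixed + n_curves * curve_len + n_surface < 10:
        raise ValueError("template too small")
    rng = np.random.default_rng(seed)

    coords: list[np.ndarray] = []
    roles: list[str] = []
    pairs: list[tuple[int, int]] = []
    midline: list[int] = []

    # fixed landmarks: ~1/3 on the midline (sagittal plane x = 0), rest mirrored
    n_mid = k_fixed // 3
    if (k_fixed - n_mid) % 2:
        n_mid += 1
    phi_mid = np.linspace(0.15, np.pi - 0.15, n_mid)
    theta_mid = np.where(np.arange(n_mid) % 2 == 0, np.pi / 2, -np.pi / 2)
    for p in _on_ellipsoid(theta_mid, phi_mid):
        p[0] = 0.0
        midline.append(len(coords))
        coords.append(p)
        roles.append(ROLE_FIXED)
    n_pairfix = (k_fixed - n_mid) // 2
    theta_r = rng.uniform(-np.pi / 2 + 0.25, np.pi / 2 - 0.25, n_pairfix)
    phi_r = rng.uniform(0.2, np.pi - 0.2, n_pairfix)
    for p in _on_ellipsoid(theta_r, phi_r):
        p[0] = abs(p[0]) + 2.0  # keep clear of the midline
        i = len(coords)
        coords.append(p)
        roles.append(ROLE_FIXED)
        q = p.copy()
        q[0] = -q[0]
        coords.append(q)
        roles.append(ROLE_FIXED)
        pairs.append((i, i + 1))

    # curve semilandmarks: mirrored pairs of arcs on the anterior ("facial")
    # part of the ellipsoid
    curves: list[list[int]] = []
    for c in range(n_curves // 2):
        t = np.linspace(0.25, np.pi - 0.25, curve_len)
        theta = np.full(curve_len, 0.35 + 0.5 * c)
        pts = _on_ellipsoid(theta, t)
        right_chain, left_chain = [], []
        for p in pts:
            i = len(coords)
            coords.append(p)
            roles.append(ROLE_CURVE)
            q = p.copy()
            q[0] = -q[0]
            coords.append(q)
            roles.append(ROLE_CURVE)
            pairs.append((i, i + 1))
            right_chain.append(i)
            left_chain.append(i + 1)
        curves.append(right_chain)
        curves.append(left_chain)

    # surface semilandmarks: mirrored pairs scattered on the upper posterior
    # ("calvarial") part
    n_half = n_surface // 2
    theta_s = rng.uniform(-np.pi / 2 + 0.3, np.pi / 2 - 0.3, n_half)
    phi_s = rng.uniform(0.15, np.pi / 2, n_half)  # upper half
    surf_right: list[int] = []
    surf_left: list[int] = []
    for p in _on_ellipsoid(theta_s + np.pi, phi_s):  # posterior side
        p[0] = abs(p[0]) + 1.0
        i = len(coords)
        coords.append(p)
        roles.append(ROLE_SURFACE)
        q = p.copy()
        q[0] = -q[0]
        coords.append(q)
        roles.append(ROLE_SURFACE)
        pairs.append((i, i + 1))
        surf_right.append(i)
        surf_left.append(i + 1)

    base = np.array(coords)

    # neighbour graph for surface tangent planes: nearest surface points on
    # the same side, mirrored consistently
    surfaces: dict[int, list[int]] = {}
    right_pts = base[surf_right]
    tree = cKDTree(right_pts)
    k_nb = min(7, len(surf_right))
    _, nb = tree.query(right_pts, k=k_nb)
    for row, i in enumerate(surf_right):
        nbr = [surf_right[j] for j in np.atleast_1d(nb[row]) if surf_right[j] != i][:6]
        surfaces[i] = nbr
        surfaces[i + 1] = [j + 1 for j in nbr]  # mirrored partner indices

    scheme = LandmarkScheme(
        n_landmarks=base.shape[0],
        roles=roles,
        curves=curves,
        surfaces=surfaces,
        symmetry_pairs=pairs,
        midline=midline,
    )
    return scheme, base


def simulate_bm_shapes(
    tree: Chronogram, base_shape: np.ndarray, rate: float, seed: int
) -> dict[str, np.ndarray]:
    """Brownian-motion evolution of every coordinate along the tree.

    Each coordinate evolves independently; a child's shape is its parent's
    plus Gaussian noise of variance ``rate * branch_length`` (mm^2; branch
    lengths in ka).  Returns shapes at every node and tip, keyed by node id
    or tip label; the root carries ``base_shape`` itself.
    """
    if rate < 0:
        raise ValueError("rate must be non-negative")
    rng = np.random.default_rng(seed)
    base = np.asarray(base_shape, dtype=float)
    shapes = {tree.root_id: base.copy()}
    for parent, child, length in tree.edges():  # preorder: parents precede children
        step = rng.normal(0.0, np.sqrt(rate * length), size=base.shape)
        shapes[child] = shapes[parent] + step
    return shapes


def sample_population(
    mean_shape: np.ndarray, n: int, within_sd: float, seed: int
) -> np.ndarray:
    """n individuals around a mean shape with isotropic landmark noise (mm)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    mean = np.asarray(mean_shape, dtype=float)
    return mean[None] + rng.normal(0.0, within_sd, size=(n, *mean.shape))


def apply_fossil_mask(
    config: LandmarkConfiguration,
    pattern: str,
    scheme: LandmarkScheme,
    seed: int | None = None,
    unilateral_fraction: float = 0.0,
) -> LandmarkConfiguration:
    """Mark landmarks missing the way a fossil of analysis A-D preserves them.

    Everything outside the analysis subset is flagged missing; optionally a
    random fraction of the surviving right-side landmarks is also deleted to
    exercise mirror-based imputation (deterministic given ``seed``).
    """
    spec = make_analysis_spec(pattern, scheme)
    out = config.copy()
    missing = np.ones(scheme.n_landmarks, dtype=bool)
    missing[spec.landmark_indices] = False
    if unilateral_fraction > 0:
        if seed is None:
            raise ValueError("seed required for random unilateral deletions")
        rng = np.random.default_rng(seed)
        right = np.array([a for a, _ in scheme.symmetry_pairs], dtype=int)
        right = right[~missing[right]]
        n_del = int(round(unilateral_fraction * right.size))
        if n_del:
            missing[rng.choice(right, size=n_del, replace=False)] = True
    out.missing = missing
    out.coords = out.coords.copy()
    out.coords[missing] = np.nan
    prov = np.array(["observed"] * scheme.n_landmarks, dtype=object)
    prov[missing] = "missing"
    out.provenance = prov
    return out


# number of specimens per fossil terminal taxon, mirroring the study sample
FOSSIL_TAXON_SIZES = {
    "Hhabilis": 2,
    "Hergaster": 3,
    "Hgeorgicus": 2,
    "Neandertal_Early": 2,
    "Neandertal_NearEast": 2,
    "Neandertal_SouthEurope": 2,
    "Neandertal_WestEurope": 2,
    "EarlyHsapiens": 3,
}

# stand-in LMP fossils and the analysis pattern shaped on each one's
# preservation (analysis A is the full template; B: Omo II & LH18; C:
# Florisbad; D: KNM-ES 11693)
LMP_FOSSILS = {
    "Florisbad": "C",
    "OmoII": "B",
    "LH18": "B",
    "KNM-ES11693": "D",
    "Irhoud1": "A",
}


@dataclass
class SyntheticDataset:
    """A complete simulated study with known truth at every node."""

    tree: Chronogram
    scheme: LandmarkScheme
    base_shape: np.ndarray
    rate: float
    within_sd: float
    individuals_per_taxon: dict[str, int]
    true_node_shapes: dict[str, np.ndarray]
    individuals: list[LandmarkConfiguration]
    fossils: list[LandmarkConfiguration]
    seed: int

    def manifest(self) -> dict:
        return {
            "seed": int(self.seed),
            "rate": float(self.rate),
            "within_sd": float(self.within_sd),
            "n_landmarks": int(self.scheme.n_landmarks),
            "individuals_per_taxon": {k: int(v) for k, v in self.individuals_per_taxon.items()},
            "n_individuals": len(self.individuals),
            "fossils": [f.specimen_id for f in self.fossils],
        }


def make_dataset(
    preset: str = "h1",
    rate: float = 0.002,
    within_sd: float = 1.0,
    n_extant: int = 10,
    seed: int = 0,
    template_kwargs: dict | None = None,
    with_fossils: bool = True,
    fossil_divergence_ka: float = 150.0,
) -> SyntheticDataset:
    """Simulate the full study structure on a preset tree.

    Population means evolve by Brownian motion (``rate`` in mm^2/ka per
    coordinate); every extant population gets ``n_extant`` individuals and
    fossil terminal taxa their study sample sizes; LMP fossil stand-ins
    branch off the modern-human root shape with ``fossil_divergence_ka`` of
    extra Brownian evolution, then receive their analysis-style
    preservation masks.  All randomness flows from ``seed``.
    """
    rng = np.random.default_rng(seed)
    scheme, base = make_template(seed=int(rng.integers(2**31)), **(template_kwargs or {}))
    tree = build_hypothesis(preset)
    shapes = simulate_bm_shapes(tree, base, rate, seed=int(rng.integers(2**31)))

    individuals: list[LandmarkConfiguration] = []
    sizes: dict[str, int] = {}
    for taxon in tree.tip_labels:
        n = FOSSIL_TAXON_SIZES.get(taxon, n_extant)
        sizes[taxon] = n
        arr = sample_population(shapes[taxon], n, within_sd, seed=int(rng.integers(2**31)))
        for i in range(n):
            individuals.append(
                LandmarkConfiguration(f"{taxon}_{i}", arr[i], group=taxon)
            )

    fossils: list[LandmarkConfiguration] = []
    if with_fossils:
        # LMP stand-ins: extra BM drift from the modern-human clade root
        modern_root = tree.mrca("EarlyHsapiens", tree.tip_labels[-1])
        for name, pattern in LMP_FOSSILS.items():
            drift = rng.normal(0.0, np.sqrt(rate * fossil_divergence_ka), size=base.shape)
            noisy = shapes[modern_root] + drift + rng.normal(0.0, within_sd, size=base.shape)
            cfg = LandmarkConfiguration(name, noisy)
            fossils.append(
                apply_fossil_mask(cfg, pattern, scheme, seed=int(rng.integers(2**31)))
            )

    return SyntheticDataset(
        tree=tree,
        scheme=scheme,
        base_shape=base,
        rate=rate,
        within_sd=within_sd,
        individuals_per_taxon=sizes,
        true_node_shapes=shapes,
        individuals=individuals,
        fossils=fossils,
        seed=seed,
    )


def write_dataset(ds: SyntheticDataset, outdir) -> None:
    """Write a dataset as CSV landmark files + Newick + JSON manifest."""
    from .io import write_landmarks_csv
    from .phylo import write_newick

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_newick(ds.tree, out / "tree.nwk")
    ds.scheme.to_yaml(out / "scheme.yaml")
    lm = out / "landmarks"
    lm.mkdir(exist_ok=True)
    for c in ds.individuals + ds.fossils:
        write_landmarks_csv(c, lm / f"{c.specimen_id}.csv")
    with open(out / "manifest.json", "w") as fh:
        json.dump(ds.manifest(), fh, indent=2)
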