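"""Landmark template description: roles, curve/surface topology, bilateral symmetry.

A :class:`LandmarkScheme` declares, for a template of ``n_landmarks`` points,
which landmarks are fixed anatomical (type I) landmarks, which are curve
semilandmarks (ordered chains that may slide along their tangent), and which
are surface semilandmarks (free to slide in a local tangent plane estimated
from a declared neighbour set).  Bilateral symmetry is declared as left/right
index pairs plus a midline set of unpaired landmarks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

ROLE_FIXED = "fixed"
ROLE_CURVE = "curve"
ROLE_SURFACE = "surface"
_ROLES = (ROLE_FIXED, ROLE_CURVE, ROLE_SURFACE)


class SchemeError(ValueError):
    """Raised when a landmark scheme is internally inconsistent."""


@dataclass
class LandmarkScheme:
    """Template topology for a landmark configuration.

    Parameters
    ----------
    n_landmarks : int
        Total number of landmarks in the template.
    roles : sequence of str
        Per-landmark role, each one of ``"fixed"``, ``"curve"``, ``"surface"``.
    curves : list of list of int
        Ordered index chains (each of length >= 3) of curve semilandmarks.
    surfaces : dict mapping int -> list of int
        For every surface semilandmark, the indices of its neighbours
        (>= 3) used to estimate the local tangent plane.
    symmetry_pairs : list of (int, int)
        ``(left, right)`` landmark index pairs.
    midline : list of int
        Unpaired landmarks lying on the midsagittal plane.
    """

    n_landmarks: int
    roles: list[str]
    curves: list[list[int]] = field(default_factory=list)
    surfaces: dict[int, list[int]] = field(default_factory=dict)
    symmetry_pairs: list[tuple[int, int]] = field(default_factory=list)
    midline: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.roles = list(self.roles)
        self.curves = [list(map(int, c)) for c in self.curves]
        self.surfaces = {int(i): list(map(int, nb)) for i, nb in self.surfaces.items()}
        self.symmetry_pairs = [(int(a), int(b)) for a, b in self.symmetry_pairs]
        self.midline = [int(i) for i in self.midline]
        self.validate()

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        k = self.n_landmarks
        if k <= 0:
            raise SchemeError("n_landmarks must be positive")
        if len(self.roles) != k:
            raise SchemeError(f"roles has length {len(self.roles)}, expected {k}")
        for r in self.roles:
            if r not in _ROLES:
                raise SchemeError(f"unknown role {r!r}")

        seen_in_curves: set[int] = set()
        for ci, chain in enumerate(self.curves):
            if len(chain) < 3:
                raise SchemeError(f"curve {ci} has fewer than 3 landmarks")
            for idx in chain:
                self._check_index(idx)
                if self.roles[idx] != ROLE_CURVE:
                    raise SchemeError(f"landmark {idx} in curve {ci} has role {self.roles[idx]!r}")
                if idx in seen_in_curves:
                    raise SchemeError(f"landmark {idx} appears in two curves")
                seen_in_curves.add(idx)
        curve_role = {i for i, r in enumerate(self.roles) if r == ROLE_CURVE}
        if seen_in_curves != curve_role:
            raise SchemeError("curve-role landmarks and curve chains do not match")

        surf_role = {i for i, r in enumerate(self.roles) if r == ROLE_SURFACE}
        if set(self.surfaces) != surf_role:
            raise SchemeError("surface-role landmarks and surface neighbour sets do not match")
        for idx, nb in self.surfaces.items():
            if len(nb) < 3:
                raise SchemeError(f"surface landmark {idx} has fewer than 3 neighbours")
            for j in nb:
                self._check_index(j)

        paired: set[int] = set()
        for a, b in self.symmetry_pairs:
            self._check_index(a)
            self._check_index(b)
            if a == b:
                raise SchemeError(f"landmark {a} paired with itself")
            if a in paired or b in paired:
                raise SchemeError("landmark appears in more than one symmetry pair")
            paired.update((a, b))
        mid = set(self.midline)
        for idx in mid:
            self._check_index(idx)
        if paired & mid:
            raise SchemeError("landmark both paired and on midline")
        if paired | mid != set(range(k)):
            missing = sorted(set(range(k)) - (paired | mid))
            raise SchemeError(f"landmarks neither paired nor midline: {missing}")

    def _check_index(self, idx: int) -> None:
        if not 0 <= idx < self.n_landmarks:
            raise SchemeError(f"landmark index {idx} out of range [0, {self.n_landmarks})")

    # -- convenience --------------------------------------------------------
    @property
    def fixed_indices(self) -> np.ndarray:
        return np.array([i for i, r in enumerate(self.roles) if r == ROLE_FIXED], dtype=int)

    @property
    def curve_indices(self) -> np.ndarray:
        return np.array(sorted({i for c in self.curves for i in c}), dtype=int)

    @property
    def surface_indices(self) -> np.ndarray:
        return np.array(sorted(self.surfaces), dtype=int)

    def partner(self) -> np.ndarray:
        """Index map sending each landmark to its bilateral partner (self on midline)."""
        p = np.arange(self.n_landmarks)
        for a, b in self.symmetry_pairs:
            p[a], p[b] = b, a
        return p

    # -- I/O -----------------------------------------------------------------
    def to_yaml(self, path) -> None:
        doc = {
            "n_landmarks": int(self.n_landmarks),
            "roles": list(self.roles),
            "curves": [list(map(int, c)) for c in self.curves],
            "surfaces": {int(i): list(map(int, nb)) for i, nb in self.surfaces.items()},
            "symmetry_pairs": [[int(a), int(b)] for a, b in self.symmetry_pairs],
            "midline": [int(i) for i in self.midline],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "LandmarkScheme":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(
            n_landmarks=doc["n_landmarks"],
            roles=doc["roles"],
            curves=doc.get("curves", []),
            surfaces=doc.get("surfaces", {}),
            symmetry_pairs=[tuple(p) for p in doc.get("symmetry_pairs", [])],
            midline=doc.get("midline", []),
        )
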