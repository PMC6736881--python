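"""Dated phylogenies, Brownian-motion ancestral estimation, phylogenetic signal.

A :class:`Chronogram` is a fully resolved rooted tree with branch lengths in
ka.  Tips need not be contemporaneous: fossil terminals sit at their own
ages, so root-to-tip path lengths differ.  All phylogenetic computation runs
through shared-path covariance matrices C, where ``C[i, j]`` is the path
length from the root to the most recent common ancestor of tips i and j.

Ancestral states under Brownian motion are generalized-least-squares
estimates: the root state is ``a = (1'C^-1 1)^-1 1'C^-1 y`` and every other
internal node is estimated by re-rooting the tree at that node and applying
the same formula, which reproduces the joint maximum-likelihood node states.
The ML rate is ``sigma^2 = (y - 1a)'C^-1(y - 1a)/N`` (an REML variant,
dividing by N-1, is available).

Phylogenetic signal for multivariate data is Blomberg's K generalized to
p traits (Kmult), tested by permuting tip rows.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import scipy.linalg


class TreeError(ValueError):
    """Tree is not a valid chronogram (polytomies, missing lengths...)."""


@dataclass
class AncestralEstimate:
    """Per-node ML ancestral state under Brownian motion."""

    node_id: str
    values: np.ndarray  # (p,)
    variances: np.ndarray  # (p,)
    ci95: np.ndarray  # (p, 2) rows (lo, hi)
    sigma2: np.ndarray  # (p,) ML rate per unit branch length


@dataclass
class KmultResult:
    """Multivariate phylogenetic-signal statistic with its permutation test."""

    K: float
    p_value: float
    n_perm: int
    seed: int


class Chronogram:
    """Rooted binary dated tree with branch lengths in ka.

    Internally a flat node table in preorder; node 0 is the root.  Internal
    nodes get stable identifiers ``n<preorder index>`` (the root is ``n0``);
    tips are identified by their labels.
    """

    def __init__(
        self,
        parents: np.ndarray,
        lengths: np.ndarray,
        labels: list[str | None],
        allow_polytomies: bool = False,
    ):
        self._parents = np.asarray(parents, dtype=int)
        self._lengths = np.asarray(lengths, dtype=float)
        self._labels = list(labels)
        n = len(self._labels)
        children: list[list[int]] = [[] for _ in range(n)]
        for i in range(1, n):
            children[self._parents[i]].append(i)
        self._children = children
        for i, ch in enumerate(children):
            if len(ch) == 1 or (len(ch) > 2 and not allow_polytomies):
                raise TreeError(f"node {i} has {len(ch)} children; tree must be fully resolved")
            if len(ch) == 0 and self._labels[i] is None:
                raise TreeError(f"tip node {i} has no label")
        if np.any(self._lengths[1:] <= 0):
            bad = np.where(self._lengths[1:] <= 0)[0] + 1
            raise TreeError(f"non-positive branch lengths at nodes {bad.tolist()}")
        # depths from root
        depth = np.zeros(n)
        for i in range(1, n):
            depth[i] = depth[self._parents[i]] + self._lengths[i]
        self._depth = depth
        self._tips = [i for i in range(n) if not children[i]]
        if len(set(self._labels[i] for i in self._tips)) != len(self._tips):
            raise TreeError("duplicate tip labels")
        # ancestor paths (root..node) for MRCA queries; trees here are small
        paths: list[tuple[int, ...]] = [()] * n
        for i in range(n):
            p = [] if i == 0 else list(paths[self._parents[i]])
            p.append(i)
            paths[i] = tuple(p)
        self._paths = paths

    # -- construction --------------------------------------------------------
    @classmethod
    def from_newick(cls, newick: str, allow_polytomies: bool = False) -> "Chronogram":
        tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
        return cls._from_dendropy(tree, allow_polytomies=allow_polytomies)

    @classmethod
    def star(cls, labels: list[str], branch_length: float = 1.0) -> "Chronogram":
        """Star phylogeny: every tip attached directly to the root.

        The shared-path covariance of a unit-branch star tree is the
        identity, the degenerate reference case for ancestral estimation
        (root = tip mean) and phylogenetic signal (K = 1).
        """
        n = len(labels)
        parents = np.concatenate([[-1], np.zeros(n, dtype=int)])
        lengths = np.concatenate([[0.0], np.full(n, float(branch_length))])
        return cls(parents, lengths, [None, *labels], allow_polytomies=True)

    @classmethod
    def _from_dendropy(cls, tree: dendropy.Tree, allow_polytomies: bool = False) -> "Chronogram":
        parents, lengths, labels = [], [], []
        index: dict[int, int] = {}
        for node in tree.preorder_node_iter():
            i = len(labels)
            index[id(node)] = i
            if node.parent_node is None:
                parents.append(-1)
                lengths.append(0.0)
            else:
                parents.append(index[id(node.parent_node)])
                if node.edge.length is None:
                    raise TreeError("tree has edges without branch lengths")
                lengths.append(float(node.edge.length))
            labels.append(node.taxon.label if node.taxon is not None else None)
        return cls(np.array(parents), np.array(lengths), labels, allow_polytomies=allow_polytomies)

    # -- basic properties ----------------------------------------------------
    @property
    def n_tips(self) -> int:
        return len(self._tips)

    @property
    def tip_labels(self) -> list[str]:
        return [self._labels[i] for i in self._tips]

    @property
    def internal_node_ids(self) -> list[str]:
        return [f"n{i}" for i in range(len(self._labels)) if self._children[i]]

    @property
    def root_id(self) -> str:
        return "n0"

    @property
    def root_age(self) -> float:
        """Root age in ka, taking the deepest tip to be at age 0."""
        return float(self._depth[self._tips].max())

    def node_index(self, node_id: str) -> int:
        if node_id.startswith("n"):
            try:
                i = int(node_id[1:])
            except ValueError:
                i = -1
            if 0 <= i < len(self._labels) and self._children[i]:
                return i
        for i in self._tips:
            if self._labels[i] == node_id:
                return i
        raise KeyError(f"unknown node {node_id!r}")

    def node_age(self, node_id: str) -> float:
        return self.root_age - float(self._depth[self.node_index(node_id)])

    def tip_ages(self) -> dict[str, float]:
        return {self._labels[i]: self.root_age - float(self._depth[i]) for i in self._tips}

    def edges(self) -> list[tuple[str, str, float]]:
        """(parent_id, child_id, branch length) triples; tips named by label."""
        out = []
        for i in range(1, len(self._labels)):
            child = self._labels[i] if not self._children[i] else f"n{i}"
            out.append((f"n{self._parents[i]}", child, float(self._lengths[i])))
        return out

    def mrca_index(self, i: int, j: int) -> int:
        pi, pj = self._paths[i], self._paths[j]
        m = 0
        for a, b in zip(pi, pj):
            if a != b:
                break
            m = a
        return m

    def distance(self, i: int, j: int) -> float:
        m = self.mrca_index(i, j)
        return float(self._depth[i] + self._depth[j] - 2 * self._depth[m])

    def mrca(self, a: str, b: str) -> str:
        """Node id of the most recent common ancestor of two named nodes."""
        m = self.mrca_index(self.node_index(a), self.node_index(b))
        return f"n{m}" if self._children[m] else self._labels[m]

    # -- covariance matrices -------------------------------------------------
    def _tip_order(self, taxa: list[str] | None) -> list[int]:
        if taxa is None:
            return list(self._tips)
        lab2idx = {self._labels[i]: i for i in self._tips}
        missing = [t for t in taxa if t not in lab2idx]
        if missing:
            raise KeyError(f"taxa not in tree: {missing}")
        return [lab2idx[t] for t in taxa]

    def covariance(self, taxa: list[str] | None = None) -> np.ndarray:
        """Shared-path matrix C from the root (N x N, ka)."""
        order = self._tip_order(taxa)
        n = len(order)
        c = np.empty((n, n))
        for a in range(n):
            for b in range(a, n):
                m = self.mrca_index(order[a], order[b])
                c[a, b] = c[b, a] = self._depth[m]
        return c

    def rerooted_covariance(self, node_id: str, taxa: list[str] | None = None) -> np.ndarray:
        """Shared-path matrix with paths measured from ``node_id`` instead of the root.

        Uses ``C_v[i, j] = (d(v, i) + d(v, j) - d(i, j)) / 2`` with d the
        patristic distance on the unrooted tree.
        """
        v = self.node_index(node_id)
        order = self._tip_order(taxa)
        dv = np.array([self.distance(v, i) for i in order])
        n = len(order)
        c = np.empty((n, n))
        for a in range(n):
            for b in range(a, n):
                c[a, b] = c[b, a] = 0.5 * (dv[a] + dv[b] - self.distance(order[a], order[b]))
        return c

    # -- editing -------------------------------------------------------------
    def drop_tips(self, labels: list[str]) -> "Chronogram":
        """Remove the named tips, collapsing resulting unifurcations."""
        drop = set(labels)
        unknown = drop - set(self.tip_labels)
        if unknown:
            raise KeyError(f"tips not in tree: {sorted(unknown)}")

        def build(i: int):
            if not self._children[i]:
                if self._labels[i] in drop:
                    return None
                return ("leaf", self._labels[i], 0.0)
            kept = []
            for ch in self._children[i]:
                sub = build(ch)
                if sub is not None:
                    kept.append((sub, self._lengths[ch]))
            if not kept:
                return None
            if len(kept) == 1:
                sub, extra = kept[0]
                kind, payload, acc = sub
                return (kind, payload, acc + extra)
            return ("node", kept, 0.0)

        top = build(0)
        if top is None or top[0] == "leaf":
            raise TreeError("pruning removed too much of the tree")

        parents: list[int] = []
        lengths: list[float] = []
        labels_out: list[str | None] = []

        # accumulated collapse length is carried in the node tuple
        def emit2(node, parent: int, edge: float) -> None:
            kind, payload, acc = node
            i = len(labels_out)
            parents.append(parent)
            lengths.append(edge + acc)
            if kind == "leaf":
                labels_out.append(payload)
            else:
                labels_out.append(None)
                for sub, el in payload:
                    emit2(sub, i, el)

        parents.clear()
        lengths.clear()
        labels_out.clear()
        emit2(top, -1, 0.0)
        return Chronogram(np.array(parents), np.array(lengths), labels_out)

    # -- serialization -------------------------------------------------------
    def to_newick(self) -> str:
        def rec(i: int) -> str:
            if not self._children[i]:
                return f"{_quote(self._labels[i])}:{_fmt(self._lengths[i])}"
            inner = ",".join(rec(ch) for ch in self._children[i])
            if i == 0:
                return f"({inner})"
            return f"({inner}):{_fmt(self._lengths[i])}"

        return rec(0) + ";"


def _fmt(x: float) -> str:
    return format(float(x), ".12g")


def _quote(label: str) -> str:
    if any(ch in label for ch in " (),:;[]'"):
        return "'" + label.replace("'", "''") + "'"
    return label


def read_newick(path) -> Chronogram:
    """Read a dated tree from a Newick file (branch lengths in ka)."""
    with open(path) as fh:
        return Chronogram.from_newick(fh.read())


def write_newick(tree: Chronogram, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")


def phylo_covariance(tree: Chronogram, taxa: list[str] | None = None) -> np.ndarray:
    """Shared root-to-MRCA path matrix C (ka) in the given taxon order."""
    return tree.covariance(taxa)


# ---------------------------------------------------------------------------
# preset hominin chronograms
# ---------------------------------------------------------------------------
# Nested (age, children) description; leaves are (label, tip age).  Anchors:
# sapiens-Neandertal LCA 600 ka, Neandertal clade root 300 ka, modern clade
# root 305 ka, early out-of-Africa (Sahul) 90 ka, main out-of-Africa 75 ka,
# deepest extant split 260 ka; fossil tip ages are specimen chronology
# midpoints averaged per terminal taxon.  Remaining node ages are package
# choices documented in docs/methods.md.

AFRICAN_DROPPED_IN_B = ["San", "Khoikhoi", "Bayaka", "Mbuti"]

_INUIT_NA = (28.0, [
    ("InuitGreenland", 0.0),
    (18.0, [("InuitAlaska", 0.0), ("NorthAmerica", 0.0)]),
])
_ASIA = (55.0, [
    ("SouthAsia", 0.0),
    (48.0, [
        ("SouthEastAsia", 0.0),
        (40.0, [
            ("EastAsiaChina", 0.0),
            (35.0, [("EastAsiaJapan", 0.0), _INUIT_NA]),
        ]),
    ]),
])
_EUROPE = (40.0, [("SouthEurope", 0.0), ("NorthEurope", 0.0)])
_SAHUL = (50.0, [("Australia", 0.0), ("Papua", 0.0)])

_EURASIA_H1 = (65.0, [_EUROPE, _ASIA])
_NONAFRICAN_H2 = (65.0, [_SAHUL, (60.0, [_EUROPE, _ASIA])])


def _african_ladder(inner):
    return (260.0, [
        ("San", 0.0),
        (240.0, [
            ("Khoikhoi", 0.0),
            (220.0, [
                (120.0, [("Mbuti", 0.0), ("Bayaka", 0.0)]),
                (190.0, [
                    ("WestAfrica", 0.0),
                    (170.0, [
                        ("CentralAfrica", 0.0),
                        (150.0, [
                            ("SouthAfrica", 0.0),
                            (130.0, [
                                ("EastAfrica", 0.0),
                                (110.0, [("Nilotic", 0.0), inner]),
                            ]),
                        ]),
                    ]),
                ]),
            ]),
        ]),
    ])


_EXTANT_H1 = _african_ladder(
    (90.0, [_SAHUL, (75.0, [("NorthAfrica", 0.0), _EURASIA_H1])])
)
_EXTANT_H2 = _african_ladder(
    (75.0, [("NorthAfrica", 0.0), _NONAFRICAN_H2])
)

_NEANDERTALS = (300.0, [
    ("Neandertal_Early", 195.0),
    (150.0, [
        ("Neandertal_NearEast", 50.0),
        (90.0, [("Neandertal_SouthEurope", 53.5), ("Neandertal_WestEurope", 55.0)]),
    ]),
])


def _homo_tree(extant):
    modern = (305.0, [("EarlyHsapiens", 100.0), extant])
    return (2000.0, [
        ("Hhabilis", 1800.0),
        (1900.0, [
            ("Hgeorgicus", 1770.0),
            (1800.0, [("Hergaster", 1567.0), (600.0, [_NEANDERTALS, modern])]),
        ]),
    ])


EARLY_HOMO = ["Hhabilis", "Hgeorgicus", "Hergaster"]
NEANDERTAL_TAXA = [
    "Neandertal_Early",
    "Neandertal_NearEast",
    "Neandertal_SouthEurope",
    "Neandertal_WestEurope",
]

_PRESETS = ("h1", "h2", "h1b", "h2b")


def _nested_to_newick(node, parent_age: float | None = None) -> str:
    if isinstance(node[0], str):
        label, age = node
        return f"{_quote(label)}:{_fmt(parent_age - age)}"
    age, children = node
    inner = ",".join(_nested_to_newick(ch, age) for ch in children)
    if parent_age is None:
        return f"({inner})"
    return f"({inner}):{_fmt(parent_age - age)}"


def build_hypothesis(name: str) -> Chronogram:
    """Return one of the built-in dated hypothesis trees ``h1/h2/h1b/h2b``.

    ``h1`` includes an early out-of-Africa for the Sahul populations at 90 ka;
    ``h2`` has a single out-of-Africa at 75 ka; the ``b`` variants drop the
    Khoisan and Pygmy populations (San, Khoikhoi, Bayaka, Mbuti).
    """
    if name not in _PRESETS:
        raise ValueError(f"unknown hypothesis {name!r}; presets are {list(_PRESETS)}")
    base = _homo_tree(_EXTANT_H1 if name.startswith("h1") else _EXTANT_H2)
    tree = Chronogram.from_newick(_nested_to_newick(base) + ";")
    if name.endswith("b"):
        tree = tree.drop_tips(AFRICAN_DROPPED_IN_B)
    return tree


# ---------------------------------------------------------------------------
# Brownian-motion ancestral states
# ---------------------------------------------------------------------------

def _gls_root(c: np.ndarray, y: np.ndarray):
    """GLS root mean and its structural variance factor for covariance c.

    Returns ``(a, vfac, cinv_resid)`` with ``a`` the (p,) root estimate,
    ``vfac = (1'C^-1 1)^-1`` and ``cinv_resid = C^-1 (y - 1a)``.
    """
    try:
        cho = scipy.linalg.cho_factor(c)
    except scipy.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(f"phylogenetic covariance not positive definite: {err}")
    one = np.ones(c.shape[0])
    ci1 = scipy.linalg.cho_solve(cho, one)
    vfac = 1.0 / float(one @ ci1)
    a = vfac * (ci1 @ y)
    resid = y - np.outer(one, a)
    return a, vfac, scipy.linalg.cho_solve(cho, resid), resid


def bm_ancestral_states(
    tree: Chronogram,
    tip_values: np.ndarray,
    taxa: list[str] | None = None,
    method: str = "ML",
) -> dict[str, AncestralEstimate]:
    """Maximum-likelihood ancestral states under Brownian motion, per node.

    Parameters
    ----------
    tree : Chronogram
    tip_values : ndarray (N, p)
        Trait values ordered to match ``taxa`` (default: tree tip order).
    taxa : list of str, optional
        Explicit tip ordering of the rows of ``tip_values``.
    method : {"ML", "REML"}
        Rate estimated dividing by N (ML, default) or N-1 (REML).

    Returns
    -------
    dict mapping internal node id to :class:`AncestralEstimate`.  Each node
    is the GLS root estimate of the tree re-rooted at that node; the 95%
    confidence interval is ``estimate +/- 1.96 sqrt(sigma2 * (1'C_v^-1 1)^-1)``.
    """
    y = np.asarray(tip_values, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    if y.shape[1] < 1:
        raise ValueError("need at least one trait")
    if y.shape[0] != tree.n_tips:
        raise ValueError(f"{y.shape[0]} rows of tip values for {tree.n_tips} tips")
    if method not in ("ML", "REML"):
        raise ValueError("method must be 'ML' or 'REML'")

    c = tree.covariance(taxa)
    n = c.shape[0]
    a_root, _, cinv_resid, resid = _gls_root(c, y)
    denom = n if method == "ML" else n - 1
    sigma2 = np.einsum("ij,ij->j", resid, cinv_resid) / denom

    out: dict[str, AncestralEstimate] = {}
    for node_id in tree.internal_node_ids:
        cv = c if node_id == tree.root_id else tree.rerooted_covariance(node_id, taxa)
        a_v, vfac, _, _ = _gls_root(cv, y)
        var = sigma2 * vfac
        half = 1.96 * np.sqrt(var)
        ci = np.stack([a_v - half, a_v + half], axis=1)
        out[node_id] = AncestralEstimate(node_id, a_v, var, ci, sigma2.copy())
    return out


class BrownianAncestralReconstruction:
    """Estimator-style wrapper around :func:`bm_ancestral_states`.

    Parameters
    ----------
    tree : Chronogram
    method : {"ML", "REML"}

    Attributes (after ``fit``)
    --------------------------
    nodes_ : dict node_id -> AncestralEstimate
    root_ : AncestralEstimate
    sigma2_ : ndarray (p,)
    """

    def __init__(self, tree: Chronogram, method: str = "ML"):
        self.tree = tree
        self.method = method

    def get_params(self, deep: bool = True):
        return {"tree": self.tree, "method": self.method}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, X, y=None, taxa: list[str] | None = None):
        self.nodes_ = bm_ancestral_states(self.tree, X, taxa=taxa, method=self.method)
        self.root_ = self.nodes_[self.tree.root_id]
        self.sigma2_ = self.root_.sigma2
        return self


# ---------------------------------------------------------------------------
# multivariate phylogenetic signal
# ---------------------------------------------------------------------------

def kmult(
    tree: Chronogram,
    tip_values: np.ndarray,
    n_perm: int = 999,
    seed: int | None = None,
    taxa: list[str] | None = None,
) -> KmultResult:
    """Multivariate Blomberg's K with a tip-permutation test.

    ``K = [tr(S'S) / tr(S'C^-1 S)] / [(tr C - N (1'C^-1 1)^-1) / (N - 1)]``
    with ``S = Y - 1a`` and ``a`` the phylogenetic GLS mean.  Values near 1
    match Brownian-motion expectation; the p-value is
    ``(1 + #{K_perm >= K_obs}) / (1 + n_perm)`` over random permutations of
    the tip rows.
    """
    if seed is None:
        raise ValueError("a seed is required for the permutation test")
    y = np.asarray(tip_values, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    n = y.shape[0]
    if n < 4:
        raise ValueError("Kmult needs at least 4 tips")
    if n != tree.n_tips:
        raise ValueError(f"{n} rows of tip values for {tree.n_tips} tips")
    if float(((y - y.mean(0)) ** 2).sum()) == 0.0:
        raise ValueError("tip values have zero variance; K undefined")

    c = tree.covariance(taxa)
    cho = scipy.linalg.cho_factor(c)
    one = np.ones(n)
    ci1 = scipy.linalg.cho_solve(cho, one)
    vfac = 1.0 / float(one @ ci1)
    expectation = (np.trace(c) - n * vfac) / (n - 1)

    def stat(yy: np.ndarray) -> float:
        a = vfac * (ci1 @ yy)
        s = yy - np.outer(one, a)
        num = float((s * s).sum())
        den = float((s * scipy.linalg.cho_solve(cho, s)).sum())
        return (num / den) / expectation

    k_obs = stat(y)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if stat(y[perm]) >= k_obs:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return KmultResult(K=k_obs, p_value=p, n_perm=n_perm, seed=seed)
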