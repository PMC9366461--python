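"""Phylogeny input, validation, and tree-derived matrices.

The central objects are :class:`Phylogeny`, a lightweight array-based view of
a rooted tree with branch lengths, and the shared-branch-length matrix ``T``
whose entry ``T[i, j]`` is the time from the root to the most recent common
ancestor of tips ``i`` and ``j``.  Under Brownian motion with rate ``s2`` the
tip values are jointly Gaussian with covariance ``s2 * T``, so ``T`` carries
all the phylogenetic structure the regression machinery needs.

Tip order convention: the tree's post-order tip sequence is canonical.  Every
vector and matrix produced by this package is aligned to it, and trait tables
are joined by label against it (unmatched labels are an error, never silently
dropped).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .errors import (
    DuplicateTipLabelError,
    LabelMismatchError,
    MissingBranchLengthError,
    NewickParseError,
    NonUltrametricError,
    SingularMatrixError,
    ValidationError,
)

#: relative spread of root-to-tip depths accepted as "ultrametric"
ULTRAMETRIC_RTOL = 1e-6


@dataclass
class Phylogeny:
    """Rooted phylogeny with branch lengths, stored as flat preorder arrays.

    Attributes
    ----------
    parent : ndarray of int
        ``parent[k]`` is the preorder index of node ``k``'s parent; the root
        (index 0) has parent ``-1``.
    edge_length : ndarray of float
        Length of the edge above each node; 0 for the root.
    children : list of list of int
        Child indices per node, in input order.
    tip_node : ndarray of int
        Preorder node index of each tip, in canonical (post-order) tip order.
    tip_labels : list of str
        Labels matching ``tip_node``.
    original_height : float or None
        Height of the tree before :func:`scale_to_unit_height`, retained so
        rate estimates can be converted back to the original time units.
    """

    parent: np.ndarray
    edge_length: np.ndarray
    children: list
    tip_node: np.ndarray
    tip_labels: list
    original_height: float | None = None
    _depths: np.ndarray = field(default=None, repr=False)

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    def node_depths(self) -> np.ndarray:
        """Distance from the root to every node (preorder indexing)."""
        if self._depths is None:
            d = np.zeros(self.n_nodes)
            for k in range(1, self.n_nodes):
                d[k] = d[self.parent[k]] + self.edge_length[k]
            self._depths = d
        return self._depths

    def tip_depths(self) -> np.ndarray:
        return self.node_depths()[self.tip_node]

    @property
    def height(self) -> float:
        """Maximum root-to-tip distance."""
        return float(self.tip_depths().max())

    def is_ultrametric(self, rtol: float = ULTRAMETRIC_RTOL) -> bool:
        d = self.tip_depths()
        return float(d.max() - d.min()) <= rtol * float(d.max())

    def to_newick(self) -> str:
        """Serialize back to a Newick string (branch lengths kept)."""

        def rec(k: int) -> str:
            if not self.children[k]:
                lab = self.tip_labels[int(np.where(self.tip_node == k)[0][0])]
                return f"{lab}:{self.edge_length[k]:.12g}"
            inner = ",".join(rec(c) for c in self.children[k])
            if k == 0:
                return f"({inner});"
            return f"({inner}):{self.edge_length[k]:.12g}"

        return rec(0)


@dataclass
class SharedBranchMatrix:
    """Matrix of shared branch lengths T with its tip order.

    ``T[i, j]`` is the depth of the MRCA of tips i and j; the diagonal holds
    the root-to-tip distances (all 1 on a unit-height ultrametric tree).  T is
    symmetric and positive semidefinite.
    """

    T: np.ndarray
    tip_order: list

    @property
    def n(self) -> int:
        return self.T.shape[0]


@dataclass
class RootPrediction:
    """GLS prediction of the trait value at the root of the tree.

    ``m`` is the best linear unbiased predictor of the root state under
    Brownian motion, ``n_e = 1' T^-1 1`` is the effective sample size for
    that prediction, and ``v = rate / n_e`` is its error variance.
    """

    m: float
    n_e: float
    v: float


def read_newick(path_or_string: str) -> Phylogeny:
    """Read a rooted tree from a Newick file path or literal string.

    Every edge must carry a branch length and tip labels must be unique;
    violations raise :class:`MissingBranchLengthError` or
    :class:`DuplicateTipLabelError`.  Polytomies are accepted.
    """
    text = path_or_string
    if "(" not in text:
        try:
            with open(path_or_string) as fh:
                text = fh.read()
        except OSError as exc:
            raise NewickParseError(f"cannot read tree: {exc}") from exc
    try:
        dtree = dendropy.Tree.get(
            file=io.StringIO(text),
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several parser error types
        if "Duplicate taxon labels" in str(exc):
            raise DuplicateTipLabelError(str(exc)) from exc
        raise NewickParseError(f"invalid Newick: {exc}") from exc
    return _from_dendropy(dtree)


def _from_dendropy(dtree: dendropy.Tree) -> Phylogeny:
    root = dtree.seed_node
    nodes = []
    parent_of = {}
    stack = [(root, -1)]
    while stack:  # preorder
        nd, par = stack.pop()
        idx = len(nodes)
        nodes.append(nd)
        parent_of[idx] = par
        for ch in reversed(nd.child_nodes()):
            stack.append((ch, idx))

    n = len(nodes)
    parent = np.array([parent_of[k] for k in range(n)], dtype=int)
    edge_length = np.zeros(n)
    children: list[list[int]] = [[] for _ in range(n)]
    for k in range(1, n):
        bl = nodes[k].edge.length
        if bl is None:
            raise MissingBranchLengthError(
                "every edge must have a branch length"
            )
        if bl < 0:
            raise ValidationError(f"negative branch length {bl}")
        edge_length[k] = float(bl)
        children[parent[k]].append(k)

    # canonical tip order: post-order tip sequence
    tip_idx: list[int] = []
    labels: list[str] = []

    def post(k: int):
        for c in children[k]:
            post(c)
        if not children[k]:
            tip_idx.append(k)
            nd = nodes[k]
            lab = nd.taxon.label if nd.taxon is not None else nd.label
            if lab is None:
                raise NewickParseError("tip without a label")
            labels.append(str(lab))

    post(0)
    if len(set(labels)) != len(labels):
        dups = sorted({x for x in labels if labels.count(x) > 1})
        raise DuplicateTipLabelError(f"duplicate tip labels: {dups}")
    if len(labels) < 2:
        raise ValidationError("tree must have at least 2 tips")
    return Phylogeny(
        parent=parent,
        edge_length=edge_length,
        children=children,
        tip_node=np.array(tip_idx, dtype=int),
        tip_labels=labels,
    )


def scale_to_unit_height(
    tree: Phylogeny, rtol: float = ULTRAMETRIC_RTOL
) -> Phylogeny:
    """Rescale all branch lengths so the root-to-tip distance is 1.

    The tree must already be ultrametric within ``rtol`` (relative spread of
    tip depths); non-ultrametric trees raise :class:`NonUltrametricError`
    rather than being silently forced.  The original height is kept in
    ``original_height`` so parameters estimated on the unit tree can be
    converted back (a Brownian rate per unit tree is the rate per
    ``original_height`` time units).
    """
    d = tree.tip_depths()
    h = float(d.max())
    if h <= 0:
        raise ValidationError("tree height must be positive")
    if float(d.max() - d.min()) > rtol * h:
        raise NonUltrametricError(
            f"tip depths range from {d.min():.6g} to {d.max():.6g}; "
            "the Brownian-path models assume an ultrametric tree"
        )
    return Phylogeny(
        parent=tree.parent.copy(),
        edge_length=tree.edge_length / h,
        children=[list(c) for c in tree.children],
        tip_node=tree.tip_node.copy(),
        tip_labels=list(tree.tip_labels),
        original_height=h if tree.original_height is None
        else tree.original_height,
    )


def shared_branch_matrix(tree: Phylogeny) -> SharedBranchMatrix:
    """Build the matrix of shared branch lengths between all tip pairs.

    ``T[i, j]`` = depth of MRCA(i, j); diagonal = root-to-tip distance.
    Computed in one post-order sweep: at each internal node of depth d every
    pair of tips drawn from two different child subtrees has its MRCA there.
    """
    depths = tree.node_depths()
    n = tree.n_tips
    T = np.zeros((n, n))
    pos = {int(nd): i for i, nd in enumerate(tree.tip_node)}

    def post(k: int) -> list[int]:
        if not tree.children[k]:
            i = pos[k]
            T[i, i] = depths[k]
            return [i]
        groups = [post(c) for c in tree.children[k]]
        for gi in range(len(groups)):
            for gj in range(gi + 1, len(groups)):
                for i in groups[gi]:
                    for j in groups[gj]:
                        T[i, j] = T[j, i] = depths[k]
        return [i for g in groups for i in g]

    post(0)
    return SharedBranchMatrix(T=T, tip_order=list(tree.tip_labels))


def chol_with_jitter(M: np.ndarray):
    """Cholesky factor of a symmetric matrix, with one documented retry.

    If the first factorization fails, a diagonal jitter of
    ``1e-10 * trace(M)/n`` is added once; a second failure raises
    :class:`SingularMatrixError`.  Returns ``(L, jitter_used)`` with ``L``
    lower triangular.
    """
    try:
        return np.linalg.cholesky(M), 0.0
    except np.linalg.LinAlgError:
        n = M.shape[0]
        jit = 1e-10 * float(np.trace(M)) / n
        if jit <= 0:
            jit = 1e-12
        try:
            return np.linalg.cholesky(M + jit * np.eye(n)), jit
        except np.linalg.LinAlgError as exc:
            raise SingularMatrixError(
                "matrix not positive definite even after diagonal jitter "
                f"({jit:.3g}); check for zero-length branches or duplicated "
                "tip positions"
            ) from exc


def chol_solve(L: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Solve ``M x = B`` given the lower Cholesky factor L of M."""
    from scipy.linalg import solve_triangular

    y = solve_triangular(L, B, lower=True)
    return solve_triangular(L.T, y, lower=False)


def root_predictor(
    T: SharedBranchMatrix | np.ndarray, z: np.ndarray, rate: float = 0.0
) -> RootPrediction:
    """Predict the root value of a trait from its tip values.

    Under Brownian motion, ``m = (1' T^-1 z) / (1' T^-1 1)`` is the best
    linear unbiased predictor of the root state.  The denominator
    ``n_e = 1' T^-1 1`` acts as an effective sample size (equal to the tip
    count on a star tree, smaller on any resolved tree), and the prediction
    error variance is ``v = rate / n_e`` where ``rate`` is the Brownian rate
    of the trait.
    """
    Tm = T.T if isinstance(T, SharedBranchMatrix) else np.asarray(T)
    z = np.asarray(z, dtype=float)
    if z.shape[0] != Tm.shape[0]:
        raise ValidationError(
            f"trait vector length {z.shape[0]} != matrix size {Tm.shape[0]}"
        )
    if rate < 0:
        raise ValidationError("rate must be nonnegative")
    L, _ = chol_with_jitter(Tm)
    ones = np.ones(Tm.shape[0])
    Ti1 = chol_solve(L, ones)
    n_e = float(ones @ Ti1)
    m = float(Ti1 @ z) / n_e
    return RootPrediction(m=m, n_e=n_e, v=rate / n_e)


def align_traits(
    tree: Phylogeny,
    table: pd.DataFrame,
    species_col: str,
) -> pd.DataFrame:
    """Reindex a trait table to the tree's canonical tip order.

    Every tree tip must appear exactly once in the table and vice versa;
    any mismatch raises :class:`LabelMismatchError` listing the offenders.
    """
    if species_col not in table.columns:
        raise LabelMismatchError(
            f"species column {species_col!r} not in table columns "
            f"{list(table.columns)}"
        )
    labels = table[species_col].astype(str)
    if labels.duplicated().any():
        raise LabelMismatchError(
            f"duplicated species in table: "
            f"{sorted(labels[labels.duplicated()].unique())}"
        )
    tree_set = set(tree.tip_labels)
    tab_set = set(labels)
    missing = sorted(tree_set - tab_set)
    extra = sorted(tab_set - tree_set)
    if missing or extra:
        raise LabelMismatchError(
            f"tips missing from table: {missing}; "
            f"table species not in tree: {extra}"
        )
    return table.set_index(labels.values).loc[tree.tip_labels].reset_index(
        drop=True
    )
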