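"""Phylogeny input/output and phylogenetic covariance construction.

A :class:`Phylogeny` is a thin, validated wrapper around a rooted
:class:`dendropy.Tree` with branch lengths.  The species-by-species
covariance implied by a Brownian-motion model of trait evolution is the
matrix of shared root-to-MRCA path lengths; Pagel's λ scales its
off-diagonal entries to attenuate phylogenetic signal.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "Phylogeny",
    "PhyloCovariance",
    "read_newick",
    "write_newick",
    "prune",
    "vcv",
    "read_trait_table",
    "normalize_label",
]


def normalize_label(label: str) -> str:
    """Canonical species label: underscores for spaces, case-folded."""
    return re.sub(r"\s+", "_", str(label).strip()).casefold()


class Phylogeny:
    """A rooted phylogeny with branch lengths.

    Parameters
    ----------
    tree : dendropy.Tree
        Rooted tree; every edge below the root must carry a nonnegative
        branch length.  Polytomies are allowed.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self._validate()

    # -- construction ------------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str, default_branch_length: float | None = None) -> "Phylogeny":
        try:
            tree = dendropy.Tree.get(
                data=newick,
                schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:  # dendropy raises several parse error types
            raise ValueError(f"malformed Newick: {exc}") from exc
        for edge in tree.preorder_edge_iter():
            if edge.head_node is tree.seed_node:
                continue
            if edge.length is None:
                if default_branch_length is None:
                    raise ValueError(
                        "tree has edges without branch lengths; pass "
                        "default_branch_length to assign one"
                    )
                edge.length = default_branch_length
        tree.is_rooted = True
        return cls(tree)

    def _validate(self) -> None:
        labels = self.taxa
        if len(labels) != len(set(labels)):
            dupes = sorted({t for t in labels if labels.count(t) > 1})
            raise ValueError(f"duplicate tip labels: {dupes}")
        if len(labels) < 2:
            raise ValueError("tree must have at least 2 tips")
        for edge in self._tree.preorder_edge_iter():
            if edge.head_node is self._tree.seed_node:
                continue
            if edge.length is None or edge.length < 0:
                raise ValueError("all branch lengths must be present and >= 0")

    # -- properties --------------------------------------------------------

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def taxa(self) -> list[str]:
        return [leaf.taxon.label for leaf in self._tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return len(self.taxa)

    def root_to_tip_distances(self) -> dict[str, float]:
        self._tree.calc_node_root_distances(
            return_leaf_distances_only=False
        )
        return {
            leaf.taxon.label: leaf.root_distance
            for leaf in self._tree.leaf_node_iter()
        }

    def is_ultrametric(self, tol: float = 1e-8) -> bool:
        d = np.array(list(self.root_to_tip_distances().values()))
        return float(d.max() - d.min()) <= tol

    def scale_branch_lengths(self, factor: float) -> "Phylogeny":
        if factor <= 0:
            raise ValueError("scale factor must be positive")
        t = self._tree.clone(depth=1)
        for edge in t.preorder_edge_iter():
            if edge.length is not None:
                edge.length *= factor
        return Phylogeny(t)

    def resolve_polytomies(self) -> "Phylogeny":
        """Arbitrarily resolve multifurcations with zero-length branches."""
        t = self._tree.clone(depth=1)
        t.resolve_polytomies()
        for edge in t.preorder_edge_iter():
            if edge.head_node is t.seed_node:
                continue
            if edge.length is None:
                edge.length = 0.0
        return Phylogeny(t)

    def to_newick(self) -> str:
        s = self._tree.as_string(schema="newick", suppress_rooting=True)
        return s.strip()

    def __repr__(self) -> str:  # pragma: no cover
        return f"Phylogeny(n_tips={self.n_tips})"


@dataclass
class PhyloCovariance:
    """Phylogenetic covariance: shared root-to-MRCA path lengths.

    ``base_matrix`` holds the λ = 1 (Brownian) covariance; ``lam`` is the
    Pagel's λ multiplier applied to the off-diagonals by :attr:`matrix`.
    """

    species_order: list[str]
    base_matrix: np.ndarray
    lam: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.lam <= 1.0):
            raise ValueError("lambda must lie in [0, 1]")
        m = np.asarray(self.base_matrix, dtype=float)
        if m.shape[0] != m.shape[1] or m.shape[0] != len(self.species_order):
            raise ValueError("matrix shape does not match species_order")
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValueError("covariance matrix must be symmetric")
        self.base_matrix = m

    @property
    def matrix(self) -> np.ndarray:
        return self.with_lambda(self.lam)

    def with_lambda(self, lam: float) -> np.ndarray:
        if not (0.0 <= lam <= 1.0):
            raise ValueError("lambda must lie in [0, 1]")
        m = self.base_matrix * lam
        np.fill_diagonal(m, np.diag(self.base_matrix))
        return m

    def correlation(self) -> np.ndarray:
        """Unit-diagonal version of the λ = 1 matrix."""
        d = np.sqrt(np.diag(self.base_matrix))
        return self.base_matrix / np.outer(d, d)

    def subset(self, species: list[str]) -> "PhyloCovariance":
        idx = [self.species_order.index(s) for s in species]
        return PhyloCovariance(
            species_order=list(species),
            base_matrix=self.base_matrix[np.ix_(idx, idx)],
            lam=self.lam,
        )


def read_newick(path, default_branch_length: float | None = None) -> Phylogeny:
    """Read a rooted Newick tree with branch lengths from ``path``."""
    if hasattr(path, "read"):
        newick = path.read()
    else:
        with open(path) as fh:
            newick = fh.read()
    return Phylogeny.from_newick(newick, default_branch_length=default_branch_length)


def write_newick(tree: Phylogeny, path) -> None:
    s = tree.to_newick()
    if hasattr(path, "write"):
        path.write(s + "\n")
    else:
        with open(path, "w") as fh:
            fh.write(s + "\n")


def prune(tree: Phylogeny, keep) -> Phylogeny:
    """Restrict ``tree`` to the tip set ``keep``.

    Degree-2 internal nodes left by the pruning are collapsed with branch
    lengths summed, so every kept tip retains its root-to-tip distance.
    """
    keep = list(dict.fromkeys(keep))
    tips = set(tree.taxa)
    missing = sorted(set(keep) - tips)
    if missing:
        raise KeyError(f"species not in tree: {missing}")
    if len(keep) < 2:
        raise ValueError("need at least 2 tips to prune to")
    if set(keep) == tips:
        return Phylogeny(tree.dendropy_tree.clone(depth=1))
    t = tree.dendropy_tree.clone(depth=1)
    taxa = [tx for tx in t.taxon_namespace if tx.label in set(keep)]
    t.retain_taxa(taxa, suppress_unifurcations=False)
    # collapse degree-2 internal nodes with branch lengths summed, so every
    # kept tip retains its root-to-tip distance (including the chain above
    # the retained clade's MRCA)
    for node in list(t.postorder_internal_node_iter(exclude_seed_node=True)):
        kids = node.child_nodes()
        if len(kids) == 1:
            child = kids[0]
            child.edge.length = ((child.edge.length or 0.0)
                                 + (node.edge.length or 0.0))
            parent = node.parent_node
            parent.remove_child(node)
            parent.add_child(child)
    # a single child of the root is kept as a root stem (not collapsed):
    # the shared path from the root to the retained clade's MRCA is common
    # history and must stay in the covariance
    return Phylogeny(t)


def vcv(tree: Phylogeny, lam: float = 1.0) -> PhyloCovariance:
    """Brownian covariance matrix of a tree, with Pagel's-λ off-diagonal scaling.

    Entry (i, j) is the root-to-MRCA path length shared by tips i and j
    (times λ off the diagonal); the diagonal is each tip's root-to-tip
    distance.  Handles multifurcations natively.
    """
    if not (0.0 <= lam <= 1.0):
        raise ValueError("lambda must lie in [0, 1]")
    t = tree.dendropy_tree
    leaves = list(t.leaf_node_iter())
    labels = [lf.taxon.label for lf in leaves]
    n = len(leaves)
    index = {id(lf): i for i, lf in enumerate(leaves)}
    cov = np.zeros((n, n))
    # postorder accumulation: each node contributes its root-to-parent depth
    # ... computed top-down, then every pair of leaves below via distinct
    # children shares exactly depth(node) + its own edge length.
    depth: dict[int, float] = {id(t.seed_node): 0.0}
    for node in t.preorder_node_iter():
        if node is t.seed_node:
            continue
        depth[id(node)] = depth[id(node.parent_node)] + (node.edge.length or 0.0)
    below: dict[int, list[int]] = {}
    for node in t.postorder_node_iter():
        if node.is_leaf():
            i = index[id(node)]
            below[id(node)] = [i]
            cov[i, i] = depth[id(node)]
            continue
        groups = [below[id(c)] for c in node.child_nodes()]
        d = depth[id(node)]
        for a in range(len(groups)):
            for b in range(a + 1, len(groups)):
                for i in groups[a]:
                    for j in groups[b]:
                        cov[i, j] = cov[j, i] = d
        below[id(node)] = [i for g in groups for i in g]
    return PhyloCovariance(species_order=labels, base_matrix=cov, lam=lam)


def read_trait_table(
    path,
    schema: dict,
    normalize_names: bool = True,
) -> pd.DataFrame:
    """Read a species trait table from CSV.

    ``schema`` maps roles to column names: required keys ``species`` and
    ``urban``; optional ``order``, ``realm``, ``traits`` (list of continuous
    trait columns) and ``diet`` (list of diet-proportion columns).  The
    urban column may be binary (0/1) or categorical with values in
    {none, visitor, dweller, both}.  Rows with missing values in any
    schema-named column are dropped (complete-case analysis); the count of
    dropped rows is recorded in ``df.attrs['n_dropped']``.
    """
    df = pd.read_csv(path)
    sp_col = schema["species"]
    urban_col = schema["urban"]
    cols = [sp_col, urban_col]
    cols += [c for c in (schema.get("order"), schema.get("realm")) if c]
    cols += list(schema.get("traits", [])) + list(schema.get("diet", []))
    missing_cols = [c for c in cols if c not in df.columns]
    if missing_cols:
        raise KeyError(f"columns missing from trait table: {missing_cols}")
    df = df[cols].copy()
    if normalize_names:
        df[sp_col] = df[sp_col].map(normalize_label)
    if df[sp_col].duplicated().any():
        dupes = sorted(df.loc[df[sp_col].duplicated(), sp_col].unique())
        raise ValueError(f"duplicate species in trait table: {dupes}")
    n0 = len(df)
    df = df.dropna(subset=cols).reset_index(drop=True)
    df.attrs["n_dropped"] = n0 - len(df)
    allowed = {"none", "visitor", "dweller", "both"}
    u = df[urban_col]
    if u.dtype == object or str(u.dtype) == "category":
        vals = set(str(v).strip().lower() for v in u.unique())
        if not vals <= allowed:
            raise ValueError(
                f"urban column values not coercible: {sorted(vals - allowed)}"
            )
        df[urban_col] = u.astype(str).str.strip().str.lower()
    else:
        vals = set(u.unique())
        if not vals <= {0, 1}:
            raise ValueError("numeric urban column must be 0/1")
        df[urban_col] = u.astype(int)
    return df
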