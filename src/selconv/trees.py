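"""Rooted phylogenies with per-branch partition tags.

The tree is stored in flat arrays indexed by node id (postorder-friendly),
which is what the likelihood engine consumes.  Newick round-trips go
through dendropy.  Every non-root node owns the branch to its parent;
branch attributes (length, tag) are therefore stored per node.
"""

from __future__ import annotations

from typing import Sequence

import dendropy
import numpy as np

#: branch partition tags
SEC = "SEC"
EXCHANGE = "EXCHANGE"
INHERITED = "INHERITED"
VALID_TAGS = (SEC, EXCHANGE, INHERITED)


class TreeError(ValueError):
    pass


class PhyloTree:
    """Rooted tree with branch lengths and optional branch partition tags.

    Parameters
    ----------
    names : sequence of str
        One per node; leaf names must be unique and non-empty.  Internal
        node labels are used to address branches in tag tables.
    parent : sequence of int
        Parent node id per node; -1 for the root.
    lengths : sequence of float
        Branch length (expected substitutions per site) of the branch
        above each node; ignored for the root.
    tags : sequence of str or None, optional
        Partition tag of the branch above each node.
    """

    def __init__(self, names, parent, lengths, tags=None, rooted=True):
        self.names = list(names)
        self.parent = np.asarray(parent, dtype=int)
        self.lengths = np.asarray(lengths, dtype=float).copy()
        n = len(self.names)
        if not (len(self.parent) == len(self.lengths) == n):
            raise TreeError("names/parent/lengths must have equal length")
        self.tags = list(tags) if tags is not None else [None] * n
        self.rooted = rooted
        self.children: list[list[int]] = [[] for _ in range(n)]
        roots = []
        for i, p in enumerate(self.parent):
            if p < 0:
                roots.append(i)
            else:
                self.children[p].append(i)
        if len(roots) != 1:
            raise TreeError(f"tree must have exactly one root, found {len(roots)}")
        self.root = roots[0]
        self._postorder = None
        self.validate()

    # ------------------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.names)

    @property
    def leaves(self) -> list[int]:
        return [i for i in range(self.n_nodes) if not self.children[i]]

    @property
    def leaf_names(self) -> list[str]:
        return [self.names[i] for i in self.leaves]

    @property
    def branches(self) -> list[int]:
        """Node ids owning a branch (all but the root)."""
        return [i for i in range(self.n_nodes) if i != self.root]

    def postorder(self) -> list[int]:
        if self._postorder is None:
            order, stack = [], [(self.root, False)]
            while stack:
                node, done = stack.pop()
                if done:
                    order.append(node)
                else:
                    stack.append((node, True))
                    for c in self.children[node]:
                        stack.append((c, False))
            self._postorder = order
        return self._postorder

    def is_leaf(self, i: int) -> bool:
        return not self.children[i]

    def node_by_name(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise TreeError(f"no node named {name!r}") from None

    def path_to_root(self, i: int) -> list[int]:
        out = []
        while i >= 0:
            out.append(i)
            i = self.parent[i]
        return out

    def is_ancestral(self, a: int, b: int) -> bool:
        """True if branch/node ``a`` lies on the path from ``b`` to the root."""
        return a in self.path_to_root(b)[1:]

    def subtree_nodes(self, i: int) -> list[int]:
        out, stack = [], [i]
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(self.children[n])
        return out

    def leaf_set_below(self, i: int) -> set[str]:
        return {self.names[n] for n in self.subtree_nodes(i) if self.is_leaf(n)}

    # ------------------------------------------------------------------
    def validate(self):
        lnames = self.leaf_names
        if len(set(lnames)) != len(lnames):
            dup = sorted({x for x in lnames if lnames.count(x) > 1})
            raise TreeError(f"duplicate leaf names: {dup}")
        if any(not x for x in lnames):
            raise TreeError("leaf names must be non-empty")
        blen = self.lengths[[i for i in range(self.n_nodes) if i != self.root]]
        if not np.all(np.isfinite(blen)) or np.any(blen < 0):
            raise TreeError("branch lengths must be finite and non-negative")

    def validate_tags(self):
        """All branches tagged; EXCHANGE never ancestral to SEC."""
        for i in self.branches:
            if self.tags[i] not in VALID_TAGS:
                raise TreeError(
                    f"branch above node {self.names[i] or i!r} has invalid tag "
                    f"{self.tags[i]!r}"
                )
        for i in self.branches:
            if self.tags[i] != SEC:
                continue
            for a in self.path_to_root(i)[1:]:
                if a != self.root and self.tags[a] == EXCHANGE:
                    raise TreeError(
                        f"EXCHANGE branch {self.names[a] or a!r} is ancestral to "
                        f"SEC branch {self.names[i] or i!r}"
                    )

    def set_tags(self, table: dict[str, str]):
        """Assign tags from a mapping of node name -> tag."""
        named = {self.names[i]: i for i in self.branches if self.names[i]}
        unknown = set(table) - set(named)
        if unknown:
            raise TreeError(f"tag table names not in tree: {sorted(unknown)}")
        for name, tag in table.items():
            if tag not in VALID_TAGS:
                raise TreeError(f"invalid tag {tag!r} for branch {name!r}")
            self.tags[named[name]] = tag
        missing = [self.names[i] or str(i) for i in self.branches if self.tags[i] is None]
        if missing:
            raise TreeError(f"untagged branches: {missing}")
        self.validate_tags()

    def tagged(self, tag: str) -> list[int]:
        return [i for i in self.branches if self.tags[i] == tag]

    # ------------------------------------------------------------------
    def copy(self) -> "PhyloTree":
        return PhyloTree(self.names, self.parent, self.lengths, self.tags, self.rooted)

    def with_lengths(self, lengths: Sequence[float]) -> "PhyloTree":
        t = self.copy()
        t.lengths = np.asarray(lengths, dtype=float).copy()
        t.validate()
        return t

    # ------------------------------------------------------------------
    @classmethod
    def from_dendropy(cls, dtree: dendropy.Tree) -> "PhyloTree":
        nodes = list(dtree.preorder_node_iter())
        idx = {id(nd): i for i, nd in enumerate(nodes)}
        names, parent, lengths, tags = [], [], [], []
        for nd in nodes:
            if nd.is_leaf():
                names.append(nd.taxon.label if nd.taxon else (nd.label or ""))
            else:
                names.append(nd.label or "")
            parent.append(idx[id(nd.parent_node)] if nd.parent_node else -1)
            lengths.append(nd.edge.length if nd.edge.length is not None else 0.0)
            tags.append(getattr(nd, "partition_tag", None))
        return cls(names, parent, lengths, tags, rooted=True)

    def to_dendropy(self) -> dendropy.Tree:
        taxa = dendropy.TaxonNamespace()
        dnodes = [dendropy.Node() for _ in range(self.n_nodes)]
        for i in range(self.n_nodes):
            if self.is_leaf(i):
                dnodes[i].taxon = taxa.new_taxon(self.names[i])
            elif self.names[i]:
                dnodes[i].label = self.names[i]
            if i != self.root:
                dnodes[i].edge.length = float(self.lengths[i])
                dnodes[self.parent[i]].add_child(dnodes[i])
        tree = dendropy.Tree(taxon_namespace=taxa)
        tree.seed_node = dnodes[self.root]
        tree.is_rooted = self.rooted
        return tree

    @classmethod
    def from_newick(cls, source: str, *, is_path: bool | None = None) -> "PhyloTree":
        if is_path is None:
            is_path = "(" not in source
        kw = dict(schema="newick", suppress_internal_node_taxa=True, preserve_underscores=True)
        try:
            if is_path:
                dtree = dendropy.Tree.get(path=source, **kw)
            else:
                dtree = dendropy.Tree.get(data=source, **kw)
        except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as e:
            raise TreeError(f"duplicate leaf names in newick: {e}") from e
        return cls.from_dendropy(dtree)

    def to_newick(self) -> str:
        s = self.to_dendropy().as_string(
            schema="newick", suppress_rooting=True, unquoted_underscores=True
        )
        return s.strip()

    def write_newick(self, path):
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    def __repr__(self):
        return (
            f"PhyloTree({len(self.leaves)} leaves, {self.n_nodes} nodes, "
            f"tagged={all(t is not None for i, t in enumerate(self.tags) if i != self.root)})"
        )


def label_internal_nodes(tree: PhyloTree, prefix: str = "N") -> PhyloTree:
    """Assign labels ``N1..Nk`` (preorder) to unlabeled internal nodes."""
    t = tree.copy()
    k = 0
    for i in range(t.n_nodes):
        if not t.is_leaf(i) and not t.names[i]:
            k += 1
            t.names[i] = f"{prefix}{k}"
    return t
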