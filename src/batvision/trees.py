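"""Phylogenetic trees: an array-backed container, newick I/O, rerooting.

Newick reading is delegated to dendropy; writing is native so that the
PAML-style foreground-branch dialect round-trips exactly: a ``#<int>``
suffix on a leaf or internal-node label tags the branch *above* that node
with a foreground class (e.g. ``((A,B)#1,C);`` marks the AB stem).

The container is index-based (parent pointers, child lists, branch-length
array) because the likelihood engine, the ancestral reconstruction and the
simulator all address nodes by integer id.
"""

from __future__ import annotations

import re

import dendropy
import numpy as np

from .errors import TreeError

_TAG_RE = re.compile(r"^(.*?)\s*#(\d+)$")


class PhyloTree:
    """Rooted tree with branch lengths and optional foreground tags.

    Node ids are 0..n_nodes-1.  ``parent[i]`` is -1 for the root;
    ``length[i]`` is the length of the branch above node i (NaN when the
    source newick carried no length); ``tag[i]`` is the foreground class of
    that same branch (0 = background).  Leaves carry taxon names; internal
    nodes may carry labels.
    """

    def __init__(self, parent, children, length, name, tag, root):
        self.parent = list(parent)
        self.children = [list(c) for c in children]
        self.length = np.asarray(length, dtype=float)
        self.name = list(name)
        self.tag = list(tag)
        self.root = root
        self._validate()

    def _validate(self):
        leaves = [self.name[i] for i in self.leaf_indices()]
        if len(set(leaves)) != len(leaves):
            dupes = sorted({t for t in leaves if leaves.count(t) > 1})
            raise TreeError(f"duplicate leaf names: {dupes}")
        finite = self.length[np.isfinite(self.length)]
        if (finite < 0).any():
            raise TreeError("negative branch length")

    # ------------------------------------------------------------------ shape
    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    def leaf_indices(self) -> list:
        return [i for i in range(self.n_nodes) if not self.children[i]]

    @property
    def leaf_names(self) -> list:
        return [self.name[i] for i in self.leaf_indices()]

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_indices())

    def internal_indices(self) -> list:
        return [i for i in range(self.n_nodes) if self.children[i]]

    def is_leaf(self, i: int) -> bool:
        return not self.children[i]

    def is_binary(self) -> bool:
        for i in self.internal_indices():
            k = len(self.children[i])
            if i == self.root:
                if k not in (2, 3):
                    return False
            elif k != 2:
                return False
        return True

    def postorder(self) -> list:
        out, stack = [], [self.root]
        while stack:
            v = stack.pop()
            out.append(v)
            stack.extend(self.children[v])
        return out[::-1]

    def preorder(self) -> list:
        return self.postorder()[::-1]

    def total_length(self) -> float:
        return float(np.nansum(self.length))

    # --------------------------------------------------------------- queries
    def node_by_name(self, name: str) -> int:
        for i, n in enumerate(self.name):
            if n == name:
                return i
        raise TreeError(f"no node named {name!r}")

    def leafset(self, node: int) -> frozenset:
        """Taxon names below (and including) ``node``."""
        out, stack = [], [node]
        while stack:
            v = stack.pop()
            if self.is_leaf(v):
                out.append(self.name[v])
            stack.extend(self.children[v])
        return frozenset(out)

    def mrca(self, taxa) -> int:
        target = set(taxa)
        missing = target - set(self.leaf_names)
        if missing:
            raise TreeError(f"taxa not in tree: {sorted(missing)}")
        best = self.root
        # deepest node whose leafset covers the target
        for v in self.postorder():
            if self.is_leaf(v):
                continue
            ls = self.leafset(v)
            if target <= ls and len(ls) < len(self.leafset(best)):
                best = v
        if len(target) == 1:
            return self.node_by_name(next(iter(target)))
        return best

    def stem_branch(self, clade_taxa, require_monophyly: bool = True) -> int:
        """Node whose parent branch subtends the clade's MRCA (the stem)."""
        node = self.mrca(clade_taxa)
        if require_monophyly and self.leafset(node) != frozenset(clade_taxa):
            raise TreeError(
                f"clade {sorted(clade_taxa)} is not monophyletic in this tree"
            )
        return node

    def is_ancestor(self, a: int, b: int) -> bool:
        """True when node a lies on the path from b to the root (a != b)."""
        v = self.parent[b]
        while v != -1:
            if v == a:
                return True
            v = self.parent[v]
        return False

    def copy(self) -> "PhyloTree":
        return PhyloTree(self.parent, self.children, self.length.copy(),
                         self.name, self.tag, self.root)

    # ------------------------------------------------------------- rerooting
    def reroot_at_edge(self, node: int, fraction: float = 0.5) -> "PhyloTree":
        """Return a new tree rooted on the branch above ``node``.

        The branch is split ``fraction`` (child side) : 1-fraction (parent
        side).  An old root left with a single child is suppressed, its two
        incident branch lengths summed.
        """
        if node == self.root:
            raise TreeError("cannot reroot on the root's (nonexistent) parent branch")
        # undirected adjacency: (neighbor, length, tag-owner-node)
        adj = {i: [] for i in range(self.n_nodes)}
        for i in range((self.n_nodes)):
            p = self.parent[i]
            if p != -1:
                adj[i].append((p, self.length[i], i))
                adj[p].append((i, self.length[i], i))
        new_id = self.n_nodes  # the new root, splitting edge (parent(node), node)
        p = self.parent[node]
        t = self.length[node]
        t_child = t * fraction if np.isfinite(t) else np.nan
        t_parent = t * (1 - fraction) if np.isfinite(t) else np.nan
        adj[node] = [e for e in adj[node] if e[0] != p]
        adj[p] = [e for e in adj[p] if e[0] != node]
        adj[new_id] = [(node, t_child, node), (p, t_parent, node)]
        adj[node].append((new_id, t_child, node))
        adj[p].append((new_id, t_parent, node))

        n = self.n_nodes + 1
        parent = [-1] * n
        children = [[] for _ in range(n)]
        length = np.full(n, np.nan)
        name = self.name + [None]
        tag = self.tag + [0]
        seen = {new_id}
        stack = [new_id]
        order = []
        while stack:
            v = stack.pop()
            order.append(v)
            for (u, t_vu, owner) in adj[v]:
                if u in seen:
                    continue
                seen.add(u)
                parent[u] = v
                children[v].append(u)
                length[u] = t_vu
                tag[u] = self.tag[owner]
                stack.append(u)
        tree = PhyloTree(parent, children, length, name, tag, new_id)
        return tree._suppress_unifurcations()

    def _suppress_unifurcations(self) -> "PhyloTree":
        parent = list(self.parent)
        children = [list(c) for c in self.children]
        length = self.length.copy()
        tag = list(self.tag)
        removed = set()
        for v in range(self.n_nodes):
            if v == self.root or v in removed:
                continue
            if len(children[v]) == 1:
                (c,) = children[v]
                p = parent[v]
                length[c] = np.nansum([length[c], length[v]])
                tag[c] = max(tag[c], tag[v])
                parent[c] = p
                children[p][children[p].index(v)] = c
                removed.add(v)
        if not removed:
            return self
        keep = [i for i in range(self.n_nodes) if i not in removed]
        remap = {old: new for new, old in enumerate(keep)}
        return PhyloTree(
            [remap[parent[i]] if parent[i] != -1 else -1 for i in keep],
            [[remap[c] for c in children[i]] for i in keep],
            length[keep],
            [self.name[i] for i in keep],
            [tag[i] for i in keep],
            remap[self.root],
        )

    def root_with_outgroup(self, outgroup_taxa) -> "PhyloTree":
        """Reroot on the stem branch of the designated outgroup."""
        node = self.mrca(outgroup_taxa)
        if node == self.root:
            # outgroup spans the present root; try the complementary clade
            comp = set(self.leaf_names) - set(outgroup_taxa)
            node = self.mrca(comp)
            if node == self.root:
                raise TreeError("outgroup does not define a root position")
        return self.reroot_at_edge(node, fraction=0.5)

    # ------------------------------------------------------------------- I/O
    def to_newick(self, lengths: bool = True, fmt: str = "%.10g") -> str:
        def rec(v):
            label = self.name[v] or ""
            if self.tag[v]:
                label = f"{label}#{self.tag[v]}"
            if self.is_leaf(v):
                s = label
            else:
                s = "(" + ",".join(rec(c) for c in self.children[v]) + ")" + label
            if lengths and v != self.root and np.isfinite(self.length[v]):
                s += ":" + (fmt % self.length[v])
            return s

        return rec(self.root) + ";"

    def __repr__(self):
        return f"<PhyloTree {self.n_leaves} leaves, {self.n_nodes} nodes>"


def read_newick(text: str) -> PhyloTree:
    """Parse newick (PAML ``#<int>`` foreground tags honoured)."""
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick",
            suppress_internal_node_taxa=True, preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise TreeError(f"malformed newick: {exc}") from exc

    parent, children, length, name, tag = [], [], [], [], []

    def add(dnode, parent_id):
        i = len(parent)
        parent.append(parent_id)
        children.append([])
        length.append(dnode.edge.length if dnode.edge.length is not None else np.nan)
        raw = dnode.taxon.label if dnode.taxon else dnode.label
        t = 0
        if raw:
            m = _TAG_RE.match(raw)
            if m:
                raw, t = m.group(1) or None, int(m.group(2))
        name.append(raw if raw else None)
        tag.append(t)
        if parent_id != -1:
            children[parent_id].append(i)
        for ch in dnode.child_nodes():
            add(ch, i)
        return i

    root = add(dtree.seed_node, -1)
    tree = PhyloTree(parent, children, np.asarray(length), name, tag, root)
    if tree.n_leaves < 2:
        raise TreeError("tree must have at least 2 leaves")
    return tree


def write_newick(tree: PhyloTree, lengths: bool = True) -> str:
    return tree.to_newick(lengths=lengths)


def read_newick_file(path) -> PhyloTree:
    with open(path) as fh:
        return read_newick(fh.read())


def robinson_foulds(t1: PhyloTree, t2: PhyloTree) -> int:
    """Unrooted Robinson-Foulds distance (symmetric bipartition difference)."""
    if set(t1.leaf_names) != set(t2.leaf_names):
        raise TreeError("trees must share the same leaf set")
    taxa = frozenset(t1.leaf_names)

    def splits(t):
        out = set()
        for v in t.internal_indices():
            if v == t.root:
                continue
            side = t.leafset(v)
            if 1 < len(side) < len(taxa) - 1:
                out.add(min(side, taxa - side, key=sorted))
        return out

    s1, s2 = splits(t1), splits(t2)
    return len(s1 ^ s2)
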