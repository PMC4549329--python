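"""Rooted, dated phylogeny container used by the signal and regression tests.

Wraps a dendropy tree (newick in/out, pruning, polytomy resolution) and
exposes flat array views — preorder parent/edge arrays and postorder
internal-node child pairs — that let the permutation-heavy statistics run
vectorized across thousands of randomizations.  Branch lengths are expected
in millions of years but any consistent unit works.

A tip->species mapping layer supports "replacement" tips: when a focal
species lacks sequence data, a close congener's tip stands in for it and the
trait vector is aligned through the mapping.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

__all__ = ["Phylogeny", "PolytomyError"]


class PolytomyError(ValueError):
    """Raised when an operation requires a strictly bifurcating tree."""


class Phylogeny:
    """Rooted tree with branch lengths and unique tip labels."""

    def __init__(self, tree: dendropy.Tree, replacements: Mapping[str, str] | None = None):
        #: maps tip label -> species it stands in for (congeneric replacement)
        self.replacements = dict(replacements or {})
        self._tree = tree
        labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
        if len(labels) != len(set(labels)):
            raise ValueError("tip labels must be unique")
        for edge in tree.preorder_edge_iter():
            if edge.head_node is not tree.seed_node and edge.length is None:
                raise ValueError("missing branch length on an edge")
        self._arrays = None
        self._patristic = None

    # -- construction ------------------------------------------------------
    @classmethod
    def from_newick(cls, source: str | Path, **kw) -> "Phylogeny":
        text = str(source)
        if "(" not in text:  # a path, not newick text
            text = Path(source).read_text()
        tree = dendropy.Tree.get(data=text, schema="newick")
        return cls(tree, **kw)

    def to_newick(self) -> str:
        return self._tree.as_string(schema="newick", suppress_rooting=True).strip()

    # -- basic views -------------------------------------------------------
    @property
    def tip_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self._tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return len(self._tree.leaf_nodes())

    @property
    def is_bifurcating(self) -> bool:
        return all(
            len(nd.child_nodes()) == 2
            for nd in self._tree.preorder_node_iter()
            if not nd.is_leaf()
        )

    @property
    def total_length(self) -> float:
        return float(
            sum(e.length or 0.0 for e in self._tree.preorder_edge_iter()
                if e.head_node is not self._tree.seed_node)
        )

    # -- transformations ---------------------------------------------------
    def resolve_polytomies(self, seed: int | None = None) -> "Phylogeny":
        """Random bifurcating resolution with zero-length inserted branches."""
        clone = self._tree.clone(depth=1)
        rng = __import__("random").Random(seed)
        clone.resolve_polytomies(rng=rng)
        for edge in clone.preorder_edge_iter():
            if edge.head_node is not clone.seed_node and edge.length is None:
                edge.length = 0.0
        return Phylogeny(clone, replacements=self.replacements)

    def prune_to(self, labels: Iterable[str]) -> "Phylogeny":
        """Subtree on the given tips, preserving tip-to-tip path lengths."""
        keep = set(labels)
        missing = keep - set(self.tip_labels)
        if missing:
            raise KeyError(f"tips not in tree: {sorted(missing)}")
        clone = self._tree.clone(depth=1)
        taxa = [t for t in clone.taxon_namespace if t.label in keep]
        sub = clone.extract_tree_with_taxa(taxa=taxa,
                                           suppress_unifurcations=True)
        return Phylogeny(sub, replacements={
            k: v for k, v in self.replacements.items() if k in keep
        })

    def rename_tips(self, mapping: Mapping[str, str],
                    as_replacements: bool = True) -> "Phylogeny":
        """Relabel tips, optionally logging the original label as a stand-in."""
        clone = self._tree.clone(depth=1)
        repl = dict(self.replacements)
        for lf in clone.leaf_node_iter():
            old = lf.taxon.label
            if old in mapping:
                lf.taxon.label = mapping[old]
                if as_replacements:
                    repl[mapping[old]] = old
        return Phylogeny(clone, replacements=repl)

    # -- array views -------------------------------------------------------
    def arrays(self) -> dict:
        """Flat arrays (cached): node indexing with tips first.

        Keys: ``n_tips``, ``n_nodes``, ``tip_labels``, ``parent`` (index, -1
        at root), ``edge_length``, ``preorder`` (node indices, root first),
        ``postorder_internal`` (list of (node, left, right); requires a
        bifurcating tree and raises :class:`PolytomyError` otherwise).
        """
        if self._arrays is not None:
            return self._arrays
        tips = self._tree.leaf_nodes()
        internals = [nd for nd in self._tree.preorder_node_iter() if not nd.is_leaf()]
        index: dict[int, int] = {}
        for i, lf in enumerate(tips):
            index[id(lf)] = i
        for j, nd in enumerate(internals):
            index[id(nd)] = len(tips) + j
        n_nodes = len(tips) + len(internals)
        parent = np.full(n_nodes, -1, dtype=int)
        edge_length = np.zeros(n_nodes)
        for nd in self._tree.preorder_node_iter():
            i = index[id(nd)]
            if nd.parent_node is not None:
                parent[i] = index[id(nd.parent_node)]
                edge_length[i] = float(nd.edge.length or 0.0)
        preorder = np.array(
            [index[id(nd)] for nd in self._tree.preorder_node_iter()], dtype=int
        )
        postorder_internal = []
        bifurcating = True
        for nd in self._tree.postorder_internal_node_iter():
            ch = nd.child_nodes()
            if len(ch) != 2:
                bifurcating = False
                continue
            postorder_internal.append(
                (index[id(nd)], index[id(ch[0])], index[id(ch[1])])
            )
        self._arrays = {
            "n_tips": len(tips),
            "n_nodes": n_nodes,
            "tip_labels": [lf.taxon.label for lf in tips],
            "parent": parent,
            "edge_length": edge_length,
            "preorder": preorder,
            "postorder_internal": postorder_internal if bifurcating else None,
        }
        return self._arrays

    def postorder_internal(self) -> list[tuple[int, int, int]]:
        po = self.arrays()["postorder_internal"]
        if po is None:
            raise PolytomyError(
                "tree contains polytomies; call resolve_polytomies(seed=...) first"
            )
        return po

    # -- distances ---------------------------------------------------------
    def patristic_matrix(self) -> pd.DataFrame:
        """All-pairs tip distances: sum of branch lengths along each path."""
        if self._patristic is not None:
            return self._patristic
        arr = self.arrays()
        n_tips = arr["n_tips"]
        dist = np.zeros((n_tips, n_tips))
        # Bottom-up merge: carry (tip index, distance-to-node) per subtree.
        carried: dict[int, tuple[np.ndarray, np.ndarray]] = {}
        for i in range(n_tips):
            carried[i] = (np.array([i]), np.array([0.0]))
        for nd in self._tree.postorder_internal_node_iter():
            idx = self._node_index(nd)
            groups = []
            for ch in nd.child_nodes():
                ci = self._node_index(ch)
                tips_c, d_c = carried.pop(ci)
                groups.append((tips_c, d_c + self.arrays()["edge_length"][ci]))
            for a in range(len(groups)):
                for b in range(a + 1, len(groups)):
                    ta, da = groups[a]
                    tb, db = groups[b]
                    dd = da[:, None] + db[None, :]
                    dist[np.ix_(ta, tb)] = dd
                    dist[np.ix_(tb, ta)] = dd.T
            carried[idx] = (
                np.concatenate([g[0] for g in groups]),
                np.concatenate([g[1] for g in groups]),
            )
        labels = arr["tip_labels"]
        self._patristic = pd.DataFrame(dist, index=labels, columns=labels)
        return self._patristic

    def _node_index(self, nd) -> int:
        arr = self.arrays()
        tips = self._tree.leaf_nodes()
        if not hasattr(self, "_idmap"):
            self._idmap = {}
            for i, lf in enumerate(tips):
                self._idmap[id(lf)] = i
            j = len(tips)
            for nd2 in self._tree.preorder_node_iter():
                if not nd2.is_leaf():
                    self._idmap[id(nd2)] = j
                    j += 1
        return self._idmap[id(nd)]
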