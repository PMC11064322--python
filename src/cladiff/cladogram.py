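"""Cladogram of means.

The processed features are positioned at the leaves of the taxonomy tree;
every internal node carries, per sample, the unweighted mean of its
*direct* descendants.  Kingdoms form a forest (no artificial super-root).

A feature resolved only to, say, genus while siblings resolve to species
becomes a direct leaf child of the internal node with its own path, and
participates in that node's mean like any other direct child.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import TaxaTable, ValidationError
from .taxonomy import RankPath


@dataclass
class CladoNode:
    path: RankPath
    is_leaf: bool
    values: np.ndarray = field(default=None, repr=False)  # per-sample vector
    children: list["CladoNode"] = field(default_factory=list, repr=False)

    @property
    def depth(self) -> int:
        return self.path.depth

    @property
    def key(self) -> tuple[RankPath, bool]:
        return (self.path, self.is_leaf)

    def walk(self):
        yield self
        for c in self.children:
            yield from c.walk()


@dataclass
class MeanCladogram:
    roots: list[CladoNode]
    sample_ids: list[str]
    max_depth: int

    def walk(self):
        for r in self.roots:
            yield from r.walk()

    @property
    def nodes(self) -> list[CladoNode]:
        return sorted(self.walk(), key=lambda n: (n.path, n.is_leaf))

    def leaves(self) -> list[CladoNode]:
        return [n for n in self.nodes if n.is_leaf]

    def node_by_key(self, path: RankPath, is_leaf: bool = False) -> CladoNode:
        for n in self.walk():
            if n.path == path and n.is_leaf == is_leaf:
                return n
        raise KeyError(str(path))

    def nodes_at_depth(self, depth: int) -> list[CladoNode]:
        """All nodes (internal and leaf) at a taxonomy depth, path-sorted."""
        if not 1 <= depth <= self.max_depth:
            raise ValueError(f"depth {depth} outside 1..{self.max_depth}")
        return [n for n in self.nodes if n.depth == depth]

    def to_newick(self) -> str:
        """Topology as Newick, names = last rank."""
        from skbio import TreeNode

        def convert(node: CladoNode) -> TreeNode:
            t = TreeNode(name=node.path.name)
            for c in sorted(node.children, key=lambda n: (n.path, n.is_leaf)):
                t.append(convert(c))
            return t

        if len(self.roots) == 1:
            tree = convert(self.roots[0])
        else:
            tree = TreeNode(name="root")
            for r in sorted(self.roots, key=lambda n: n.path):
                tree.append(convert(r))
        return str(tree)

    def values_frame(self) -> pd.DataFrame:
        """Long-format (node_path, sample_id, value) frame of every node."""
        rows = []
        for n in self.nodes:
            for sid, v in zip(self.sample_ids, n.values):
                rows.append((str(n.path), "leaf" if n.is_leaf else "internal", sid, v))
        return pd.DataFrame(rows, columns=["node_path", "role", "sample_id", "value"])

    def write_values(self, path: str | Path) -> None:
        self.values_frame().to_csv(path, sep="\t", index=False)


def build_cladogram(table: TaxaTable) -> MeanCladogram:
    """Build the cladogram of means from a processed table.

    Internal values are computed bottom-up as the unweighted mean of each
    node's direct children.
    """
    if table.value_kind == "raw":
        raise ValidationError("build_cladogram expects a processed (non-raw) table")
    features = table.features
    if len(set(features)) != len(features):
        raise ValidationError("two features share an identical full path")

    # internal node paths: every strict prefix of a feature, plus any
    # feature path that is itself a strict prefix of another feature
    feature_set = set(features)
    internal_paths: set[RankPath] = set()
    for f in features:
        for lvl in range(1, f.depth):
            internal_paths.add(f.prefix(lvl))
    for f in features:
        if any(f.is_ancestor_of(g) for g in feature_set if g is not f):
            internal_paths.add(f)

    internal = {p: CladoNode(path=p, is_leaf=False) for p in internal_paths}
    leaves = {f: CladoNode(path=f, is_leaf=True, values=table.values_for(f))
              for f in features}

    # attach leaves: under the internal node with the same path if it
    # exists (mixed-depth case), else under the parent prefix
    for f, leaf in leaves.items():
        if f in internal:
            internal[f].children.append(leaf)
        elif f.depth == 1:
            pass  # depth-1 leaf is a root on its own
        else:
            internal[f.parent].children.append(leaf)
    for p, node in internal.items():
        if p.depth > 1:
            internal[p.parent].children.append(node)

    roots: list[CladoNode] = []
    for p, node in sorted(internal.items()):
        if p.depth == 1:
            roots.append(node)
    for f, leaf in sorted(leaves.items(), key=lambda kv: kv[0]):
        if f.depth == 1 and f not in internal:
            roots.append(leaf)
    roots.sort(key=lambda n: (n.path, n.is_leaf))

    def fill(node: CladoNode) -> np.ndarray:
        if node.is_leaf:
            return node.values
        node.children.sort(key=lambda n: (n.path, n.is_leaf))
        child_vals = np.stack([fill(c) for c in node.children])
        node.values = child_vals.mean(axis=0)
        return node.values

    for r in roots:
        fill(r)

    max_depth = max(f.depth for f in features)
    return MeanCladogram(roots=roots, sample_ids=table.sample_ids, max_depth=max_depth)


def check_mean_conservation(clad: MeanCladogram, atol: float = 1e-12) -> None:
    """Assert every internal node equals the mean of its direct children."""
    for n in clad.walk():
        if n.is_leaf:
            continue
        expect = np.stack([c.values for c in n.children]).mean(axis=0)
        if not np.allclose(n.values, expect, rtol=0, atol=atol):
            raise AssertionError(f"mean conservation violated at {n.path}")
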