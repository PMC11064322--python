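"""Plot-data builders: serialisable summaries behind the visualisations.

These are pure functions of a fitted result — node sizes are -log10(p)
for significant taxa, colors are direction signs, shapes record which
branch of the procedure found each taxon.  Rendering proper is left to
the caller (the data frames plug straight into matplotlib/graphviz).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cladogram import MeanCladogram
from .model import DifferentialAbundanceResults
from .io import TaxaTable
from .stats import spearman_test
from .taxonomy import RankPath

SOURCE_SHAPE = {"both": "both", "trajectory": "trajectory_only", "leaf": "leaf_only"}


@dataclass
class PlotNode:
    path: RankPath
    size: float           # -log10(p) if significant else 0
    color_sign: int       # -1 red, 0 gray, +1 blue
    shape: str            # both | trajectory_only | leaf_only | none
    family: str | None


def cladogram_plot_data(
    result: DifferentialAbundanceResults,
    clad: MeanCladogram | None = None,
) -> list[PlotNode]:
    """One PlotNode per cladogram node of the run."""
    clad = clad if clad is not None else result.model.cladogram
    sig = {t.key: t for t in result.taxa}
    nodes = []
    for n in clad.nodes:
        t = sig.get((n.path, n.is_leaf))
        if t is None:
            size, sign, shape = 0.0, 0, "none"
        else:
            size = float(-np.log10(max(t.p_value, 1e-300)))
            sign, shape = t.direction, SOURCE_SHAPE[t.source]
        nodes.append(PlotNode(
            path=n.path, size=size, color_sign=sign, shape=shape,
            family=n.path.rank_at("family"),
        ))
    return nodes


@dataclass
class NetworkEdge:
    a: RankPath
    b: RankPath
    scc: float
    sign: int


def interaction_network(
    result: DifferentialAbundanceResults,
    table: TaxaTable | None = None,
    scc_threshold: float = 0.3,
    alpha: float = 0.05,
) -> list[NetworkEdge]:
    """Spearman co-abundance edges among the significant taxa.

    An edge is drawn when |SCC| exceeds ``scc_threshold`` and its
    p-value is below ``alpha``.  Values are the (processed) cladogram
    node values of the run that produced the result.
    """
    import warnings

    clad = result.model.cladogram
    sig = sorted({t.key for t in result.taxa})
    if len(sig) < 2:
        warnings.warn("fewer than 2 significant taxa: empty network", stacklevel=2)
        return []
    vecs = {k: clad.node_by_key(*k).values for k in sig}
    edges = []
    for i in range(len(sig)):
        for j in range(i + 1, len(sig)):
            out = spearman_test(vecs[sig[i]], vecs[sig[j]])
            if abs(out.statistic) > scc_threshold and out.p_value < alpha:
                edges.append(NetworkEdge(
                    a=sig[i][0], b=sig[j][0],
                    scc=float(out.statistic), sign=int(np.sign(out.statistic)),
                ))
    return edges


def family_relation_counts(result: DifferentialAbundanceResults) -> dict[str, tuple[int, int]]:
    """Per-family counts of (positive, negative) significant descendants.

    Families with no significant descendant are absent from the output."""
    counts: dict[str, list[int]] = {}
    for t in result.taxa:
        fam = t.path.rank_at("family")
        if fam is None or t.depth <= 5:
            continue
        c = counts.setdefault(fam, [0, 0])
        if t.direction > 0:
            c[0] += 1
        elif t.direction < 0:
            c[1] += 1
    return {f: (c[0], c[1]) for f, c in counts.items() if c[0] + c[1] > 0}


def plot_nodes_frame(nodes: list[PlotNode]) -> pd.DataFrame:
    return pd.DataFrame([
        {"taxonomy_path": str(n.path), "size": n.size,
         "color_sign": n.color_sign, "shape": n.shape, "family": n.family}
        for n in nodes
    ])


def edges_frame(edges: list[NetworkEdge]) -> pd.DataFrame:
    return pd.DataFrame([
        {"a": str(e.a), "b": str(e.b), "scc": e.scc, "sign": e.sign}
        for e in edges
    ], columns=["a", "b", "scc", "sign"])
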