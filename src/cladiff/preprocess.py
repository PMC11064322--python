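"""Abundance preprocessing: normalisation and taxonomic merging.

Two normalisations are supported: element-wise log10(x + eps) with a small
eps (default 0.1) guarding zeros, and per-sample relative abundances.
Features are then merged at a chosen taxonomy level by one of three rules:

* ``mean`` / ``sum`` — element-wise mean/sum of the group's columns;
* ``sub_pca`` — each taxonomy group is z-scored and replaced by the
  minimal set of leading principal components whose cumulative explained
  variance exceeds one half (so every group contributes at least one
  feature).  Component signs are fixed so each component correlates
  non-negatively with the group's mean profile.

The standard pipeline is normalise first, then merge.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .io import TaxaTable, ValidationError
from .taxonomy import RankPath


@dataclass
class PreprocessConfig:
    """Defaults mirror the standard 16S workflow: species-level Sub-PCA
    merging of log10(x + 0.1) abundances."""

    taxonomy_level: int = 7
    merge_method: str = "sub_pca"  # sub_pca | mean | sum
    normalization: str = "log"     # log | relative
    epsilon: float = 0.1
    # cumulative: keep the minimal leading PCs whose cumulative explained
    # variance exceeds 0.5; per_component: keep every PC individually
    # explaining > 0.5 (can be empty, so cumulative is the default).
    sub_pca_criterion: str = "cumulative"

    def __post_init__(self) -> None:
        if not 1 <= self.taxonomy_level <= 7:
            raise ValueError("taxonomy_level must be in 1..7")
        if self.merge_method not in ("sub_pca", "mean", "sum"):
            raise ValueError(f"unknown merge_method {self.merge_method!r}")
        if self.normalization not in ("log", "relative"):
            raise ValueError(f"unknown normalization {self.normalization!r}")
        if self.normalization == "log" and self.epsilon <= 0:
            raise ValueError("epsilon must be > 0 for log normalization")


def normalize(table: TaxaTable, mode: str = "log", epsilon: float = 0.1) -> TaxaTable:
    """Normalise a raw table; returns a new TaxaTable with updated kind."""
    if table.value_kind != "raw":
        raise ValidationError(f"normalize expects raw values, got {table.value_kind}")
    if mode == "log":
        if epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        out = np.log10(table.data + epsilon)
        return TaxaTable(out, value_kind="log_processed")
    if mode == "relative":
        sums = table.data.sum(axis=1)
        zero = sums.index[sums == 0].tolist()
        if zero:
            raise ValidationError(f"all-zero sample rows: {zero}")
        out = table.data.div(sums, axis=0)
        return TaxaTable(out, value_kind="relative")
    raise ValueError(f"unknown normalization mode {mode!r}")


def _sub_pca_group(block: pd.DataFrame, criterion: str) -> np.ndarray:
    """Z-score a group's columns and return retained components (n x k)."""
    x = block.to_numpy(dtype=float)
    sd = x.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    z = (x - x.mean(axis=0)) / sd
    if z.shape[1] == 1:
        return z
    pca = PCA(n_components=min(z.shape))
    scores = pca.fit_transform(z)
    evr = pca.explained_variance_ratio_
    if criterion == "cumulative":
        k = int(np.searchsorted(np.cumsum(evr), 0.5) + 1)
    else:  # per_component
        k = max(int((evr > 0.5).sum()), 1)
    scores = scores[:, :k]
    # deterministic sign: align each PC with the group's mean profile
    ref = z.mean(axis=1)
    for j in range(k):
        c = float(scores[:, j] @ ref)
        if c < 0:
            scores[:, j] = -scores[:, j]
    return scores


def collapse_taxonomy(
    table: TaxaTable,
    level: int = 7,
    method: str = "sub_pca",
    sub_pca_criterion: str = "cumulative",
) -> TaxaTable:
    """Merge features sharing the same rank-path prefix up to ``level``.

    Features shallower than ``level`` keep their own (full) path and form
    their own group.  For ``sub_pca`` each group emits features named
    ``<last-rank>__pcK`` when more than one component is retained.
    """
    depths = [f.depth for f in table.features]
    if level > max(depths):
        raise ValidationError(
            f"collapse level {level} exceeds deepest feature depth {max(depths)}"
        )
    if method == "sub_pca" and table.value_kind == "raw":
        raise ValidationError("sub_pca requires a normalized table")

    groups: dict[RankPath, list[RankPath]] = {}
    for f in table.features:
        key = f.prefix(min(level, f.depth))
        groups.setdefault(key, []).append(f)

    cols: dict[RankPath, np.ndarray] = {}
    for key in sorted(groups):
        block = table.data[groups[key]]
        if method == "mean":
            cols[key] = block.mean(axis=1).to_numpy()
        elif method == "sum":
            cols[key] = block.sum(axis=1).to_numpy()
        else:
            scores = _sub_pca_group(block, sub_pca_criterion)
            if scores.shape[1] == 1:
                cols[key] = scores[:, 0]
            else:
                for j in range(scores.shape[1]):
                    nk = RankPath(key.ranks[:-1] + (f"{key.ranks[-1]}__pc{j + 1}",))
                    cols[nk] = scores[:, j]

    out = pd.DataFrame(cols, index=table.data.index)
    kind = table.value_kind if table.value_kind != "raw" else "raw"
    if method == "sub_pca":
        kind = "log_processed" if table.value_kind == "log_processed" else table.value_kind
    return TaxaTable(out, value_kind=kind)


def preprocess(table: TaxaTable, cfg: PreprocessConfig | None = None) -> TaxaTable:
    """Full pipeline: normalise, then merge at ``cfg.taxonomy_level``."""
    cfg = cfg or PreprocessConfig()
    normed = normalize(table, mode=cfg.normalization, epsilon=cfg.epsilon)
    return collapse_taxonomy(
        normed, level=cfg.taxonomy_level, method=cfg.merge_method,
        sub_pca_criterion=cfg.sub_pca_criterion,
    )
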