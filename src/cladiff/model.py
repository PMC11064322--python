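"""Hierarchical differential-abundance model.

The procedure has three stages:

1. *A priori gate* — a nested label-effect F-test is run at taxonomy
   depths 1, 2, ... until the first significant depth.  If no depth is
   significant the label is declared not microbially explainable and no
   per-taxon testing happens at all.
2. *Trajectory test* — every node at a coarse starting level is tested
   (Mann-Whitney for binary labels, Spearman for continuous), corrected
   across that level only.  Descent continues only through significant
   nodes: children are tested at the raw threshold, a sister
   Benjamini-Hochberg correction is applied among the siblings of each
   significant child (all but the most significant sister), and
   surviving children are recursed into.  No further level-wise
   correction is applied past the first level — the requirement of
   significance along the whole ancestor chain is itself stringent.
3. *Leaf rescue* — all leaves are additionally tested with a Bonferroni
   (or BH) correction across leaves, so rare taxa without a significant
   ancestor chain can still be reported.

The public surface follows the statsmodels idiom:
``DifferentialAbundanceModel(table, labels).fit()`` returns a
:class:`DifferentialAbundanceResults` carrying the significant taxa, the
gate p-values and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .cladogram import CladoNode, MeanCladogram, build_cladogram
from .io import LabelVector, TaxaTable, ValidationError, join_samples
from .preprocess import PreprocessConfig, preprocess as preprocess_table
from .stats import TestOutcome, adjust_pvalues, mann_whitney, nested_label_test, spearman_test
from .taxonomy import RankPath

MAX_START_LEVEL = 3  # escalation stops at the class level


@dataclass
class AnalysisConfig:
    """Tuning knobs of the hierarchical test.

    alpha is the per-test significance threshold (default 0.05);
    start_level "auto" escalates 1 -> 2 -> 3 until the trajectory test
    finds at least one taxon, a fixed integer pins the level and disables
    escalation.
    """

    alpha: float = 0.05
    start_level: int | str = "auto"
    first_level_correction: str = "bonferroni"  # bonferroni | bh
    leaf_correction: str = "bonferroni"         # bonferroni | bh
    label_kind: str | None = None               # inferred from labels when None

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0,1)")
        if self.start_level != "auto":
            lvl = int(self.start_level)
            if not 1 <= lvl <= MAX_START_LEVEL:
                raise ValueError(f"start_level must be auto or 1..{MAX_START_LEVEL}")
        for corr in (self.first_level_correction, self.leaf_correction):
            if corr not in ("bonferroni", "bh"):
                raise ValueError(f"unknown correction {corr!r}")


@dataclass
class SignificantTaxon:
    path: RankPath
    p_value: float
    adjusted_p: float | None
    direction: int
    source: str          # trajectory | leaf | both
    depth: int
    is_leaf: bool

    @property
    def key(self):
        return (self.path, self.is_leaf)


@dataclass
class AprioriResult:
    per_depth_p: dict[int, float]
    first_significant_depth: int | None

    @property
    def explainable(self) -> bool:
        return self.first_significant_depth is not None


def _node_test(node: CladoNode, labels: LabelVector) -> TestOutcome:
    if labels.kind == "binary":
        y = labels.values
        return mann_whitney(node.values[y == 1], node.values[y == 0])
    return spearman_test(node.values, labels.values)


def apriori_scan(clad: MeanCladogram, labels: LabelVector, alpha: float = 0.05) -> AprioriResult:
    """Nested-test gate: scan depths 1..max, stop at the first p < alpha."""
    per_depth: dict[int, float] = {}
    for depth in range(1, clad.max_depth + 1):
        out = nested_label_test(clad, labels, depth)
        per_depth[depth] = out.p_value
        if out.p_value < alpha:
            return AprioriResult(per_depth, depth)
    return AprioriResult(per_depth, None)


def sister_correct(child_p: dict, alpha: float = 0.05) -> set:
    """Sibling-level BH correction.

    The most significant child (ties broken lexicographically by path) is
    kept on its raw p alone; BH is applied over *all* remaining children,
    and a remaining child survives only if both its raw and adjusted p
    are below alpha.
    """
    if not child_p:
        raise ValidationError("sister_correct: empty sibship")
    for p in child_p.values():
        if not 0 <= p <= 1:
            raise ValidationError(f"p-value {p} outside [0,1]")
    items = sorted(child_p.items(), key=lambda kv: (kv[1], str(kv[0])))
    best, best_p = items[0]
    survivors = {best} if best_p < alpha else set()
    rest = items[1:]
    if rest:
        adj = adjust_pvalues([p for _, p in rest], method="bh")
        for (node, p), a in zip(rest, adj):
            if p < alpha and a < alpha:
                survivors.add(node)
    return survivors


def trajectory_test(
    clad: MeanCladogram,
    labels: LabelVector,
    cfg: AnalysisConfig,
    start_level: int,
) -> list[SignificantTaxon]:
    """Level-corrected test at ``start_level`` followed by raw-threshold
    descent with sister correction; returns every significant node on an
    unbroken significant chain."""
    if not 1 <= start_level <= clad.max_depth:
        raise ValueError(f"start_level {start_level} outside tree depth")
    first = clad.nodes_at_depth(start_level)
    outcomes = {n.key: _node_test(n, labels) for n in first}
    raw = np.array([outcomes[n.key].p_value for n in first])
    adj = adjust_pvalues(raw, method=cfg.first_level_correction)

    found: list[SignificantTaxon] = []
    frontier: list[CladoNode] = []
    for node, p, a in zip(first, raw, adj):
        if a < cfg.alpha:
            o = outcomes[node.key]
            found.append(SignificantTaxon(
                path=node.path, p_value=p, adjusted_p=float(a),
                direction=o.direction, source="trajectory",
                depth=node.depth, is_leaf=node.is_leaf,
            ))
            frontier.append(node)

    def descend(node: CladoNode) -> None:
        if node.is_leaf or not node.children:
            return
        child_out = {c.key: _node_test(c, labels) for c in node.children}
        child_p = {c.key: child_out[c.key].p_value for c in node.children}
        survivors = sister_correct(child_p, alpha=cfg.alpha)
        for c in node.children:
            if c.key in survivors:
                o = child_out[c.key]
                found.append(SignificantTaxon(
                    path=c.path, p_value=o.p_value, adjusted_p=None,
                    direction=o.direction, source="trajectory",
                    depth=c.depth, is_leaf=c.is_leaf,
                ))
                descend(c)

    for node in frontier:
        descend(node)
    return found


def leaf_test(clad: MeanCladogram, labels: LabelVector, cfg: AnalysisConfig) -> list[SignificantTaxon]:
    """Correction-adjusted test over all leaves (the rescue path)."""
    leaves = clad.leaves()
    if not leaves:
        raise ValidationError("cladogram has no leaves")
    outcomes = [_node_test(n, labels) for n in leaves]
    raw = np.array([o.p_value for o in outcomes])
    adj = adjust_pvalues(raw, method=cfg.leaf_correction)
    out: list[SignificantTaxon] = []
    for node, o, a in zip(leaves, outcomes, adj):
        if a < cfg.alpha:
            out.append(SignificantTaxon(
                path=node.path, p_value=o.p_value, adjusted_p=float(a),
                direction=o.direction, source="leaf",
                depth=node.depth, is_leaf=True,
            ))
    return out


class DifferentialAbundanceModel:
    """Phylogeny-aware differential-abundance test, statsmodels-style.

    Parameters
    ----------
    table : TaxaTable
        Raw counts/relative abundances, or an already-processed table
        (``value_kind != "raw"``), in which case preprocessing is skipped.
    labels : LabelVector
        Binary (0/1) or continuous per-sample label.
    preprocess : PreprocessConfig, optional
        Normalisation + merging settings; defaults to species-level
        Sub-PCA of log10(x + 0.1) when the input is raw.
    config : AnalysisConfig, optional
        Test thresholds and correction choices.
    """

    def __init__(
        self,
        table: TaxaTable,
        labels: LabelVector,
        preprocess: PreprocessConfig | None = None,
        config: AnalysisConfig | None = None,
    ):
        self.config = config or AnalysisConfig()
        if self.config.label_kind is None:
            self.config = replace(self.config, label_kind=labels.kind)
        if labels.kind == "binary":
            labels.require_both_classes()
        self.raw_table = table
        if table.value_kind == "raw":
            self.pre_config = preprocess or PreprocessConfig()
            table = preprocess_table(table, self.pre_config)
        else:
            self.pre_config = preprocess
        self.table, self.labels = join_samples(table, labels)
        self.cladogram = build_cladogram(self.table)

    @classmethod
    def from_files(
        cls,
        taxa_path: str | Path,
        metadata_path: str | Path,
        label_col: str,
        orientation: str = "samples_rows",
        **kwargs,
    ) -> "DifferentialAbundanceModel":
        from .io import read_metadata, read_taxa_table

        table = read_taxa_table(taxa_path, orientation=orientation)
        labels = read_metadata(metadata_path, label_col=label_col)
        return cls(table, labels, **kwargs)

    def fit(self) -> "DifferentialAbundanceResults":
        cfg = self.config
        apriori = apriori_scan(self.cladogram, self.labels, alpha=cfg.alpha)
        if not apriori.explainable:
            return DifferentialAbundanceResults(self, [], apriori, used_start_level=None)

        if cfg.start_level == "auto":
            levels = [l for l in (1, 2, 3) if l <= self.cladogram.max_depth]
        else:
            levels = [int(cfg.start_level)]
        traj: list[SignificantTaxon] = []
        used = levels[0]
        for lvl in levels:
            traj = trajectory_test(self.cladogram, self.labels, cfg, lvl)
            used = lvl
            if traj:
                break
        rescued = leaf_test(self.cladogram, self.labels, cfg)

        merged: dict = {t.key: t for t in traj}
        for t in rescued:
            if t.key in merged:
                prev = merged[t.key]
                merged[t.key] = replace(prev, source="both", adjusted_p=t.adjusted_p)
            else:
                merged[t.key] = t
        taxa = sorted(merged.values(), key=lambda t: (t.path, t.is_leaf))
        return DifferentialAbundanceResults(self, taxa, apriori, used_start_level=used)


class DifferentialAbundanceResults:
    """Fit results: significant taxa, gate p-values, diagnostics."""

    def __init__(self, model, taxa, apriori: AprioriResult, used_start_level):
        self.model = model
        self.taxa: list[SignificantTaxon] = list(taxa)
        self.apriori = apriori
        self.used_start_level = used_start_level
        self._check_trajectory_soundness()

    # -- integrity ---------------------------------------------------------
    def _check_trajectory_soundness(self) -> None:
        """Every trajectory taxon's ancestor chain back to the start level
        must itself be significant."""
        traj_paths = {t.path for t in self.taxa if t.source in ("trajectory", "both")}
        for t in self.taxa:
            if t.source not in ("trajectory", "both"):
                continue
            for lvl in range(self.used_start_level, t.depth):
                anc = t.path.prefix(lvl)
                if anc not in traj_paths:
                    raise AssertionError(
                        f"broken trajectory: {t.path} lacks significant ancestor {anc}"
                    )

    # -- accessors ---------------------------------------------------------
    @property
    def explainable(self) -> bool:
        return self.apriori.explainable

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "taxonomy_path": str(t.path),
                "depth": t.depth,
                "p_value": t.p_value,
                "adjusted_p": t.adjusted_p if t.adjusted_p is not None else np.nan,
                "direction": t.direction,
                "source": t.source,
                "is_leaf": t.is_leaf,
            }
            for t in self.taxa
        ]
        return pd.DataFrame(
            rows,
            columns=["taxonomy_path", "depth", "p_value", "adjusted_p",
                     "direction", "source", "is_leaf"],
        )

    def significant_paths(self, sources=("trajectory", "leaf", "both")) -> set[RankPath]:
        return {t.path for t in self.taxa if t.source in sources}

    def summary(self) -> str:
        lines = ["Hierarchical differential-abundance test", "=" * 44]
        lines.append(f"samples: {len(self.model.labels.sample_ids)}  "
                     f"features: {len(self.model.table.features)}  "
                     f"label: {self.model.labels.kind}")
        lines.append("a priori gate p-values by depth:")
        for d, p in self.apriori.per_depth_p.items():
            lines.append(f"  depth {d}: p = {p:.3g}")
        if not self.explainable:
            lines.append("label NOT microbially explainable; no taxa tested")
            return "\n".join(lines)
        lines.append(f"first significant depth: {self.apriori.first_significant_depth}")
        lines.append(f"trajectory start level: {self.used_start_level}")
        counts = {s: sum(t.source == s for t in self.taxa) for s in ("trajectory", "leaf", "both")}
        lines.append(f"significant taxa: {len(self.taxa)} "
                     f"(trajectory {counts['trajectory']}, leaf {counts['leaf']}, "
                     f"both {counts['both']})")
        df = self.to_frame()
        if len(df):
            lines.append("")
            lines.append(df.to_string(index=False, max_rows=40,
                                      float_format=lambda v: f"{v:.3g}"))
        return "\n".join(lines)

    def run_summary(self) -> dict:
        return {
            "explainable": self.explainable,
            "apriori_p": {str(k): v for k, v in self.apriori.per_depth_p.items()},
            "used_start_level": self.used_start_level,
            "n_significant": len(self.taxa),
            "n_by_source": {s: sum(t.source == s for t in self.taxa)
                            for s in ("trajectory", "leaf", "both")},
            "config": {
                "alpha": self.model.config.alpha,
                "start_level": self.model.config.start_level,
                "first_level_correction": self.model.config.first_level_correction,
                "leaf_correction": self.model.config.leaf_correction,
                "label_kind": self.model.config.label_kind,
            },
        }

    def write(self, out_dir: str | Path) -> None:
        import json

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(out / "significant_taxa.tsv", sep="\t", index=False)
        (out / "run_summary.json").write_text(json.dumps(self.run_summary(), indent=2))


def run_analysis(
    table: TaxaTable,
    labels: LabelVector,
    pre_cfg: PreprocessConfig | None = None,
    cfg: AnalysisConfig | None = None,
) -> DifferentialAbundanceResults:
    """Functional one-shot wrapper around the Model/Results pair."""
    return DifferentialAbundanceModel(table, labels, preprocess=pre_cfg, config=cfg).fit()
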