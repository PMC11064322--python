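"""Benchmarking without ground truth (RSP), with ground truth (TPR/FPR/F1),
and the sister-label similarity analysis.

RSP(beta) = (beta*RP - SP) / (beta*RP + SP), where RP is the number of
significant taxa found under the real labels, SP the mean number found
under shuffled labels, and beta in (0,1] the confidence weight: the score
crosses zero exactly when RP = SP/beta, so e.g. RSP(0.05) = 0 when real
discoveries outnumber shuffled ones twenty-fold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cladogram import MeanCladogram
from .io import LabelVector, TaxaTable, ValidationError
from .model import DifferentialAbundanceModel, AnalysisConfig
from .preprocess import PreprocessConfig
from .stats import spearman_test
from .taxonomy import RankPath


def rsp_score(rp: float, sp: float, beta: float) -> float:
    """The confidence-weighted real-vs-shuffled positives score.

    Returns 0 when beta*rp + sp == 0 (nothing found either way).
    """
    if not 0 < beta <= 1:
        raise ValueError("beta must be in (0, 1]")
    if rp < 0 or sp < 0:
        raise ValueError("rp and sp must be non-negative")
    denom = beta * rp + sp
    if denom == 0:
        return 0.0
    return (beta * rp - sp) / denom


@dataclass
class RSPCurve:
    rp: float
    sp: float
    betas: np.ndarray
    rsp: np.ndarray
    n_shuffles: int
    seed: int
    per_shuffle_sp: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "beta": self.betas, "rsp": self.rsp,
            "rp": self.rp, "sp": self.sp,
        })

    def per_shuffle_rsp(self) -> np.ndarray | None:
        """beta-grid RSP computed per shuffle then averaged (the
        alternative aggregation); None when per-shuffle SPs not kept."""
        if self.per_shuffle_sp is None:
            return None
        vals = np.array([
            [rsp_score(self.rp, sp, b) for b in self.betas]
            for sp in self.per_shuffle_sp
        ])
        return vals.mean(axis=0)


def estimate_sp(
    table: TaxaTable,
    labels: LabelVector,
    pre_cfg: PreprocessConfig | None,
    cfg: AnalysisConfig | None,
    n_shuffles: int = 10,
    seed: int = 0,
) -> tuple[float, np.ndarray]:
    """Mean significant-taxon count over label shuffles.

    Returns (mean, per-shuffle counts).  Labels are permuted with a
    seeded generator and the full procedure is re-run each time.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    rng = np.random.default_rng(seed)
    counts = np.empty(n_shuffles)
    vals = labels.series.to_numpy()
    for i in range(n_shuffles):
        perm = rng.permutation(vals)
        shuffled = LabelVector(
            pd.Series(perm, index=labels.series.index),
            kind=labels.kind, mapping=labels.mapping,
        )
        res = DifferentialAbundanceModel(
            table, shuffled, preprocess=pre_cfg, config=cfg
        ).fit()
        counts[i] = len(res.taxa)
    return float(counts.mean()), counts


def rsp_curve(
    table: TaxaTable,
    labels: LabelVector,
    pre_cfg: PreprocessConfig | None = None,
    cfg: AnalysisConfig | None = None,
    n_shuffles: int = 10,
    seed: int = 0,
    betas: np.ndarray | None = None,
) -> RSPCurve:
    """Run the test on real labels, estimate SP on shuffled labels and
    evaluate RSP over a beta grid (default 100 steps over (0, 1])."""
    if betas is None:
        betas = np.linspace(0.01, 1.0, 100)
    res = DifferentialAbundanceModel(table, labels, preprocess=pre_cfg, config=cfg).fit()
    rp = float(len(res.taxa))
    sp, per_shuffle = estimate_sp(table, labels, pre_cfg, cfg, n_shuffles, seed)
    vals = np.array([rsp_score(rp, sp, b) for b in betas])
    return RSPCurve(rp=rp, sp=sp, betas=np.asarray(betas), rsp=vals,
                    n_shuffles=n_shuffles, seed=seed, per_shuffle_sp=per_shuffle)


def confusion_metrics(predicted: set, truth: set, universe: set | None = None) -> dict:
    """Set-overlap counts and rates.

    f1 is defined as 1 when both truth and prediction are empty, 0 when
    only the truth is.  fpr needs a ``universe`` of testable taxa.
    """
    predicted, truth = set(predicted), set(truth)
    tp = len(predicted & truth)
    fp = len(predicted - truth)
    fn = len(truth - predicted)
    if not truth and not predicted:
        f1 = 1.0
    elif 2 * tp + fp + fn == 0:
        f1 = 0.0
    else:
        f1 = 2 * tp / (2 * tp + fp + fn)
    out = {"tp": tp, "fp": fp, "fn": fn,
           "tpr": tp / len(truth) if truth else float("nan"), "f1": f1}
    if universe is not None:
        negatives = len(set(universe) - truth)
        out["fpr"] = fp / negatives if negatives else float("nan")
    return out


@dataclass
class SisterStat:
    taxon: RankPath
    s: float
    m0: float
    m1: float
    v0: float
    v1: float


def sister_statistic(
    values: np.ndarray,
    labels: LabelVector,
    taxon: RankPath | None = None,
    denominator: str = "difference",
    eps_den: float = 1e-8,
) -> SisterStat:
    """Per-taxon label-effect size s = |M0-M1| / |V0-V1|^0.5.

    M/V are class means/variances.  The printed denominator (the square
    root of the *difference* of variances) is used as-is with an epsilon
    guard against near-equal variances; ``denominator="sum"`` switches to
    the conventional (V0+V1)^0.5.
    """
    if labels.kind != "binary":
        raise ValidationError("sister_statistic needs binary labels")
    y = labels.values
    v = np.asarray(values, dtype=float)
    g0, g1 = v[y == 0], v[y == 1]
    if g0.size < 2 or g1.size < 2:
        raise ValidationError("each class needs >= 2 samples for a variance")
    m0, m1 = float(g0.mean()), float(g1.mean())
    v0, v1 = float(g0.var(ddof=1)), float(g1.var(ddof=1))
    if denominator == "difference":
        den2 = abs(v0 - v1)
    elif denominator == "sum":
        den2 = v0 + v1
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    den = np.sqrt(den2) if den2 >= eps_den ** 2 else eps_den
    return SisterStat(taxon=taxon, s=abs(m0 - m1) / den, m0=m0, m1=m1, v0=v0, v1=v1)


def sister_correlation(
    clad: MeanCladogram,
    labels: LabelVector,
    denominator: str = "difference",
) -> dict:
    """Spearman correlation of the label-effect size s between sister taxa.

    For every internal node, all unordered pairs of direct children enter
    the pool, ordered lexicographically by path within each pair.
    """
    pairs: list[tuple[float, float]] = []
    for node in clad.walk():
        if node.is_leaf or len(node.children) < 2:
            continue
        kids = sorted(node.children, key=lambda n: (n.path, n.is_leaf))
        stats = [sister_statistic(k.values, labels, taxon=k.path,
                                  denominator=denominator).s for k in kids]
        for i in range(len(kids)):
            for j in range(i + 1, len(kids)):
                pairs.append((stats[i], stats[j]))
    if len(pairs) < 3:
        raise ValidationError("insufficient sister pairs (< 3)")
    a = np.array([p[0] for p in pairs])
    b = np.array([p[1] for p in pairs])
    out = spearman_test(a, b)
    return {"scc": out.statistic, "p_value": out.p_value, "n_pairs": len(pairs)}
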