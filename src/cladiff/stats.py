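"""Statistical primitives: Mann-Whitney, Spearman, p-value adjustment and
the nested label-effect F-test used as the a priori gate.

The Mann-Whitney wrapper is exact (full enumeration of the null) for small
tie-free groups and falls back to the normal approximation with tie and
continuity corrections otherwise.  Every outcome carries a direction sign
reported from the positive class's perspective: +1 means the positive
class ranks higher.

The nested label test stacks one observation per (sample, node) over all
cladogram nodes at depths 1..k and compares, by a partial F-test, the
fixed-effects model ``value ~ node`` against
``value ~ node + label + label:node``.  Because the design is a node
factor plus a per-node label slope, both fits decompose exactly into
per-node regressions, which is how they are computed; at depth 1 with a
single kingdom this reduces to a one-way ANOVA of kingdom values by label.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .io import LabelVector, ValidationError

EXACT_MW_MAX = 8  # largest min-group size for which the exact null is enumerated


@dataclass
class TestOutcome:
    statistic: float
    p_value: float
    direction: int  # -1, 0, +1; positive-class perspective
    method: str     # mw_exact | mw_normal | spearman | nested_f

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise ValueError(f"p-value {self.p_value} outside [0,1]")


def mann_whitney(x: np.ndarray, y: np.ndarray) -> TestOutcome:
    """Two-sided Mann-Whitney U of ``x`` (positive class) vs ``y``.

    Exact enumeration null when min group size <= 8 and values are
    tie-free, otherwise normal approximation with tie and continuity
    corrections.  direction = sign(U_x - nm/2).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("mann_whitney: empty group")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    exact = min(x.size, y.size) <= EXACT_MW_MAX and not has_ties
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    u_x = float(res.statistic)
    centred = u_x - x.size * y.size / 2.0
    return TestOutcome(
        statistic=u_x,
        p_value=min(float(res.pvalue), 1.0),
        direction=int(np.sign(centred)),
        method="mw_exact" if exact else "mw_normal",
    )


def spearman_test(x: np.ndarray, y: np.ndarray) -> TestOutcome:
    """Spearman rank correlation with average-rank ties; two-sided p via
    the t approximation.  direction = sign(rho)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValidationError("spearman_test: length mismatch")
    if x.size < 3:
        raise ValidationError("spearman_test: need at least 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValidationError("spearman_test: zero variance input")
    rho, p = sps.spearmanr(x, y)
    return TestOutcome(
        statistic=float(rho),
        p_value=min(float(p), 1.0),
        direction=int(np.sign(rho)) if rho == rho else 0,
        method="spearman",
    )


def adjust_pvalues(p, method: str = "bonferroni") -> np.ndarray:
    """Bonferroni (min(1, p*m)) or Benjamini-Hochberg step-up adjusted
    p-values, in the input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any():
        raise ValidationError("p-values outside [0,1]")
    if method == "bonferroni":
        return np.minimum(p * p.size, 1.0)
    if method == "bh":
        return multipletests(p, method="fdr_bh")[1]
    raise ValueError(f"unknown adjustment method {method!r}")


def _per_node_rss(values: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """(null RSS, full RSS) for one node: intercept-only vs intercept+slope."""
    v = values - values.mean()
    rss0 = float(v @ v)
    yc = y - y.mean()
    syy = float(yc @ yc)
    if syy == 0:
        return rss0, rss0
    sxy = float(v @ yc)
    return rss0, rss0 - sxy * sxy / syy


def nested_label_test(clad, labels: LabelVector, depth: int) -> TestOutcome:
    """Partial F-test for a label effect over all cladogram nodes at
    depths 1..``depth``.

    The added terms (label main effect + label-by-node interaction) amount
    to one slope per node, so df1 = K (number of nodes) and
    df2 = n_obs - 2K.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    y = labels.values
    if labels.kind == "binary":
        if (y == 1).sum() < 2 or (y == 0).sum() < 2:
            raise ValidationError("need >= 2 samples in each binary class")
    nodes = [n for d in range(1, depth + 1) for n in clad.nodes_at_depth(d)]
    if not nodes:
        raise ValidationError(f"no cladogram nodes at depths 1..{depth}")
    rss0 = rss1 = 0.0
    slopes = []
    for n in nodes:
        r0, r1 = _per_node_rss(n.values, y)
        rss0 += r0
        rss1 += r1
        yc = y - y.mean()
        syy = float(yc @ yc)
        slopes.append(float((n.values - n.values.mean()) @ yc) / syy if syy else 0.0)
    if rss0 <= 0:
        raise ValidationError("degenerate response: zero variance at all nodes")
    k = len(nodes)
    n_obs = k * y.size
    df1, df2 = k, n_obs - 2 * k
    if df2 <= 0:
        raise ValidationError("not enough observations for the nested test")
    if rss1 <= 0:
        # label explains everything: F is unbounded
        return TestOutcome(statistic=np.inf, p_value=0.0,
                           direction=int(np.sign(np.mean(slopes))), method="nested_f")
    f = ((rss0 - rss1) / df1) / (rss1 / df2)
    p = float(sps.f.sf(f, df1, df2))
    mean_slope = float(np.mean(slopes))
    return TestOutcome(statistic=float(f), p_value=p,
                       direction=int(np.sign(mean_slope)) if mean_slope else 0,
                       method="nested_f")
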