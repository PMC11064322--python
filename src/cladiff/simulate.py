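"""Synthetic data generators.

Two families of fixtures are produced, matching the two validation
settings of the method:

* *Hierarchical Gaussian regimes* — triplets of sister taxa z1, z2, z3
  under a common mother m = (z1+z2+z3)/3, with class-dependent means:
  regime (0,0,0) is a pure null, (0,0,mu) plants a mean shift mu on one
  daughter in the positive class, and (0,mu,alpha*mu) shifts two
  daughters with relative strength alpha (alpha < 0 gives the known
  hard case of oppositely-associated sisters).
* *Spike-in microbiome tables* — a random 7-level taxonomy over
  zero-inflated log-normal counts, with 10 taxa (and all their ASVs)
  elevated by 20% in positive samples and another 10 in negative
  samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import LabelVector, TaxaTable
from .taxonomy import RankPath

REGIMES = ("zzz", "zzm", "zma")


@dataclass
class RegimeConfig:
    regime: str = "zzz"
    mu: float = 0.0
    alpha_coef: float | None = None
    n_per_class: int = 50
    n_triplets: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.regime not in REGIMES:
            raise ValueError(f"unknown regime {self.regime!r}")
        if self.n_per_class < 2 or self.n_triplets < 1:
            raise ValueError("need n_per_class >= 2 and n_triplets >= 1")
        if self.mu < 0:
            raise ValueError("mu must be >= 0")
        if self.regime == "zzm" and self.mu == 0:
            raise ValueError("regime zzm needs mu > 0")
        if self.regime == "zma" and self.alpha_coef is None:
            raise ValueError("regime zma needs alpha_coef")


@dataclass
class SimDataset:
    table: TaxaTable
    labels: LabelVector
    truth: set[RankPath]

    def truth_leaves(self) -> set[RankPath]:
        """Planted taxa restricted to leaves (for leaf-only baselines)."""
        leaves = set(self.table.features)
        return {t for t in self.truth if t in leaves}

    def truth_with_ancestors(self) -> set[RankPath]:
        """Planted taxa plus every ancestor (for scoring trajectory
        output, where significant ancestors are expected findings)."""
        out = set(self.truth)
        for t in self.truth:
            for lvl in range(1, t.depth):
                out.add(t.prefix(lvl))
        return out


def simulate_regime(cfg: RegimeConfig) -> SimDataset:
    """Triplet-structured Gaussian data under a three-level taxonomy.

    The negative class is always N(0,1) on every daughter; the positive
    class follows the regime.  Values are emitted as an
    already-processed table (they are Gaussian, not counts), so the
    cladogram can be built directly.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_per_class
    n_samples = 2 * n
    labels = np.concatenate([np.ones(n, dtype=int), np.zeros(n, dtype=int)])

    means = {1: 0.0, 2: 0.0, 3: 0.0}  # positive-class daughter means
    if cfg.regime == "zzm":
        means[1] = cfg.mu
    elif cfg.regime == "zma":
        means[1] = cfg.mu
        means[2] = cfg.alpha_coef * cfg.mu

    cols: dict[RankPath, np.ndarray] = {}
    truth: set[RankPath] = set()
    for t in range(cfg.n_triplets):
        mother = RankPath(("SimKingdom", f"mother{t:03d}"))
        planted = False
        for d in (1, 2, 3):
            path = RankPath(mother.ranks + (f"z{d}",))
            vals = rng.standard_normal(n_samples)
            if means[d] != 0.0:
                vals[:n] += means[d]
                truth.add(path)
                planted = True
            cols[path] = vals
        if planted:
            truth.add(mother)

    sample_ids = [f"s{i:04d}" for i in range(n_samples)]
    table = TaxaTable(pd.DataFrame(cols, index=sample_ids), value_kind="log_processed")
    lv = LabelVector(pd.Series(labels, index=sample_ids), kind="binary")
    return SimDataset(table=table, labels=lv, truth=truth)


@dataclass
class SpikeConfig:
    """Zero-inflated log-normal spike-in table.

    Baseline counts are 0 with a per-taxon occupancy probability and
    otherwise round(LogNormal(baseline_log_mean, dispersion)).  Zero
    probabilities vary across taxa following a U-shaped Beta(1/2, 1/2)
    profile (core taxa present almost everywhere, rare taxa almost
    nowhere), quantile-stratified so the table-wide zero fraction equals
    ``sparsity``.  ``n_up``/``n_down`` genus-level taxa (with all their
    ASVs) are multiplied by ``spike_factor`` in positive / negative
    samples respectively.
    """

    n_samples: int = 200
    n_features: int = 300
    n_up: int = 10
    n_down: int = 10
    spike_factor: float = 1.2
    sparsity: float = 0.5
    dispersion: float = 1.0
    baseline_log_mean: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.spike_factor <= 1:
            raise ValueError("spike_factor must be > 1")
        if not 0 <= self.sparsity < 1:
            raise ValueError("sparsity must be in [0,1)")


def _random_taxonomy(n_features: int, rng: np.random.Generator) -> list[RankPath]:
    """A random 7-rank taxonomy with unique species leaves (the ASVs)."""
    paths = []
    for i in range(n_features):
        ranks = (
            "Bacteria",
            f"P{rng.integers(3)}",
            f"C{rng.integers(2)}",
            f"O{rng.integers(2)}",
            f"F{rng.integers(3)}",
            f"G{rng.integers(2)}",
            f"sp{i:05d}",
        )
        paths.append(RankPath(ranks))
    return paths


def simulate_microbiome(cfg: SpikeConfig) -> SimDataset:
    """Spike-in benchmark table with known ground truth.

    Genus-level taxa are selected at random without replacement: the
    first ``n_up`` are elevated in positive samples, the next ``n_down``
    in negative samples (sets are disjoint by construction).  Sample
    labels are independent fair coin flips.
    """
    rng = np.random.default_rng(cfg.seed)
    paths = _random_taxonomy(cfg.n_features, rng)

    genus_paths = sorted({p.prefix(6) for p in paths})
    if cfg.n_up + cfg.n_down > len(genus_paths):
        raise ValueError(
            f"cannot spike {cfg.n_up}+{cfg.n_down} taxa: only "
            f"{len(genus_paths)} genus-level taxa available"
        )
    picked = rng.choice(len(genus_paths), size=cfg.n_up + cfg.n_down, replace=False)
    up = {genus_paths[i] for i in picked[:cfg.n_up]}
    down = {genus_paths[i] for i in picked[cfg.n_up:]}

    n, m = cfg.n_samples, cfg.n_features
    counts = np.round(rng.lognormal(cfg.baseline_log_mean, cfg.dispersion, size=(n, m)))
    # per-taxon zero probabilities: U-shaped Beta(1/2,1/2) rescaled to the
    # target mean, quantile-stratified so the overall zero fraction is
    # cfg.sparsity by construction
    from scipy import stats as _sps

    if cfg.sparsity > 0:
        q = (np.arange(m) + 0.5) / m
        base = _sps.beta.ppf(q, 0.5, 0.5)  # mean 1/2
        p_zero = np.clip(base * (cfg.sparsity / 0.5), 0.0, 0.995)
        p_zero = rng.permutation(p_zero)
        zero_mask = rng.random((n, m)) < p_zero[None, :]
        counts[zero_mask] = 0.0

    y = (rng.random(n) < 0.5).astype(int)
    if y.sum() == 0:
        y[0] = 1
    elif y.sum() == n:
        y[0] = 0

    truth: set[RankPath] = set(up) | set(down)
    for j, p in enumerate(paths):
        g = p.prefix(6)
        if g in up:
            counts[y == 1, j] *= cfg.spike_factor
            truth.add(p)
        elif g in down:
            counts[y == 0, j] *= cfg.spike_factor
            truth.add(p)

    sample_ids = [f"s{i:04d}" for i in range(n)]
    table = TaxaTable(pd.DataFrame(counts, index=sample_ids, columns=paths),
                      value_kind="raw")
    lv = LabelVector(pd.Series(y, index=sample_ids), kind="binary")
    return SimDataset(table=table, labels=lv, truth=truth)


def write_fixture(ds: SimDataset, out_dir, stem: str) -> None:
    """Write table + metadata + truth as TSVs (fixture CLI backend)."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ds.table.write(out / f"{stem}_taxa.tsv")
    meta = pd.DataFrame({"sample_id": ds.labels.sample_ids,
                         "label": ds.labels.series.to_numpy()})
    meta.to_csv(out / f"{stem}_meta.tsv", sep="\t", index=False)
    pd.Series(sorted(str(t) for t in ds.truth)).to_csv(
        out / f"{stem}_truth.tsv", sep="\t", index=False, header=False)
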