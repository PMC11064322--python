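# Methods

## Model and procedure

`cladiff` tests for associations between a per-sample label (binary 0/1 or
continuous) and microbial abundances arranged on their taxonomy tree. Let
x_ij be the processed abundance of taxon j in sample i and y_i the label.
The cladogram of means places the observed (processed) features at the
leaves; every internal node carries, per sample, the unweighted mean of its
*direct* descendants. A feature resolved only to, say, genus while its
siblings resolve to species is attached as a direct leaf child of the
internal node with its own path and enters that node's mean with the same
weight as any other child. Kingdoms form a forest; no super-root value is
computed.

**A priori gate.** For depth k the gate stacks one observation per
(sample, node) over all nodes at depths 1..k and compares, by a partial
F-test, `value ~ node` against `value ~ node + label + label:node`
(label as a 0/1 covariate or the continuous covariate; Gaussian errors).
Because the design is a node factor plus a per-node label slope, both fits
decompose into per-node simple regressions: the F statistic is computed
analytically from per-node residual sums of squares with df1 = K (number
of nodes) and df2 = n·K − 2K. At depth 1 with a single kingdom this is
exactly a one-way ANOVA of kingdom values by label. The scan runs k = 1, 2,
… until the first p < α; if no depth is significant the label is reported
as not microbially explainable and no taxon-level test is run.

A caveat the package documents rather than hides: for k ≥ 2 the stacked
observations are correlated across nodes (a parent is the mean of its
children), so the F reference distribution is approximate there. The
depth-1 test is exact under Gaussian errors, and the gate's null behaviour
is verified at depth 1 by simulation (1000 permuted-label replicates,
rejection rate within the 95% binomial interval of α).

**Trajectory test.** Every node at the starting level is tested —
Mann–Whitney U for binary labels (direction reported from the positive
class's perspective, +1 when positives rank higher), Spearman for
continuous — and corrected across that level only (Bonferroni by default).
Descent from a significant node tests its children at the raw threshold α
and applies the sister correction: the most significant child (ties broken
lexicographically by path) is kept on its raw p alone; BH is applied over
all remaining children, and a remaining child survives only if both raw
and adjusted p are below α. Only survivors are descended into. No further
level-wise correction is applied past the first level: requiring
significance along the entire chain is itself the multiplicity control.
If the starting level yields nothing, the start escalates one level
(kingdom → phylum → class) and stops at class; a user-pinned start level
disables escalation.

**Leaf rescue.** All leaves are tested and corrected across the number of
leaves (Bonferroni by default, BH available), admitting rare taxa with no
significant ancestor chain. Taxa found by both branches are reported once
with `source = "both"`.

## Statistical primitives

* Mann–Whitney U uses the exact enumeration null when min(n, m) ≤ 8 and
  the pooled values are tie-free, and otherwise the normal approximation
  with tie and continuity corrections. The exact path is verified against
  an independent brute-force enumeration over every tie-free rank
  arrangement with group sizes ≤ 6.
* BH adjustment is the step-up procedure (verified against a literal
  step-up oracle); Bonferroni is min(1, m·p).
* Degenerate inputs raise: empty Mann–Whitney groups, constant Spearman
  vectors, zero residual variance in the gate's null model, binary labels
  with one class absent.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| α | 0.05 | per-test significance threshold throughout |
| start_level | auto | trajectory start (auto escalates 1→2→3) |
| first_level_correction | bonferroni | correction across the start level |
| leaf_correction | bonferroni | correction across leaves in the rescue test |
| taxonomy_level | 7 | merge depth (species) for preprocessing |
| merge_method | sub_pca | sub_pca / mean / sum group merging |
| normalization | log | log10(x + ε) or per-sample relative |
| ε | 0.1 | log-normalisation offset guarding zeros |

Preprocessing normalises first, then merges. Sub-PCA z-scores each
taxonomy group and keeps the minimal set of leading principal components
whose *cumulative* explained variance exceeds one half. The cumulative
reading guarantees at least one component per group; the per-component
reading (each PC individually above one half, which can return an empty
group) is available via `sub_pca_criterion="per_component"`. Component
signs are fixed by non-negative correlation with the group's mean profile,
making the output and the downstream direction signs deterministic.

## Evaluation

RSP(β) = (β·RP − SP)/(β·RP + SP) with β ∈ (0, 1]. SP is the mean
significant-taxon count over label shuffles (10 by default, seeded); the
default curve computes RSP once from the mean SP, and per-shuffle RSP
curves are also available since the two aggregations differ slightly. The
score is defined as 0 when β·RP + SP = 0 (nothing found either way). It is
bounded in [−1, 1], antisymmetric in (RP, SP) at β = 1, increasing in RP
and decreasing in SP.

The sister effect size s = |M0 − M1| / |V0 − V1|^0.5 (class means and
unbiased class variances) is implemented with the denominator as printed —
the square root of the absolute *difference* of variances — guarded by
ε = 1e-8 when the variances nearly coincide; the conventional pooled form
(V0 + V1)^0.5 is available via `denominator="sum"`. For the sister
correlation analysis, all unordered pairs of direct children of each
internal node enter the pool (ordered lexicographically within a pair) and
a Spearman correlation over the paired s values is reported.

F1 comparisons between the hierarchical test and per-leaf baselines are
scored on leaf sets (the units both can call); trajectory output as a
whole is scored against the planted taxa *plus their ancestors*, because a
mother averaging a shifted daughter genuinely carries a μ/3 shift and
detecting it is a true positive, while leaf-only baselines are scored
against the planted leaves alone.

## Synthetic data: what it emulates and what it does not

**Gaussian triplet regimes.** Three sister taxa z1, z2, z3 under a common
mother m = (z1+z2+z3)/3, 2N samples (N per class), negative class always
N(0,1): regime (0,0,0) is a pure null; (0,0,μ) shifts z1 by μ in
positives; (0,μ,α·μ) shifts z1 by μ and z2 by α·μ (α < 0 is the known
failure mode where oppositely-associated sisters cancel in the mother and
only the leaf rescue recovers them). The default is a single triplet,
matching the analytic setting; any number of triplets can be planted under
a shared kingdom. Two identities follow directly and are tested: the
mother's null sd is 1/√3 ≈ 0.5774, and the mother equals the daughters'
mean exactly per sample.

One analytic claim deliberately does *not* hold and is left as a failing
check rather than being weakened: the joint null rate of (mother
significant AND a fixed daughter significant) at α = 0.05 is not ≈ α². The
two rank statistics are correlated with ρ = 1/√3 (the mother contains the
daughter), and the bivariate-normal orthant value puts the joint rate at
≈ 0.0117 ≈ 4.4·α² — much smaller than α, which is what the descent
actually relies on, but well above the α²-within-factor-2 band.

**Spike-in microbiome tables.** A random 7-rank taxonomy (unique species
leaves = ASVs, a few ASVs per genus at the default 300-feature scale);
baseline counts round(LogNormal(4, 1)) — median count ≈ 55, log10 sd
≈ 0.43, typical of 16S cross-sample variability — zeroed with per-taxon
probabilities following a U-shaped Beta(1/2, 1/2) occupancy profile
(core taxa nearly always present, rare taxa nearly never),
quantile-stratified so the table-wide zero fraction equals the `sparsity`
setting (0.5 by default). Labels are independent fair coin flips. Ten
genus-level taxa (with all their ASVs) are multiplied by 1.2 in positive
samples and a disjoint ten in negative samples; the truth set is the 20
taxa plus their ASVs.

What this does not emulate: cross-ASV correlation beyond the spike itself,
compositional coupling between taxa, sequencing-depth variation, and the
very high ASV multiplicity of real cohorts (hundreds of ASVs per spiked
taxon), which is where aggregation along the tree gains most of its power.
Consequently a 20% spike at 200 samples × 300 ASVs sits at the edge of
detectability — log10(1.2) ≈ 0.079 against per-ASV noise of ≈ 0.43 plus
the zero/non-zero bimodality — and both the hierarchical test and a
Bonferroni leaf sweep have near-zero F1 at this scale; the hierarchical
test's measured advantage comes from a handful of trajectory discoveries
the corrected sweep misses. Passing that comparison therefore shows the
mechanism works, not that real-data F1 levels are reproduced.

## Problem sizes used in the validation suite

Chosen so the full suite runs comfortably on a single CPU: 10^6 draws for
the mother-sd identity; 20,000 replicates at N = 50/class for the joint
significance rate; all tie-free Mann–Whitney inputs with group sizes ≤ 6
against the enumeration oracle and 1000 random vectors against the BH
oracle; 100 random tables for mean conservation; 1000 permuted-label
replicates at n = 60 for gate calibration; 200 seeds × N ∈ {20, 80, 320}
for the FP/TP dominance comparison; 20 seeds of 200 × 300 spike-in tables
for the F1 comparison.

## Known limitations

* The gate's partial-F reference is approximate for depths ≥ 2 (correlated
  stacked observations); the scan also inspects several depths without a
  multiplicity adjustment, by design — it is a screening gate, not an
  inferential endpoint.
* Escalation beyond the class level is intentionally not performed; very
  deep sparse signals are left to the leaf rescue test.
* Multi-class categorical labels, covariate adjustment and
  repeated-measures designs are out of scope.
* The sister statistic's printed denominator |V0 − V1|^0.5 is unusual
  (near-equal variances inflate s); it is kept as the primary form for
  fidelity, with the pooled alternative one flag away.
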