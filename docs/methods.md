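# Methods

## Model

The package predicts disease–miRNA associations by local structural
similarity on a bipartite network. Its core assumption is the standard
one in this field: functionally similar miRNAs tend to associate with
phenotypically similar diseases. Three inputs encode it — the Boolean
association matrix AS (diseases on rows, miRNAs on columns, one
orientation enforced everywhere), the disease semantic-similarity matrix
SD, and the miRNA functional-similarity matrix SM with an optional
miRNA → family table.

Scoring proceeds in three stages.

**Co-neighbor counting.** For a pair (dᵢ, mⱼ) the raw signal is the
number of simple three-edge paths dᵢ → m′ → d′ → mⱼ with all four nodes
distinct. We compute it as the length-3 walk count (A AᵀA)ᵢⱼ minus a
correction applied only on known pairs: a three-edge walk between dᵢ
and mⱼ can only fail to be simple by reusing the direct edge
(dᵢ, mⱼ) — either m′ = mⱼ (deg mⱼ walks) or d′ = dᵢ (deg dᵢ walks),
with the doubly degenerate walk counted once — giving
deg dᵢ + deg mⱼ − 1 degenerate walks, all requiring A(i,j) = 1. The
closed form is verified against exhaustive enumeration in the test
suite. On unknown pairs (the ones actually ranked) walk count and
simple-path count coincide.

**Degree normalization.** Eight local indexes rescale the count by the
endpoint degrees (CN, Salton, Jaccard, Sørensen, HPI, HDI, LHN1, PA;
see the README table). Jaccard is exactly half of Sørensen and is kept
only so the index menu is complete. PA multiplies by the degree product
rather than dividing — it deliberately favors hub pairs. Pairs with a
zero count score 0, as do pairs involving a degree-zero node (the
denominator would be undefined; treating "no information" as 0 keeps
the zero rule uniform). Known pairs are then clamped to the global
maximum of the matrix (1 if the matrix is all zero) so that training
positives are never out-ranked before propagation. Clamping to the
*global* maximum, rather than a per-row maximum, is a deliberate choice:
it guarantees the property the clamp exists for — with clamping on, the
argmax of the initial-score matrix is attained at every known pair —
which a per-row clamp cannot.

**Similarity propagation and blending.** The clamped initial scores are
propagated through the fused miRNA network (R^FBM = R^PB · SIM) and the
fused disease network (R^FBD = SDDᵀ · R^PB); both sums run over *all*
nodes, including the pair's own row/column. The fused networks are
SIM(i,j) = SM(i,j)·(α + (1−α)·SM^fam(i,j)) and
SDD = β·SDAS + (1−β)·SD with SDAS(i,j) = comm(i,j)/(deg dᵢ + deg dⱼ).
The final score is the convex blend R^FB = (1−γ)R^FBM + γR^FBD.

Propagation is a single linear pass — no iteration, no random walk, no
renormalization between stages. Because the evaluation is rank-based,
score scale is irrelevant and renormalization would change nothing.

### Diagonal convention

SDAS gives any associated disease a self-similarity of exactly 0.5,
which would make a disease less similar to itself than two distinct
diseases can be to each other; the raw fusion formulas inherit that
defect. Both fused matrices therefore get their diagonal forced to 1
*after* fusion. With a unit diagonal the self-term of each propagation
sum carries the pair's own initial score through unchanged, which is the
behavior one wants from a similarity-smoothing step. The same is applied
to the unfused matrices in the no-reconstruction scenarios for
consistency.

### Scenarios

Six configurations expose the ablation structure of the method: `MDA`
(clamped initial scores only), `MS-noMSR`/`MS-MSR` (miRNA-space score,
without/with family-informed reconstruction), `DS-noDSR`/`DS-DSR`
(disease-space score, without/with association-informed reconstruction),
and `full` (the γ-blend). Structural consequences, enforced by tests: an
isolated disease has a zero initial-score row, so its miRNA-space row is
also zero — only the disease channel can rank its candidates; a new
miRNA is the mirror case. In the isolated-disease regime, reconstruction
(DSR) cannot help either: the held-out disease's SDAS row is recomputed
from the training matrix, where it is zero, so DS-DSR and DS-noDSR give
identical fold rankings there.

## Parameters

| parameter | default | meaning |
|---|---|---|
| α | 0.5 | weight of cross-family miRNA similarity; 1 ignores families |
| β | 0.5 | weight of association-derived disease similarity vs semantic |
| γ | 0.5 | weight of the disease-space channel in the final blend |
| index | HPI | degree normalization of the co-neighbor count |
| scenario | full | which part of the scoring chain to return |
| clamp | on | overwrite known pairs with the matrix maximum |

All three weights are dimensionless convex-combination coefficients in
[0, 1]. The 0.5 defaults treat the fused information sources as equally
trustworthy and are the method's standard operating point; HPI is the
default index because dividing by the *smaller* degree is the natural
choice for heavily skewed bipartite degree distributions. None of the
weights is learned from data.

## Evaluation protocol

Leave-one-out cross-validation in three regimes. Global: each known
pair is removed in turn, everything downstream of AS is recomputed
(degrees, co-neighbor counts, clamping, and SDAS when the scenario
reconstructs the disease network), and the held-out pair is ranked
among all pairs unknown in the full dataset plus itself.
Isolated-disease / new-miRNA: an entire row / column is removed and each
of its true partners is ranked among that node's unknown partners plus
itself. Side-information matrices (SM, SD, families) are never modified
by a fold.

The ROC construction pools fold ranks as percentiles
p = (rank − 0.5)/candidates, with ties sharing the average rank;
sweeping a threshold t gives TPR(t) = P(p ≤ t) against FPR(t) = t, so
AUC = 1 − mean(p) exactly. The choices here — percentile pooling (no
cross-fold score calibration assumed) and average-rank ties (an
uninformative, constant score matrix calibrates to AUC 0.5 rather than
an artifact) — are the package's own; other negative-set conventions can
shift absolute AUCs by a point or two, which is why the test suite pins
calibration properties and orderings rather than absolute values on
real data. AUCs are reported to 4 decimals.

## Synthetic data

The generator plants the method's own structural hypothesis: diseases
and miRNAs are assigned round-robin to matched blocks (so "similar
miRNAs ↔ similar diseases" holds by construction); associations are
Bernoulli with probability `p_in` within a block and `p_out` across;
both similarity matrices are `sim_signal`·(block indicator) plus
N(0, `noise_sd`) noise, symmetrized by averaging with the transpose,
clipped to [0, 1], unit diagonal — in that order, so fixtures are
bit-reproducible from the seed; families coincide with miRNA blocks.

Defaults: 40 diseases × 60 miRNAs, 4 blocks, p_in = 0.3, p_out = 0.02
(a sparse network of roughly two hundred associations, comparable in
density to curated benchmarks), sim_signal = 0.8 and noise_sd = 0.1
(strong but noisy block correlation, typical of curated semantic and
functional similarity matrices). Evaluation-based checks average over
20 independent seeds; the acceptance script averages 5 seeds per
regime, enough to stabilize a mean AUC to well under its tolerance.

What the generator does *not* emulate: the heavy-tailed degree
distribution of real association databases, block-free "background"
similarity structure, and annotation noise in family tables. Passing
tests therefore demonstrate correctness of the machinery and the
direction of its structural effects, not absolute performance on any
real benchmark.

## Numerical notes

* All matrices are dense float64; problem sizes in this domain
  (hundreds of nodes) make sparse machinery unnecessary.
* Similarity matrices must be symmetric to 1 × 10⁻⁹ and inside
  [0, 1] by the same tolerance; violations are errors, not warnings —
  inputs are curated matrices, and silent repair would mask upstream
  bugs. Missing entries are likewise not imputed.
* Duplicate edges in association files deduplicate with a warning
  (duplicates are common in merged curations); labels present in a
  similarity file but absent from the association matrix are dropped
  with a warning, and the reverse direction is an error.
* Co-neighbor counts are computed in int64; they are exact.
* Ties in ranking are resolved by average rank everywhere.

## Limitations

* Strictly local: only three-edge paths carry signal; no damped longer
  walks, no global diffusion.
* Scores are not comparable across datasets or scenarios — only ranks
  are meaningful.
* The disease channel is only as good as SD; with an uninformative SD
  row, an isolated disease's candidates are unrankable (tied midpoint)
  by construction.
* Known pairs are emitted in the score output (the evaluator excludes
  them); downstream consumers ranking "novel" candidates should mask
  training positives themselves.
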