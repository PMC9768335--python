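# Methods

## Problem setting

The package infers a directed gene regulatory network (GRN) from a
single-gene knockout compendium at steady state: an n-gene wild-type
expression vector `A0` and an n x n matrix `A` whose row *i* holds the
steady state of all genes after deletion of gene *i* (the layout of the
DREAM in-silico knockout challenges). One experiment per gene, no
replicates, no time series. The output is a scored list of directed edges
regulator -> target.

## The inference pipeline

### 1. Downstream-target identification

For target gene *j*, the change under knockout of *i* is
`Δa_ij = a_ij − a_0j`. Changes are normalised per target by the gene's mean
change, giving relative changes `Δs_ij = Δa_ij / ΔA̅_j`, and the whole
column is damped by a sigmoid weight

    w_j = 1 / (1 + exp(r (b_j − u))),    r < 0, 0 < u < 1,

where `b_j = max_{i≠j} |Δa_ij| / a_0j` is the gene's maximum relative
response to the deletion of *another* gene. The weighted matrix is
`S = w ⊙ Δs`; the candidate targets of regulator *i* are the genes with
`|s_ij| > θ0`.

Two normalisation choices deserve comment, because the obvious literal
readings conflate interventions with responses:

- **`b_j` excludes the self-knockout row.** The diagonal entry is a forced
  drop to zero; including it makes `b_j ≡ 1` for every gene in
  absolute-value mode and the weighting becomes a no-op. `b_j` is a
  response strength to *other* genes' perturbations.
- **`ΔA̅_j` excludes the self-knockout row** (for square change matrices;
  single-column inputs keep the plain mean). The diagonal term `−a_0j`
  otherwise dominates the mean, so the "relative change" would effectively
  measure response relative to wild-type level rather than relative to the
  gene's typical response to regulators — and `θ0 = 1` ("at least the mean
  response") would lose its meaning.

`b_j` uses `|Δa_ij|` by default (a strong repression is a strong response);
the literal signed maximum is available as `b_mode="signed"`. The mean-
change denominator offers `denom_mode="abs-mean"` for data where activating
and repressing responses cancel in the signed mean. Near-zero denominators
and zero wild-type levels are floored at `eps = 1e-12` with a warning, so
the pipeline is total on degenerate inputs.

Defaults: `r = −10`, `u = 0.5` (the weight is 0.5 at a 50% maximal relative
response), `θ0 = 1.0`. `r` and `u` shape only the damping, not the ranking
of responses within a gene.

### 2. Two-layer dissection with conditional mutual information

Candidates mix direct targets with genes reached through intermediates.
Under a joint-Gaussian model over the n knockout experiments, the
conditional mutual information

    I(g_i; g_j | g_k) = 1/2 ln( |C_ik| |C_jk| / (C_kk |C_ijk|) )

is zero when candidate *k* carries all the information *j* has about the
regulator *i*; such *j* is assigned to the *indirect* (second) layer with
mediator *k* (implying edges i -> k and k -> j), everything else stays
*direct*. The decision rule is: *j* is indirect if `min_k I(g_i; g_j | g_k)
< ε`, with the argmin as mediator; default `ε = 0.1` nats, the same value
as the mutual-information threshold below.

Practical choices:

- **Observations.** MI/CMI are computed over the n knockout rows (the wild
  type is not appended). For CMI the row that deletes the *target j* is
  dropped — its forced zero is an intervention on *j*, not a response — but
  the regulator's and the candidate mediator's rows are kept: the
  mediator's own knockout row is precisely the evidence that separates
  "i -> k -> j" from "i -> j directly" (if *j* is direct, deleting *k*
  leaves *j* at wild type while *k* collapses, breaking the j = f(k)
  relation).
- **Mediator admissibility.** A candidate *k* may only mediate i -> j if
  *j* is itself a downstream target of *k* under the method's own response
  criterion (`|s_kj| > θ0`). Without this, near-singular covariances let
  genes whose deletion does not touch *j* at all "explain" it.
- **Conflict resolution.** Proposals are accepted greedily by ascending
  CMI (ties by gene index): a target already used as a mediator stays
  direct, and a proposal whose mediator has itself become indirect is
  dropped. This yields a deterministic partition in which every mediator is
  a member of the direct layer and each indirect target has exactly one
  mediator.
- **Ridge.** All covariance determinants add `1e-8 x mean(diag)` to the
  diagonal; knockout panels routinely produce singular covariances.
  Logarithms are natural (nats) throughout.

### 3. Orienting same-layer pairs

Within each layer, pairs with Gaussian mutual information
`I = −1/2 ln(1−ρ²)` above `mi_threshold` (default 0.1 nats) are considered
strongly dependent and are oriented. With X the shared regulator (direct
layer) or common ancestor (indirect layer) and (X0, Y0, Z0) the wild-type
operating point, assuming Y drives Z and expanding both steady-state
responses to second order — using that the responses are stationary at the
operating point, so the first-order terms vanish — yields the no-intercept
model

    Z − Z0 = a (X − X0)² + b (Y − Y0),    b = ∂Z/∂Y |_{X0}.

The model and its mirror (Y regressed on (X−X0)² and Z−Z0) are fitted by
least squares on the knockout rows excluding the rows that delete Y or Z
themselves; whichever cross-gain has the larger magnitude wins (if Y truly
drives Z, the reverse gain is asymptotically zero). Magnitudes rather than
raw values are compared because regulation may be repressive. Rank-
deficient designs are fitted with the pseudoinverse (minimum-norm solution,
zero coefficient for a constant regressor) and flagged; the verdict is a
tie only when the two magnitudes are exactly equal, and ties are resolved
upstream by emitting the direction from the lexicographically smaller
source, flagged in the log. An oriented edge u -> v is only emitted if v
responds to the deletion of u (`|s_uv| > θ0`); otherwise the verdict
contradicts the knockout evidence.

A diagnostic (`wildtype_stationarity_check`) reports, per gene, the ratio
of the scaled linear to the scaled quadratic term of its response to its
strongest perturber — a check on the stationarity assumption that is logged
but never blocks inference.

### 4. Aggregation and scoring

Edges from all regulators (regulator -> direct, mediator -> indirect,
Taylor-directed) are pooled and deduplicated. The confidence of edge
u -> v is `|s_uv|` — the method's own effect-size measure, defined for
every ordered pair; repeated discovery keeps the maximum. When two
regulators orient the same pair in opposite directions, the higher-
confidence direction is kept and the conflict logged. For ROC evaluation
the remaining ordered pairs are appended with confidence 0 (ordered by
`|s_uv|`, then lexicographically, for byte-deterministic output). The whole
pipeline is a deterministic function of (panel, configuration).

Note that the *number* of emitted edges is not guaranteed monotone in θ0:
shrinking candidate sets can repartition layers and change which mediated
and oriented edges appear. Monotonicity does hold for the candidate sets
themselves.

## Evaluation

Confusion counts are over all n(n−1) ordered non-self pairs and are
direction-sensitive. TPR, FPR, PPV, ACC and MCC follow the standard
formulas; a zero denominator yields 0 with a warning and a flag in the
report rather than NaN. ROC curves sweep the full ranking with tied scores
collapsed into single steps, and the trapezoidal AUC therefore equals the
tie-corrected Mann–Whitney statistic (asserted against
`scipy.stats.mannwhitneyu` in the tests). The curve construction stands on
`sklearn.metrics.roc_curve`.

## Synthetic benchmark generator

The generator emulates the structure of the in-silico knockout challenges:
a sparse random directed network (acyclic by default, drawn uniformly over
the pairs consistent with a random topological order; optionally cyclic),
and steady states from a multiplicative regulation model

    x_j = basal_j · Π_{u→j, g>0} (1 + g_uj h_u(x_u))
                  / Π_{u→j, g<0} (1 + |g_uj| h_u(x_u)),
    h_u(x) = x² / (K_u² + x²),  K_u = basal_u / 3.

Defaults: 10 genes, 10 edges, gain magnitudes uniform in [0.5, 2] with
random sign, basal levels uniform in [1, 10] arbitrary units, noise-free
measurements. Acyclic systems are solved exactly in topological order;
cyclic ones by damped fixed-point iteration (error on non-convergence). A
knockout clamps one gene to zero and re-solves; optional measurement noise
is multiplicative lognormal (larger absolute noise at higher expression).

Design rationale:

- **Multiplicative regulation** gives order-one *relative* knockout
  effects (direct targets move by tens of percent to several-fold), the
  regime real knockout compendia and the DREAM generators produce, and the
  regime the sigmoid weighting (midpoint u = 0.5) presupposes. An additive
  model with the same gain and basal ranges yields effects of a few percent
  of expression level and every gene would be damped as a weak responder.
- **Near-saturated regulators** (`K = basal/3`, so h ≈ 0.9 at wild type)
  place the operating point in the flat part of the response — exactly the
  stationarity regime the direction test assumes — while a knockout moves
  the regulator to the quadratic rise of the Hill curve, giving the
  curvature term real work to do.
- **Knockout = clamp to zero**, and noise multiplies every measured value.

What the generator does *not* emulate: transcription/translation dynamics,
biological + experimental noise mixtures, autoregulation, and replicated
measurements. Passing the synthetic benchmark therefore shows the pipeline
recovers sparse networks whose knockout responses are strong, complete and
noise-free; it does not by itself establish performance on noisy or
unfaithful data.

## Known limitations

- The two-layer hierarchy cannot represent depth-3 chains exactly: a
  grandchild reached through two intermediates is either attached to the
  wrong mediator or kept direct (the dominant error mode on the synthetic
  benchmark, and the reason the method's false-positive rate grows on
  larger networks).
- Gaussian CMI over ~n observations detects mediation only when the
  mediator-target relation is close to linear over its observed support;
  strongly saturating relations can hide a true mediation or mimic one.
- With one experiment per gene there is no replication; all information
  criteria are heuristics over a single design matrix.
- Weak edges whose maximal relative response falls well below the sigmoid
  midpoint are deliberately damped and may be missed at the default θ0; the
  threshold sweep helper (`ddtg.pipeline.theta0_sweep`) exposes the
  operating curve.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run 20 ten-gene/ten-edge
noise-free panels (seeds 1-20 in the suite; seeds derived from `--seed` in
the script), 200 direction-test triples at m = 50 observations with noise
σ ≤ 0.1, and 1000 random rankings for the AUC oracle comparison — sizes at
which every stage's behaviour is exercised while the whole suite runs in
seconds.
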