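# Methods

## Model

The predictor treats association strength as a damped count of weighted
walks in the heterogeneous graph whose nodes are the `nl` lncRNAs and `nd`
diseases and whose symmetric adjacency is `A* = [[LS, A], [Aᵀ, DS]]`. A
length-`l` walk contributes its edge-weight product times `β^l`, so the
score matrix is the lncRNA x disease block of `Σ_{l=1..k} β^l (A*)^l`,
or of `(I − βA*)⁻¹ − I` when the series converges (`β·ρ(A*) < 1`). The
score of a pair therefore grows with the number, shortness and weight of
similarity-mediated paths connecting the two nodes; because every edge
weight is nonnegative, scores are monotone in β, in the truncation order
and under edge addition. Length-1 walks reproduce known associations;
ranking of *candidate* pairs is driven by length ≥ 2 walks through the
similarity layers, which is what lets the model score diseases or lncRNAs
with no known partner.

Assumptions: similarities are meaningful as nonnegative walk capacities on
a common [0, 1] scale; associations are undirected evidence; no
normalization of `A*` is applied before exponentiation.

## Similarity layers

**Disease semantic similarity (SS).** Each annotated disease maps to an
ontology term; its DAG is the ancestor closure of that term. A term's
contribution is its information content in the corpus of the loaded
annotated diseases, `D_A(t) = −log(count(t)/N)` (natural log; the base
cancels in the similarity ratio). The similarity of two diseases is the
contribution mass of shared terms over the sum of their semantic values.
Degenerate diseases whose every term occurs in all DAGs (semantic value 0)
get identity-pattern similarity with a logged warning. Two diseases mapped
to the same term are maximally similar. Counting over the loaded corpus —
not a universal ontology — makes the statistic self-contained and mirrors
how such corpora are assembled in practice.

**Expression similarity (ES).** Spearman midrank correlation of lincRNA
profiles across tissues. Pairs where either lncRNA lacks a profile score 0
and are flagged `we = 0`; constant profiles score 0 with a warning.
Negative correlations are clamped to 0 by default (`absolute` and `keep`
are available): the walk interpretation requires nonnegative capacities,
and an anticorrelated profile is weak, not negative, evidence of shared
function.

**Functional similarity (FS).** A precomputed labeled table consumed as
ground input: restricted to the network's lncRNAs, coverage tracked in
`wf`, asymmetries beyond 1e−8 averaged and out-of-range entries clamped,
both logged; no other transformation.

**Gaussian interaction-profile kernels (KD, KL).**
`exp(−γ‖IP(a)−IP(b)‖²)` on the binary rows/columns of `A`, with
`γ = γ′ / mean ‖IP‖²` and `γ′ = 1` on both sides; for binary profiles the
denominator is the mean association count per entity, so the bandwidth
adapts to network density. An entity with no associations (common after
cross-validation masking) carries no topological signal; its kernel
row/column is set to the identity pattern so that integration falls back
to the remaining sources — this is what preserves applicability to new
diseases and lncRNAs. The raw-formula behaviour is available via
`isolated="kernel"`.

**Integration.** Equal-weight means over the sources available per pair:
`DS = (SS + KD)/2` on annotated x annotated pairs, else `KD`;
`LS = (we·ES + wf·FS + KL)/(we + wf + 1)`. The weights are exposed
(`semantic_weight`, `lncrna_weights`) for sensitivity analysis but equal
weighting is the default and the tested configuration.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `beta` | 0.01 | walk damping; must satisfy `β·ρ(A*) < 1` for the closed form |
| `order` | `closed_form` | series evaluation; integer `k` truncates at walk length `k` |
| `fallback_order` | 4 | truncation used when the spectral condition fails |
| `gamma_prime` (both sides) | 1.0 | raw kernel bandwidth before density normalization |
| `negative_policy` | `clamp` | treatment of negative expression correlations |
| `kernel_policy` | `recompute` | kernels rebuilt from each (masked) network; `freeze` reuses kernels from the full network |

β = 0.01 keeps the closed form well inside its convergence region for
networks of the sizes used here while preserving the short-walk-dominated
ranking; the ranking is insensitive to β over a wide range because, at the
scores of candidate pairs, the leading term is the length-2 walk count.

## Evaluation protocols

Global LOOCV masks one known pair at a time and ranks it (midrank ties)
against all pairs without known evidence; local LOOCV restricts the
candidates to the test pair's disease; repeated k-fold CV masks one fold
of the known pairs at a time and reports per-repetition AUC mean ± sd.
Scoring functions receive only the masked network, and the kernels are
recomputed from it by default, so held-out associations cannot leak into
the model (`kernel_policy="freeze"` reproduces the leakier protocol some
studies use, for comparison).

ROC construction places each held-out pair at the fraction `u = (rank−1)/m`
of its `m` candidates ranked above it; sweeping the threshold over `u`
gives FPR = u, TPR = cumulative fraction of test pairs, and the
trapezoidal area equals `1 − mean(u)`, the normalized Mann–Whitney
statistic. "Rank above a threshold" means numerically smaller rank.
Midranks make a constant predictor score exactly 0.5. For global LOOCV an
alternative pooling on the raw score scale across folds is the default in
the CLI-facing `global_loocv` (`pooling="score"`); rank pooling is a flag,
and the two coincide whenever fold score scales are comparable.

## Synthetic study conditions

The fixture generators emulate the four inputs with a planted module
structure: lncRNAs and diseases are split round-robin into `n_blocks`
paired modules; associations appear with probability ∝ `signal_strength`
inside paired modules and ∝ `1 − signal_strength` outside, normalized so
the expected density equals `density` at every signal strength (0.5 =
uniform, 1.0 = block diagonal, ≥ 1 association per module pair). The
ontology gives each module a subtree under a shared root (so same-module
diseases share a positive-information ancestor), expression profiles are
module latent patterns plus Gaussian noise (sd 0.5, 22 tissues, 80 % of
lncRNAs profiled), and the functional table centers within-module pairs on
0.75 and cross-module pairs on 0.25 (noise sd 0.15, 70 % coverage, 80 % of
diseases annotated). Each generator draws from its own fixed sub-stream of
the `FixtureSpec` seed, so outputs are bit-reproducible and adding a
generator never perturbs the others.

The default condition (60 lncRNAs x 40 diseases, density 0.05, 4 modules,
depth-4 DAG) keeps the mean associations per disease near the sparsity of
real curated sets while letting the full LOOCV/k-fold suites run in
seconds on one CPU; the acceptance script averages 10 seeds x 2
repetitions per signal strength at these sizes.

What passing on these fixtures shows: the pipeline recovers planted
structure that is jointly expressed in the similarity layers and the
association pattern, monotonically in the planted strength. What it does
not show: performance on real curated associations, whose degree
distributions are heavy-tailed, whose similarity layers are biased toward
well-studied entities, and whose annotations are incomplete in non-random
ways. Real-data AUCs can differ substantially in either direction.

## Numerical choices and degenerate inputs

- Spectral radius via symmetric eigendecomposition; closed form solved as
  a linear system, never an explicit inverse.
- Similarity matrices validated symmetric to 1e−10; kernels to unit
  diagonal exactly.
- Ties broken by midrank everywhere (candidate ranking, ROC).
- Empty association table, all-zero adjacency (kernel bandwidth), empty
  test sets and cyclic ontologies raise typed errors rather than produce
  NaNs; an all-zero *masked* network inside the pipeline falls back to
  identity kernels so cross-validation never skips a fold silently.
- Identifiers are whitespace-trimmed, case-sensitive by default
  (case-insensitive matching is a flag), and sorted so matrix layouts are
  independent of input row order.

## Known limitations

- The information-content contribution and the equal integration weights
  are one defensible member of a family; coefficient learning is out of
  scope.
- Kernel similarity is computed from the same network being evaluated;
  even with per-fold recomputation it biases toward high-degree entities.
- The expression layer covers only lincRNAs with profiles; unprofiled
  lncRNAs rely on FS and the kernel alone.
- Comparison methods (least-squares, random-walk-with-restart variants)
  are not reimplemented; the packaged published rank table is the only
  cross-method reference shipped.
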