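# Methods

## The event-based mixture model

`stagepath` models cross-sectional binary mutation data with a mixture of
event-based models.  Each subtype c is an ordering S_c (a permutation of
the N event names) with mixing fraction f_c.  A subject of subtype c at
latent stage k ∈ {0, …, N} has accumulated exactly the first k events of
S_c — mutations are irreversible, so progression is monotone by
construction.  Observation noise is symmetric Bernoulli: a spurious call
appears with probability α when the event has not occurred, and a true
event is missed with probability β.  The stage prior is uniform over
0..N, including the zero-event stage; event stages are reported 1-based
(stage of an event = its position in the ordering), with subject stage 0
meaning "no events yet".

Assumptions worth stating explicitly: every tumor follows exactly one
ordering (no subclonal mixtures); stages are exchangeable across
subjects (no age or exposure structure); noise rates are shared by all
events.  None of these are tested by the model — they define it.

### Noise handling

α and β are fixed hyper-parameters (default 0.05/0.05), not estimated.
No estimation procedure is defined for them here; fixing them keeps the
model identifiable at the default scale (N = 17 events, ~400 subjects),
and both are exposed in `NoiseModel` / `PipelineConfig`.  The rates must
lie in [0, 0.5); zero is allowed and handled exactly (the likelihood
code computes suffix sums directly so −∞ log-terms never produce NaNs).

### Fitting

`fit_model` is stochastic ascent: Metropolis MCMC whose proposal swaps
two positions (uniformly random transposition; an adjacent-swap kernel
is available via `proposal="adjacent"`) in a uniformly chosen subtype's
ordering.  Both kernels are symmetric and irreducible over the
permutation group, so the Metropolis ratio is just the likelihood ratio.
Mixture fractions are not sampled: every sweep (N iterations) they are
refreshed to the mean posterior responsibilities, an EM-style move that
reduces variance at this problem scale; fractions are floored at 1e-4 to
avoid irrecoverable component collapse.  The returned model is the
maximum-likelihood state visited across all restarts (best-state
tracking starts at iteration 0; burn-in only scopes the acceptance-rate
diagnostic).  Initialisation is greedy: samples are k-means-clustered
(k = C, seeded) and each cluster's events are ordered by descending
within-cluster mutation frequency — more frequent events are earlier
under any of these models — with later restarts perturbed by random
transpositions.  Defaults are 100,000 iterations with 10,000 burn-in;
the recovery experiments in the test suite use 20,000 iterations, which
suffices at n = 400, N = 17, α = β = 0.05 (planted orderings are
typically recovered with Kendall tau 1.0).

Subtype labels are canonicalised by descending fraction (ties by first
event name) so seeded runs are stable; MAP assignment ties break toward
the lower subtype index and earlier stage.

### Choosing the number of subtypes

`select_subtype_count` runs k-fold cross-validation (default 5 folds)
over C = 1..C_max, scoring each C by the mean per-sample held-out
log-likelihood.  Candidates within one standard error of the best mean
are near-ties resolved toward the smaller C — the conservative reading
of "maximum likelihood and model stability".  CV fits use a reduced
MCMC budget (default 2,000 iterations, one start); the selection signal
at this scale is large compared with what longer chains add.

## The synthetic cohort generator

`GroundTruth` defaults encode the study conditions: 17 events (six
genes + eleven families), two subtypes with fractions 0.65/0.35, frozen
orderings whose position sequences agree only weakly (Kendall tau
0.1765, matching the reported divergence between the accelerated and
gradual paths; TP53 sits at stage 3 in one and stage 8 in the other, and
the longest common subsequence of the two defaults has 7 events),
α = β = 0.05, and a uniform stage law over 0..17.  Expression plants ten
stage-linear genes per subtype (slope ±1, residual SD 9.0, giving
|ρ| ≈ 0.5 against uniform stages) on a standard-normal null background;
planted genes follow their law only in their own subtype.  Survival is
exponential with the accelerated subtype's hazard multiplied by 1.5 and
independent uniform censoring calibrated by bisection to a 30% censored
fraction; nodal pN categories are drawn per subtype from the printed
cohort proportions (so the N3 dichotomy reproduces at scale).  The
noise rates are a modeling choice, not a reported value — no mutation
call error rates are published for the design being emulated.

What the generator does *not* emulate: copy-number events, subclonal
fractions, hypermutators, covariance among null genes, realistic RNA-seq
library effects (expression is generated already "normalized"), or
informative censoring.  Passing tests therefore demonstrate that the
algorithms recover what they assume, not that real cohorts satisfy those
assumptions.

## Downstream statistics

**Stage-gene screen** — per-gene Spearman ρ against the MAP stage within
one subtype (posterior-mean stage available via `stage=`), two-sided p
from the t approximation, BH adjustment within each subtype's screen,
selection at |ρ| > 0.35 and q < 0.05.  The absolute-value criterion is
deliberate: reported stage-associated genes include negative
correlations.  Constant genes are flagged and excluded from testing.

**ssGSEA** — integral convention: rank genes by descending expression
(average ranks for ties), in-set steps weighted by rank^α (α = 0.25)
normalised by total in-set weight, out-of-set steps 1/(G−|set|); the
score is the sum of the running sum over all positions.  No cross-sample
rescaling.  The convention and parameters travel with every
`ScoreMatrix` in a sidecar JSON.

**AUCell-style score** — area under the set-recovery curve within the
top ⌈0.05·G⌉ ranks, normalised by the best achievable area for the set
size, hence in [0, 1] with 1 meaning "entire set at the very top".

**Suppes-style progression tree** — a validation oracle, not a
reimplementation of any published progression-inference package:
candidate edge a→b requires temporal priority (P(a) > P(b)) and
probability raising (P(b|a) > P(b|¬a)); edges carry pointwise mutual
information weights and Edmonds' algorithm extracts the maximum-weight
arborescence from a synthetic root attached to all events.  Ties are
made deterministic by a name-keyed 1e-9 weight offset.  The concordance
rate of a linear sequence against a tree counts ancestor pairs whose
order matches; the default "all-pairs" mode divides by all C(N,2) pairs
(tree-incomparable pairs count as mismatches, the literal reading of
"total gene pairs"), and "comparable-only" divides by ancestor-related
pairs — both are provided because the published definition is ambiguous.

**Rank correlations between orderings** — computed from the closed
permutation forms (inversion count for tau, squared position differences
for rho), which are exact at the ±1 endpoints.

**Survival** — Kaplan–Meier, log-rank and Cox fits are delegated to
lifelines; Efron tie handling (the common software default; no tie
method is stated for the original analysis).  The 2×2 continuity-
corrected chi-square is the closed Yates formula, which reproduces the
printed N3 contingency p = 0.0168; Fisher's exact test replaces it when
any expected cell is below 5.

**Drug transfer** — per-drug ridge regression on a reference panel with
genes standardised on the panel and the penalty chosen by 10-fold CV on
a 13-point log grid 1e-3..1e3 (only "ridge regression with 10-fold CV"
is specified; the grid is this package's choice).  Cohort expression is
z-scored per gene *within the cohort* before applying coefficients —
the per-gene reading of "batch-corrected using standardization", which
makes predictions invariant to gene-wise affine rescaling — and genes
missing from the cohort contribute zero in z-space (mean imputation).
The real pharmacogenomic panel is replaced by a generated
`ReferencePanel` (ln(IC50) linear in a sparse latent signature, default
4:1 signal-to-noise variance ratio) so the module is testable offline;
the predictor API accepts any panel with the same shape.  Per-subtype
stage trends use Spearman ρ with Fisher's z for the between-subtype
difference (correlations clipped at 1−1e-12 so degenerate |ρ| = 1
inputs stay finite).

## Numerical and design notes

- All randomness flows through `numpy.random.default_rng(seed)`; seeded
  runs are byte-reproducible end to end (manifests differ only in their
  timestamp).
- Frequency thresholding uses strict ">" (a gene at exactly the
  threshold is dropped), matching the stated selection rule.
- The gene→family membership table ships as an editable default (family
  names are fixed by the design; full curated membership lists are not
  reproduced here), as a two-column TSV or `FamilyMap`.
- The survival generator applies the hazard multiplier to subtype 0
  (the accelerated, larger-fraction subtype) so that "accelerated path
  has worse survival" holds under the package's 0-based labels.
- In synthetic pipeline runs the frequency-selection step is skipped:
  the generator already encodes the curated 17-event design, and a 150-
  count threshold is a property of the full-cohort call table, not of a
  400-subject simulation.
- Problem sizes in the test suite (20,000-iteration fits, 50-seed
  screening and survival replicates, 10-seed selection experiments,
  exhaustive LCS checks to N = 6) were chosen as the smallest scales at
  which the planted-recovery properties are stable.

## Known limitations

- Only the maximum-likelihood state plus acceptance diagnostics are
  returned; no posterior uncertainty bands over orderings.
- The continuous-marker (z-score) event-based model variant is out of
  scope; inputs must be binary.
- Whether the original "cumulative frequency" input was per-sample
  binary or pooled counts is ambiguous; per-sample binary is assumed, as
  only it supports staging individual tumors.
- Real-data preprocessing (variant pipelines, expression normalisation,
  scRNA-seq QC) is out of scope; the readers accept any conforming
  minimal-MAF/TSV/GMT input.
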