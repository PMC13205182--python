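# stagepath

Event-based subtype and stage inference for tumor somatic-mutation
cohorts, with downstream trajectory analysis: stage-correlated gene
expression, single-sample signature scoring, survival comparison and
ridge-transferred drug-sensitivity prediction.

## The problem

Cross-sectional molecular classifications of gastric cancer ignore *when*
mutations happen.  Given only one binary mutation profile per tumor,
`stagepath` infers a small number of **subtypes**, each defined by its own
temporal **ordering** of irreversible mutation events, and places every
tumor at a latent **stage** along its subtype's ordering.  The default
event set is the 17-event gastric design: six frequently mutated genes
(*TTN, MUC16, TP53, LRP1B, OBSCN, ARID1A*) plus eleven aggregated gene
families (*SYNE, FAT, CSMD, CDH, PCDH, DNAH, NOTCH, ERBB, FGF, KMT, BMP*).

## The model

A subtype *c* is a permutation S_c of the N events with mixing fraction
f_c.  A subject at stage k has accumulated exactly the first k events of
its subtype's ordering; observed calls are noisy indicators with
false-positive rate α and false-negative rate β.  With a uniform stage
prior, the likelihood of a binary profile x is

    P(x) = Σ_c f_c · 1/(N+1) Σ_{k=0}^{N} Π_{i≤k} Bern(x_{S_c(i)}; 1−β) · Π_{i>k} Bern(x_{S_c(i)}; α)

Fitting maximises this mixture likelihood by Metropolis MCMC over
orderings (random transpositions within one subtype at a time) with
EM-style fraction updates; the number of subtypes is chosen by
cross-validated held-out likelihood with a one-standard-error rule.
Downstream stages consume the per-sample MAP subtype and stage:
Spearman screens with BH-FDR control (|ρ| > 0.35, FDR < 0.05), ssGSEA /
AUCell gene-set scores, Kaplan–Meier / log-rank / Cox survival
comparisons, Suppes-style progression-tree concordance, and per-drug
ridge models transferring ln(IC50) from a reference expression panel.

## Worked example

```python
import stagepath as sp

truth = sp.GroundTruth()                       # planted two-subtype design
cohort = sp.generate_mutations(truth, n=400, seed=7)
model = sp.fit_model(cohort.mutations, C=2, noise=sp.NoiseModel(0.05, 0.05),
                     iters=20_000, burn_in=2_000, n_starts=2, seed=7)
for c, o in enumerate(model.orderings):
    print(c, model.fractions[c].round(3), "TP53 at stage", o.stage_of("TP53"))
```

prints

```
0 0.645 TP53 at stage 3
1 0.355 TP53 at stage 8
```

i.e. the fitted mixture recovers the planted design: about 65% of tumors
follow an "accelerated" ordering that places *TP53* at stage 3, the rest
a "gradual" ordering deferring it to stage 8.  Comparing the two fitted
sequences (`sp.rank_correlations`, `sp.lcs`) gives Kendall tau 0.176,
Spearman rho 0.211 and a 7-event longest common subsequence — the two
paths share little temporal logic.  The scripts in `examples/` walk
through each capability (simulation, fitting, sequence/tree comparison,
stage-gene screening and scoring, survival, drug transfer) and print a
short interpretation of every number.

A thin CLI chains everything into a run directory:

```bash
stagepath --seed 7 --out run7 all
```

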