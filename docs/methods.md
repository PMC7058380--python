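# Methods

## The model

`tcrmotif` classifies a TCRβ CDR3 repertoire as cancer-associated (label 1)
or healthy (label 0) from short physicochemical motifs.

**Motif extraction.** The first and last three residues of each CDR3 are
trimmed (they rarely contact peptide in TCR–pMHC structures); the remaining
interior of length m is cut into every contiguous window of k residues
(k = 3 or 4), and, when up to g gaps are allowed, into every in-order
subsequence of a (k+g')-residue window (1 ≤ g' ≤ g) obtained by skipping
exactly g' interior residues of the window — never the window's first or
last residue, so gaps are internal. For k = 3, g = 1 this yields
max(0, m−2) + 2·max(0, m−3) occurrences. Coordinates are 0-based,
half-open throughout. A gap is recorded as the 1-based motif position the
skipped residue would have occupied; `restrict_gap_to_position` filters
gapped occurrences on that position (contiguous occurrences always pass).

**Counting.** A motif's count C^motif sums the template counts C^CDR3 of
every unique sequence containing it; containment is boolean per sequence (a
CDR3 yielding the same motif at several positions contributes its count
once). T = Σ C^motif over the sample, and the relative abundance is
f_q = C^motif / T, so Σ f_q = 1 per sample. For the default configuration a
triplet reachable both contiguously and via a gap is a single motif key
(the features could not distinguish them); `key_includes_gap` /
`gap_onehot` switch to gap-resolved keys. Only the 65,536 most abundant
motifs per sample are kept (ties broken lexicographically); the cap is a
runtime bound, so abundances are *not* renormalized after truncation.

**Features.** Each residue maps to its five Atchley factors (polarity,
secondary structure, molecular volume, codon diversity, electrostatic
charge; shipped as `data/atchley_factors.tsv` so the values are auditable),
giving f1..f15 for a triplet, followed by f_q (or ln f_q) as the 16th
feature, then optional gap one-hot indicators and optional squared copies
of everything (second-order terms). Features are standardized with
f_q-weighted means and variances so abundant motifs dominate the
statistics; the abundance feature is standardized like any other.
Statistics are fitted on the pooled motifs of the *training* samples only
(each motif weighted by its within-sample f_q, so each sample contributes
total weight ≈ 1) and frozen for held-out and test samples — computing them
per-sample instead would leak nothing but is not the default because the
train/refit/score workflow freezes one preprocessing state. Variances are
floored at 1e-8 so constant features (e.g. a one-hot column that never
fires) do not divide by zero.

**Scoring and aggregation.** Motif i receives a logit
l_i = β0 + Σ_j β_j f_j and probability P_i = σ(l_i). The repertoire score
is P_tumor = max_i P_i — the standard multiple-instance-learning
assumption: a repertoire is tumor-derived iff at least one motif is. The
decision threshold is 0.5, with ties called positive. The objective is the
mean negative log-likelihood over repertoires (Eq. in nats; printed values
can be converted with `nats_to_bits`), with probabilities clipped to
[1e-12, 1−1e-12] inside the log only.

## Fitting

The max makes the loss surface piecewise and multimodal, so fitting runs
full-batch Adam (step size 0.01, 2,500 steps, b1 = 0.9, b2 = 0.999,
ε = 1e-8) from many random initializations and keeps the restart with the
lowest final training loss. β0 starts at 0; the 15 Atchley weights are
drawn as (1/2)·N(0, 1/15) and the abundance (and any extension) weights as
(1/2)·N(0, 1), so both blocks contribute the same expected squared
magnitude (0.25). The printed form of this scheme is typographically
ambiguous; the variance-1/15 reading is the default because it alone
yields the equal-magnitude property, and `init_variance_squared` exposes
the N(0, (1/15)²) alternative. For 4-residue motifs the Atchley variance
generalizes to 1/20 to preserve the property. One master seed spawns an
independent stream per restart, so any restart is individually
reproducible regardless of batching.

Numerical choices: the max is non-smooth, so each step only the argmax
motif of each repertoire receives gradient (straight-through subgradient),
with ties broken by lowest motif index; gradients use the unclipped
sigmoid. Restarts are advanced together in a restart-major float32 batch
(samples padded to a rectangle with sentinel logits that can never win the
max); per-restart losses are accumulated in float64 — in float32 the upper
clip bound 1−1e-12 is not representable and converged restarts would
spuriously report infinite loss. The reference single-parameter-set path
(`loss_and_grad`) is float64 and is what the finite-difference gradient
check exercises. No L1/L2 penalty or dropout is used anywhere.

The desk-scale default is 256 restarts; 131,072 (2^17) mirrors the
original protocol and only affects how close the best fit is to the global
optimum. `loss_by_step[i]` is the training loss after i updates (index 0 =
initial parameters), so early stopping on a monotone 2,500-step curve
selects index 2,499.

## Evaluation protocol

*Cross-validation*: exhaustive leave-one-sample-out. The normalizer is
refitted on each fold's n−1 training samples; one shared set of initial
weight draws is reused across folds so the only variation is the held-out
patient. The held-out score is recorded at every step; early stopping
selects the step minimizing the mean held-out loss (earliest on ties), and
reported accuracies/losses are taken at that step.

*Permutation null*: labels are permuted uniformly (class counts preserved
automatically; the identity permutation is a legal draw), CV with early
stopping is rerun per permutation, and the p-value for an observed
accuracy is the add-one estimator (1 + #{runs ≥ observed})/(1 + n_perm).
Permutation runs reuse the same initial draws as the unpermuted CV.

*Model grid*: each configuration is cross-validated and ranked by mean
held-out loss; configurations requesting the expected-frequency-in-blood
feature or batch normalization are skipped with a notice (neither is
implemented: the former needs an external 786-subject blood cohort, the
latter is a model variant outside this package's scope).

*Testing*: the selected configuration is refitted on all training samples,
reusing the CV's initial draws and running exactly the early-stopping step
count; test samples are standardized with the frozen training statistics
and scored once. Sensitivity = TP/(TP+FN) over tumor labels, specificity =
TN/(TN+FP) over healthy labels; the ROC sweeps the threshold over
repertoire scores and AUC is the trapezoid-rule area (scikit-learn).

## Synthetic data

The generator emulates survey-depth TCRβ sequencing of tissue samples:
per-sample unique CDR3s (default 25 per sample, lengths 11–16, uniform
residue composition with conserved-looking "CASS"…"QYF" ends) with
geometric template counts (mean 2 — in the real data most motif-bearing
clones were seen once). Positive samples additionally carry 3 planted
CDR3s whose interior contains a triplet from {KWH, RWH, KYH, RYH} — the
{K,R}×{W,Y}×{H} product of the residue preferences reported for the real
HGSOC motif, restricted to physicochemically interchangeable pairs so the
set forms one tight Atchley-space cluster (max pairwise distance 3.9
versus ≈7.4 for random triplet pairs) — with template counts multiplied by
10. Each positive sample draws *one* triplet shared by its planted
sequences, by analogy with clonal responses: a patient's expanded clones
respond to the same antigen. This makes ground truth unambiguous — the
exact triplet accumulates the counts of all planted clones in the sample,
whereas each overlapping gap-variant of a planted insert is private to one
clone. Backgrounds are rejection-resampled so no background sequence's
extracted motif set (gaps included) contains a planted triplet; the null
generator plants nothing anywhere, so labels are independent of content.

What the generator does *not* emulate: VDJ recombination statistics,
realistic clone-size power laws (only the geometric option), repertoire
sizes in the hundreds-to-thousands (deliberately scaled to tens so
fitting, cross-validation and permutation analysis run in seconds), or
batch effects between cohorts. Passing the synthetic benchmarks therefore
demonstrates correctness of the machinery and recoverability of a planted
MIL signal — not clinical performance on real repertoires, which depends
on signal strength, sequencing depth and cohort size.

Under these conditions (256 restarts, 500 steps for fitting and
cross-validation; permutation nulls use 64 restarts × 250 steps, since
their near-chance accuracy is insensitive to optimizer strength),
leave-one-out CV accuracy on strong-signal cohorts is ≥ 95% per seed, the
planted-triplet hit rate (fraction of positive samples whose top-scoring
motif is the exact planted triplet) is 1.0, null-cohort CV accuracy
averages near chance, and permutation nulls average ≈ 50% accuracy — all
recomputed by `scripts/acceptance.py` and the test suite.

## Degenerate inputs and edge cases

CDR3s shorter than 6 + motif_size residues yield no motifs; a sample whose
sequences are all too short produces an empty motif table with a warning
and is rejected before fitting. Empty repertoire files and missing
required columns raise typed errors; rows with non-canonical residues
(stop `*`, ambiguous `X`, `_`) are dropped and counted, since Atchley
factors exist only for the 20 canonical residues — whether the original
study excluded non-productive rearrangements is not stated, so exclusion
is the default and configurable at the I/O layer. Missing or zero template
counts default to 1 with a warning (presence information is preserved).
Restarts reaching a non-finite loss are excluded with a warning; an
all-divergent fit raises.

## Known limitations

The expected-frequency-in-blood feature and the batch-normalization
variant are deliberately not implemented. V/J gene context is ignored by
design (the model consumes only CDR3 residues and template counts).
Reproducing the published patient-data numbers requires the deposited
cohorts and the 131,072-restart protocol (hours of CPU); this package
runs that protocol unchanged via `OptimizerConfig(n_restarts=131072)` but
its shipped benchmarks are synthetic.
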