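# tcrmotif

Classify T cell receptor β (TCRβ) CDR3 repertoires as cancer-associated or
healthy from short biophysicochemical motifs, using multiple instance
learning (MIL).

Cancer patients mount T cell responses against shared tumor antigens, and
the responding receptors need not share an amino-acid sequence — only
overlapping binding chemistry. `tcrmotif` therefore represents every 3–4
residue motif of a trimmed CDR3 (optionally allowing an internal gap) by
the Atchley factors of its residues plus its template-weighted relative
abundance, scores each motif with a logistic model, and labels a
repertoire by its best motif:

    l_i = β₀ + β₁f₁ + … + β₁₅f₁₅ + β₁₆f_q        (motif logit)
    P_i = σ(l_i)                                  (motif probability)
    P_tumor = max{P₁, P₂, …}                      (repertoire score)

A repertoire is called tumor-derived when P_tumor ≥ 0.5 — the standard MIL
assumption that a positive bag contains at least one positive instance.
Parameters maximize the repertoire-label likelihood via Adam from many
random restarts (the max aggregation makes the surface multimodal), and
models are compared by exhaustive patient-hold-out cross-validation with
early stopping, a label-permutation null, and refit-then-score testing on
an unseen cohort. A synthetic-repertoire generator with planted motifs
provides ground truth for end-to-end testing without downloads.

The intended users are computational immunologists working with AIRR
Rearrangement or Adaptive immunoSEQ TSV exports of TCRβ repertoires.

## Worked example

```python
import tcrmotif as tm

spec = tm.SyntheticSpec(seed=0)                  # 10 tumor + 10 healthy samples
cohort, truth = tm.generate_cohort(spec)

config = tm.ModelConfig(motif_size=3, n_gap_positions=1)
opt = tm.OptimizerConfig(n_restarts=256, n_steps=500, seed=0)

cv = tm.leave_one_out_cv(cohort, config, opt)
print(f"CV accuracy: {cv.accuracy:.0%}  mean held-out loss: {cv.mean_loss:.3f} nats "
      f"({tm.nats_to_bits(cv.mean_loss):.3f} bits)  early stop: step {cv.early_stop_step}")

fc = tm.featurize_cohort(cohort, config)
fc.stats = tm.pooled_normalizer(fc.samples)
fit = tm.fit(fc.normalized(), fc.labels, opt)
report = tm.recovery_report(fit, fc, truth)
print(f"training loss: {fit.training_loss:.3f} nats  planted-motif hit rate: {report.hit_rate:.0%}")
print(report.motifs[report.motifs.planted].head(3)[["sample_id", "motif", "score", "cdr3", "count"]])
```

prints

```
CV accuracy: 95%  mean held-out loss: 0.130 nats (0.188 bits)  early stop: step 499
training loss: 0.059 nats  planted-motif hit rate: 100%
         sample_id motif     score             cdr3  count
2  synthetic_pos01   RYH  0.975453   CASSMGHARYHQYF     40
3  synthetic_pos01   RYH  0.975453   CASSPRYHMNWQYF     10
4  synthetic_pos01   RYH  0.975453  CASSRYHASRTEQYF     20
```

Leave-one-out cross-validation classifies 19 of the 20 synthetic samples
correctly; the held-out loss keeps falling through the last optimization
step, so early stopping selects it. Refitting on the whole cohort, the
top-scoring motif in every positive sample is the exact triplet planted
there (hit rate 100%), and each high-scoring motif is reported in the
context of the CDR3 clones carrying it with their template counts.

The same pipeline runs from the shell on real or simulated exports:

```sh
tcrmotif simulate --n-pos 10 --n-neg 10 --seed 0 --out sim/
tcrmotif cv --manifest sim/manifest.csv --restarts 256 --steps 500 --out cv_out/
tcrmotif permute --manifest sim/manifest.csv --n-perm 20 --out perm_out/
tcrmotif test --manifest train/manifest.csv --test-manifest test/manifest.csv --out test_out/
```

`extract`, `fit` and `grid` cover motif-table export, single fits and the
model-selection grid; every output embeds the exact run configuration.
Replicating the published patient-data protocol end to end is a matter of
pointing the manifests at the deposited cohort exports and raising
`--restarts` to 131072 (hours of CPU).

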