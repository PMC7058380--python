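"""Patient-hold-out cross-validation, early stopping, permutation null, model grid, testing.

The workflow mirrors the original protocol: exhaustive leave-one-sample-out
cross-validation on the training cohort with one shared set of random
initial weights across folds (so the only variation between folds is the
held-out patient), early stopping at the step minimizing the mean held-out
loss, a label-permutation null for the observed accuracy, a model-selection
grid ranked by cross-validated loss, and a final refit on all training
samples that is scored on an unseen test cohort with an ROC.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from .feature_encoding import apply_normalizer, encode_table, fit_normalizer, NormStats
from .mil_classifier import (
    FitResult,
    ModelParams,
    OptimizerConfig,
    classify,
    draw_initial_params,
    fit,
    negative_log_likelihood,
    predict_repertoires,
)
from .motif_engine import ModelConfig, build_motif_table, truncate_top_k
from .repertoire_io import Cohort

DEFAULT_TOP_K = 65536


@dataclass
class SampleFeatures:
    """One sample's motif keys, raw (unnormalized) features and f_q weights."""

    sample_id: str
    label: int
    keys: list
    raw: np.ndarray
    fq: np.ndarray


@dataclass
class FeaturizedCohort:
    """A cohort's per-sample motif features under one model configuration."""

    cohort: Cohort
    config: ModelConfig
    samples: list[SampleFeatures]
    stats: NormStats | None = None

    @property
    def labels(self) -> np.ndarray:
        return np.array([s.label for s in self.samples])

    def normalized(self) -> list[np.ndarray]:
        if self.stats is None:
            raise ValueError("no normalization stats attached")
        return [apply_normalizer(s.raw, self.stats) for s in self.samples]


def featurize_cohort(
    cohort: Cohort, config: ModelConfig, top_k: int = DEFAULT_TOP_K
) -> FeaturizedCohort:
    """Build per-sample motif tables (top-k capped) and raw feature matrices."""
    config.check_implemented()
    samples = []
    for rep in cohort:
        table = truncate_top_k(build_motif_table(rep, config), top_k)
        keys, raw, fq = encode_table(table, config)
        if raw.shape[0] == 0:
            raise ValueError(f"sample {rep.sample_id} yields no motifs under this config")
        samples.append(SampleFeatures(rep.sample_id, rep.label, keys, raw, fq))
    return FeaturizedCohort(cohort=cohort, config=config, samples=samples)


def pooled_normalizer(samples: list[SampleFeatures]) -> NormStats:
    """Fit weighted normalization on the pooled motifs of the given (training) samples.

    Each motif is weighted by its within-sample f_q, so every sample
    contributes total weight ~1 regardless of its repertoire size.
    """
    raw = np.vstack([s.raw for s in samples])
    w = np.concatenate([s.fq for s in samples])
    return fit_normalizer(raw, w)


@dataclass
class CVResult:
    """Leave-one-out cross-validation outcome at the early-stopping step."""

    per_sample: pd.DataFrame  # sample_id, label, probability, predicted, loss
    accuracy: float
    mean_loss: float
    loss_curve: np.ndarray  # mean held-out loss after each optimization step
    early_stop_step: int
    fold_prob_curves: np.ndarray  # (n_steps, n_samples) held-out score per step


@dataclass
class PermutationResult:
    """Label-permutation null for the cross-validated accuracy."""

    per_run: pd.DataFrame  # run, mean_loss, accuracy, early_stop_step, labels
    mean_loss: float
    mean_accuracy: float
    p_value: float | None = None


@dataclass
class GridResult:
    table: pd.DataFrame
    best_index: int
    skipped: list[str]

    @property
    def best_row(self) -> pd.Series:
        return self.table.loc[self.best_index]


@dataclass
class TestResult:
    """Unseen-cohort scoring of the refitted model."""

    per_sample: pd.DataFrame
    accuracy: float
    sensitivity: float
    specificity: float
    auc: float
    roc: pd.DataFrame  # threshold sweep: fpr, tpr, threshold
    early_stop_step: int
    train_fit: FitResult
    stats: NormStats
    params: ModelParams


def select_early_stopping(loss_curve) -> int:
    """0-based step index minimizing the mean held-out loss; earliest on ties."""
    curve = np.asarray(loss_curve, dtype=float)
    if curve.size == 0:
        raise ValueError("empty loss curve")
    return int(curve.argmin())


def sensitivity_specificity(labels, predictions) -> tuple[float, float]:
    """Sensitivity = TP/(TP+FN) over tumor labels; specificity = TN/(TN+FP)."""
    y = np.asarray(labels)
    p = np.asarray(predictions)
    pos = y == 1
    neg = y == 0
    sens = float((p[pos] == 1).mean()) if pos.any() else float("nan")
    spec = float((p[neg] == 0).mean()) if neg.any() else float("nan")
    return sens, spec


def leave_one_out_cv(
    cohort: Cohort,
    config: ModelConfig,
    opt: OptimizerConfig,
    top_k: int = DEFAULT_TOP_K,
    labels_override=None,
    featurized: FeaturizedCohort | None = None,
    initial_weights: np.ndarray | None = None,
) -> CVResult:
    """Exhaustive patient-hold-out cross-validation.

    For each sample: the normalizer is refitted on the other n-1 samples, the
    model is fitted on them (same shared initial weight draws in every fold),
    and the held-out sample's score is recorded at every optimization step.
    Early stopping picks the step minimizing the mean held-out loss, and the
    reported per-sample probabilities/accuracy are taken at that step.

    ``labels_override`` substitutes a permuted label vector (same multiset);
    ``featurized``/``initial_weights`` let callers reuse precomputed motif
    features and initial draws.
    """
    fc = featurized if featurized is not None else featurize_cohort(cohort, config, top_k)
    labels = fc.labels if labels_override is None else np.asarray(labels_override)
    if len(set(labels.tolist())) < 2:
        raise ValueError("cross-validation requires both classes in the cohort")
    n = len(fc.samples)
    d = fc.samples[0].raw.shape[1]
    n_atchley = 5 * config.motif_size
    if initial_weights is None:
        initial_weights = draw_initial_params(opt, d, n_atchley=n_atchley)

    prob_curves = np.empty((opt.n_steps, n))
    for j in range(n):
        train = [s for i, s in enumerate(fc.samples) if i != j]
        stats = pooled_normalizer(train)
        Xtr = [apply_normalizer(s.raw, stats) for s in train]
        ytr = np.delete(labels, j)
        Xte = [apply_normalizer(fc.samples[j].raw, stats)]
        fr = fit(
            Xtr,
            ytr,
            opt,
            initial_weights=initial_weights,
            eval_features=Xte,
            eval_labels=np.array([labels[j]]),
            n_atchley=n_atchley,
        )
        prob_curves[:, j] = fr.eval_probs_by_step[:, 0]

    y = labels.astype(float)
    p_clip = np.clip(prob_curves, 1e-12, 1 - 1e-12)
    loss_curves = -(y * np.log(p_clip) + (1 - y) * np.log(1 - p_clip))  # (steps, n)
    mean_curve = loss_curves.mean(axis=1)
    step = select_early_stopping(mean_curve)

    probs = prob_curves[step]
    preds = np.array([classify(p) for p in probs])
    per_sample = pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in fc.samples],
            "label": labels,
            "probability": probs,
            "predicted": preds,
            "loss": loss_curves[step],
        }
    )
    return CVResult(
        per_sample=per_sample,
        accuracy=float((preds == labels).mean()),
        mean_loss=float(mean_curve[step]),
        loss_curve=mean_curve,
        early_stop_step=step,
        fold_prob_curves=prob_curves,
    )


def permutation_test(
    cohort: Cohort,
    config: ModelConfig,
    opt: OptimizerConfig,
    n_perm: int = 20,
    seed: int = 0,
    top_k: int = DEFAULT_TOP_K,
    observed_accuracy: float | None = None,
) -> PermutationResult:
    """Label-permutation null: permute labels, rerun hold-out CV with early stopping.

    Permutations are drawn uniformly over label-vector permutations (the
    class counts are preserved automatically); the identity permutation is a
    legal draw.  The empirical p-value for an observed accuracy uses the
    add-one estimator (1 + #{runs >= observed}) / (1 + n_perm).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    fc = featurize_cohort(cohort, config, top_k)
    labels = fc.labels
    d = fc.samples[0].raw.shape[1]
    W0 = draw_initial_params(opt, d, n_atchley=5 * config.motif_size)
    rng = np.random.default_rng(seed)
    rows = []
    for run in range(n_perm):
        permuted = labels[rng.permutation(len(labels))]
        cv = leave_one_out_cv(
            cohort, config, opt, top_k,
            labels_override=permuted, featurized=fc, initial_weights=W0,
        )
        rows.append(
            {
                "run": run + 1,
                "mean_loss": cv.mean_loss,
                "accuracy": cv.accuracy,
                "early_stop_step": cv.early_stop_step,
                "labels": "".join(map(str, permuted)),
            }
        )
    per_run = pd.DataFrame(rows)
    p_value = None
    if observed_accuracy is not None:
        p_value = float(
            (1 + (per_run["accuracy"] >= observed_accuracy).sum()) / (1 + n_perm)
        )
    return PermutationResult(
        per_run=per_run,
        mean_loss=float(per_run["mean_loss"].mean()),
        mean_accuracy=float(per_run["accuracy"].mean()),
        p_value=p_value,
    )


def run_model_grid(
    cohort: Cohort,
    configs: list[ModelConfig],
    opt: OptimizerConfig,
    top_k: int = DEFAULT_TOP_K,
) -> GridResult:
    """Cross-validate every configuration and rank by mean held-out loss.

    Configurations with unimplemented flags (expected-frequency-in-blood,
    batch normalization) are skipped with an explicit notice.
    """
    if not configs:
        raise ValueError("at least one configuration is required")
    rows = []
    skipped = []
    for config in configs:
        try:
            config.check_implemented()
        except NotImplementedError as exc:
            skipped.append(f"{config}: {exc}")
            continue
        cv = leave_one_out_cv(cohort, config, opt, top_k)
        rows.append(
            {
                "motif_size": config.motif_size,
                "n_gap_positions": config.n_gap_positions,
                "gap_onehot": config.gap_onehot,
                "restrict_gap_to_position": config.restrict_gap_to_position,
                "log_frequency": config.log_frequency,
                "second_order": config.second_order,
                "cv_loss": cv.mean_loss,
                "cv_accuracy": cv.accuracy,
                "early_stop_step": cv.early_stop_step,
                "n_restarts": opt.n_restarts,
            }
        )
    if not rows:
        raise ValueError("every configuration was skipped as unimplemented")
    table = pd.DataFrame(rows)
    best_index = int(table["cv_loss"].idxmin())
    return GridResult(table=table, best_index=best_index, skipped=skipped)


def refit_and_score_test(
    train: Cohort,
    test: Cohort,
    config: ModelConfig,
    opt: OptimizerConfig,
    top_k: int = DEFAULT_TOP_K,
    early_stop_step: int | None = None,
) -> TestResult:
    """Refit on the whole training cohort, then score the unseen test cohort.

    The early-stopping step chosen by cross-validation on the training cohort
    is reused as the refit's step count (run CV here if not supplied); the
    same initial weight draws are reused.  Test samples are normalized with
    the frozen training statistics.  The ROC sweeps the decision threshold
    over repertoire scores; AUC is the trapezoid-rule area.
    """
    overlap = set(train.sample_ids) & set(test.sample_ids)
    if overlap:
        raise ValueError(f"train/test cohorts share sample_ids: {sorted(overlap)}")
    fc_train = featurize_cohort(train, config, top_k)
    n_atchley = 5 * config.motif_size
    d = fc_train.samples[0].raw.shape[1]
    W0 = draw_initial_params(opt, d, n_atchley=n_atchley)
    if early_stop_step is None:
        cv = leave_one_out_cv(train, config, opt, top_k, featurized=fc_train, initial_weights=W0)
        early_stop_step = cv.early_stop_step

    stats = pooled_normalizer(fc_train.samples)
    Xtr = [apply_normalizer(s.raw, stats) for s in fc_train.samples]
    refit_opt = replace(opt, n_steps=max(int(early_stop_step), 1))
    fr = fit(Xtr, fc_train.labels, refit_opt, initial_weights=W0, n_atchley=n_atchley)

    fc_test = featurize_cohort(test, config, top_k)
    Xte = [apply_normalizer(s.raw, stats) for s in fc_test.samples]
    scores = predict_repertoires(Xte, fr.params)
    labels = fc_test.labels
    preds = np.array([classify(s) for s in scores])
    sens, spec = sensitivity_specificity(labels, preds)
    fpr, tpr, thresholds = _sk_roc_curve(labels, scores)
    per_sample = pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in fc_test.samples],
            "label": labels,
            "probability": scores,
            "predicted": preds,
            "loss": [negative_log_likelihood([p], [y]) for p, y in zip(scores, labels)],
        }
    )
    return TestResult(
        per_sample=per_sample,
        accuracy=float((preds == labels).mean()),
        sensitivity=sens,
        specificity=spec,
        auc=float(_sk_auc(fpr, tpr)),
        roc=pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thresholds}),
        early_stop_step=int(early_stop_step),
        train_fit=fr,
        stats=stats,
        params=fr.params,
    )
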