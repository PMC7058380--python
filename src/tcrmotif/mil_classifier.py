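"""Max-aggregated logistic model over motif features, fitted by multi-restart Adam.

Every motif i is scored P_i = sigmoid(beta0 + beta . f_i); a repertoire's
tumor probability is the maximum motif probability (the standard
multiple-instance-learning assumption: a bag is positive iff at least one
instance is).  The objective is the mean negative log-likelihood of the
repertoire labels.  Because the max makes the landscape multimodal, fitting
runs Adam from many random initializations and keeps the best final fit; all
restarts are advanced together as one batched computation.

The max is non-smooth: each step, only the argmax motif of each repertoire
receives gradient (straight-through subgradient; ties broken by lowest motif
index).  No L1/L2 penalty or dropout is applied anywhere.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

PROB_CLIP = 1e-12


@dataclass
class ModelParams:
    """Bias beta0 and weight vector beta1..betaD of the logistic motif scorer."""

    bias: float
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if not (np.isfinite(self.bias) and np.all(np.isfinite(self.weights))):
            raise ValueError("parameters must be finite")


@dataclass(frozen=True)
class OptimizerConfig:
    """Adam settings and the restart scheme.

    2,500 steps at step size 0.01 with Adam defaults mirror the original
    fitting protocol; 131,072 restarts were used there, 256 is the desk-scale
    default (the restart count only affects how close the best fit gets to
    the global optimum).  ``init_variance_squared`` switches the weight
    initialization to the alternative N(0, (1/n)^2) reading.
    """

    step_size: float = 0.01
    n_steps: int = 2500
    b1: float = 0.9
    b2: float = 0.999
    epsilon: float = 1e-8
    n_restarts: int = 256
    seed: int = 0
    init_variance_squared: bool = False
    restart_chunk: int = 4096

    def __post_init__(self) -> None:
        for name in ("step_size", "n_steps", "b1", "b2", "epsilon", "n_restarts", "restart_chunk"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class FitResult:
    """Best restart of a fit: parameters, final training loss (nats) and curves.

    ``loss_by_step[i]`` is the training loss with parameters after i Adam
    updates (index 0 = initial parameters); ``training_loss`` is the loss
    after all ``n_steps`` updates, which is what restarts are ranked by.
    When a held-out set was supplied, ``eval_probs_by_step[i, s]`` is held-out
    sample s's repertoire score after i updates.
    """

    params: ModelParams
    training_loss: float
    restart_index: int
    loss_by_step: np.ndarray
    eval_probs_by_step: np.ndarray | None = None
    eval_loss_by_step: np.ndarray | None = None
    n_failed_restarts: int = 0


def nats_to_bits(loss: float) -> float:
    """Convert a mean negative log-likelihood from nats to bits."""
    return loss / math.log(2.0)


def score_motif(features, params: ModelParams) -> float:
    """P_i = sigmoid(beta0 + beta . f), numerically stable for large |logit|."""
    f = np.asarray(features, dtype=float)
    if not np.all(np.isfinite(f)):
        raise ValueError("non-finite feature values")
    if f.shape[-1] != params.weights.shape[0]:
        raise ValueError("feature/weight length mismatch")
    logit = params.bias + f @ params.weights
    return float(expit(logit)) if np.ndim(logit) == 0 else expit(logit)


def score_repertoire(motif_probs) -> float:
    """Max over motif probabilities; an empty repertoire scores 0 (with a warning)."""
    probs = np.asarray(motif_probs, dtype=float)
    if probs.size == 0:
        warnings.warn("empty motif probability list; repertoire scored 0", stacklevel=2)
        return 0.0
    return float(probs.max())


def classify(score: float, threshold: float = 0.5) -> int:
    """1 (tumor) iff score >= threshold: a tie at the threshold is called positive."""
    return int(score >= threshold)


def negative_log_likelihood(predictions, labels) -> float:
    """Mean negative log-likelihood (nats) with predictions clipped away from {0,1}."""
    p = np.asarray(predictions, dtype=float)
    y = np.asarray(labels, dtype=float)
    if p.shape != y.shape:
        raise ValueError("predictions and labels differ in length")
    p = np.clip(p, PROB_CLIP, 1.0 - PROB_CLIP)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def init_params(
    rng: np.random.Generator,
    feature_length: int,
    n_atchley: int = 15,
    init_variance_squared: bool = False,
) -> ModelParams:
    """Draw one random initialization.

    beta0 starts at 0.  The ``n_atchley`` physicochemical weights are drawn
    as (1/2)·N(0, 1/n_atchley) and the remaining weights (abundance term and
    any extensions) as (1/2)·N(0, 1), so the Atchley block and the abundance
    term contribute with the same expected squared magnitude (0.25 each).
    Draws are consumed in fixed order (Atchley block first).
    """
    n_rest = feature_length - n_atchley
    if n_rest < 1:
        raise ValueError("feature_length must exceed the Atchley block")
    if init_variance_squared:
        w_a = rng.normal(0.0, 1.0 / n_atchley, size=n_atchley)
        w_r = rng.normal(0.0, 1.0, size=n_rest)
    else:
        w_a = 0.5 * rng.normal(0.0, math.sqrt(1.0 / n_atchley), size=n_atchley)
        w_r = 0.5 * rng.normal(0.0, 1.0, size=n_rest)
    return ModelParams(bias=0.0, weights=np.concatenate([w_a, w_r]))


def draw_initial_params(
    opt: OptimizerConfig, feature_length: int, n_atchley: int = 15
) -> np.ndarray:
    """Weight matrix (n_restarts, d) of independent per-restart initializations.

    One master seed spawns an independent stream per restart, so any single
    restart is individually reproducible regardless of batching.
    """
    children = np.random.SeedSequence(opt.seed).spawn(opt.n_restarts)
    W0 = np.empty((opt.n_restarts, feature_length))
    for r, child in enumerate(children):
        p = init_params(
            np.random.Generator(np.random.PCG64(child)),
            feature_length,
            n_atchley=n_atchley,
            init_variance_squared=opt.init_variance_squared,
        )
        W0[r] = p.weights
    return W0


def _stack(features) -> tuple[np.ndarray, np.ndarray]:
    """Concatenate per-sample feature matrices; return (X, sample boundaries)."""
    sizes = []
    for i, f in enumerate(features):
        f = np.asarray(f)
        if f.ndim != 2 or f.shape[0] == 0:
            raise ValueError(f"sample {i} has no motifs; empty samples must be rejected upstream")
        sizes.append(f.shape[0])
    X = np.vstack([np.asarray(f, dtype=float) for f in features])
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    return X, bounds


_NEG_LARGE = -3.0e38  # sentinel logit for padding slots; never the argmax


class _PaddedBags:
    """Per-sample feature matrices in a rectangular layout for batched scoring.

    Samples are padded to the largest motif count with all-zero feature rows;
    the corresponding logit slots are overwritten with a very negative
    sentinel before the per-sample argmax, so padding never wins the max and
    motif order within each sample (hence the lowest-index tie-break) is
    preserved.
    """

    def __init__(self, features, dtype) -> None:
        mats = []
        for i, f in enumerate(features):
            f = np.asarray(f, dtype=dtype)
            if f.ndim != 2 or f.shape[0] == 0:
                raise ValueError(
                    f"sample {i} has no motifs; empty samples must be rejected upstream"
                )
            mats.append(f)
        self.n_samples = len(mats)
        self.d = mats[0].shape[1]
        self.maxn = max(m.shape[0] for m in mats)
        Xpad = np.zeros((self.n_samples * self.maxn, self.d), dtype=dtype)
        pad_cols = []
        for j, m in enumerate(mats):
            Xpad[j * self.maxn : j * self.maxn + m.shape[0]] = m
            pad_cols.append(np.arange(j * self.maxn + m.shape[0], (j + 1) * self.maxn))
        self.Xpad = Xpad  # (S*maxn, d), row-gatherable
        self.Xq = np.ascontiguousarray(Xpad.T)  # (d, S*maxn) for W @ Xq
        self.pad_cols = np.concatenate(pad_cols) if pad_cols else np.empty(0, dtype=np.intp)

    def max_logits(self, W: np.ndarray, b: np.ndarray, out: np.ndarray | None = None):
        """Per-sample max logit and argmax row, for every restart.

        Returns (Lmax (R, S), rows (R, S) global row indices into Xpad).
        """
        L = np.dot(W, self.Xq, out=out)  # (R, S*maxn)
        L += b[:, None]
        if self.pad_cols.size:
            L[:, self.pad_cols] = _NEG_LARGE
        L3 = L.reshape(W.shape[0], self.n_samples, self.maxn)
        local = L3.argmax(axis=2)  # first max -> lowest motif index
        Lmax = np.take_along_axis(L3, local[:, :, None], axis=2)[:, :, 0]
        rows = local + np.arange(self.n_samples) * self.maxn
        return Lmax, rows


def _bag_max(logits: np.ndarray, bounds: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample max and (lowest-index) argmax of motif logits, per restart."""
    S = len(bounds) - 1
    R = logits.shape[1]
    Lmax = np.empty((S, R))
    idx = np.empty((S, R), dtype=np.intp)
    for j in range(S):
        lo, hi = bounds[j], bounds[j + 1]
        block = logits[lo:hi]
        local = block.argmax(axis=0)  # first occurrence on ties -> lowest index
        idx[j] = local + lo
        Lmax[j] = block[local, np.arange(R)]
    return Lmax, idx


def _bag_nll(Lmax: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Mean NLL per restart from per-sample max logits (clipped probabilities)."""
    P = np.clip(expit(Lmax), PROB_CLIP, 1.0 - PROB_CLIP)
    return -(y[:, None] * np.log(P) + (1.0 - y[:, None]) * np.log(1.0 - P)).mean(axis=0)


def loss_and_grad(features, labels, params: ModelParams):
    """Single-parameter-set objective and straight-through subgradient.

    Returns (loss, grad_bias, grad_weights).  Exposed so the analytic
    gradient can be checked against finite differences.
    """
    X, bounds = _stack(features)
    y = np.asarray(labels, dtype=float)
    logits = (X @ params.weights + params.bias)[:, None]
    Lmax, idx = _bag_max(logits, bounds)
    loss = float(_bag_nll(Lmax, y)[0])
    P = expit(Lmax[:, 0])
    G = (P - y) / y.shape[0]
    Xsel = X[idx[:, 0]]
    return loss, float(G.sum()), G @ Xsel


def fit(
    cohort_features,
    labels,
    opt: OptimizerConfig,
    *,
    initial_weights: np.ndarray | None = None,
    eval_features=None,
    eval_labels=None,
    n_atchley: int = 15,
) -> FitResult:
    """Fit the MIL model by full-batch Adam from ``opt.n_restarts`` initializations.

    ``cohort_features`` is a list of per-sample normalized feature matrices.
    ``initial_weights`` (n_restarts, d) lets callers reuse one set of draws
    across cross-validation folds; by default they are drawn from ``opt.seed``.
    If ``eval_features``/``eval_labels`` are given, the held-out repertoire
    scores and losses are recorded at every step for the winning restart.
    Restarts whose final loss is non-finite are excluded with a warning.
    """
    dtype = np.float32
    bags = _PaddedBags(cohort_features, dtype)
    y = np.asarray(labels, dtype=dtype)
    if y.shape[0] != bags.n_samples:
        raise ValueError("labels and feature list differ in length")
    d = bags.d
    if initial_weights is None:
        initial_weights = draw_initial_params(opt, d, n_atchley=n_atchley)
    W_all = np.asarray(initial_weights, dtype=dtype)
    if W_all.shape != (opt.n_restarts, d):
        raise ValueError(f"initial_weights must have shape ({opt.n_restarts}, {d})")

    has_eval = eval_features is not None
    if has_eval:
        bags_e = _PaddedBags(eval_features, dtype)
        ye = np.asarray(eval_labels, dtype=float)

    y64 = y.astype(np.float64)

    def _nll_per_restart(Lmax: np.ndarray) -> np.ndarray:
        # Lmax: (R, S) max logits; mean NLL per restart, in float64 so the
        # 1 - 1e-12 clip bound is representable even when sigmoids saturate
        P = np.clip(expit(Lmax.astype(np.float64)), PROB_CLIP, 1.0 - PROB_CLIP)
        return -(y64[None, :] * np.log(P) + (1.0 - y64[None, :]) * np.log(1.0 - P)).mean(axis=1)

    best = {"loss": np.inf, "restart": -1}
    n_failed = 0
    a, b1, b2, eps = (dtype(v) for v in (opt.step_size, opt.b1, opt.b2, opt.epsilon))
    inv_n = dtype(1.0 / bags.n_samples)

    for chunk_start in range(0, opt.n_restarts, opt.restart_chunk):
        W = W_all[chunk_start : chunk_start + opt.restart_chunk].copy()  # (R, d)
        R = W.shape[0]
        b = np.zeros(R, dtype=dtype)
        mW = np.zeros_like(W)
        vW = np.zeros_like(W)
        mb = np.zeros(R, dtype=dtype)
        vb = np.zeros(R, dtype=dtype)
        train_curve = np.empty((opt.n_steps, R))
        if has_eval:
            eval_probs = np.empty((opt.n_steps, bags_e.n_samples, R))
        Lbuf = np.empty((R, bags.Xq.shape[1]), dtype=dtype)

        for t in range(opt.n_steps):
            Lmax, rows = bags.max_logits(W, b, out=Lbuf)  # (R, S)
            train_curve[t] = _nll_per_restart(Lmax)
            if has_eval:
                Lmax_e, _ = bags_e.max_logits(W, b)
                eval_probs[t] = expit(Lmax_e.astype(float)).T
            P = expit(Lmax)
            G = (P - y[None, :]) * inv_n  # (R, S)
            Xsel = bags.Xpad[rows]  # (R, S, d)
            gW = np.einsum("rs,rsd->rd", G, Xsel)
            gb = G.sum(axis=1)
            # Adam with bias correction
            mW = b1 * mW + (1 - b1) * gW
            vW = b2 * vW + (1 - b2) * gW**2
            mb = b1 * mb + (1 - b1) * gb
            vb = b2 * vb + (1 - b2) * gb**2
            c1 = dtype(1) - b1 ** (t + 1)
            c2 = dtype(1) - b2 ** (t + 1)
            W -= a * (mW / c1) / (np.sqrt(vW / c2) + eps)
            b -= a * (mb / c1) / (np.sqrt(vb / c2) + eps)

        Lmax, _ = bags.max_logits(W, b, out=Lbuf)
        final = _nll_per_restart(Lmax)
        bad = ~np.isfinite(final)
        if bad.any():
            n_failed += int(bad.sum())
            warnings.warn(f"{int(bad.sum())} restarts diverged to non-finite loss; excluded")
            final = np.where(bad, np.inf, final)
        r = int(final.argmin())
        if final[r] < best["loss"]:
            best.update(
                loss=float(final[r]),
                restart=chunk_start + r,
                params=ModelParams(bias=float(b[r]), weights=W[r].astype(float)),
                curve=train_curve[:, r].copy(),
                eval_probs=eval_probs[:, :, r].copy() if has_eval else None,
            )

    if not np.isfinite(best["loss"]):
        raise RuntimeError("every restart diverged to a non-finite loss")

    eval_loss = None
    if has_eval and best["eval_probs"] is not None:
        p = np.clip(best["eval_probs"], PROB_CLIP, 1.0 - PROB_CLIP)
        eval_loss = -(ye * np.log(p) + (1.0 - ye) * np.log(1.0 - p)).mean(axis=1)

    return FitResult(
        params=best["params"],
        training_loss=best["loss"],
        restart_index=best["restart"],
        loss_by_step=best["curve"],
        eval_probs_by_step=best["eval_probs"] if has_eval else None,
        eval_loss_by_step=eval_loss,
        n_failed_restarts=n_failed,
    )


def predict_repertoires(features, params: ModelParams) -> np.ndarray:
    """Repertoire scores (max motif sigmoid) for a list of feature matrices."""
    return np.array(
        [score_repertoire(score_motif(f, params)) for f in features], dtype=float
    )
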