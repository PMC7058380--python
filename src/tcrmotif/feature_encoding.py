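"""Atchley-factor feature encoding of motifs and abundance-weighted normalization.

Each amino acid maps to five standardized physicochemical factors (polarity,
secondary structure, molecular volume, codon diversity, electrostatic
charge).  A motif of three residues therefore contributes 15 values f1..f15,
followed by its within-sample relative abundance f_q (or ln f_q) as the 16th
feature, plus optional gap one-hot indicators and second-order (squared)
copies.  Features are standardized with an f_q-weighted mean/variance so that
abundant motifs dominate the statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .motif_engine import ModelConfig, MotifOccurrence, MotifTable

VARIANCE_FLOOR = 1e-8


def _load_atchley() -> pd.DataFrame:
    with resources.files("tcrmotif.data").joinpath("atchley_factors.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", index_col="residue")
    assert df.shape == (20, 5)
    return df


ATCHLEY_TABLE: pd.DataFrame = _load_atchley()
_ATCHLEY: dict[str, np.ndarray] = {
    aa: ATCHLEY_TABLE.loc[aa].to_numpy(dtype=float) for aa in ATCHLEY_TABLE.index
}


def atchley_vector(residue: str) -> np.ndarray:
    """The five Atchley factor values for one canonical amino-acid letter."""
    try:
        return _ATCHLEY[residue].copy()
    except KeyError:
        raise ValueError(f"no Atchley factors for residue {residue!r}") from None


def _base_vector(residues: str, gap_pattern: tuple[int, ...], f_q: float, config: ModelConfig) -> np.ndarray:
    config.check_implemented()
    parts = [np.concatenate([_ATCHLEY[r] for r in residues])]
    abundance = np.log(f_q) if config.log_frequency else f_q
    parts.append(np.array([abundance]))
    if config.gap_onehot:
        onehot = np.zeros(config.motif_size)
        for p in gap_pattern:
            onehot[p - 1] = 1.0
        parts.append(onehot)
    vec = np.concatenate(parts)
    if config.second_order:
        vec = np.concatenate([vec, vec**2])
    return vec


def encode_motif(occurrence, f_q: float, config: ModelConfig) -> np.ndarray:
    """Encode one motif occurrence (or motif key) plus abundance as a feature vector.

    Order is fixed: residue 1 factors 1-5, residue 2 factors 1-5, ... then the
    abundance term, then optional gap one-hot indicators, then (if enabled)
    squared copies of everything preceding.
    """
    if not 0 < f_q <= 1:
        raise ValueError("f_q must lie in (0, 1]")
    if isinstance(occurrence, MotifOccurrence):
        residues, gaps = occurrence.residues, occurrence.gap_pattern
    elif isinstance(occurrence, tuple):
        residues, gaps = occurrence
    else:
        residues, gaps = occurrence, ()
    return _base_vector(residues, gaps, f_q, config)


def encode_table(table: MotifTable, config: ModelConfig) -> tuple[list, np.ndarray, np.ndarray]:
    """Encode every motif of a per-sample table.

    Returns (keys, feature matrix, f_q weights) with rows in deterministic
    (sorted-key) order.  The weights are the raw relative abundances, used
    both as the 16th feature (possibly logged) and as normalization weights.
    """
    from .motif_engine import _sort_key

    keys = sorted(table.entries, key=_sort_key)
    if not keys:
        return [], np.empty((0, config.n_features)), np.empty(0)
    mat = np.empty((len(keys), config.n_features))
    fq = np.empty(len(keys))
    for i, key in enumerate(keys):
        f_q = table.entries[key].rel_abundance
        mat[i] = encode_motif(key, f_q, config)
        fq[i] = f_q
    return keys, mat, fq


@dataclass
class NormStats:
    """Weighted per-feature mean/variance used to standardize model input."""

    mean: np.ndarray
    var: np.ndarray
    floor: float = VARIANCE_FLOOR

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.var = np.asarray(self.var, dtype=float)
        if np.any(self.var < self.floor):
            raise ValueError("variances below floor")


def fit_normalizer(vectors, weights) -> NormStats:
    """Weighted mean/variance over motifs, weights = relative abundances f_q.

    Variances are floored at 1e-8 so constant features (e.g. a one-hot column
    that never fires) do not divide by zero.
    """
    mat = np.asarray(vectors, dtype=float)
    w = np.asarray(weights, dtype=float)
    if mat.size == 0:
        raise ValueError("cannot fit a normalizer on empty input")
    if w.shape[0] != mat.shape[0]:
        raise ValueError("weights and vectors differ in length")
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    wsum = w.sum()
    mean = (w[:, None] * mat).sum(axis=0) / wsum
    var = (w[:, None] * (mat - mean) ** 2).sum(axis=0) / wsum
    return NormStats(mean=mean, var=np.maximum(var, VARIANCE_FLOOR))


def apply_normalizer(vectors, stats: NormStats) -> np.ndarray:
    """Standardize: z = (v - mean) / sqrt(var), with the fitted (frozen) stats."""
    mat = np.asarray(vectors, dtype=float)
    if mat.shape[-1] != stats.mean.shape[0]:
        raise ValueError(
            f"feature length {mat.shape[-1]} does not match fitted stats ({stats.mean.shape[0]})"
        )
    return (mat - stats.mean) / np.sqrt(stats.var)
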