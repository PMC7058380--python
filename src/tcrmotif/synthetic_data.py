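"""Synthetic labeled CDR3 cohorts with planted physicochemical motifs.

Positive samples carry a few extra CDR3s whose interior contains a triplet
from a small set of planted 3-mers chosen to be mutually close in
Atchley-factor space (default {K,R}x{W,Y}x{H}: a positively charged,
hydrophilic first position, a bulky aromatic second, histidine third —
residue preferences a real HGSOC-associated motif shows, restricted to
physicochemically interchangeable pairs so the set forms one tight cluster).  Background CDR3s are drawn residue-wise with
conserved-looking ends ("CASS" ... "QYF") and are rejection-resampled so that
no background sequence's extracted motif set contains a planted triplet;
only planted sequences carry the signal, giving exact ground truth.

Sizes are deliberately desk-scale (tens of unique CDR3s per sample, versus
hundreds to thousands in real surveys) so that fitting, cross-validation and
permutation analysis run in seconds.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .feature_encoding import atchley_vector
from .mil_classifier import FitResult, score_motif
from .motif_engine import ModelConfig, extract_motifs
from .repertoire_io import CANONICAL_AA, Cohort, Repertoire, SequenceRecord

DEFAULT_PLANTED = ("KWH", "RWH", "KYH", "RYH")


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator settings; the defaults are the package's standard study conditions."""

    n_pos: int = 10
    n_neg: int = 10
    seqs_per_sample: tuple[int, int] = (25, 25)  # inclusive range of unique CDR3s
    length_range: tuple[int, int] = (11, 16)  # inclusive CDR3 length range
    residue_frequencies: tuple[float, ...] | None = None  # None = uniform over 20
    planted_triplets: tuple[str, ...] = DEFAULT_PLANTED
    n_planted_per_pos: int = 3
    planted_count_boost: int = 10
    count_geometric_mean: float = 2.0
    seed: int = 0
    prefix: str = "CASS"
    suffix: str = "QYF"
    gap_check: int = 1  # gaps allowed when screening backgrounds for planted triplets
    max_rejections: int = 200

    def __post_init__(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("need at least one sample per class")
        if self.n_planted_per_pos < 1:
            raise ValueError("n_planted_per_pos must be >= 1")
        if self.planted_count_boost < 1:
            raise ValueError("planted_count_boost must be >= 1")
        if self.length_range[0] < max(10, len(self.prefix) + len(self.suffix) + 3):
            raise ValueError("minimum length too short to host an interior triplet")
        for t in self.planted_triplets:
            if len(t) != 3 or set(t) - set(CANONICAL_AA):
                raise ValueError(f"planted triplet {t!r} is not a canonical 3-mer")
        if self.residue_frequencies is not None:
            f = np.asarray(self.residue_frequencies)
            if f.shape != (20,) or abs(float(f.sum()) - 1.0) > 1e-9 or (f < 0).any():
                raise ValueError("residue_frequencies must be a 20-vector summing to 1")


@dataclass
class GroundTruth:
    """Planted signal per positive sample, plus the planted Atchley centroid."""

    planted: dict[str, list[tuple[str, str]]]  # sample_id -> [(cdr3, triplet), ...]
    triplets: tuple[str, ...]
    centroid: np.ndarray  # 15-dim mean Atchley encoding of the planted triplets

    def __post_init__(self) -> None:
        for sid, entries in self.planted.items():
            if not entries:
                raise ValueError(f"positive sample {sid} lists no planted sequence")


def triplet_atchley(triplet: str) -> np.ndarray:
    return np.concatenate([atchley_vector(r) for r in triplet])


def _contains_planted(cdr3: str, spec: SyntheticSpec) -> bool:
    check = ModelConfig(motif_size=3, n_gap_positions=spec.gap_check)
    planted = set(spec.planted_triplets)
    return any(occ.residues in planted for occ in extract_motifs(cdr3, check))


def _draw_background(rng: np.random.Generator, spec: SyntheticSpec, length: int) -> str:
    interior = length - len(spec.prefix) - len(spec.suffix)
    probs = spec.residue_frequencies
    for _ in range(spec.max_rejections):
        mid = "".join(rng.choice(list(CANONICAL_AA), size=interior, p=probs))
        cdr3 = spec.prefix + mid + spec.suffix
        if not _contains_planted(cdr3, spec):
            return cdr3
    raise RuntimeError(
        "could not draw a background CDR3 free of planted triplets; "
        "choose rarer planted triplets or a longer length range"
    )


def _draw_planted(
    rng: np.random.Generator, spec: SyntheticSpec, length: int, triplet: str
) -> tuple[str, str]:
    interior = length - len(spec.prefix) - len(spec.suffix)
    for _ in range(spec.max_rejections):
        mid = list(rng.choice(list(CANONICAL_AA), size=interior, p=spec.residue_frequencies))
        pos = int(rng.integers(0, interior - 2))
        mid[pos : pos + 3] = list(triplet)
        cdr3 = spec.prefix + "".join(mid) + spec.suffix
        # interior sits >= 3 residues from both CDR3 ends, so trimming keeps it
        if extract_motifs(cdr3, ModelConfig(motif_size=3, n_gap_positions=0)):
            return cdr3, triplet
    raise RuntimeError("failed to place a planted triplet")


def _draw_count(rng: np.random.Generator, spec: SyntheticSpec) -> int:
    return int(rng.geometric(1.0 / spec.count_geometric_mean))


def generate_cohort(spec: SyntheticSpec, name: str = "synthetic") -> tuple[Cohort, GroundTruth]:
    """Generate a labeled cohort plus exact ground truth; deterministic given spec.seed."""
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.seqs_per_sample
    repertoires = []
    planted_map: dict[str, list[tuple[str, str]]] = {}

    for label, count, tag in ((1, spec.n_pos, "pos"), (0, spec.n_neg, "neg")):
        for i in range(count):
            sample_id = f"{name}_{tag}{i + 1:02d}"
            n_seqs = int(rng.integers(lo, hi + 1))
            seqs: dict[str, int] = {}
            if label == 1:
                planted_map[sample_id] = []
                # one triplet per positive sample: a patient's expanded clones
                # respond to the same antigen, so they share the motif
                sample_triplet = str(rng.choice(spec.planted_triplets))
                for _ in range(spec.n_planted_per_pos):
                    for _ in range(spec.max_rejections):
                        length = int(rng.integers(*spec.length_range, endpoint=True))
                        cdr3, triplet = _draw_planted(rng, spec, length, sample_triplet)
                        if cdr3 not in seqs:
                            break
                    seqs[cdr3] = _draw_count(rng, spec) * spec.planted_count_boost
                    planted_map[sample_id].append((cdr3, triplet))
            while len(seqs) < n_seqs + (spec.n_planted_per_pos if label == 1 else 0):
                length = int(rng.integers(*spec.length_range, endpoint=True))
                cdr3 = _draw_background(rng, spec, length)
                if cdr3 in seqs:
                    continue
                seqs[cdr3] = _draw_count(rng, spec)
            records = [SequenceRecord(c, n) for c, n in seqs.items()]
            repertoires.append(Repertoire(sample_id=sample_id, label=label, records=records))

    cohort = Cohort(name=name, repertoires=repertoires)
    centroid = np.mean([triplet_atchley(t) for t in spec.planted_triplets], axis=0)
    truth = GroundTruth(planted=planted_map, triplets=spec.planted_triplets, centroid=centroid)
    return cohort, truth


def generate_null_cohort(seed: int = 0, name: str = "null", **overrides) -> Cohort:
    """A cohort whose labels are independent of sequence content.

    All samples are drawn from the background distribution only (no planted
    sequences anywhere); half are arbitrarily labeled positive.
    """
    spec = SyntheticSpec(seed=seed, **overrides)
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.seqs_per_sample
    repertoires = []
    for label, count, tag in ((1, spec.n_pos, "pos"), (0, spec.n_neg, "neg")):
        for i in range(count):
            n_seqs = int(rng.integers(lo, hi + 1))
            seqs: dict[str, int] = {}
            while len(seqs) < n_seqs:
                length = int(rng.integers(*spec.length_range, endpoint=True))
                cdr3 = _draw_background(rng, spec, length)
                if cdr3 not in seqs:
                    seqs[cdr3] = _draw_count(rng, spec)
            repertoires.append(
                Repertoire(
                    sample_id=f"{name}_{tag}{i + 1:02d}",
                    label=label,
                    records=[SequenceRecord(c, n) for c, n in seqs.items()],
                )
            )
    return Cohort(name=name, repertoires=repertoires)


@dataclass
class RecoveryReport:
    """High-scoring motifs in the context of their source CDR3s, plus the hit rate."""

    motifs: pd.DataFrame  # sample_id, label, motif, score, cdr3, count, planted
    hit_rate: float  # fraction of positive samples whose top motif is planted


def recovery_report(
    fit_result: FitResult,
    featurized,
    truth: GroundTruth,
    threshold: float = 0.5,
) -> RecoveryReport:
    """List all motifs scoring >= threshold with their source CDR3s and counts.

    ``featurized`` is an :class:`~tcrmotif.evaluation.FeaturizedCohort` with
    normalization stats attached.  The hit rate is the fraction of positive
    samples whose top-scoring motif is one of the planted triplets.
    """
    if featurized.stats is None:
        raise ValueError("featurized cohort must carry normalization stats")
    planted = set(truth.triplets)
    config = featurized.config
    rows = []
    hits = 0
    n_pos = 0
    reps = {r.sample_id: r for r in featurized.cohort}
    for s, X in zip(featurized.samples, featurized.normalized()):
        probs = np.atleast_1d(score_motif(X, fit_result.params))
        # map each motif key back to the CDR3s containing it
        sources: dict = {}
        for rec in reps[s.sample_id].records:
            for occ in extract_motifs(rec.cdr3_aa, config):
                sources.setdefault(occ.key(config), set()).add((rec.cdr3_aa, rec.template_count))
        for key, p in zip(s.keys, probs):
            if p < threshold:
                continue
            residues = key[0] if isinstance(key, tuple) else key
            for cdr3, count in sorted(sources.get(key, ())):
                rows.append(
                    {
                        "sample_id": s.sample_id,
                        "label": s.label,
                        "motif": residues,
                        "score": float(p),
                        "cdr3": cdr3,
                        "count": count,
                        "planted": residues in planted,
                    }
                )
        if s.label == 1:
            n_pos += 1
            top = s.keys[int(probs.argmax())]
            top_res = top[0] if isinstance(top, tuple) else top
            hits += int(top_res in planted)
    motifs = pd.DataFrame(
        rows,
        columns=["sample_id", "label", "motif", "score", "cdr3", "count", "planted"],
    )
    return RecoveryReport(motifs=motifs, hit_rate=hits / n_pos if n_pos else float("nan"))


def write_airr_cohort(cohort: Cohort, out_dir: str | Path) -> Path:
    """Write one AIRR Rearrangement TSV per sample plus a manifest; returns manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rep in cohort:
        fname = f"{rep.sample_id}.tsv"
        pd.DataFrame(
            {
                "junction_aa": [r.cdr3_aa for r in rep.records],
                "duplicate_count": [r.template_count for r in rep.records],
            }
        ).to_csv(out_dir / fname, sep="\t", index=False)
        rows.append(
            {"path": fname, "dialect": "airr", "label": rep.label, "sample_id": rep.sample_id}
        )
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
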