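"""Gapped/contiguous CDR3 motif enumeration, template-weighted counting and the top-k cap.

A motif is a short (3-4 residue) in-order subsequence of a CDR3 from which the
first and last three residues have been trimmed (they rarely contact peptide).
Contiguous windows give ungapped motifs; when gaps are allowed, up to
``n_gap_positions`` interior residues of a longer window may be skipped —
never the first or last residue of the window, so every gap is internal.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

from .repertoire_io import Repertoire

#: Motif key type: residue string, or (residues, gap_pattern) when gapped and
#: ungapped instances of the same triplet are kept distinct.
MotifKey = "str | tuple[str, tuple[int, ...]]"


@dataclass(frozen=True)
class ModelConfig:
    """Configuration of the motif representation and the feature set.

    ``restrict_gap_to_position`` (1-based motif position) keeps only gapped
    occurrences whose skipped residue would have occupied that position.
    ``key_includes_gap`` controls whether gapped and ungapped instances of the
    same residue string are distinct motif keys; ``None`` follows
    ``gap_onehot`` (one-hot gap features require gap-resolved keys).
    ``use_blood_frequency`` and ``batch_norm`` are accepted so that
    model-selection grids can list and skip them, but featurization with
    either enabled raises :class:`NotImplementedError`.
    """

    motif_size: int = 3
    n_gap_positions: int = 1
    gap_onehot: bool = False
    restrict_gap_to_position: int | None = None
    use_blood_frequency: bool = False
    log_frequency: bool = False
    second_order: bool = False
    batch_norm: bool = False
    key_includes_gap: bool | None = None

    def __post_init__(self) -> None:
        if self.motif_size not in (3, 4):
            raise ValueError("motif_size must be 3 or 4")
        if self.n_gap_positions not in (0, 1, 2, 3):
            raise ValueError("n_gap_positions must be in 0..3")
        if self.restrict_gap_to_position is not None and not (
            1 <= self.restrict_gap_to_position <= self.motif_size
        ):
            raise ValueError("restrict_gap_to_position must lie in [1, motif_size]")
        if self.key_includes_gap is False and self.gap_onehot:
            raise ValueError("gap_onehot features require gap-resolved motif keys")

    @property
    def keyed_by_gap(self) -> bool:
        return self.gap_onehot if self.key_includes_gap is None else self.key_includes_gap

    def check_implemented(self) -> None:
        if self.use_blood_frequency:
            raise NotImplementedError("expected-frequency-in-blood feature is not implemented")
        if self.batch_norm:
            raise NotImplementedError("batch-normalization model variant is not implemented")

    @property
    def n_features(self) -> int:
        n = 5 * self.motif_size + 1
        if self.gap_onehot:
            n += self.motif_size
        if self.second_order:
            n *= 2
        return n


@dataclass(frozen=True)
class MotifOccurrence:
    """One extraction of a motif from a trimmed CDR3.

    ``gap_pattern`` lists, for each skipped residue, the 1-based motif
    position it would have occupied had it been kept (empty for contiguous
    motifs).  ``source_span`` is the 0-based half-open window within the
    trimmed CDR3 that the occurrence was assembled from.
    """

    residues: str
    gap_pattern: tuple[int, ...] = ()
    source_span: tuple[int, int] = (0, 0)

    def key(self, config: ModelConfig):
        if config.keyed_by_gap:
            return (self.residues, self.gap_pattern)
        return self.residues


@dataclass
class MotifEntry:
    count: int
    rel_abundance: float


@dataclass
class MotifTable:
    """Per-sample motif counts ``C^motif``, total ``T`` and abundances ``f_q = C/T``."""

    sample_id: str
    entries: dict
    total: int

    def __len__(self) -> int:
        return len(self.entries)


def extract_motifs(cdr3: str, config: ModelConfig) -> list[MotifOccurrence]:
    """Enumerate every motif occurrence in a CDR3's trimmed interior.

    The first and last three residues are removed; every contiguous window of
    ``motif_size`` residues is emitted, and for each g in 1..n_gap_positions,
    every subsequence of a (motif_size+g)-window obtained by skipping exactly
    g interior residues.  Short CDR3s simply yield an empty list.
    """
    k = config.motif_size
    trimmed = cdr3[3:-3] if len(cdr3) > 6 else ""
    m = len(trimmed)
    out: list[MotifOccurrence] = []
    restrict = config.restrict_gap_to_position
    for g in range(0, config.n_gap_positions + 1):
        w = k + g
        if m < w:
            break
        for start in range(m - w + 1):
            window = trimmed[start : start + w]
            if g == 0:
                out.append(MotifOccurrence(window, (), (start, start + w)))
                continue
            # skip exactly g interior residues of the window (never ends)
            for skips in itertools.combinations(range(1, w - 1), g):
                skipped = set(skips)
                positions = tuple(
                    sum(1 for i in range(s) if i not in skipped) + 1 for s in skips
                )
                if restrict is not None and any(p != restrict for p in positions):
                    continue
                residues = "".join(window[i] for i in range(w) if i not in skipped)
                out.append(MotifOccurrence(residues, positions, (start, start + w)))
    return out


def build_motif_table(repertoire: Repertoire, config: ModelConfig) -> MotifTable:
    """Count motifs over a repertoire with template weights.

    Containment is boolean per unique sequence: a CDR3's template count enters
    a motif's count once even if the motif occurs at several positions.
    """
    counts: dict = {}
    for rec in repertoire.records:
        keys = {occ.key(config) for occ in extract_motifs(rec.cdr3_aa, config)}
        for key in keys:
            counts[key] = counts.get(key, 0) + rec.template_count
    total = sum(counts.values())
    if total == 0:
        warnings.warn(
            f"{repertoire.sample_id}: no motifs extractable (all CDR3s too short)",
            stacklevel=2,
        )
        return MotifTable(repertoire.sample_id, {}, 0)
    entries = {key: MotifEntry(c, c / total) for key, c in counts.items()}
    return MotifTable(repertoire.sample_id, entries, total)


def _sort_key(key) -> tuple:
    # uniform lexicographic ordering for plain and gap-resolved keys
    if isinstance(key, tuple):
        return (key[0], key[1])
    return (key, ())


def truncate_top_k(table: MotifTable, k: int = 65536) -> MotifTable:
    """Keep the k most abundant motifs (ties broken lexicographically by key).

    Relative abundances are *not* recomputed: the cap is a runtime bound, not
    a change of the probability model.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(table.entries) <= k:
        return table
    ordered = sorted(table.entries.items(), key=lambda kv: (-kv[1].count, _sort_key(kv[0])))
    kept = dict(ordered[:k])
    return MotifTable(table.sample_id, kept, table.total)


def motif_table_to_frame(table: MotifTable) -> pd.DataFrame:
    """Export a motif table as a tidy DataFrame (TSV-ready)."""
    rows = []
    for key, entry in sorted(table.entries.items(), key=lambda kv: _sort_key(kv[0])):
        if isinstance(key, tuple):
            motif, gaps = key
        else:
            motif, gaps = key, ()
        rows.append(
            {
                "sample_id": table.sample_id,
                "motif": motif,
                "gap_pattern": ",".join(map(str, gaps)),
                "count": entry.count,
                "rel_abundance": entry.rel_abundance,
            }
        )
    return pd.DataFrame(rows, columns=["sample_id", "motif", "gap_pattern", "count", "rel_abundance"])


def expected_occurrences_size3_gap1(cdr3_length: int) -> int:
    """Closed-form occurrence count for motif_size=3, one gap: max(0,m-2)+2*max(0,m-3)."""
    m = cdr3_length - 6
    return max(0, m - 2) + 2 * max(0, m - 3)
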