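"""Reading TCRβ rearrangement tables into deduplicated CDR3 repertoires.

Two tabular dialects are supported: the AIRR Rearrangement TSV
(``junction_aa`` + ``duplicate_count``) and the Adaptive immunoSEQ export
(``aminoAcid``/``amino_acid`` + ``templates``/``count``/``reads``).  Rows are
deduplicated on the CDR3 amino-acid string alone, summing template counts;
rows whose CDR3 is empty, missing, or contains a non-canonical character
(stop ``*``, ambiguous ``X``, frame-shift ``_`` ...) are dropped and counted.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

logger = logging.getLogger(__name__)

CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"
_CANONICAL_SET = frozenset(CANONICAL_AA)


class FormatError(ValueError):
    """A required column is missing or a manifest is malformed."""


class EmptyRepertoireError(ValueError):
    """No usable CDR3 rows survived filtering."""


@dataclass(frozen=True)
class SequenceRecord:
    """One unique CDR3 amino-acid sequence with its summed template count."""

    cdr3_aa: str
    template_count: int

    def __post_init__(self) -> None:
        if not self.cdr3_aa:
            raise ValueError("cdr3_aa must be non-empty")
        bad = set(self.cdr3_aa) - _CANONICAL_SET
        if bad:
            raise ValueError(f"non-canonical residues {sorted(bad)} in {self.cdr3_aa!r}")
        if self.template_count < 1:
            raise ValueError("template_count must be >= 1")


@dataclass
class Repertoire:
    """One sample's unique CDR3 sequences with counts, plus its class label.

    ``label`` is 1 for tumor-derived (HGSOC) and 0 for healthy tissue.
    ``n_skipped`` records how many input rows were dropped by the
    canonical-CDR3 filter.
    """

    sample_id: str
    label: int
    records: list[SequenceRecord]
    n_skipped: int = 0

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")
        seqs = [r.cdr3_aa for r in self.records]
        if len(seqs) != len(set(seqs)):
            raise ValueError("duplicate CDR3 sequences within a repertoire")

    @property
    def n_unique(self) -> int:
        return len(self.records)

    @property
    def total_templates(self) -> int:
        return sum(r.template_count for r in self.records)


@dataclass
class Cohort:
    """A named collection of labeled repertoires with unique sample ids."""

    name: str
    repertoires: list[Repertoire] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.sample_id for r in self.repertoires]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate sample_id within a cohort")

    def __len__(self) -> int:
        return len(self.repertoires)

    def __iter__(self):
        return iter(self.repertoires)

    @property
    def labels(self) -> list[int]:
        return [r.label for r in self.repertoires]

    @property
    def sample_ids(self) -> list[str]:
        return [r.sample_id for r in self.repertoires]

    def class_counts(self) -> dict[int, int]:
        counts = {0: 0, 1: 0}
        for r in self.repertoires:
            counts[r.label] += 1
        return counts


# Candidate column names per dialect: (cdr3 candidates, count candidates).
_DIALECTS: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {
    "airr": (("junction_aa",), ("duplicate_count",)),
    "immunoseq": (
        ("aminoAcid", "amino_acid"),
        ("templates", "count", "templates (reads)", "reads"),
    ),
}


def _pick_column(columns: Sequence[str], candidates: tuple[str, ...], what: str) -> str:
    for name in candidates:
        if name in columns:
            return name
    raise FormatError(
        f"missing required {what} column; expected one of {list(candidates)}, "
        f"found {list(columns)}"
    )


def is_canonical(cdr3: str) -> bool:
    return bool(cdr3) and not (set(cdr3) - _CANONICAL_SET)


def read_repertoire(
    path: str | Path,
    dialect: str,
    label: int,
    sample_id: str,
) -> Repertoire:
    """Read one rearrangement TSV into a deduplicated :class:`Repertoire`.

    Rows sharing a CDR3 amino-acid string are merged with counts summed.
    Rows with a missing, empty or non-canonical CDR3 are dropped and counted
    in ``Repertoire.n_skipped``.  Missing or non-positive counts default to 1
    (a warning is emitted once per file).
    """
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {sorted(_DIALECTS)}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    cdr3_col = _pick_column(df.columns, _DIALECTS[dialect][0], "CDR3 amino-acid")
    count_col = _pick_column(df.columns, _DIALECTS[dialect][1], "template-count")

    counts: dict[str, int] = {}
    n_skipped = 0
    n_defaulted = 0
    for cdr3, raw_count in zip(df[cdr3_col], df[count_col]):
        if pd.isna(cdr3) or not is_canonical(str(cdr3)):
            n_skipped += 1
            continue
        try:
            count = int(float(raw_count))
        except (TypeError, ValueError):
            count = 0
        if count < 1:
            count = 1
            n_defaulted += 1
        counts[str(cdr3)] = counts.get(str(cdr3), 0) + count

    if n_defaulted:
        warnings.warn(
            f"{path}: {n_defaulted} rows had missing/zero counts; defaulted to 1",
            stacklevel=2,
        )
    if n_skipped:
        logger.info("%s: skipped %d rows with non-canonical or missing CDR3", path, n_skipped)
    if not counts:
        raise EmptyRepertoireError(f"{path}: no usable CDR3 rows after filtering")

    records = [SequenceRecord(cdr3, c) for cdr3, c in counts.items()]
    return Repertoire(sample_id=sample_id, label=int(label), records=records, n_skipped=n_skipped)


def load_cohort(manifest: str | Path | pd.DataFrame, name: str = "cohort") -> Cohort:
    """Assemble a :class:`Cohort` from a manifest of (path, dialect, label, sample_id).

    ``manifest`` may be a CSV/TSV path (header required) or a DataFrame.
    Relative data paths are resolved against the manifest's directory.
    """
    if isinstance(manifest, pd.DataFrame):
        table = manifest
        base = Path(".")
    else:
        manifest = Path(manifest)
        sep = "\t" if manifest.suffix.lower() in (".tsv", ".tab") else ","
        table = pd.read_csv(manifest, sep=sep, dtype=str)
        base = manifest.parent

    required = ["path", "dialect", "label", "sample_id"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise FormatError(f"manifest missing columns {missing}")
    ids = list(table["sample_id"])
    if len(ids) != len(set(ids)):
        raise ValueError("manifest contains duplicate sample_id values")

    repertoires = []
    for row in table.itertuples(index=False):
        p = Path(str(row.path))
        if not p.is_absolute():
            p = base / p
        rep = read_repertoire(p, str(row.dialect), int(row.label), str(row.sample_id))
        logger.info("%s: %d unique CDR3s", rep.sample_id, rep.n_unique)
        repertoires.append(rep)
    return Cohort(name=name, repertoires=repertoires)
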