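import numpy as np
import pandas as pd
import pytest

import tcrmotif as tm


@pytest.fixture
def airr_file(tmp_path):
    """Factory writing an AIRR Rearrangement TSV from (junction_aa, count) rows."""

    def _write(rows, name="sample.tsv", columns=("junction_aa", "duplicate_count")):
        path = tmp_path / name
        pd.DataFrame(rows, columns=list(columns)).to_csv(path, sep="\t", index=False)
        return path

    return _write


@pytest.fixture(scope="session")
def strong_cohort():
    """Strong planted-signal cohort (seed 0) with ground truth."""
    return tm.generate_cohort(tm.SyntheticSpec(seed=0))


@pytest.fixture(scope="session")
def small_opt():
    """Reduced optimizer settings for fast unit tests (not the study protocol)."""
    return tm.OptimizerConfig(n_restarts=32, n_steps=150, seed=0)


def build_cohort(seq_count_label, name="toy"):
    """Cohort from [(sample_id, [(cdr3, count), ...], label), ...]."""
    reps = [
        tm.Repertoire(
            sample_id=sid,
            label=label,
            records=[tm.SequenceRecord(c, n) for c, n in seqs],
        )
        for sid, seqs, label in seq_count_label
    ]
    return tm.Cohort(name=name, repertoires=reps)
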