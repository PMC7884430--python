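import numpy as np
import pytest

from hdxsolver.hx_io import Dataset, IntrinsicRateTable, Peptide

TIMEPOINTS7 = (0.25, 1.0, 5.0, 20.0, 60.0, 240.0, 480.0)


def make_peptide(pid, start, end, sequence, rfu=None, n_t=7):
    if rfu is None:
        rfu = tuple(min(1.0, 0.1 * (i + 1)) for i in range(n_t))
    return Peptide(id=pid, start=start, end=end, sequence=sequence, rfu=tuple(rfu))


def make_dataset(spans, n_residues=None, timepoints=TIMEPOINTS7, sequence=None,
                 rfu_rows=None):
    """Build a dataset from (start, end) spans over an alanine backbone."""
    n = n_residues or max(e for _, e in spans)
    seq = sequence or "A" * n
    peptides = []
    for i, (s, e) in enumerate(spans):
        rfu = rfu_rows[i] if rfu_rows is not None else None
        peptides.append(make_peptide(i, s, e, seq[s - 1:e], rfu, len(timepoints)))
    return Dataset(protein_id="test", timepoints=timepoints, peptides=peptides)


def uniform_kch(dataset, value=100.0):
    """Flat intrinsic-rate table covering a dataset (prolines excluded)."""
    entries = {}
    for r in dataset.residues:
        aa = dataset.residue_aa[r]
        entries[r] = (aa, None if aa == "P" else value)
    return IntrinsicRateTable(entries=entries)


@pytest.fixture
def toy_dataset():
    """Two overlapping peptides, residues 1..8, no prolines."""
    return make_dataset([(1, 5), (3, 8)])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
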