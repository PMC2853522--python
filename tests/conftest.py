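"""Shared fixtures: small planted arrays and alignments built at test time."""

import numpy as np
import pytest

from alphadom.model import ArrayAlignment, SequenceRecord


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_alignment(rows: list[str], ids=None) -> ArrayAlignment:
    """Alignment from literal rows; consensus by the package's majority rule."""
    from alphadom.io import _majority_state

    matrix = np.array([list(r) for r in rows], dtype="<U1")
    consensus = "".join(_majority_state(matrix[:, j])
                        for j in range(matrix.shape[1]))
    ids = ids or [f"c{i + 1}" for i in range(len(rows))]
    return ArrayAlignment(copy_ids=ids, matrix=matrix, consensus=consensus)


@pytest.fixture
def tandem_array(rng):
    """Ten exact tandem copies of a random 171-bp monomer."""
    monomer = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 171)])
    return SequenceRecord("tandem", monomer * 10), monomer


@pytest.fixture
def hor_array(rng):
    """Planted k=4 HOR: 12 units of 4 diverged monomer variants (171 bp)."""
    base = rng.integers(0, 4, 171)
    variants = []
    for _ in range(4):
        v = base.copy()
        pos = rng.choice(171, 12, replace=False)
        v[pos] = (v[pos] + 1) % 4
        variants.append(v)
    unit = np.concatenate(variants)
    seq = "".join(np.array(list("ACGT"))[np.tile(unit, 12)])
    return SequenceRecord("hor", seq), 4
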