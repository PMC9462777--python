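import numpy as np
import pytest

from miprot.quant import QuantTable


@pytest.fixture
def two_condition_table():
    """Small complete table: 6 analytes, two conditions of 3 samples."""
    rng = np.random.default_rng(7)
    values = rng.normal(20.0, 1.0, size=(6, 6))
    samples = ["a1", "a2", "a3", "b1", "b2", "b3"]
    cond = {s: s[0].upper() for s in samples}
    return QuantTable(values, [f"pep{i}" for i in range(6)], samples, cond)


@pytest.fixture
def masked_table(two_condition_table):
    """Same table with three cells masked."""
    values = two_condition_table.values.copy()
    values[0, 0] = np.nan
    values[2, 4] = np.nan
    values[5, 2] = np.nan
    return QuantTable(
        values,
        two_condition_table.analyte_ids,
        two_condition_table.sample_ids,
        two_condition_table.condition_of,
    )


def make_table(values, n1, n2, ids=None):
    values = np.asarray(values, dtype=float)
    samples = [f"a{i}" for i in range(n1)] + [f"b{i}" for i in range(n2)]
    cond = {s: s[0].upper() for s in samples}
    ids = ids or [f"p{i}" for i in range(values.shape[0])]
    return QuantTable(values, ids, samples, cond)
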