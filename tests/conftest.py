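import numpy as np
import pandas as pd
import pytest

from cladiff import LabelVector, TaxaTable
from cladiff.taxonomy import RankPath


def rp(*ranks: str) -> RankPath:
    return RankPath(tuple(ranks))


@pytest.fixture
def tiny_table() -> TaxaTable:
    """2 genera x 4 species leaves, 6 samples, already log-processed."""
    paths = [
        rp("Bacteria", "Firmicutes", "Ca", "Oa", "Fa", "Ga", "s1"),
        rp("Bacteria", "Firmicutes", "Ca", "Oa", "Fa", "Ga", "s2"),
        rp("Bacteria", "Firmicutes", "Ca", "Oa", "Fa", "Gb", "s3"),
        rp("Bacteria", "Firmicutes", "Ca", "Oa", "Fa", "Gb", "s4"),
    ]
    rng = np.random.default_rng(42)
    data = pd.DataFrame(
        rng.normal(size=(6, 4)),
        index=[f"s{i}" for i in range(6)],
        columns=paths,
    )
    return TaxaTable(data, value_kind="log_processed")


@pytest.fixture
def tiny_labels(tiny_table) -> LabelVector:
    return LabelVector(
        pd.Series([1, 1, 1, 0, 0, 0], index=tiny_table.sample_ids), kind="binary"
    )


def make_labels(values, ids=None, kind="binary") -> LabelVector:
    values = list(values)
    ids = ids if ids is not None else [f"s{i}" for i in range(len(values))]
    return LabelVector(pd.Series(values, index=ids), kind=kind)
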