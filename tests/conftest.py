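import numpy as np
import pandas as pd
import pytest

from pqtlmr.sumstats import SummaryDataset


def make_records(rows: list[dict]) -> pd.DataFrame:
    """Build a summary-statistics frame from terse row dicts."""
    defaults = {
        "chromosome": "1",
        "position": 1000,
        "effect_allele": "A",
        "other_allele": "G",
        "eaf": 0.3,
        "beta": 0.1,
        "se": 0.05,
        "pvalue": 0.05,
        "n": 10_000,
    }
    out = []
    for i, row in enumerate(rows):
        r = {"variant_id": f"rs{i + 1}", **defaults, **row}
        out.append(r)
    return pd.DataFrame(out)


@pytest.fixture
def quant_dataset():
    def _build(rows, name="protein"):
        return SummaryDataset(name, "quantitative", make_records(rows))

    return _build


@pytest.fixture
def cc_dataset():
    def _build(rows, name="outcome", case_proportion=0.5):
        return SummaryDataset(
            name, "case_control", make_records(rows), case_proportion=case_proportion
        )

    return _build


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
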