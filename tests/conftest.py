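import numpy as np
import pytest

from sigratio.datatypes import ExpressionMatrix, SurvivalRecord


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def make_matrix():
    """Build an ExpressionMatrix from a dict gene -> values (plus groups)."""

    def _make(data: dict, groups: dict | None = None) -> ExpressionMatrix:
        genes = list(data)
        values = np.array([data[g] for g in genes], dtype=float)
        samples = [f"s{i}" for i in range(values.shape[1])]
        g = None
        if groups is not None:
            g = {samples[i]: lab for i, lab in groups.items()}
        return ExpressionMatrix(genes, samples, values, g)

    return _make


@pytest.fixture
def make_records():
    """Build SurvivalRecords from (time, event, group) triples."""

    def _make(triples):
        return [
            SurvivalRecord(f"m{i}", t, bool(e), g) for i, (t, e, g) in enumerate(triples)
        ]

    return _make
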