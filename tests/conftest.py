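import numpy as np
import pandas as pd
import pytest

from metabostate.tables import FeatureTable


def make_table(values, labels, mz=None, rt=None, batches=None, provenance=()):
    """Build a FeatureTable from plain arrays with auto-generated metadata."""
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    if mz is None:
        mz = 100.0 + 50.0 * np.arange(p)
    if rt is None:
        rt = 60.0 + 10.0 * np.arange(p)
    features = pd.DataFrame(
        {"mz": mz, "rt": rt},
        index=pd.Index([f"F{j:04d}" for j in range(p)], name="feature_id"),
    )
    return FeatureTable(
        values=values,
        sample_ids=np.array([f"S{i:04d}" for i in range(n)], dtype=object),
        labels=np.asarray(labels, dtype=int),
        features=features,
        batches=None if batches is None else np.asarray(batches, dtype=object),
        provenance=tuple(provenance),
    )


@pytest.fixture
def table_factory():
    return make_table
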