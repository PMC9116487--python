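import numpy as np
import pytest

from dbst.models import branched_pathway_truth, generate_synthetic_timeseries


@pytest.fixture(scope="session")
def branched_dense_series():
    """Noiseless reference data for the branched pathway, t = 0..60 step 1."""
    spec = branched_pathway_truth()
    return generate_synthetic_timeseries(spec, np.arange(0.0, 61.0, 1.0),
                                         generator="fine_grid_reference")


@pytest.fixture(scope="session")
def branched_sparse_series():
    """The same reference data observed every 3 time units (21 rows)."""
    spec = branched_pathway_truth()
    return generate_synthetic_timeseries(spec, np.arange(0.0, 61.0, 3.0),
                                         generator="fine_grid_reference")
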