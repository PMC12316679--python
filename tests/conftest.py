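import numpy as np
import pytest

from vaimri import generate_phantom, run_subject_data
from vaimri.phantom import PhantomConfig


@pytest.fixture(scope="session")
def default_phantom():
    """Noise-free phantom at the study's acquisition settings."""
    return generate_phantom(PhantomConfig())


@pytest.fixture(scope="session")
def default_result(default_phantom):
    """Full pipeline output on the default phantom."""
    ds = default_phantom
    return run_subject_data(ds.ge, ds.se, ds.dwi, ds.bvals, ds.roi_set)


def roi_mean(summaries, roi, metric):
    row = summaries[(summaries.roi == roi) & (summaries.metric == metric)]
    assert len(row) == 1
    return float(row["mean"].iloc[0])


@pytest.fixture(scope="session")
def roi_mean_getter():
    return roi_mean
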