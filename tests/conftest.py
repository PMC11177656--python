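import numpy as np
import pandas as pd
import pytest

from pbrtqc.core_model import PatientResult, ResultStream


@pytest.fixture
def rng():
    return np.random.default_rng(20240615)


def make_stream(values, start="2022-01-01", freq="1h", analyte="X"):
    """Evenly spaced stream from a value sequence (test helper)."""
    ts = pd.date_range(start, periods=len(values), freq=freq)
    return ResultStream(
        analyte_name=analyte,
        results=[
            PatientResult(timestamp=t, value=float(v), instrument_id="t")
            for t, v in zip(ts, values)
        ],
    )


@pytest.fixture
def stream_factory():
    return make_stream
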