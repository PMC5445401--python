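import numpy as np
import pandas as pd
import pytest

from ohcpipe.io import ExpressionMatrix, SampleRecord, SampleSheet


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    """2 probes x 2 arrays with values ((10, 20), (5, 5))."""
    return ExpressionMatrix(
        pd.DataFrame([[10.0, 20.0], [5.0, 5.0]], index=["p1", "p2"], columns=["a1", "a2"])
    )


@pytest.fixture
def study_sheet() -> SampleSheet:
    """8 lines x 3 replicates, flags per the study design."""
    lines = [
        ("MCF-7", False, False, True),
        ("pcDNA-blank", False, False, False),
        ("MT3", True, True, False),
        ("MT3dCT", False, True, False),
        ("MT3dNT", True, False, False),
        ("MT1E", False, False, False),
        ("MT1E-CT", True, False, False),
        ("MT1E-NT", False, True, False),
    ]
    records = [
        SampleRecord(f"{name}_{rep}", name, rep, ref, ct, nt)
        for name, ct, nt, ref in lines
        for rep in "abc"
    ]
    return SampleSheet(records)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
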