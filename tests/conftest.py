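import numpy as np
import pandas as pd
import pytest

from cclr import CaseControlDataset, PenetranceModel


@pytest.fixture
def const_model():
    """Constant baseline incidence 0.01/yr, carrier relative risk 2, ages 21-80."""
    return PenetranceModel.constant(0.01, 2.0)


def dataset(carrier, status, age, stratum=None):
    f = pd.DataFrame({"carrier": carrier, "status": status, "age": age})
    f["stratum"] = stratum if stratum is not None else None
    return CaseControlDataset(f)


@pytest.fixture
def toy4():
    """Two cases and two controls, all aged 50; the single carrier is a case."""
    return dataset([1, 0, 0, 0], [1, 1, 0, 0], [50.0] * 4)


@pytest.fixture
def toy4_control_carrier():
    """Same four individuals but the single carrier is a control."""
    return dataset([0, 0, 1, 0], [1, 1, 0, 0], [50.0] * 4)
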