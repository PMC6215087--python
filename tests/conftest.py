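"""Shared fixtures: tiny constructed datasets and helpers."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from ecocrit import ClassBoundaries, Dataset, SyntheticConfig, generate

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def boundaries() -> ClassBoundaries:
    return ClassBoundaries(hg_eqr=0.8, gm_eqr=0.6)


@pytest.fixture
def toy_mismatch_dataset(boundaries) -> Dataset:
    """8 lake-years: 4 with good-or-better biology (TP 10,20,30,60) and 4
    moderate-or-worse (TP 25,50,70,90).  TN is a constant placeholder."""
    tp = [10.0, 20.0, 30.0, 60.0, 25.0, 50.0, 70.0, 90.0]
    eqr = [0.9, 0.9, 0.9, 0.9, 0.4, 0.4, 0.4, 0.4]
    frame = pd.DataFrame(
        {
            "lake_id": [f"L{i}" for i in range(8)],
            "type_code": "TOY",
            "year": 2010,
            "tp": tp,
            "tn": 1.0,
            "eqr": eqr,
        }
    )
    return Dataset(frame, "TOY")


@pytest.fixture
def default_synthetic() -> Dataset:
    return generate(SyntheticConfig(seed=42))


def make_dataset(tp, tn, eqr, type_code="TST") -> Dataset:
    tp = np.asarray(tp, dtype=float)
    frame = pd.DataFrame(
        {
            "lake_id": [f"L{i}" for i in range(len(tp))],
            "type_code": type_code,
            "year": 2010,
            "tp": tp,
            "tn": np.asarray(tn, dtype=float),
            "eqr": np.asarray(eqr, dtype=float),
        }
    )
    return Dataset(frame, type_code)
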