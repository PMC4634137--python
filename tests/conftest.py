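import dataclasses

import numpy as np
import pandas as pd
import pytest

from hcregulon import ExpressionMatrix, SimulationParams


def make_design(organs=("cochlea", "vestibule"),
                cell_types=("HC", "ENHC", "NEC"), reps=3) -> pd.DataFrame:
    rows = [{"sample_id": f"{o}_{c}_r{r}", "organ": o, "cell_type": c,
             "replicate": r}
            for o in organs for c in cell_types for r in range(1, reps + 1)]
    return pd.DataFrame(rows)


def make_matrix(values: np.ndarray, design: pd.DataFrame,
                feature_ids=None, detection_p=None) -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    if feature_ids is None:
        feature_ids = [f"g{i}" for i in range(values.shape[0])]
    frame = pd.DataFrame(values, index=feature_ids,
                         columns=list(design["sample_id"]))
    dp = None
    if detection_p is not None:
        dp = pd.DataFrame(np.asarray(detection_p, dtype=float),
                          index=feature_ids, columns=frame.columns)
    return ExpressionMatrix(values=frame, design=design, detection_p=dp)


@pytest.fixture
def design18() -> pd.DataFrame:
    return make_design()


@pytest.fixture
def small_params() -> SimulationParams:
    """Scaled-down study conditions for unit tests."""
    return SimulationParams(n_genes=300, n_regulon=30, n_markers_per_type=8,
                            chip_extra=15, seed=7)


@pytest.fixture
def tiny_rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def replace_params(params: SimulationParams, **kw) -> SimulationParams:
    return dataclasses.replace(params, **kw)
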