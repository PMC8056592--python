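import numpy as np
import pandas as pd
import pytest

from longicluster import (
    LongitudinalExpressionSet,
    RESPONDER,
    NONRESPONDER,
    SimulationConfig,
    build_views,
    reference_simulation,
    simulate_longitudinal,
)

ANALYSIS_TIMEPOINTS = ["LS0", "W1", "W2", "W4"]


@pytest.fixture(scope="session")
def reference_data():
    """The fixed study-shaped scenario (30 subjects, 300 genes, 20 planted)."""
    return reference_simulation()


@pytest.fixture(scope="session")
def reference_views(reference_data):
    data, _ = reference_data
    return build_views(data, ANALYSIS_TIMEPOINTS)


@pytest.fixture(scope="session")
def reference_labels(reference_data, reference_views):
    data, _ = reference_data
    return data.response_labels(reference_views.subject_ids)


@pytest.fixture(scope="session")
def small_signal():
    """A small strong-signal dataset for fast ensemble/evaluation tests."""
    cfg = SimulationConfig(
        n_subjects=16, p_genes=60, n_informative=12,
        delta_range=(2.0, 3.0), sigma_subject=0.2, sigma_noise=0.4, seed=7)
    return simulate_longitudinal(cfg)


@pytest.fixture(scope="session")
def noise_data():
    """Pure-noise dataset: no informative genes at all."""
    cfg = SimulationConfig(
        n_subjects=30, p_genes=80, n_informative=0, seed=11)
    return simulate_longitudinal(cfg)


def tiny_expression_set(missing_cells=()):
    """3 genes x 2 subjects x 2 timepoints, values 1..12, optional missing."""
    values = np.arange(1.0, 13.0).reshape(3, 2, 2)
    mask = np.zeros_like(values, dtype=bool)
    for cell in missing_cells:
        mask[cell] = True
        values[cell] = np.nan
    meta = pd.DataFrame(
        {"subject": ["A", "B"], "response": [RESPONDER, NONRESPONDER]}
    ).set_index("subject")
    return LongitudinalExpressionSet(
        gene_ids=["g1", "g2", "g3"],
        subject_ids=["A", "B"],
        timepoint_labels=["NL", "LS0"],
        values=values,
        missing_mask=mask,
        sample_meta=meta,
    )
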