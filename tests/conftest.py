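"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from camoquant.stats_pipeline import ModelSpec, fit_lmm
from camoquant.synthetic_data import (
    BackgroundSpec,
    DEFAULT_PROFILES,
    ExperimentDesign,
    generate_cone_catch_table,
)
from camoquant.visual_model import add_metric_columns

#: Single achromatic test background at the measured black-paper reflectance.
BLACK_ONLY = (BackgroundSpec("black", reflectance=0.059),)


def generic_rnl_distance(qa, qb, noises) -> float:
    """Independent n-receptor receptor-noise-limited distance oracle.

    The RNL distance is the noise-weighted distance of the log-contrast
    vector from the nearest uniform (achromatic) shift:
    ``dS^2 = min_c sum_i ((df_i - c) / e_i)^2`` with
    ``df_i = ln(qa_i / qb_i)``. Solved here by numerical scalar
    minimisation — a different route from the pairwise closed form under
    test, valid for any number of receptors.
    """
    df = np.log(np.asarray(qa, float) / np.asarray(qb, float))
    e = np.asarray(noises, float)

    def objective(c: float) -> float:
        return float(np.sum(((df - c) / e) ** 2))

    res = minimize_scalar(objective, bracket=(df.min() - 1, df.max() + 1))
    return float(np.sqrt(max(res.fun, 0.0)))


@pytest.fixture(scope="session")
def black_metrics_table():
    """Small black-background experiment (4 populations x 5 fish x 4 times)."""
    design = ExperimentDesign(backgrounds=BLACK_ONLY, fish_per_cell=5, seed=3)
    return add_metric_columns(generate_cone_catch_table(design, DEFAULT_PROFILES))


@pytest.fixture(scope="session")
def black_luminance_fit(black_metrics_table):
    """REML fit of the full interaction model for luminance."""
    return fit_lmm(black_metrics_table, ModelSpec(response="luminance"))


@pytest.fixture(scope="session")
def full_size_black_fit():
    """Study-sized black-background fit: 4 populations x 20 fish x 4 times."""
    design = ExperimentDesign(backgrounds=BLACK_ONLY, fish_per_cell=20, seed=11)
    table = add_metric_columns(generate_cone_catch_table(design, DEFAULT_PROFILES))
    return fit_lmm(table, ModelSpec(response="luminance", transform="log"))
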