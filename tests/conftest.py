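import warnings

import numpy as np
import pandas as pd
import pytest

import autologit as al


@pytest.fixture
def toy_points():
    """Three collinear points at x = 0, 1, 2 on the x-axis."""
    return pd.DataFrame({"unit_id": [0, 1, 2], "x": [0.0, 1.0, 2.0], "y": [0.0] * 3})


@pytest.fixture
def toy_weights(toy_points):
    return al.build_weights(toy_points, radius=2.5)


@pytest.fixture(scope="session")
def small_cohort():
    """A small complete synthetic cohort with spatial outcome structure."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cohort, prov = al.generate_dataset(al.SimConfig(n=400, seed=11))
    return cohort, prov


@pytest.fixture(scope="session")
def small_fit(small_cohort):
    """Converged logistic and auto-logistic fits on the small cohort."""
    cohort, prov = small_cohort
    design = al.DesignSpec(
        [
            al.Covariate("age"),
            al.Covariate("triage", "binary", reference="levels12"),
            al.Covariate("los"),
        ]
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        weights = al.build_weights(
            cohort[["unit_id", "x", "y"]], prov["config"]["radius"]
        )
        flog = al.fit_logistic(design, cohort)
        fauto = al.fit_autologistic(design, cohort, weights)
    return flog, fauto, weights, cohort
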