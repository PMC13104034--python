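import numpy as np
import pandas as pd
import pytest

from liverpfas import CohortTable, default_panel, default_params
from liverpfas.dataset import table_from_truth  # re-exported for test modules
from liverpfas.synth import generate_cohort, generate_true_concentrations


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def small_cohort_table(panel):
    """n=120 synthetic cohort quantified without instrument noise."""
    params = default_params(seed=11, n_donors=120)
    cohort = generate_cohort(params)
    truth = generate_true_concentrations(cohort, params)
    mdls = {name: a.idl for name, a in params.analytes.items()}
    return table_from_truth(truth, cohort, mdls)
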