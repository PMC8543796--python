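"""Shared fixtures: synthetic banks and fitted models reused across tests.

Expensive fits are session-scoped so the parameter-recovery and
fit-statistic suites share one estimation run per configuration.
"""

import numpy as np
import pytest

from itemharmony import irt, synthetic
from itemharmony.pipeline import PipelineConfig, run_pipeline_objects


def bank_matrix(bank, study_id):
    """Response matrix and aligned truth arrays for one study of a bank."""
    ds = [d for d in bank.datasets if d.study_id == study_id][0]
    names = sorted(ds.items)
    X = np.column_stack([ds.items[n] for n in names])
    constructs = [n.rsplit("_", 1)[0] for n in names]
    a_t = np.array([bank.truth["items"][c]["a"] for c in constructs])
    b_t = np.array([bank.truth["items"][c]["b"] for c in constructs])
    return X, names, a_t, b_t


@pytest.fixture(scope="session")
def defect_bank():
    """Three-study bank with every defect class planted (n=1000/study)."""
    return synthetic.generate(synthetic.default_bank_config(seed=1, n_per_study=1000))


@pytest.fixture(scope="session")
def defect_pipeline(defect_bank):
    return run_pipeline_objects(defect_bank.crosswalk, defect_bank.datasets, PipelineConfig())


@pytest.fixture(scope="session")
def recovery_fit():
    """Clean bank, n=2000, 15 binary items, with the fitted 2PL and truth."""
    bank = synthetic.generate(synthetic.clean_bank_config(seed=42, n_per_study=2000, n_items=15))
    X, names, a_t, b_t = bank_matrix(bank, "S1")
    fit = irt.fit_2pl(X, item_names=names, study_id="S1")
    return {"bank": bank, "X": X, "fit": fit, "a_true": a_t, "b_true": b_t}


@pytest.fixture(scope="session")
def small_fit():
    """Tiny 3-item, n=50 fit for likelihood-oracle comparisons."""
    bank = synthetic.generate(synthetic.clean_bank_config(seed=7, n_per_study=50, n_items=3))
    X, names, _, _ = bank_matrix(bank, "S1")
    fit = irt.fit_2pl(X, item_names=names)
    return {"X": X, "fit": fit}
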