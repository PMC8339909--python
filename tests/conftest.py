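"""Shared fixtures.

The expensive simulated ensembles (the S1:600 curve dataset and the ERP(S1)
dataset) are session-scoped so that every test that needs them shares one
simulation pass.  Their sizes are the reduced-scale study conditions used
throughout the package: n=150 maximin design for the S2 curves, n=100 for
ERP(S1) over 350..700 ms at 50 ms spacing.
"""

from __future__ import annotations

import pytest

from rcemu.curves import CurveGrid
from rcemu.design import DesignSpec, build_training_dataset, maximin_lhs
from rcemu.emulator import RCE

S2_DATASET_SEED = 11
ERP_DATASET_SEED = 21
ERP_S1_LIST = list(range(350, 701, 50))


@pytest.fixture(scope="session")
def s2_dataset():
    """Simulated CV(S2)/APD(S2) training dataset at S1:600 (n=150 design)."""
    design = maximin_lhs(DesignSpec(n_points=150, seed=S2_DATASET_SEED))
    return build_training_dataset(design, s1_curve=600.0, grid=CurveGrid())


@pytest.fixture(scope="session")
def erp_dataset():
    """Simulated ERP(S1) training dataset, S1 350..700 by 50 ms (n=100 design)."""
    design = maximin_lhs(DesignSpec(n_points=100, seed=ERP_DATASET_SEED))
    return build_training_dataset(design, s1_curve=None, erp_s1_list=ERP_S1_LIST)


@pytest.fixture(scope="session")
def rce_cv(s2_dataset):
    return RCE.build(s2_dataset.design, s2_dataset.cv_curves, 3,
                     grid=s2_dataset.grid, seed=101, label="cv", s1_context=600.0)


@pytest.fixture(scope="session")
def rce_apd(s2_dataset):
    return RCE.build(s2_dataset.design, s2_dataset.apd_curves, 3,
                     grid=s2_dataset.grid, seed=202, label="apd", s1_context=600.0)


@pytest.fixture(scope="session")
def rce_erp(erp_dataset):
    return RCE.build(erp_dataset.erp_design, erp_dataset.erp_matrix, 2,
                     grid=erp_dataset.erp_s1_list, seed=303, label="erp")
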