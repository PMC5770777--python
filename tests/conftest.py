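"""Shared fixtures: synthetic cohorts at two scales.

``small_cohort`` keeps unit tests fast; ``default_cohort`` is the
desk-scale generator configuration used by the recovery checks.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mirclock.lmm import kinship_from_pedigree
from mirclock.simulate import SimParams, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    params = SimParams(
        n_families=80,
        n_mirna=40,
        n_mrna=80,
        n_coupled_pairs=12,
        rng_seed=42,
    )
    return simulate_cohort(params)


@pytest.fixture(scope="session")
def default_cohort():
    return simulate_cohort(SimParams(rng_seed=20))


@pytest.fixture(scope="session")
def small_kinship(small_cohort):
    return kinship_from_pedigree(small_cohort.pedigree)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def toy_pedigree(n_children: int = 1) -> pd.DataFrame:
    rows = [
        ("P1", "dad", "0", "0", "male"),
        ("P1", "mom", "0", "0", "female"),
    ]
    for i in range(n_children):
        rows.append(("P1", f"kid{i + 1}", "dad", "mom", "female" if i % 2 else "male"))
    return pd.DataFrame(
        rows, columns=["pedigree_id", "individual_id", "father_id", "mother_id", "sex"]
    )
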