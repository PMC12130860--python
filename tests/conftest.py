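import numpy as np
import pytest

import germdecomp as gd
from germdecomp.io import TrioRecord


@pytest.fixture(scope="session")
def table1():
    return gd.load_table1()


@pytest.fixture(scope="session")
def reference_tree():
    return gd.load_reference_tree()


@pytest.fixture(scope="session")
def table1_selected(table1):
    return gd.select_one_row_per_species(table1, prefer="Wang")


@pytest.fixture(scope="session")
def human_like_trios():
    """A deterministic trio dataset under human-like generating parameters."""
    return gd.simulate_trios(gd.TrioSimConfig(n_trios=200, seed=42))


def make_trio(trio_id="t", AP=30.0, AM=28.0, U=60.0, UP=0.0, UM=0.0, L=2.5e9, dataset="d"):
    UX = U - UP - UM
    return TrioRecord(
        trio_id=trio_id,
        dataset_label=dataset,
        paternal_age=AP,
        maternal_age=AM,
        n_mut_total=U,
        n_paternal_phased=UP,
        n_maternal_phased=UM,
        n_unphased=UX,
        callable_haploid_bp=L,
    )
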