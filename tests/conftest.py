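import numpy as np
import pytest

from clirms.results import Xlsm
from clirms.synthdata import fox1_like, simulate_xlsm_table


def make_xlsm(**kw) -> Xlsm:
    """An Xlsm with sensible defaults, overridable per test."""
    defaults = dict(
        source_file="run.mzXML",
        light_scan=100,
        heavy_scan=101,
        peptide="ELVISLIVESK",
        protein="FOX1",
        position=120,
        rna_composition="U1",
        loss="none",
        adduct_mass_da=324.035867,
        ld_score=25.0,
        mass_error_ppm=1.2,
        is_decoy=False,
        charge=2,
        subscores={"xcorrb": 1.0, "xcorrx": 1.2, "tic": 0.4},
    )
    defaults.update(kw)
    return Xlsm(**defaults)


@pytest.fixture
def xlsm_factory():
    return make_xlsm


@pytest.fixture
def small_table():
    """A small deterministic synthetic XLSM table with truth labels."""
    cfg = fox1_like(seed=11, n_true_targets=60, n_chance_targets=120,
                    n_decoys=120)
    return simulate_xlsm_table(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
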