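import numpy as np
import pytest

from dietshift.data_model import AbundanceTable, Lineage, PairRecord, PairedDesign
from dietshift.synthetic_data import CohortConfig, generate_cohort

LINS = [
    "k__Bacteria;p__Bacteroidetes;c__Bacteroidia;o__Bacteroidales;f__Bacteroidaceae;g__Bacteroides;s__vulgatus",
    "k__Bacteria;p__Bacteroidetes;c__Bacteroidia;o__Bacteroidales;f__Bacteroidaceae;g__Bacteroides;s__dorei",
    "k__Bacteria;p__Firmicutes;c__Clostridia;o__Clostridiales;f__Lachnospiraceae;g__Blautia;s__",
    "k__Bacteria;p__Firmicutes;c__Clostridia;o__Clostridiales;f__Lachnospiraceae;g__;s__",
]


@pytest.fixture
def tiny_table() -> AbundanceTable:
    """3 samples x 4 taxa, counts mode, with classified + unclassified taxa."""
    values = np.array([
        [10.0, 5.0, 20.0, 5.0],
        [0.0, 2.0, 30.0, 8.0],
        [7.0, 7.0, 7.0, 7.0],
    ])
    return AbundanceTable(
        ["sA", "sB", "sC"], list(LINS), values,
        {t: Lineage.parse(t) for t in LINS}, "counts",
    )


@pytest.fixture(scope="session")
def small_cohort():
    """40-subject synthetic cohort for cross-module recovery tests."""
    return generate_cohort(CohortConfig(n_subjects=40, seed=7))


@pytest.fixture(scope="session")
def mixture_cohort():
    """60-subject cohort with 20% planted type mixtures."""
    return generate_cohort(
        CohortConfig(n_subjects=60, seed=7, mixture_fraction=0.2)
    )


def make_design(n):
    return PairedDesign([
        PairRecord(f"S{i}", f"S{i}_B", f"S{i}_A") for i in range(n)
    ])
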