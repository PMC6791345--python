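import warnings

import pytest

from radtrio import load_registry
from radtrio.adapters import load_design_table, make_plate_layout
from radtrio.demux import RemnantSpec


@pytest.fixture(scope="session")
def registry():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return load_registry()


@pytest.fixture(scope="session")
def table():
    return load_design_table()


@pytest.fixture(scope="session")
def design1_spec(table, registry):
    return RemnantSpec.from_design(table, registry, 1, "XbaI", "EcoRI-HF", "NheI")


@pytest.fixture(scope="session")
def puc19_sequence():
    from pathlib import Path

    from Bio import SeqIO

    import radtrio

    path = Path(radtrio.enzymes.bundled_registry_path()).parent / \
        "puc19_synthetic.fasta"
    return str(next(SeqIO.parse(str(path), "fasta")).seq)


@pytest.fixture()
def small_layout(table):
    return make_plate_layout(table, 1, external=("ACGTACGT", "TGCATGCA"),
                             n_rows=2, n_cols=3)
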