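from __future__ import annotations

import numpy as np
import pytest

from exolnc import datasets
from exolnc.seeds import MatureMiRNA


@pytest.fixture(scope="session")
def exosome_table():
    return datasets.load_exosome_table()


@pytest.fixture(scope="session")
def cell_table():
    return datasets.load_cell_table()


@pytest.fixture(scope="session")
def mirna_panel():
    return datasets.load_mirna_panel()


@pytest.fixture(scope="session")
def demo_pwms():
    return datasets.load_demo_pwms()


@pytest.fixture
def rng():
    return np.random.default_rng(20160422)


@pytest.fixture
def write_fasta_file(tmp_path):
    """Write {id: sequence} to a temp FASTA and return its path."""

    def _write(entries: dict[str, str], name: str = "seqs.fasta"):
        path = tmp_path / name
        path.write_text(
            "".join(f">{sid}\n{seq}\n" for sid, seq in entries.items())
        )
        return path

    return _write


def mirna_with_seed(seed: str, mid: str = "syn-miR-x") -> MatureMiRNA:
    """A 22-nt mature miRNA whose positions 2-7 are ``seed``."""
    return MatureMiRNA(mid, "A" + seed + "C" * 15)
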