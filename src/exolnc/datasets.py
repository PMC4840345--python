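"""Bundled example data: the printed common-lncRNA fold-change tables,
a mature-miRNA fixture panel, and a small demo RBP PWM panel."""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .expression import ExpressionTable
from .rbp import PWM, read_pwms
from .seeds import MatureMiRNA, read_mirna_fasta

_DATA = resources.files("exolnc") / "data"


def _path(name: str) -> Path:
    with resources.as_file(_DATA / name) as p:
        return Path(p)


def load_exosome_table() -> ExpressionTable:
    """Fold changes of the lncRNAs enriched in exosomes of all four
    prostate cancer lines (positive = up in exosome)."""
    return ExpressionTable.from_file(_path("exosome_common_foldchange.tsv"))


def load_cell_table() -> ExpressionTable:
    """Fold changes of the lncRNAs enriched in the cells of all four
    lines (negative = up in cell)."""
    return ExpressionTable.from_file(_path("cell_common_foldchange.tsv"))


def load_mirna_panel() -> list[MatureMiRNA]:
    """Mature miRNA fixture panel (see the FASTA header for provenance:
    some flanking sequence is synthetic; seeds follow annotation)."""
    return read_mirna_fasta(_path("mirna_panel_synthetic_flanks.fasta"))


def load_demo_pwms() -> list[PWM]:
    """Illustrative ELAVL1 / RBMX / SFRS1 position-frequency models."""
    return read_pwms(_path("demo_rbp_panel.txt"))
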