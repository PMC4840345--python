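"""Synthetic inputs with the statistical structure the pipeline assumes.

The generators emulate the shape of the real study inputs so every
stage is testable without any download:

* transcript sets — random-composition RNA with log-normally
  distributed lengths (median ~1500 nt, the ballpark of lncRNAs on an
  expression array), with chosen 6-mers planted per transcript at a
  Bernoulli rate.  Planting overwrites bases in place, so the length
  law is exactly preserved and length diagnostics can be tested under a
  known null.
* expression tables — four cell-line columns with a designated enriched
  subset at a stated effect size over a near-1 background, in the
  signed fold-change encoding.
* miRNA panels — random 22-nt matures plus a designated subset whose
  position 2-7 seeds are the reverse complements (optionally with G:U
  wobble substitutions) of chosen planted motifs.

Everything is deterministic under a fixed ``rng_seed``; each generator
returns a truth record for test assertions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .expression import ExpressionTable
from .seeds import MatureMiRNA
from .seqdata import Compartment, TranscriptRecord, TranscriptSet, revcomp

BASES = "ACGU"
DEFAULT_CELL_LINES = ("VCaP", "LNCaP", "DU145", "PC3")


@dataclass
class SimConfig:
    """Design of a synthetic study.

    Defaults mirror the real study's scale where it is known: four
    prostate-line columns, a 26-transcript enriched subset, a
    2578-sequence miRNA panel, lncRNA lengths with median ~1500 nt.
    """

    rng_seed: int = 0
    n_test: int = 300
    n_control: int = 300
    length_median: float = 1500.0
    length_sigma: float = 0.5  # log-space sd of the log-normal length law
    base_composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    # (motif, per-transcript rate in test, rate in control)
    planted_motifs: list[tuple[str, float, float]] = field(default_factory=list)
    n_features: int = 500
    n_enriched: int = 26
    effect_fold: float = 8.0
    background_fold_max: float = 1.5
    cross_line_agreement: float = 1.0
    cell_lines: tuple[str, ...] = DEFAULT_CELL_LINES
    mirna_panel_size: int = 2578
    mirna_length: int = 22

    def __post_init__(self) -> None:
        if abs(sum(self.base_composition) - 1.0) > 1e-9:
            raise ValueError("base_composition must sum to 1")
        for motif, r_test, r_ctrl in self.planted_motifs:
            if not (0 <= r_test <= 1 and 0 <= r_ctrl <= 1):
                raise ValueError(f"planting rates for {motif} must be in [0, 1]")
        if self.effect_fold <= 1:
            raise ValueError("effect_fold must be > 1")
        if self.n_enriched > self.n_features:
            raise ValueError("n_enriched > n_features")


def _random_sequences(rng: np.random.Generator, cfg: SimConfig, n: int) -> list[str]:
    mu = math.log(cfg.length_median)
    lengths = np.maximum(
        np.exp(rng.normal(mu, cfg.length_sigma, size=n)).astype(int), 50
    )
    return [
        "".join(rng.choice(list(BASES), size=ln, p=list(cfg.base_composition)))
        for ln in lengths
    ]


def generate_transcript_sets(
    cfg: SimConfig,
) -> tuple[TranscriptSet, TranscriptSet, dict]:
    """Random test and control transcript sets with planted motifs.

    Each planted motif is written (overwriting, never inserting) at a
    uniform random position of each transcript with the configured
    per-set Bernoulli rate.  The truth record maps set label ->
    transcript id -> list of (motif, 0-based position).
    """
    rng = np.random.default_rng(cfg.rng_seed)
    truth: dict = {"test": {}, "control": {}}
    sets = []
    for label, n, compartment in (
        ("test", cfg.n_test, Compartment.EXOSOME),
        ("control", cfg.n_control, Compartment.CELL),
    ):
        records = []
        seqs = _random_sequences(rng, cfg, n)
        for i, seq in enumerate(seqs):
            tid = f"{label}_{i:04d}"
            planted: list[tuple[str, int]] = []
            for motif, r_test, r_ctrl in cfg.planted_motifs:
                rate = r_test if label == "test" else r_ctrl
                if len(motif) > len(seq):
                    raise ValueError(f"motif {motif} longer than transcript {tid}")
                if rng.random() < rate:
                    pos = int(rng.integers(0, len(seq) - len(motif) + 1))
                    seq = seq[:pos] + motif + seq[pos + len(motif) :]
                    planted.append((motif, pos))
            if planted:
                truth[label][tid] = planted
            records.append(
                TranscriptRecord(tid, seq, compartment=compartment, cell_line="sim")
            )
        sets.append(TranscriptSet(records, label=label, provenance="synthetic"))
    return sets[0], sets[1], truth


def generate_expression(cfg: SimConfig) -> tuple[ExpressionTable, set[str]]:
    """Signed fold-change table with a planted enriched subset.

    Enriched features get fold change effect_fold x lognormal(0, 0.2)
    noise (> 2 by construction when effect_fold >= 4); background
    features get |fold change| drawn uniformly in
    [1, background_fold_max] with random sign.  cross_line_agreement is
    the probability that an enriched feature is enriched in each cell
    line beyond the first; misses fall back to background behaviour, so
    agreement < 1 erodes the Venn intersection.
    """
    rng = np.random.default_rng(cfg.rng_seed + 1)
    ids = [f"lnc{i:04d}" for i in range(cfg.n_features)]
    enriched = set(
        rng.choice(ids, size=cfg.n_enriched, replace=False).tolist()
    )
    data = {}
    for j, line in enumerate(cfg.cell_lines):
        col = np.empty(cfg.n_features)
        for i, fid in enumerate(ids):
            is_enriched = fid in enriched and (
                j == 0 or rng.random() < cfg.cross_line_agreement
            )
            if is_enriched:
                col[i] = cfg.effect_fold * rng.lognormal(0.0, 0.2)
            else:
                mag = rng.uniform(1.0, cfg.background_fold_max)
                col[i] = mag if rng.random() < 0.5 else -mag
        data[line] = col
    frame = pd.DataFrame(data, index=ids)
    return ExpressionTable(frame, kind="lncRNA"), enriched


def generate_mirna_panel(
    cfg: SimConfig,
    target_motifs: Sequence[str] = (),
    wobbles_per_seed: int = 0,
) -> tuple[list[MatureMiRNA], dict[str, str]]:
    """Random mature miRNAs plus one constructed responder per target motif.

    Responder i has its positions 2-7 set to the reverse complement of
    target_motifs[i], optionally with ``wobbles_per_seed`` G:U
    substitutions (seed G -> U or seed U -> G at wobble-compatible
    positions).  Returns the panel and a truth map motif -> responder id.
    """
    rng = np.random.default_rng(cfg.rng_seed + 2)
    panel: list[MatureMiRNA] = []
    truth: dict[str, str] = {}
    for i, motif in enumerate(target_motifs):
        seed = revcomp(motif)
        if wobbles_per_seed:
            seed = _wobble_seed(seed, wobbles_per_seed, rng)
        flanks = rng.choice(list(BASES), size=cfg.mirna_length)
        seq = flanks[0] + seed + "".join(flanks[7:])
        mid = f"syn-miR-{i:03d}-5p"
        panel.append(MatureMiRNA(mid, seq))
        truth[motif] = mid
    n_decoys = max(cfg.mirna_panel_size - len(panel), 0)
    for i in range(n_decoys):
        seq = "".join(rng.choice(list(BASES), size=cfg.mirna_length))
        panel.append(MatureMiRNA(f"syn-decoy-{i:04d}", seq))
    return panel, truth


def _wobble_seed(seed: str, n_wobbles: int, rng) -> str:
    """Substitute up to n_wobbles seed positions so WC pairs become wobbles.

    With seed = revcomp(motif), a seed A faces a motif U (A->G makes a
    U:G wobble) and a seed C faces a motif G (C->U makes a G:U wobble);
    both substitutions keep every duplex position legal.  Only A/C
    positions qualify, so fewer than n_wobbles may be applied on
    G/U-rich seeds.
    """
    chars = list(seed)
    candidates = [i for i, c in enumerate(chars) if c in "AC"]
    rng.shuffle(candidates)
    for i in candidates[:n_wobbles]:
        chars[i] = "G" if chars[i] == "A" else "U"
    return "".join(chars)
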