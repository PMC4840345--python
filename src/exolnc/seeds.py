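"""Wobble-aware matching of enriched motifs to miRNA seed regions.

A motif (a hexamer on the lncRNA, i.e. target, strand) matches a miRNA
when it pairs antiparallel with the miRNA's seed region — mature
positions 2-7 by convention — with every position forming either a
Watson-Crick pair (A:U, U:A, C:G, G:C) or a G:U wobble.  No bulges,
gaps or mismatches are tolerated.  Because both strands of a G:U pair
are chemically equivalent, wobbles are accepted in both orientations
(target G : miRNA U and target U : miRNA G).  The number of wobbles per
match is unlimited but reported, so stricter post-filters can be
applied downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

from .motifs import EnrichedMotif
from .seqdata import normalize_rna

WATSON_CRICK = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C")}
WOBBLE = {("G", "U"), ("U", "G")}

SEED_START_DEFAULT = 2  # 1-based mature position
SEED_LEN_DEFAULT = 6


@dataclass
class MatureMiRNA:
    """A mature miRNA sequence, 5'->3', with a miRBase-style id."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        self.sequence = normalize_rna(self.sequence)

    def seed(
        self, seed_start: int = SEED_START_DEFAULT, seed_len: int = SEED_LEN_DEFAULT
    ) -> str:
        return seed_region(self, seed_start, seed_len)


def seed_region(
    mirna: MatureMiRNA,
    seed_start: int = SEED_START_DEFAULT,
    seed_len: int = SEED_LEN_DEFAULT,
) -> str:
    """The seed substring, 1-based inclusive positions seed_start..seed_start+seed_len-1."""
    end = seed_start + seed_len - 1
    if len(mirna.sequence) < end:
        raise ValueError(
            f"miRNA {mirna.id} too short ({len(mirna.sequence)} nt) for seed "
            f"positions {seed_start}-{end}"
        )
    return mirna.sequence[seed_start - 1 : end]


@dataclass
class SeedMatch:
    """A motif/miRNA pair in which every duplex position is WC or wobble."""

    motif: str
    mirna_id: str
    pairings: list[str]  # per motif position, 'WC' or 'wobble'
    wobble_count: int


def is_seed_match(
    motif: str,
    mirna: MatureMiRNA,
    allow_wobble: bool = True,
    seed_start: int = SEED_START_DEFAULT,
    seed_len: int = SEED_LEN_DEFAULT,
) -> SeedMatch | None:
    """Test whether ``motif`` pairs perfectly with the miRNA seed.

    The motif is aligned antiparallel to the seed: motif position i
    (1-based) pairs seed position seed_len+1-i.  Returns a
    :class:`SeedMatch` or None.
    """
    seed = seed_region(mirna, seed_start, seed_len)
    if len(motif) != seed_len:
        raise ValueError(f"motif length {len(motif)} != seed length {seed_len}")
    pairings: list[str] = []
    wobbles = 0
    for i, m_base in enumerate(motif):
        s_base = seed[seed_len - 1 - i]
        pair = (m_base, s_base)
        if pair in WATSON_CRICK:
            pairings.append("WC")
        elif allow_wobble and pair in WOBBLE:
            pairings.append("wobble")
            wobbles += 1
        else:
            return None
    return SeedMatch(motif, mirna.id, pairings, wobbles)


def read_mirna_fasta(path: str | Path) -> list[MatureMiRNA]:
    """Read a miRBase-style mature FASTA.

    The id is the header token beginning 'hsa-' if present, else the
    full first token (miRBase headers carry accession and species name
    after the id).
    """
    mirnas: list[MatureMiRNA] = []
    # fasta-pearson tolerates the ';' comment lines miRBase-style files carry
    for entry in SeqIO.parse(str(path), "fasta-pearson"):
        tokens = entry.description.split()
        name = next((t for t in tokens if t.startswith("hsa-")), tokens[0])
        mirnas.append(MatureMiRNA(name, str(entry.seq)))
    if not mirnas:
        raise ValueError(f"no miRNA sequences in {path}")
    return mirnas


@dataclass
class MotifSeedReport:
    """map_motifs output: matches grouped per motif plus the discards."""

    matches: dict[str, list[SeedMatch]] = field(default_factory=dict)
    no_seed_motifs: list[str] = field(default_factory=list)

    def distinct_sequence_counts(
        self, mirna_db: Sequence[MatureMiRNA]
    ) -> dict[str, int]:
        """Per motif, the number of distinct mature sequences matched
        (duplicate listings under different ids collapse to one)."""
        seq_of = {m.id: m.sequence for m in mirna_db}
        return {
            motif: len({seq_of[sm.mirna_id] for sm in sms})
            for motif, sms in self.matches.items()
        }


def map_motifs(
    motifs: Sequence[EnrichedMotif | str],
    mirna_db: Sequence[MatureMiRNA],
    allow_wobble: bool = True,
    seed_start: int = SEED_START_DEFAULT,
    seed_len: int = SEED_LEN_DEFAULT,
) -> MotifSeedReport:
    """Match every enriched motif against every miRNA seed.

    Motifs without any seed match are dropped from the enriched list and
    reported separately; matches are counted per miRNA id (ids sharing a
    mature sequence each appear).
    """
    if not mirna_db:
        raise ValueError("empty miRNA database")
    report = MotifSeedReport()
    for em in motifs:
        motif = em.motif if isinstance(em, EnrichedMotif) else em
        hits = [
            sm
            for mirna in mirna_db
            if (sm := is_seed_match(motif, mirna, allow_wobble, seed_start, seed_len))
        ]
        if hits:
            report.matches[motif] = hits
        else:
            report.no_seed_motifs.append(motif)
    return report


@dataclass
class CrosslinkRow:
    motif: str
    mirna_id: str | None
    fold_change: float | None  # None rendered as 'NA-expression'


def crosslink_expression(
    report: MotifSeedReport,
    overexpressed: Mapping[str, float],
) -> list[CrosslinkRow]:
    """Join seed matches with the over-expressed miRNA set.

    Per motif, one row per matched miRNA that is also over-expressed,
    carrying its fold change; motifs whose matches all fall outside the
    over-expressed set get a single NA-expression row.
    """
    rows: list[CrosslinkRow] = []
    for motif, matches in report.matches.items():
        hit_any = False
        for sm in matches:
            if sm.mirna_id in overexpressed:
                rows.append(CrosslinkRow(motif, sm.mirna_id, overexpressed[sm.mirna_id]))
                hit_any = True
        if not hit_any:
            rows.append(CrosslinkRow(motif, None, None))
    return rows
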