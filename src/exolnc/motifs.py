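"""Exhaustive k-mer enrichment between a test and a control transcript set.

The enrichment call works on raw occurrence counts.  A sliding window
of length k (default 6, the length of a miRNA seed) scans every
transcript in each set; windows containing N are skipped.  Four
filters are then applied in order:

1. singleton filter  — a k-mer counted exactly once in a set is removed
   from that set's map (so a motif at 5 vs 1 becomes 5 vs 0);
2. equal-frequency filter — motifs with identical counts in both sets
   are discarded;
3. direction filter  — only motifs more frequent in the test set are kept;
4. z-score filter    — the count difference of each survivor is z-scored
   against the survivor difference distribution and motifs at z >= z_cut
   (default 3, one-sided normal confidence ~0.999) are reported.

Counts are raw totals per set, not per-transcript presence and not
length-normalised; an optional ``normalize_counts`` mode divides by the
total number of windows per set for grossly unequal set sizes.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .seqdata import RNA_ALPHABET, TranscriptSet


@dataclass
class MotifConfig:
    k: int = 6
    z_cut: float = 3.0
    drop_singletons: bool = True
    normalize_counts: bool = False

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.z_cut <= 0:
            raise ValueError("z_cut must be > 0")


@dataclass
class EnrichedMotif:
    """A k-mer enriched in the test (exosomal) set.

    diff is count_test - count_control; z is the z-score of diff within
    the difference distribution of all motifs surviving filters 1-3.
    """

    motif: str
    count_test: int
    count_control: int
    diff: float
    z: float


def count_kmers(transcripts: TranscriptSet | Iterable[str], k: int = 6) -> Counter:
    """Occurrence counts of every length-k window over all sequences.

    Overlapping windows all count; windows containing N are skipped;
    sequences shorter than k contribute nothing.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    counts: Counter = Counter()
    seqs = (
        transcripts.sequences()
        if isinstance(transcripts, TranscriptSet)
        else list(transcripts)
    )
    for seq in seqs:
        n = len(seq)
        if n < k:
            continue
        if "N" not in seq:
            counts.update(seq[i : i + k] for i in range(n - k + 1))
        else:
            # restart the scan after each N rather than testing every window
            start = 0
            while start < n:
                nxt = seq.find("N", start)
                end = n if nxt == -1 else nxt
                if end - start >= k:
                    counts.update(seq[i : i + k] for i in range(start, end - k + 1))
                start = end + 1
    return counts


def total_windows(transcripts: TranscriptSet | Iterable[str], k: int = 6) -> int:
    """Number of N-free windows of length k (the denominator for rates)."""
    return sum(count_kmers(transcripts, k).values())


@dataclass
class FilterTrace:
    """Per-filter motif counts, mirroring the cascade for run reports."""

    n_test_kmers: int = 0
    n_control_kmers: int = 0
    n_after_singleton: int = 0
    n_after_equal: int = 0
    n_after_direction: int = 0
    n_enriched: int = 0


def enrich_motifs(
    test_counts: Mapping[str, int],
    control_counts: Mapping[str, int],
    cfg: MotifConfig | None = None,
    trace: FilterTrace | None = None,
) -> list[EnrichedMotif]:
    """Apply the filter cascade and return enriched motifs.

    Result is sorted by z descending, ties broken lexicographically by
    motif, so identical inputs give byte-identical reports.  Raises if
    fewer than three motifs survive filters 1-3 (the difference
    distribution is then too small to z-score).
    """
    cfg = cfg or MotifConfig()
    bad = [m for m in list(test_counts) + list(control_counts) if len(m) != cfg.k]
    if bad:
        raise ValueError(f"k-mer length mismatch, expected k={cfg.k}: {bad[:3]}")

    test = dict(test_counts)
    ctrl = dict(control_counts)
    if trace is not None:
        trace.n_test_kmers = len(test)
        trace.n_control_kmers = len(ctrl)

    if cfg.drop_singletons:
        test = {m: c for m, c in test.items() if c != 1}
        ctrl = {m: c for m, c in ctrl.items() if c != 1}
    if trace is not None:
        trace.n_after_singleton = len(test)

    if cfg.normalize_counts:
        t_tot = sum(test.values()) or 1
        c_tot = sum(ctrl.values()) or 1
        value = lambda m: (test.get(m, 0) / t_tot, ctrl.get(m, 0) / c_tot)  # noqa: E731
    else:
        value = lambda m: (test.get(m, 0), ctrl.get(m, 0))  # noqa: E731

    survivors = []
    for motif in test:
        t, c = value(motif)
        if t == c:
            continue  # equal-frequency filter
        survivors.append(motif)
    if trace is not None:
        trace.n_after_equal = len(survivors)

    survivors = [m for m in survivors if value(m)[0] > value(m)[1]]
    if trace is not None:
        trace.n_after_direction = len(survivors)

    if not survivors:
        # e.g. identical sets: every motif is equal-frequency
        return []
    if len(survivors) < 3:
        raise ValueError("diff distribution too small for z-scores")

    diffs = np.array([value(m)[0] - value(m)[1] for m in survivors], dtype=float)
    sd = diffs.std(ddof=1)
    if sd == 0:
        raise ValueError("all surviving motifs have identical diffs; z undefined")
    zs = (diffs - diffs.mean()) / sd

    enriched = [
        EnrichedMotif(
            motif=m,
            count_test=test_counts.get(m, 0),
            count_control=control_counts.get(m, 0),
            diff=float(d),
            z=float(z),
        )
        for m, d, z in zip(survivors, diffs, zs)
        if z >= cfg.z_cut
    ]
    enriched.sort(key=lambda em: (-em.z, em.motif))
    if trace is not None:
        trace.n_enriched = len(enriched)
    return enriched


def enrich_from_sets(
    test_set: TranscriptSet,
    control_set: TranscriptSet,
    cfg: MotifConfig | None = None,
    trace: FilterTrace | None = None,
) -> list[EnrichedMotif]:
    """Count k-mers in both sets and run the enrichment cascade."""
    cfg = cfg or MotifConfig()
    return enrich_motifs(
        count_kmers(test_set, cfg.k),
        count_kmers(control_set, cfg.k),
        cfg,
        trace=trace,
    )
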