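"""PWM scanning of transcript sets for RNA-binding-protein sites.

A PWM is a 4 x L column-stochastic matrix over (A, C, G, U); matrices
written as counts or DNA-alphabet frequencies (T row) are accepted and
normalised on load with a small pseudocount.  A window of length L is
scored as the sum of log column probabilities, min-max rescaled to
[0, 1] between the worst and best attainable windows ("relative
score"); a window is a hit when its relative score reaches the
threshold (default 0.8, the RBPDB web default).  Degenerate matrices in
which every window attains the same score score 1.0 by convention.

The text format is one matrix per block::

    >ELAVL1
    A  0.30 0.35 ...
    C  0.10 ...
    G  0.10 ...
    U  0.50 ...

Rows may be labelled ``A:``/``A``; blocks are separated by the next
``>`` header or a blank line.  RBPDB matrix downloads convert to this
shape by prefixing the protein name as the header.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from statsmodels.stats.rates import test_poisson_2indep

from .seqdata import TranscriptSet

ROW_ORDER = "ACGU"
DEFAULT_THRESHOLD = 0.8
DEFAULT_PSEUDOCOUNT = 0.01

_BASE_INDEX = {b: i for i, b in enumerate(ROW_ORDER)}


@dataclass
class PWM:
    """A position frequency matrix for one RBP, columns normalised to 1."""

    rbp_name: str
    matrix: np.ndarray  # shape (4, L), rows A, C, G, U
    pseudocount: float = DEFAULT_PSEUDOCOUNT

    def __post_init__(self) -> None:
        mat = np.asarray(self.matrix, dtype=float)
        if mat.ndim != 2 or mat.shape[0] != 4:
            raise ValueError("matrix must be 4 x L")
        if mat.shape[1] < 4:
            raise ValueError("PWM must have length >= 4")
        if (mat < 0).any():
            raise ValueError("negative PWM entries")
        colsums = mat.sum(axis=0, keepdims=True)
        if (colsums == 0).any():
            raise ValueError("PWM has an all-zero column")
        # normalise first so counts and frequencies are interchangeable,
        # then apply the pseudocount
        mat = mat / colsums + self.pseudocount
        self.matrix = mat / mat.sum(axis=0, keepdims=True)
        self._logp = np.log(self.matrix)

    @property
    def length(self) -> int:
        return int(self.matrix.shape[1])

    @property
    def consensus(self) -> str:
        return "".join(ROW_ORDER[i] for i in self.matrix.argmax(axis=0))


def read_pwms(path: str | Path, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> list[PWM]:
    """Parse the block text format described in the module docstring."""
    pwms: list[PWM] = []
    name: str | None = None
    rows: dict[str, list[float]] = {}

    def flush() -> None:
        nonlocal name, rows
        if name is None:
            return
        missing = [b for b in "ACG" if b not in rows] + (
            [] if ("U" in rows or "T" in rows) else ["U"]
        )
        if missing:
            raise ValueError(f"PWM {name}: missing rows {missing}")
        u_row = rows.get("U", rows.get("T"))
        lengths = {len(r) for r in (rows["A"], rows["C"], rows["G"], u_row)}
        if len(lengths) != 1:
            raise ValueError(f"PWM {name}: row-length mismatch")
        mat = np.array([rows["A"], rows["C"], rows["G"], u_row], dtype=float)
        pwms.append(PWM(name, mat, pseudocount))
        name, rows = None, {}

    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith(">"):
            flush()
            name = line[1:].strip().split()[0]
            continue
        tokens = line.replace(":", " ").replace("|", " ").split()
        base = tokens[0].upper()
        if base not in "ACGTU":
            raise ValueError(f"unrecognised PWM row label: {tokens[0]!r}")
        rows[base] = [float(t) for t in tokens[1:]]
    flush()
    if not pwms:
        raise ValueError(f"no PWMs in {path}")
    return pwms


def relative_score(pwm: PWM, window: str) -> float:
    """Min-max normalised log-probability score of one window in [0, 1]."""
    if len(window) != pwm.length:
        raise ValueError(f"window length {len(window)} != PWM length {pwm.length}")
    try:
        idx = [_BASE_INDEX[b] for b in window]
    except KeyError as exc:
        raise ValueError(f"window contains non-ACGU character: {exc}") from exc
    logp = pwm._logp
    s = float(logp[idx, range(pwm.length)].sum())
    s_min = float(logp.min(axis=0).sum())
    s_max = float(logp.max(axis=0).sum())
    if s_max == s_min:
        return 1.0
    return (s - s_min) / (s_max - s_min)


@dataclass
class RBPHit:
    transcript_id: str
    rbp_name: str
    start: int  # 1-based position of the window
    rel_score: float


def scan_sequence(sequence: str, pwm: PWM, threshold: float) -> list[tuple[int, float]]:
    """(1-based start, score) of every window at rel_score >= threshold.

    Vectorised over windows: per-column log-probabilities are gathered
    with a stride trick; N-containing windows are skipped.
    """
    L = pwm.length
    n = len(sequence)
    if n < L:
        return []
    codes = np.array([_BASE_INDEX.get(b, -1) for b in sequence], dtype=np.int64)
    wins = np.lib.stride_tricks.sliding_window_view(codes, L)
    valid = (wins >= 0).all(axis=1)
    if not valid.any():
        return []
    logp = pwm._logp
    s_min = logp.min(axis=0).sum()
    s_max = logp.max(axis=0).sum()
    scores = np.full(wins.shape[0], -np.inf)
    vw = wins[valid]
    scores[valid] = logp[vw, np.arange(L)].sum(axis=1)
    if s_max == s_min:
        rel = np.where(valid, 1.0, -np.inf)
    else:
        rel = (scores - s_min) / (s_max - s_min)
    hits = np.nonzero(rel >= threshold)[0]
    return [(int(i) + 1, float(rel[i])) for i in hits]


def scan_set(
    tset: TranscriptSet,
    pwms: Sequence[PWM],
    threshold: float = DEFAULT_THRESHOLD,
) -> tuple[list[RBPHit], dict[str, int]]:
    """Score every window of every transcript against every PWM.

    Returns the hit list and per-RBP hit totals over the set (RBPs with
    zero hits are present with count 0).
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    hits: list[RBPHit] = []
    counts: dict[str, int] = {p.rbp_name: 0 for p in pwms}
    for rec in tset:
        for pwm in pwms:
            for start, score in scan_sequence(rec.sequence, pwm, threshold):
                hits.append(RBPHit(rec.id, pwm.rbp_name, start, score))
                counts[pwm.rbp_name] += 1
    return hits, counts


@dataclass
class RBPComparison:
    rbp_name: str
    count_test: int
    count_control: int
    rate_test: float
    rate_control: float
    rate_ratio: float  # inf when the control rate is zero
    p_value: float


def compare_rbp_counts(
    counts_test: Mapping[str, int],
    counts_control: Mapping[str, int],
    transcripts_test: int,
    transcripts_control: int,
) -> list[RBPComparison]:
    """Per-RBP site-rate comparison between the two compartments.

    Totals are treated as Poisson counts with the number of transcripts
    as exposure; the two-sided p-value comes from a Poisson rate-ratio
    test.  RBPs present on only one side are included with zero on the
    other.
    """
    if transcripts_test < 1 or transcripts_control < 1:
        raise ValueError("transcript counts must be positive")
    out: list[RBPComparison] = []
    for name in sorted(set(counts_test) | set(counts_control)):
        ct = int(counts_test.get(name, 0))
        cc = int(counts_control.get(name, 0))
        rt = ct / transcripts_test
        rc = cc / transcripts_control
        ratio = float("inf") if rc == 0 and rt > 0 else (rt / rc if rc else float("nan"))
        if ct == 0 and cc == 0:
            p = 1.0
        else:
            res = test_poisson_2indep(
                ct, transcripts_test, cc, transcripts_control, method="score"
            )
            p = float(res.pvalue)
        out.append(RBPComparison(name, ct, cc, rt, rc, ratio, p))
    return out


def motif_is_binding_site(
    motif: str, pwm: PWM, threshold: float = DEFAULT_THRESHOLD
) -> bool:
    """Whether a short motif can sit inside a PWM site at the threshold.

    The motif is slid over every offset of the PWM; at each offset the
    overlapped columns are scored with their own min-max normalisation.
    A motif shorter than the PWM counts as a binding site when some
    offset reaches the threshold.
    """
    k = len(motif)
    if k > pwm.length:
        return False
    idx = [_BASE_INDEX.get(b, -1) for b in motif]
    if any(i < 0 for i in idx):
        return False
    logp = pwm._logp
    for off in range(pwm.length - k + 1):
        cols = range(off, off + k)
        s = sum(logp[i, c] for i, c in zip(idx, cols))
        s_min = logp[:, off : off + k].min(axis=0).sum()
        s_max = logp[:, off : off + k].max(axis=0).sum()
        rel = 1.0 if s_max == s_min else (s - s_min) / (s_max - s_min)
        if rel >= threshold:
            return True
    return False
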