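"""Pseudo-attB motif construction and FIMO-style genome scanning.

Observed pseudo-attB windows are already aligned — every one is anchored on
its core GT — so the motif is simply the position frequency matrix of the
aligned columns; no EM-style motif discovery is needed.  The default motif
width is 34 (one column trimmed from each end of the 36 nt minimal window),
centred on the core GT at motif positions 17–18.

Scoring is standard log-odds against a 0-order background.  P-values are
exact under that background: per-column score distributions are discretized
to integer bins and convolved by dynamic programming, giving the tail
probability of every attainable score — the same construction FIMO uses.
Scanning slides the motif over both strands (wrapping on circular genomes)
and reports hits below a p-value threshold (default 1e-8).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .att_model import AttWindow, revcomp
from .io_formats import SequenceRecord

__all__ = ["MotifModel", "ScoreDistribution", "MotifHit",
           "build_motif", "exact_pvalues", "scan_genome"]

_CODE = {b: i for i, b in enumerate("ACGT")}


@dataclass(frozen=True)
class MotifModel:
    """Position frequency / log-odds model of the pseudo-attB motif.

    ``counts`` is a (width, 4) matrix over A,C,G,T.  Probabilities include a
    background-distributed pseudocount:
    ``p = (count + pseudocount·background) / (nsites + pseudocount)``;
    log-odds are ``log2(p / background)`` (bits).
    """

    counts: np.ndarray
    background: np.ndarray
    pseudocount: float = 0.5
    nsites: float | None = None
    core_columns: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, float)
        if counts.ndim != 2 or counts.shape[1] != 4:
            raise ValueError("counts must be a (width, 4) matrix")
        object.__setattr__(self, "counts", counts)
        bg = np.asarray(self.background, float)
        if abs(bg.sum() - 1.0) > 1e-9 or (bg <= 0).any():
            raise ValueError("background must be positive and sum to 1")
        object.__setattr__(self, "background", bg)
        if self.nsites is None:
            object.__setattr__(self, "nsites", float(counts[0].sum()))

    @property
    def width(self) -> int:
        return self.counts.shape[0]

    @property
    def probabilities(self) -> np.ndarray:
        return ((self.counts + self.pseudocount * self.background)
                / (self.nsites + self.pseudocount))

    @property
    def log_odds(self) -> np.ndarray:
        return np.log2(self.probabilities / self.background)

    @property
    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.counts.argmax(axis=1))

    def information_content(self) -> np.ndarray:
        """Per-column information content Σ f·log2(f/b) (bits)."""
        p = self.probabilities
        return (p * np.log2(p / self.background)).sum(axis=1)

    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    def score(self, sequence: str) -> float:
        """Log-odds score of one width-length sequence (bits)."""
        if len(sequence) != self.width:
            raise ValueError("sequence length must equal motif width")
        lo = self.log_odds
        return float(sum(lo[j, _CODE[b]] for j, b in enumerate(sequence.upper())))


@dataclass(frozen=True)
class ScoreDistribution:
    """Exact null distribution of discretized motif scores.

    Scores are integer bins of width ``granularity`` bits; ``pmf[i]`` is the
    background probability of bin ``min_bin + i`` and ``tail[i]`` the
    probability of a score ≥ that bin.
    """

    granularity: float
    min_bin: int
    pmf: np.ndarray
    tail: np.ndarray

    @property
    def min_pvalue(self) -> float:
        return float(self.tail[-1])

    def pvalue(self, score_bin: int) -> float:
        """Tail probability P(score ≥ score_bin) under the background."""
        i = score_bin - self.min_bin
        if i <= 0:
            return 1.0
        if i >= len(self.tail):
            return self.min_pvalue
        return float(self.tail[i])


@dataclass(frozen=True)
class MotifHit:
    """One motif occurrence on a genome (start is 1-based, forward strand)."""

    genome_id: str
    start: int
    strand: str
    score: float
    p_value: float
    sequence: str


def build_motif(windows: Sequence[AttWindow], pseudocount: float = 0.5,
                background: np.ndarray | None = None,
                width: int = 34) -> MotifModel:
    """Build the pseudo-attB motif from GT-anchored windows.

    All windows must share width and core index and there must be at least
    two.  The default trims one column from each end of 36 nt windows to
    yield the 34-column motif centred on the core GT (motif positions 17-18,
    offsets −16…+16 from the core).  Non-ACGT characters contribute to no
    column.
    """
    if len(windows) < 2:
        raise ValueError("motif construction needs at least 2 windows")
    w0 = windows[0]
    for w in windows:
        if len(w.sequence) != len(w0.sequence) or w.arm_left != w0.arm_left:
            raise ValueError("windows differ in width or core index")
    full = len(w0.sequence)
    if not (2 <= width <= full) or (full - width) % 2:
        raise ValueError(f"cannot trim width-{full} windows symmetrically to {width}")
    trim = (full - width) // 2
    counts = np.zeros((width, 4))
    for w in windows:
        for j, b in enumerate(w.sequence[trim:full - trim].upper()):
            if b in _CODE:
                counts[j, _CODE[b]] += 1
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    core = w0.arm_left - trim
    return MotifModel(counts=counts, background=bg, pseudocount=pseudocount,
                      nsites=float(len(windows)), core_columns=(core, core + 1))


def exact_pvalues(motif: MotifModel, granularity: float = 1e-3) -> ScoreDistribution:
    """Exact tail probabilities of discretized motif scores.

    Log-odds are rounded to integer bins of ``granularity`` bits; the total-
    score pmf is the convolution over positions of the per-column bin
    distributions under the background model.  P-values are conservative to
    ±1 bin of the discretization.
    """
    if granularity <= 0:
        raise ValueError("granularity must be positive")
    bins = np.rint(motif.log_odds / granularity).astype(np.int64)  # (w, 4)
    bg = motif.background
    min_bin = int(bins.min(axis=1).sum())
    max_bin = int(bins.max(axis=1).sum())
    pmf = np.zeros(max_bin - min_bin + 1)
    # DP over columns; offset of pmf index 0 tracks the running minimum
    cur = np.array([1.0])
    cur_min = 0
    for j in range(motif.width):
        col_min = int(bins[j].min())
        col_max = int(bins[j].max())
        nxt = np.zeros(len(cur) + col_max - col_min)
        for b in range(4):
            shift = int(bins[j, b]) - col_min
            nxt[shift:shift + len(cur)] += bg[b] * cur
        cur = nxt
        cur_min += col_min
    pmf[cur_min - min_bin: cur_min - min_bin + len(cur)] = cur
    tail = np.cumsum(pmf[::-1])[::-1]
    return ScoreDistribution(granularity=granularity, min_bin=min_bin,
                             pmf=pmf, tail=tail)


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    code = np.full(256, 4, dtype=np.int8)
    for b, i in _CODE.items():
        code[ord(b)] = i
        code[ord(b.lower())] = i
    return code[arr].astype(np.int64)


def _scan_strand(seq: str, bins: np.ndarray) -> np.ndarray:
    """Integer window scores for every start position of one strand."""
    w = bins.shape[0]
    code = _encode(seq)
    n = len(code) - w + 1
    if n <= 0:
        return np.zeros(0, dtype=np.int64)
    # non-ACGT → sentinel column scoring far below any attainable bin
    bins_ext = np.hstack([bins, np.full((w, 1), -(1 << 40), dtype=np.int64)])
    scores = np.zeros(n, dtype=np.int64)
    for j in range(w):
        scores += bins_ext[j, code[j:j + n]]
    return scores


def scan_genome(genome: SequenceRecord, motif: MotifModel,
                score_dist: ScoreDistribution | None = None,
                threshold: float = 1e-8, strands: str = "both",
                require_core: bool = False,
                granularity: float = 1e-3) -> list[MotifHit]:
    """Scan a genome for motif occurrences with p ≤ threshold.

    Both strands are scanned by default; circular genomes wrap across the
    origin.  Overlapping opposite-strand hits are both reported.  With
    ``require_core`` only windows carrying GT at the motif's core columns
    are eligible (the scan itself, like FIMO, does not require it).
    Hits are sorted by (start, strand).
    """
    if score_dist is None:
        score_dist = exact_pvalues(motif, granularity)
    w = motif.width
    seq = genome.sequence.upper()
    L = len(seq)
    if L < w:
        raise ValueError("genome shorter than motif width")
    bins = np.rint(motif.log_odds / score_dist.granularity).astype(np.int64)
    n_pos = L if genome.circular else L - w + 1
    ext = seq + seq[:w - 1] if genome.circular else seq

    # smallest score bin whose tail probability passes the threshold
    passing = np.nonzero(score_dist.tail <= threshold)[0]
    cutoff_bin = (score_dist.min_bin + int(passing[0])) if len(passing) \
        else np.iinfo(np.int64).max

    strand_list = {"both": ["+", "-"], "+": ["+"], "-": ["-"]}[strands]
    hits: list[MotifHit] = []
    for strand in strand_list:
        target = ext if strand == "+" else revcomp(ext)
        scores = _scan_strand(target, bins)[:n_pos]
        for i in np.nonzero(scores >= cutoff_bin)[0]:
            p = score_dist.pvalue(int(scores[i]))
            window = target[i:i + w]
            if require_core and motif.core_columns is not None:
                c = motif.core_columns[0]
                if window[c:c + 2] != "GT":
                    continue
            if strand == "+":
                start = int(i)
            else:
                start = (len(ext) - w - int(i)) % L if genome.circular \
                    else len(ext) - w - int(i)
            hits.append(MotifHit(genome_id=genome.id, start=start + 1,
                                 strand=strand,
                                 score=float(scores[i] * score_dist.granularity),
                                 p_value=p, sequence=window))
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits
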