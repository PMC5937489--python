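"""Core data model and arithmetic for serine-integrase attachment (att) sites.

Large serine integrases such as the one from phage ΦBT1 recombine a phage
attachment site (attP) with a bacterial attachment site (attB).  Both sites
are short imperfect inverted repeats surrounding a central crossover
dinucleotide (GT for ΦBT1); integration joins the left arm of attB to the
right arm of attP (attL) and the left arm of attP to the right arm of attB
(attR), duplicating the shared core once into each product.

Everything in this module is anchored on that core: windows are extracted
around the G of the core GT, cross-sequence identity is counted by
superposing the cores with no gaps or shifting, and integration products are
reconstructed by arm exchange around the core.  Gapped alignment is never
performed — observed pseudo-attB integration is precise, with no insertions
or deletions at the target.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "CanonicalAttSet",
    "AttWindow",
    "IdentityReport",
    "AttProductPair",
    "revcomp",
    "extract_window",
    "identity_count",
    "reconstruct_att_products",
    "round_half_up_pct",
]

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVNacgtryswkmbdhvn",
                            "TGCAYRSWMKVHDBNtgcayrswmkvhdbn")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC codes preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def round_half_up_pct(count: int, span: int) -> int:
    """Integer percentage with ties rounded away from zero (round half up)."""
    return int(math.floor(100.0 * count / span + 0.5))


@dataclass(frozen=True)
class CanonicalAttSet:
    """The reference attB/attP configuration for one integrase.

    The full attB (73 bp for ΦBT1) contains a nested minimal window
    (36 bp: ``minimal_arm_left + 2 + minimal_arm_right``) which in turn
    contains the crossover window (9 bp) — all centred on the core GT.
    Arm splits are configuration, not constants: the geometry is supplied by
    the user so the model stays correct for any serine integrase.

    Parameters
    ----------
    attB_full : str
        The full-length canonical attB sequence.
    attB_core_offset : int
        0-based index of the G of the core GT within ``attB_full``.
    minimal_arm_left, minimal_arm_right : int
        Arm lengths (nt either side of the 2 nt core) of the minimal attB
        window.
    crossover_arm_left, crossover_arm_right : int
        Arm lengths of the crossover window shared between attB and attP.
    attP : str
        The phage attachment site.
    attP_core_offset : int
        0-based index of the G of the core GT within ``attP``.
    provenance : str
        Free-text origin of the sequences (accession, figure, or synthetic).
    """

    attB_full: str
    attB_core_offset: int
    attP: str
    attP_core_offset: int
    minimal_arm_left: int = 17
    minimal_arm_right: int = 17
    crossover_arm_left: int = 4
    crossover_arm_right: int = 3
    provenance: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "attB_full", self.attB_full.upper())
        object.__setattr__(self, "attP", self.attP.upper())
        b, p = self.attB_core_offset, self.attP_core_offset
        if self.attB_full[b:b + 2] != "GT":
            raise ValueError("attB core dinucleotide is not GT at the given offset")
        if self.attP[p:p + 2] != "GT":
            raise ValueError("attP core dinucleotide is not GT at the given offset")
        if not (self.crossover_arm_left <= self.minimal_arm_left <= self.full_arm_left):
            raise ValueError("left arms are not nested: crossover ⊆ minimal ⊆ full")
        if not (self.crossover_arm_right <= self.minimal_arm_right <= self.full_arm_right):
            raise ValueError("right arms are not nested: crossover ⊆ minimal ⊆ full")

    @property
    def full_arm_left(self) -> int:
        return self.attB_core_offset

    @property
    def full_arm_right(self) -> int:
        return len(self.attB_full) - self.attB_core_offset - 2

    @property
    def minimal_length(self) -> int:
        return self.minimal_arm_left + 2 + self.minimal_arm_right

    @property
    def crossover_length(self) -> int:
        return self.crossover_arm_left + 2 + self.crossover_arm_right

    def attB_window(self, arm_left: int, arm_right: int) -> "AttWindow":
        """Extract a window of the canonical attB around its core."""
        return extract_window(self.attB_full, self.attB_core_offset + 1, "+",
                              arm_left, arm_right, genome_id="attB")

    @property
    def attB_minimal(self) -> str:
        return self.attB_window(self.minimal_arm_left, self.minimal_arm_right).sequence

    def attP_window(self, arm_left: int, arm_right: int) -> "AttWindow":
        return extract_window(self.attP, self.attP_core_offset + 1, "+",
                              arm_left, arm_right, genome_id="attP")


@dataclass(frozen=True)
class AttWindow:
    """A core-anchored genomic window: ``arm_left`` nt, the 2 nt core, ``arm_right`` nt.

    ``core_position`` is the 1-based forward-strand coordinate of the base
    corresponding to the G of the core in the window's own orientation (for a
    minus-strand window this is the forward-strand C pairing with that G).
    """

    sequence: str
    genome_id: str
    core_position: int
    strand: str
    arm_left: int
    arm_right: int
    warning: str = ""

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")
        if len(self.sequence) != self.arm_left + 2 + self.arm_right:
            raise ValueError("window length does not equal arm_left + 2 + arm_right")

    @property
    def core(self) -> str:
        return self.sequence[self.arm_left:self.arm_left + 2]

    @property
    def has_gt_core(self) -> bool:
        return self.core == "GT"


@dataclass(frozen=True)
class IdentityReport:
    """Position-wise identity of a candidate site to the canonical attB.

    Counts of identical positions over the nested full / minimal / crossover
    spans, plus cosmetic integer percentages for the two larger spans.
    Counts are the primary statistic.
    """

    count_full: int
    count_minimal: int
    count_crossover: int
    pct_full: int
    pct_minimal: int
    span_full: int
    span_minimal: int
    span_crossover: int


@dataclass(frozen=True)
class AttProductPair:
    """The attL/attR integration products with their labelled arms."""

    attL: str
    attR: str
    components: dict = field(default_factory=dict)


def _window_slice(length: int, core0: int, strand: str,
                  arm_left: int, arm_right: int) -> tuple[int, int]:
    """Forward-strand [start, end) of a core-anchored window (0-based)."""
    if strand == "+":
        return core0 - arm_left, core0 + 2 + arm_right
    return core0 - 1 - arm_right, core0 + 1 + arm_left


def extract_window(genome: str, core_position: int, strand: str,
                   arm_left: int, arm_right: int, *, circular: bool = False,
                   genome_id: str = "") -> AttWindow:
    """Extract a core-anchored window from a genome.

    Parameters
    ----------
    genome : str
        Genome sequence (forward strand).
    core_position : int
        1-based forward-strand coordinate of the core anchor base (the G of
        the GT for ``+`` windows; the complementary C for ``-`` windows).
    strand : {"+", "-"}
        Orientation of the returned window; ``-`` windows are returned
        reverse-complemented so their core GT sits at index ``arm_left``.
    arm_left, arm_right : int
        Number of nt either side of the 2 nt core, in window orientation.
    circular : bool
        If true, the window may wrap across the origin.

    Returns the :class:`AttWindow`; a non-GT core is recorded in the
    ``warning`` field rather than raised, because genome scanning must be
    able to evaluate non-GT positions.
    """
    if arm_left < 0 or arm_right < 0:
        raise ValueError("arm lengths must be non-negative")
    n = len(genome)
    if not (1 <= core_position <= n):
        raise IndexError(f"core_position {core_position} outside genome of length {n}")
    core0 = core_position - 1
    start, end = _window_slice(n, core0, strand, arm_left, arm_right)
    if circular:
        seq = "".join(genome[i % n] for i in range(start, end))
    else:
        if start < 0 or end > n:
            raise IndexError(
                f"window [{start}, {end}) out of bounds on linear genome of length {n}")
        seq = genome[start:end]
    seq = seq.upper()
    if strand == "-":
        seq = revcomp(seq)
    warning = ""
    core = seq[arm_left:arm_left + 2]
    if core != "GT":
        warning = f"core dinucleotide is {core!r}, not 'GT'"
    return AttWindow(sequence=seq, genome_id=genome_id, core_position=core_position,
                     strand=strand, arm_left=arm_left, arm_right=arm_right,
                     warning=warning)


def _count_span(query: AttWindow, reference: str, ref_core: int,
                arm_left: int, arm_right: int) -> int:
    """Identical positions between query and reference over one span.

    Both sequences are superposed on their core; comparison is gap-free and
    case-insensitive; any non-ACGT character matches nothing.
    """
    if query.arm_left < arm_left or query.arm_right < arm_right:
        raise ValueError(
            f"query window arms ({query.arm_left}, {query.arm_right}) are shorter than "
            f"the requested span arms ({arm_left}, {arm_right}); re-extract the window "
            "with wider arms")
    q = query.sequence[query.arm_left - arm_left: query.arm_left + 2 + arm_right].upper()
    r = reference[ref_core - arm_left: ref_core + 2 + arm_right].upper()
    return sum(1 for a, b in zip(q, r) if a == b and a in "ACGT")


def identity_count(query: AttWindow, canonical: CanonicalAttSet) -> IdentityReport:
    """Score a candidate window against the canonical attB (nested spans).

    The query and the canonical attB are aligned by superposing their core
    GT positions — no gaps, no shifting — and identical positions are counted
    over the full, minimal and crossover spans.  Percentages use round half
    up and are cosmetic; the integer counts are authoritative.
    """
    ref = canonical.attB_full
    c0 = canonical.attB_core_offset
    count_full = _count_span(query, ref, c0,
                             canonical.full_arm_left, canonical.full_arm_right)
    count_minimal = _count_span(query, ref, c0,
                                canonical.minimal_arm_left, canonical.minimal_arm_right)
    count_crossover = _count_span(query, ref, c0,
                                  canonical.crossover_arm_left,
                                  canonical.crossover_arm_right)
    span_full = len(ref)
    span_min = canonical.minimal_length
    return IdentityReport(
        count_full=count_full,
        count_minimal=count_minimal,
        count_crossover=count_crossover,
        pct_full=round_half_up_pct(count_full, span_full),
        pct_minimal=round_half_up_pct(count_minimal, span_min),
        span_full=span_full,
        span_minimal=span_min,
        span_crossover=canonical.crossover_length,
    )


def reconstruct_att_products(attB_window: AttWindow,
                             attP_window: AttWindow) -> AttProductPair:
    """Form the attL/attR products of integrase-mediated recombination.

    attL = attB left arm + GT + attP right arm;
    attR = attP left arm + GT + attB right arm.
    The shared core appears once in each product. Matching GT cores are a
    hard requirement: strand exchange cannot occur without them.
    """
    for name, w in (("attB", attB_window), ("attP", attP_window)):
        if not w.has_gt_core:
            raise ValueError(
                f"{name} window core is {w.core!r}, not 'GT'; recombination requires "
                "matching core dinucleotides")
    b_left = attB_window.sequence[:attB_window.arm_left]
    b_right = attB_window.sequence[attB_window.arm_left + 2:]
    p_left = attP_window.sequence[:attP_window.arm_left]
    p_right = attP_window.sequence[attP_window.arm_left + 2:]
    return AttProductPair(
        attL=b_left + "GT" + p_right,
        attR=p_left + "GT" + b_right,
        components={"B_left": b_left, "B_right": b_right,
                    "P_left": p_left, "P_right": p_right, "core": "GT"},
    )
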