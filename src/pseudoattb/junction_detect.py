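"""Recover plasmid insertion events from transformant genome assemblies.

Each precise serine-integrase integration leaves a signature the detector
exploits: the assembly is host sequence up to the core GT (the attL
junction), then the plasmid body, then host sequence again from the core GT
(the attR junction), with the 2 nt core duplicated once at each junction.

Detection is by exact k-mer anchoring: every k-mer of a contig is classified
as reference-derived, plasmid-derived, or neither, and each
host → plasmid → host transition yields one insertion event whose core
coordinate follows from simple anchor arithmetic.  Exact matching keeps the
procedure deterministic; it presumes curated/error-free assemblies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .att_model import (AttWindow, CanonicalAttSet, IdentityReport,
                        extract_window, identity_count, revcomp)
from .io_formats import SequenceRecord

log = logging.getLogger("pseudoattb")

__all__ = ["InsertionEvent", "PseudoAttSiteCall", "find_insertions",
           "collate_sites", "site_table"]

JUNCTION_FLANK = 30  # nt captured either side of each junction core


@dataclass(frozen=True)
class InsertionEvent:
    """One detected plasmid integration in one transformant.

    ``ref_core_position`` is 1-based on the reference forward strand
    (anchor base of the core, matching the window-extraction convention);
    ``orientation`` is the sense of the integrated site/plasmid relative to
    the reference forward strand.  ``precise`` is true iff the two host
    flanks abut with no gap, deletion, or duplication beyond the shared
    2 nt core.
    """

    transformant_id: str
    ref_core_position: int
    orientation: str
    left_junction: str
    right_junction: str
    precise: bool
    notes: str = ""
    reaction: str = ""


@dataclass(frozen=True)
class PseudoAttSiteCall:
    """One pseudo-attB site collated from events across transformants."""

    site_id: str
    ref_core_position: int
    strand: str
    event_count: int
    transformant_ids: tuple[str, ...]
    window_minimal: AttWindow
    window_full: AttWindow
    identity: IdentityReport
    n_reactions: int = 0


def _kmer_index(seq: str, k: int) -> dict[str, int]:
    """k-mer → position map; k-mers occurring more than once map to -1."""
    idx: dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i:i + k]
        idx[kmer] = -1 if kmer in idx else i
    return idx


def _mask_shared(ref_idx: dict[str, int], plasmid_kmers: set[str]) -> int:
    shared = set(ref_idx) & plasmid_kmers
    for kmer in shared:
        del ref_idx[kmer]
        plasmid_kmers.discard(kmer)
    return len(shared)


def find_insertions(assembly: Sequence[SequenceRecord] | SequenceRecord,
                    reference: SequenceRecord, plasmid: str,
                    anchor_k: int = 21, transformant_id: str | None = None,
                    reaction: str = "") -> list[InsertionEvent]:
    """Detect host→plasmid→host transitions in transformant contigs.

    Parameters
    ----------
    assembly : sequence records
        Transformant contigs (a single record is accepted).
    reference : SequenceRecord
        The host genome the transformant derives from.
    plasmid : str
        The integrating plasmid sequence (circular).
    anchor_k : int
        Anchor k-mer length (≥ 15); reference and plasmid must share no
        exact k-mer — shared ones are masked with a warning.
    transformant_id : str, optional
        Overrides the contig id in emitted events.
    """
    if anchor_k < 15:
        raise ValueError("anchor_k must be ≥ 15")
    if isinstance(assembly, SequenceRecord):
        assembly = [assembly]
    k = anchor_k
    ref_idx = _kmer_index(reference.sequence, k)
    # circular plasmid: k-mers across the origin included
    pseq = plasmid + plasmid[:k - 1]
    plasmid_kmers = {pseq[i:i + k] for i in range(len(plasmid))}
    plasmid_kmers |= {revcomp(m) for m in set(plasmid_kmers)}
    masked = _mask_shared(ref_idx, plasmid_kmers)
    if masked:
        log.warning("masked %d anchor %d-mers shared between reference and plasmid",
                    masked, k)

    events: list[InsertionEvent] = []
    for contig in assembly:
        tid = transformant_id or contig.id
        events.extend(_events_in_contig(contig, tid, reaction, reference,
                                        ref_idx, plasmid_kmers, pseq, k))
    return events


def _classify(seq: str, ref_idx: dict[str, int], plasmid_kmers: set[str],
              k: int) -> list[tuple[str, int]]:
    """Per-position labels: ('R', ref_pos) / ('P', 0) / ('.', 0)."""
    labels = []
    for i in range(len(seq) - k + 1):
        kmer = seq[i:i + k]
        r = ref_idx.get(kmer, None)
        if r is not None and r >= 0:
            labels.append(("R", r))
        elif kmer in plasmid_kmers:
            labels.append(("P", 0))
        else:
            labels.append((".", 0))
    return labels


def _runs(labels: list[tuple[str, int]]) -> list[tuple[str, int, int]]:
    """Maximal runs of R/P labels (gaps of '.' are dropped): (kind, start, end)."""
    runs = []
    cur_kind, cur_start = None, 0
    for i, (kind, _) in enumerate(labels + [(None, 0)]):
        if kind != cur_kind:
            if cur_kind in ("R", "P"):
                runs.append((cur_kind, cur_start, i))
            cur_kind, cur_start = kind, i
    return runs


def _events_in_contig(contig: SequenceRecord, tid: str, reaction: str,
                      reference: SequenceRecord, ref_idx, plasmid_kmers,
                      pseq: str, k: int) -> list[InsertionEvent]:
    seq = contig.sequence
    # normalize contig orientation (reference arcs in forward sense) by a
    # strided anchor vote before the full classification pass
    rc_seq = revcomp(seq)
    stride = max(1, (len(seq) - k + 1) // 200)
    def _vote(s: str) -> int:
        return sum(1 for i in range(0, len(s) - k + 1, stride)
                   if ref_idx.get(s[i:i + k], -1) >= 0)
    if _vote(rc_seq) > _vote(seq):
        seq = rc_seq
    labels = _classify(seq, ref_idx, plasmid_kmers, k)
    n_r = sum(1 for kind, _ in labels if kind == "R")
    n_p = sum(1 for kind, _ in labels if kind == "P")
    if n_r == 0 and n_p == 0:
        log.warning("contig %s matches neither reference nor plasmid; skipped",
                    contig.id)
        return []

    runs = _runs(labels)
    events: list[InsertionEvent] = []
    for j in range(1, len(runs) - 1):
        kind, p_start, p_end = runs[j]
        if kind != "P" or runs[j - 1][0] != "R" or runs[j + 1][0] != "R":
            continue
        i_l = runs[j - 1][2] - 1           # last R anchor before the plasmid run
        i_r = runs[j + 1][1]               # first R anchor after it
        r_l, r_r = labels[i_l][1], labels[i_r][1]
        orientation = _plasmid_sense(seq[p_start:p_start + k], pseq)
        if orientation == "+":
            g_left, g_right = r_l + k - 2, r_r
        else:
            g_left, g_right = r_l + k - 1, r_r + 1
        # When attP shares bases with the host flank next to the core
        # (junction microhomology), anchors overextend and g_left > g_right;
        # the true core lies in [g_right, g_left].  A clean insertion never
        # gives g_left < g_right (that indicates lost host sequence).
        delta = g_left - g_right
        precise, notes, g0 = True, "", g_left
        ref_seq = reference.sequence
        if delta < 0:
            precise = False
            g0 = g_right
            notes = f"host flanks separated by {-delta} nt (gap or deletion)"
        elif delta > 5:
            precise = False
            g0 = g_right
            notes = f"boundary irresolvable: core estimates differ by {delta}"
        elif delta > 0:
            candidates = [p for p in range(g_right, g_left + 1)
                          if _core_motif_at(ref_seq, p, orientation)]
            if candidates:
                g0 = candidates[0]  # tie-break toward the lower coordinate
                notes = f"junction microhomology of {delta} nt resolved at core motif"
            else:
                precise = False
                g0 = g_right
                notes = (f"host flanks overlap by {delta} nt beyond the core "
                         "with no core motif in range")
        # contig indices of the junction cores, shifted by the resolution
        c_l = i_l + k - 2 - (g_left - g0)
        c_r = i_r + (g0 - g_right)
        events.append(InsertionEvent(
            transformant_id=tid,
            ref_core_position=g0 + 1,
            orientation=orientation,
            left_junction=seq[max(0, c_l - JUNCTION_FLANK): c_l + 2 + JUNCTION_FLANK],
            right_junction=seq[max(0, c_r - JUNCTION_FLANK): c_r + 2 + JUNCTION_FLANK],
            precise=precise, notes=notes, reaction=reaction))
    # deduplicate within the transformant
    seen: set[tuple[int, str]] = set()
    unique = []
    for ev in events:
        key = (ev.ref_core_position, ev.orientation)
        if key not in seen:
            seen.add(key)
            unique.append(ev)
    return unique


def _plasmid_sense(kmer: str, pseq: str) -> str:
    return "+" if kmer in pseq else "-"


def _core_motif_at(ref_seq: str, g0: int, orientation: str) -> bool:
    """True if the reference carries the core dinucleotide anchored at g0
    (GT starting at g0 for '+' sites; AC ending at g0 for '-' sites)."""
    if orientation == "+":
        return ref_seq[g0:g0 + 2] == "GT"
    return g0 >= 1 and ref_seq[g0 - 1:g0 + 1] == "AC"


def collate_sites(events: Iterable[InsertionEvent], reference: SequenceRecord,
                  canonical: CanonicalAttSet,
                  site_prefix: str = "site") -> list[PseudoAttSiteCall]:
    """Group insertion events into pseudo-attB site calls.

    Events collate to one site iff they share (reference core position,
    strand).  Sites are numbered by ascending genome position.  Each call
    carries the minimal and full-width windows extracted from the reference
    and their identity report against the canonical attB.  The number of
    distinct transformation reactions is reported per site (a sibling-colony
    diagnostic) but no event is discarded.
    """
    groups: dict[tuple[int, str], list[InsertionEvent]] = {}
    for ev in events:
        groups.setdefault((ev.ref_core_position, ev.orientation), []).append(ev)

    calls = []
    for i, ((pos, strand), evs) in enumerate(sorted(groups.items())):
        w_min = extract_window(reference.sequence, pos, strand,
                               canonical.minimal_arm_left,
                               canonical.minimal_arm_right,
                               circular=reference.circular,
                               genome_id=reference.id)
        w_full = extract_window(reference.sequence, pos, strand,
                                canonical.full_arm_left, canonical.full_arm_right,
                                circular=reference.circular,
                                genome_id=reference.id)
        calls.append(PseudoAttSiteCall(
            site_id=f"{site_prefix}-{i + 1:02d}",
            ref_core_position=pos, strand=strand, event_count=len(evs),
            transformant_ids=tuple(ev.transformant_id for ev in evs),
            window_minimal=w_min, window_full=w_full,
            identity=identity_count(w_full, canonical),
            n_reactions=len({ev.reaction for ev in evs if ev.reaction})))
    return calls


def site_table(calls: Sequence[PseudoAttSiteCall],
               annotations: dict[int, str] | None = None) -> pd.DataFrame:
    """Site calls as a table (1-based coordinates).

    ``annotations`` optionally maps reference core positions to feature
    names (e.g. encoded proteins from a GFF3); absent entries are "NA".
    """
    annotations = annotations or {}
    rows = []
    for c in calls:
        rows.append({
            "site": c.site_id,
            "position": c.ref_core_position,
            "strand": c.strand,
            "events": c.event_count,
            "count_full": c.identity.count_full,
            "pct_full": c.identity.pct_full,
            "count_minimal": c.identity.count_minimal,
            "pct_minimal": c.identity.pct_minimal,
            "count_crossover": c.identity.count_crossover,
            "n_reactions": c.n_reactions,
            "transformants": ",".join(c.transformant_ids),
            "annotation": annotations.get(c.ref_core_position, "NA"),
        })
    return pd.DataFrame(rows, columns=[
        "site", "position", "strand", "events", "count_full", "pct_full",
        "count_minimal", "pct_minimal", "count_crossover", "n_reactions",
        "transformants", "annotation"])
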