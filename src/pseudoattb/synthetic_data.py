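"""Synthetic integration benchmark: host genomes with planted pseudo-attB
sites, a plasmid carrying attP, and post-integration transformant genomes.

The generator emulates the structure of a pseudo-attB mapping experiment —
a GC-rich circular host chromosome containing degenerate copies of the
minimal attB, an integrating plasmid whose attP shares the GT core, and a
set of single-insertion transformant assemblies — with full truth tables so
detection, scoring and richness estimation can be validated end to end.

Scale and sampling defaults are desk-scale analogues of the study design
they emulate: a 200 kb circular host (the real N. terpenica chromosome is
9.3 Mb), 20 planted sites spanning minimal-attB identities from 12/36 to
22/36 (the observed pseudo-attB range), 27 transformants drawn from 14
independent transformation reactions.

Every transformant carries exactly one precise insertion: the host is cut
inside the core GT and rejoined through the plasmid so the product reads
``…B_left+GT+P_right … plasmid body … P_left+GT+B_right…``, i.e. the attL
and attR products of serine-integrase recombination, with no sequence gained
or lost beyond the plasmid itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .att_model import (AttWindow, CanonicalAttSet, extract_window,
                        identity_count, reconstruct_att_products, revcomp)
from .io_formats import SequenceRecord, write_bed, write_fasta

__all__ = [
    "SimConfig", "SiteTruth", "TransformantTruth",
    "synthetic_canonical_att", "generate_host", "make_plasmid",
    "simulate_transformants", "window_with_identity", "write_truth_tables",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic integration experiment.

    ``identity_profile`` gives each planted site's target identity to the
    canonical minimal attB as a fraction (defaults span 12/36–22/36, the
    observed pseudo-attB range).  ``weight_model`` sets per-site selection
    weights: ``"uniform"``, ``"identity"`` (proportional to realized minimal
    identity), or an explicit sequence of non-negative weights.
    """

    seed: int = 0
    genome_length: int = 200_000
    gc_fraction: float = 0.68
    n_sites: int = 20
    identity_profile: tuple[float, ...] | None = None
    weight_model: str | tuple[float, ...] = "uniform"
    plasmid_length: int = 6_000
    n_transformants: int = 27
    n_reactions: int = 14
    topology: str = "circular"

    def __post_init__(self) -> None:
        if self.genome_length < self.n_sites * 200:
            raise ValueError(
                f"genome_length {self.genome_length} too small to pack "
                f"{self.n_sites} sites (need ≥ n_sites × 200)")
        if not (0.0 < self.gc_fraction < 1.0):
            raise ValueError("gc_fraction must be in (0, 1)")
        if self.topology not in ("circular", "linear"):
            raise ValueError("topology must be 'circular' or 'linear'")
        for f in self.resolved_identity_profile():
            if not (2.0 / 36.0 <= f <= 1.0):
                raise ValueError(f"identity fraction {f} outside [2/36, 1]")
        if not isinstance(self.weight_model, str):
            w = np.asarray(self.weight_model, float)
            if (w < 0).any() or w.sum() <= 0:
                raise ValueError("weights must be non-negative and not all zero")
            if len(w) != self.n_sites:
                raise ValueError("explicit weights must have length n_sites")

    def resolved_identity_profile(self) -> tuple[float, ...]:
        if self.identity_profile is not None:
            return tuple(self.identity_profile)
        if self.n_sites == 0:
            return ()
        # evenly spaced target counts over the observed 12..22 / 36 range
        counts = np.linspace(12, 22, self.n_sites).round().astype(int)
        return tuple(c / 36.0 for c in counts)


@dataclass(frozen=True)
class SiteTruth:
    """Ground truth for one planted pseudo-attB site."""

    site_id: str
    core_position: int          # 1-based, forward strand
    strand: str
    window: str                 # planted window, window orientation
    target_identity: int        # matches out of the minimal span
    realized_identity: int
    weight: float


@dataclass(frozen=True)
class TransformantTruth:
    """Ground truth for one simulated integration event."""

    transformant_id: str
    site_id: str
    reaction: str
    genome: SequenceRecord
    attL: str
    attR: str
    insertion_coordinate: int   # 0-based index of the left-junction core in the contig


def synthetic_canonical_att(seed: int = 7, attB_length: int = 73,
                            attB_core_offset: int = 35,
                            attP_length: int = 48, attP_core_offset: int = 23,
                            gc_fraction: float = 0.60) -> CanonicalAttSet:
    """A synthetic stand-in canonical attB/attP pair.

    The true ΦBT1 att sequences are published only in figure form; this
    generator produces a deterministic stand-in with the same geometry
    (73 bp attB, GT core, nested 36 bp minimal and 9 bp crossover windows,
    sub-50 bp attP sharing the core).  It is explicitly synthetic — analyses
    of real data must supply transcribed sequences via config.
    """
    rng = np.random.default_rng(seed)
    p = [(1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2, (1 - gc_fraction) / 2]

    def seq_with_core(length: int, core: int) -> str:
        s = rng.choice(_BASES, size=length, p=p)
        s[core], s[core + 1] = "G", "T"
        return "".join(s)

    return CanonicalAttSet(
        attB_full=seq_with_core(attB_length, attB_core_offset),
        attB_core_offset=attB_core_offset,
        attP=seq_with_core(attP_length, attP_core_offset),
        attP_core_offset=attP_core_offset,
        provenance=f"synthetic stand-in (seed {seed})",
    )


def _mutate_to_identity(window: str, core_index: int, target_matches: int,
                        rng: np.random.Generator) -> str:
    """Mutate non-core positions of an exact canonical copy so that exactly
    ``target_matches`` positions (core included) remain identical."""
    n = len(window)
    n_mut = n - target_matches
    non_core = [i for i in range(n) if i not in (core_index, core_index + 1)]
    if n_mut > len(non_core):
        raise ValueError("target identity below the conserved core floor")
    sites = rng.choice(len(non_core), size=n_mut, replace=False)
    out = list(window)
    for j in sites:
        i = non_core[j]
        alternatives = [b for b in "ACGT" if b != out[i]]
        out[i] = alternatives[rng.integers(3)]
    return "".join(out)


def window_with_identity(canonical: CanonicalAttSet,
                         count_full: int, count_minimal: int,
                         count_crossover: int, seed: int = 0) -> AttWindow:
    """Construct a synthetic full-width window with an exact nested identity
    structure relative to the canonical attB.

    A stand-in for sites whose published identity counts are known but whose
    sequences are not available in machine-readable form: matches are placed
    independently within the crossover shell (beyond the always-matching GT
    core), the minimal-but-not-crossover shell, and the full-but-not-minimal
    shell, and every other position is forced to mismatch.  The construction
    path is independent of :func:`~pseudoattb.att_model.identity_count`.
    """
    rng = np.random.default_rng(seed)
    ref = canonical.attB_full
    c0 = canonical.attB_core_offset
    n = len(ref)

    def span_positions(al: int, ar: int) -> set[int]:
        return set(range(c0 - al, c0 + 2 + ar))

    core = {c0, c0 + 1}
    cross = span_positions(canonical.crossover_arm_left, canonical.crossover_arm_right)
    minimal = span_positions(canonical.minimal_arm_left, canonical.minimal_arm_right)
    full = span_positions(canonical.full_arm_left, canonical.full_arm_right)
    shells = [sorted(cross - core), sorted(minimal - cross), sorted(full - minimal)]
    needs = [count_crossover - 2, count_minimal - count_crossover,
             count_full - count_minimal]
    for need, shell in zip(needs, shells):
        if not (0 <= need <= len(shell)):
            raise ValueError(
                f"infeasible identity structure ({count_full}, {count_minimal}, "
                f"{count_crossover}) for this canonical geometry")
    out = list(ref)
    for need, shell in zip(needs, shells):
        keep = set(np.asarray(shell)[rng.choice(len(shell), size=need, replace=False)]
                   ) if need else set()
        for i in shell:
            if i not in keep:
                alternatives = [b for b in "ACGT" if b != ref[i]]
                out[i] = alternatives[rng.integers(3)]
    return AttWindow(sequence="".join(out), genome_id="synthetic-standin",
                     core_position=c0 + 1, strand="+",
                     arm_left=canonical.full_arm_left,
                     arm_right=canonical.full_arm_right)


def _random_genome(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return rng.choice(_BASES, size=length, p=p)


def _place_sites(rng: np.random.Generator, length: int, n_sites: int,
                 margin: int, min_gap: int = 136) -> np.ndarray:
    """Non-overlapping core positions ≥ ``min_gap`` apart (0-based)."""
    if n_sites == 0:
        return np.array([], dtype=int)
    for _ in range(1000):
        pos = np.sort(rng.integers(margin, length - margin, size=n_sites))
        if n_sites == 1 or np.diff(pos).min() >= min_gap:
            return pos
    raise ValueError("could not pack sites: genome too small for n_sites")


def generate_host(config: SimConfig,
                  canonical: CanonicalAttSet) -> tuple[SequenceRecord, list[SiteTruth]]:
    """Generate the host genome with planted pseudo-attB sites.

    Background bases are i.i.d. at the requested GC; each site is a copy of
    the canonical minimal attB with a seeded random subset of non-core
    positions mutated so the realized identity hits its target exactly;
    planting never touches the core GT; site strand is Bernoulli(0.5).  The
    genome is checked to contain no exact copy of the canonical minimal attB
    other than any deliberately planted 36/36 site.
    """
    rng = np.random.default_rng([config.seed, 0])
    L = config.genome_length
    genome = _random_genome(rng, L, config.gc_fraction)
    mal, mar = canonical.minimal_arm_left, canonical.minimal_arm_right
    wlen = mal + 2 + mar
    margin = wlen + 4
    positions = _place_sites(rng, L, config.n_sites, margin)
    profile = config.resolved_identity_profile()

    sites: list[SiteTruth] = []
    for i, g0 in enumerate(positions):
        target = int(round(profile[i] * wlen))
        window = _mutate_to_identity(canonical.attB_minimal, mal, target, rng)
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "+":
            genome[g0 - mal: g0 + 2 + mar] = list(window)
        else:
            genome[g0 - 1 - mar: g0 + 1 + mal] = list(revcomp(window))
        sites.append(SiteTruth(site_id=f"site-{i + 1:02d}", core_position=g0 + 1,
                               strand=strand, window=window, target_identity=target,
                               realized_identity=0, weight=0.0))

    # remove accidental exact copies of the canonical minimal attB
    seq = "".join(genome)
    planted_exact = {(s.core_position, s.strand) for s in sites
                     if s.target_identity == wlen}
    pat_f, pat_r = canonical.attB_minimal, revcomp(canonical.attB_minimal)
    for _ in range(100):
        dirty = False
        for pat, strand in ((pat_f, "+"), (pat_r, "-")):
            start = seq.find(pat)
            while start != -1:
                core = start + mal + 1 if strand == "+" else start + mar + 1
                if (core, strand) not in planted_exact:
                    i = start if strand == "+" else start + wlen - 1
                    alternatives = [b for b in "ACGT" if b != seq[i]]
                    seq = seq[:i] + alternatives[rng.integers(3)] + seq[i + 1:]
                    dirty = True
                start = seq.find(pat, start + 1)
        if not dirty:
            break

    record = SequenceRecord(id="host", sequence=seq, topology=config.topology,
                            description="synthetic host genome")
    # realized identity, recomputed through the scoring path; selection weights
    weights = _site_weights(config, sites, seq, canonical)
    final = []
    for s, w in zip(sites, weights):
        win = extract_window(seq, s.core_position, s.strand, mal, mar,
                             circular=record.circular, genome_id=record.id)
        realized = identity_count(
            AttWindow(sequence=win.sequence, genome_id=win.genome_id,
                      core_position=win.core_position, strand=win.strand,
                      arm_left=mal, arm_right=mar),
            _minimal_only(canonical)).count_minimal
        final.append(SiteTruth(site_id=s.site_id, core_position=s.core_position,
                               strand=s.strand, window=win.sequence,
                               target_identity=s.target_identity,
                               realized_identity=realized, weight=float(w)))
    return record, final


def _minimal_only(canonical: CanonicalAttSet) -> CanonicalAttSet:
    """Canonical set restricted to its minimal window (for 36 nt queries)."""
    return CanonicalAttSet(
        attB_full=canonical.attB_minimal,
        attB_core_offset=canonical.minimal_arm_left,
        attP=canonical.attP, attP_core_offset=canonical.attP_core_offset,
        minimal_arm_left=canonical.minimal_arm_left,
        minimal_arm_right=canonical.minimal_arm_right,
        crossover_arm_left=canonical.crossover_arm_left,
        crossover_arm_right=canonical.crossover_arm_right,
        provenance=canonical.provenance)


def _site_weights(config: SimConfig, sites: list[SiteTruth], seq: str,
                  canonical: CanonicalAttSet) -> np.ndarray:
    n = len(sites)
    if n == 0:
        return np.array([])
    if isinstance(config.weight_model, str):
        if config.weight_model == "uniform":
            return np.ones(n)
        if config.weight_model == "identity":
            return np.array([float(s.target_identity) for s in sites])
        raise ValueError(f"unknown weight_model {config.weight_model!r}")
    return np.asarray(config.weight_model, float)


def make_plasmid(config: SimConfig,
                 canonical: CanonicalAttSet) -> tuple[SequenceRecord, int]:
    """Random circular plasmid with the attP window planted at a recorded
    offset.  Returns (plasmid record, 0-based index of the attP core G)."""
    rng = np.random.default_rng([config.seed, 1])
    Lp = config.plasmid_length
    attP = canonical.attP
    if Lp < len(attP) + 20:
        raise ValueError("plasmid_length too small to carry attP")
    plasmid = _random_genome(rng, Lp, config.gc_fraction)
    offset = int(rng.integers(10, Lp - len(attP) - 10))
    plasmid[offset: offset + len(attP)] = list(attP)
    core0 = offset + canonical.attP_core_offset
    return SequenceRecord(id="plasmid", sequence="".join(plasmid),
                          topology="circular",
                          description="synthetic integrating plasmid"), core0


def integrate(host: str, g0: int, strand: str, plasmid: str, p0: int) -> str:
    """String surgery for one precise integration.

    ``g0`` is the 0-based forward coordinate of the host core anchor (G for
    ``+`` sites, the pairing C for ``-`` sites); ``p0`` the 0-based index of
    the attP core G on the circular plasmid.  The product carries the host
    as two arcs joined through the full plasmid body with the 2 nt core
    duplicated once at each junction — attL on the left, attR on the right,
    in site orientation.
    """
    body = plasmid[p0 + 2:] + plasmid[:p0]
    if strand == "+":
        return host[:g0] + "GT" + body + "GT" + host[g0 + 2:]
    rc, gg = revcomp(host), len(host) - 1 - g0
    post_rc = rc[:gg] + "GT" + body + "GT" + rc[gg + 2:]
    return revcomp(post_rc)


def simulate_transformants(host: SequenceRecord, sites: Sequence[SiteTruth],
                           plasmid: SequenceRecord, plasmid_core0: int,
                           config: SimConfig,
                           canonical: CanonicalAttSet) -> list[TransformantTruth]:
    """Simulate independent single-insertion transformants.

    Each transformant samples one site with probability proportional to its
    weight and integrates the plasmid by the attL/attR arm-exchange rule.
    Transformants are assigned round-robin to ``n_reactions`` independent
    transformation reactions (the sibling-avoidance design of the emulated
    experiment).
    """
    if config.n_transformants > 0 and not sites:
        raise ValueError("cannot simulate transformants with an empty site list")
    rng = np.random.default_rng([config.seed, 2])
    weights = np.array([s.weight for s in sites], float)
    if len(weights) and weights.sum() <= 0:
        weights = np.ones(len(sites))
    probs = weights / weights.sum() if len(weights) else weights
    mal, mar = canonical.minimal_arm_left, canonical.minimal_arm_right

    out: list[TransformantTruth] = []
    for t in range(config.n_transformants):
        idx = int(rng.choice(len(sites), p=probs))
        site = sites[idx]
        g0 = site.core_position - 1
        post = integrate(host.sequence, g0, site.strand,
                         plasmid.sequence, plasmid_core0)
        attB_win = extract_window(host.sequence, site.core_position, site.strand,
                                  mal, mar, circular=host.circular,
                                  genome_id=host.id)
        attP_win = extract_window(plasmid.sequence, plasmid_core0 + 1, "+",
                                  canonical.attP_core_offset,
                                  len(canonical.attP) - canonical.attP_core_offset - 2,
                                  circular=True, genome_id=plasmid.id)
        pair = reconstruct_att_products(attB_win, attP_win)
        insertion = g0 if site.strand == "+" else g0 - 1
        tid = f"T{t + 1:03d}"
        out.append(TransformantTruth(
            transformant_id=tid, site_id=site.site_id,
            reaction=f"rxn-{t % config.n_reactions + 1:02d}",
            genome=SequenceRecord(id=tid, sequence=post,
                                  topology=host.topology,
                                  description=f"transformant of {host.id}"),
            attL=pair.attL, attR=pair.attR, insertion_coordinate=insertion))
    return out


def write_truth_tables(sites: Sequence[SiteTruth],
                       transformants: Sequence[TransformantTruth],
                       outdir: str | Path, genome_id: str = "host") -> None:
    """Write site and transformant truth as TSV plus a BED of planted sites."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    site_df = pd.DataFrame(
        [{"site_id": s.site_id, "core_position": s.core_position,
          "strand": s.strand, "window": s.window,
          "target_identity": s.target_identity,
          "realized_identity": s.realized_identity, "weight": s.weight}
         for s in sites])
    with open(outdir / "sites_truth.tsv", "w") as fh:
        fh.write("# coordinates: 1-based inclusive; core_position is the "
                 "forward-strand anchor of the core G\n")
        site_df.to_csv(fh, sep="\t", index=False)
    wlen = len(sites[0].window) if sites else 36
    arm = (wlen - 2) // 2
    write_bed([(genome_id, s.core_position - 1 - arm, s.core_position + 1 + arm,
                s.site_id, f"{s.weight:g}", s.strand) for s in sites],
              outdir / "sites_truth.bed")
    tr_df = pd.DataFrame(
        [{"transformant_id": t.transformant_id, "site_id": t.site_id,
          "reaction": t.reaction, "attL": t.attL, "attR": t.attR,
          "insertion_coordinate": t.insertion_coordinate}
         for t in transformants])
    tr_df.to_csv(outdir / "transformants_truth.tsv", sep="\t", index=False)
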