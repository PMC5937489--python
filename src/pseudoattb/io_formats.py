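"""Readers and writers for the formats the pipeline touches.

FASTA goes through Biopython; TSV through pandas; config is TOML (stdlib
``tomllib``).  Motifs are exchanged in MEME motif text format version 4 so
they interoperate with the MEME suite.  All writers are deterministic
byte-for-byte for identical inputs (stable ordering, fixed float formats).

Coordinate conventions: BED output is 0-based half-open; TSV/GFF3 and human
reports are 1-based inclusive.  Every file header states its convention.
"""

from __future__ import annotations

import hashlib
import logging
import tomllib
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .att_model import CanonicalAttSet

log = logging.getLogger("pseudoattb")

__all__ = [
    "SequenceRecord", "read_fasta", "write_fasta",
    "write_meme_motif", "read_meme_motif",
    "write_bed", "write_gff3", "load_config", "canonical_from_config",
    "file_sha256",
]


@dataclass(frozen=True)
class SequenceRecord:
    """One sequence with an id, description and topology (linear/circular)."""

    id: str
    sequence: str
    description: str = ""
    topology: str = "linear"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if self.topology not in ("linear", "circular"):
            raise ValueError("topology must be 'linear' or 'circular'")

    @property
    def circular(self) -> bool:
        return self.topology == "circular"


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file; sequences are upper-cased.

    Topology defaults to linear; a ``circular=true`` token in the description
    marks a record circular.  Duplicate ids are an error; an empty file
    returns an empty list with a warning.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip() if rec.description.startswith(rec.id) else rec.description
        topology = "circular" if "circular=true" in desc.lower() else "linear"
        records.append(SequenceRecord(id=rec.id, sequence=str(rec.seq).upper(),
                                      description=desc, topology=topology))
    if not records:
        log.warning("no records found in FASTA file %s", path)
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path,
                width: int = 70) -> None:
    """Write FASTA; circular records carry a ``circular=true`` token."""
    out = []
    for r in records:
        desc = r.description
        if r.circular and "circular=true" not in desc.lower():
            desc = (desc + " " if desc else "") + "circular=true"
        out.append(SeqRecord(Seq(r.sequence), id=r.id, description=desc))
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(out)


# ---------------------------------------------------------------------------
# MEME motif text format (version 4)
# ---------------------------------------------------------------------------

def write_meme_motif(motif, path: str | Path, name: str = "pseudo-attB") -> None:
    """Write a motif in MEME motif text format v4 (with background line)."""
    probs = motif.probabilities
    bg = motif.background
    lines = [
        "MEME version 4", "",
        "ALPHABET= ACGT", "",
        "strands: + -", "",
        "Background letter frequencies",
        "A {:.6f} C {:.6f} G {:.6f} T {:.6f}".format(*bg), "",
        f"MOTIF {name}",
        "letter-probability matrix: alength= 4 w= {} nsites= {} E= 0".format(
            motif.width, int(motif.nsites)),
    ]
    for row in probs:
        lines.append(" {:.6f} {:.6f} {:.6f} {:.6f}".format(*row))
    lines.append("")
    Path(path).write_text("\n".join(lines))


def read_meme_motif(path: str | Path):
    """Read the first motif from a MEME motif text file.

    Rows must be stochastic (|Σ−1| ≤ 1e-4); a malformed header is an error.
    Returns a :class:`~pseudoattb.motif_scan.MotifModel` whose count matrix
    is the probability matrix scaled by the declared nsites (pseudocount 0).
    """
    from .motif_scan import MotifModel

    text = Path(path).read_text().splitlines()
    if not any(line.strip().startswith("MEME version") for line in text[:5]):
        raise ValueError(f"{path}: missing 'MEME version' header")
    bg = np.full(4, 0.25)
    width = nsites = None
    rows: list[list[float]] = []
    it = iter(enumerate(text))
    for i, line in it:
        s = line.strip()
        if s.startswith("Background letter frequencies"):
            parts = text[i + 1].split()
            freq = {parts[j]: float(parts[j + 1]) for j in range(0, len(parts), 2)}
            bg = np.array([freq[b] for b in "ACGT"])
        if s.startswith("letter-probability matrix"):
            tokens = s.replace(":", " ").split()
            kv = {tokens[j].rstrip("="): tokens[j + 1]
                  for j in range(len(tokens) - 1) if tokens[j].endswith("=")}
            width = int(kv["w"])
            nsites = float(kv.get("nsites", 20))
            for j in range(i + 1, i + 1 + width):
                vals = [float(v) for v in text[j].split()]
                if len(vals) != 4:
                    raise ValueError(f"{path}: matrix row with {len(vals)} columns")
                if abs(sum(vals) - 1.0) > 1e-4:
                    raise ValueError(f"{path}: non-stochastic matrix row {vals}")
                rows.append(vals)
            break
    if width is None or len(rows) != width:
        raise ValueError(f"{path}: no complete letter-probability matrix found")
    probs = np.array(rows)
    return MotifModel(counts=probs * nsites, background=bg, pseudocount=0.0,
                      nsites=nsites)


# ---------------------------------------------------------------------------
# Interval formats
# ---------------------------------------------------------------------------

def write_bed(intervals: Iterable[tuple], path: str | Path) -> None:
    """Write BED6 (0-based, half-open): chrom, start, end, name, score, strand."""
    lines = ["# coordinates: 0-based half-open (BED)"]
    for chrom, start, end, name, score, strand in intervals:
        lines.append(f"{chrom}\t{start}\t{end}\t{name}\t{score}\t{strand}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_gff3(features: Iterable[tuple], path: str | Path,
               source: str = "pseudoattb") -> None:
    """Write GFF3 (1-based, inclusive): (seqid, type, start, end, score, strand, attrs)."""
    lines = ["##gff-version 3", "# coordinates: 1-based inclusive (GFF3)"]
    for seqid, ftype, start, end, score, strand, attrs in features:
        lines.append(
            f"{seqid}\t{source}\t{ftype}\t{start}\t{end}\t{score}\t{strand}\t.\t{attrs}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Config
# ---------------------------------------------------------------------------

_SCHEMA: dict[str, set[str]] = {
    "canonical": {"attB", "attB_fasta", "attB_core_offset", "attP", "attP_fasta",
                  "attP_core_offset", "minimal_arm_left", "minimal_arm_right",
                  "crossover_arm_left", "crossover_arm_right", "provenance"},
    "simulation": {"seed", "genome_length", "gc_fraction", "n_sites",
                   "identity_profile", "weight_model", "plasmid_length",
                   "n_transformants", "n_reactions", "topology"},
    "detection": {"anchor_k"},
    "motif": {"width", "pseudocount", "background"},
    "scan": {"threshold", "require_core", "strands"},
    "richness": {"model", "n_grid_max"},
    "inputs": {"reference", "plasmid", "transformants", "annotation_gff"},
}


def load_config(path: str | Path) -> dict:
    """Load and validate the TOML config.  Unknown sections/keys are errors."""
    with open(path, "rb") as fh:
        cfg = tomllib.load(fh)
    for section, content in cfg.items():
        if section not in _SCHEMA:
            raise ValueError(f"unknown config section [{section}]")
        if not isinstance(content, dict):
            raise ValueError(f"config section [{section}] must be a table")
        unknown = set(content) - _SCHEMA[section]
        if unknown:
            raise ValueError(f"unknown keys in [{section}]: {sorted(unknown)}")
    return cfg


def canonical_from_config(cfg: dict, base_dir: str | Path = ".") -> CanonicalAttSet:
    """Build the canonical att set from the ``[canonical]`` config section.

    Sequences may be inline (``attB`` / ``attP``) or paths to single-record
    FASTA files (``attB_fasta`` / ``attP_fasta``).
    """
    sec = cfg.get("canonical")
    if sec is None:
        raise ValueError("config has no [canonical] section")

    def _seq(inline_key: str, fasta_key: str) -> str:
        if inline_key in sec:
            return sec[inline_key].upper()
        if fasta_key in sec:
            recs = read_fasta(Path(base_dir) / sec[fasta_key])
            if len(recs) != 1:
                raise ValueError(f"{sec[fasta_key]}: expected a single-record FASTA")
            return recs[0].sequence
        raise ValueError(f"[canonical] needs {inline_key} or {fasta_key}")

    kwargs = {k: sec[k] for k in ("minimal_arm_left", "minimal_arm_right",
                                  "crossover_arm_left", "crossover_arm_right",
                                  "provenance") if k in sec}
    return CanonicalAttSet(
        attB_full=_seq("attB", "attB_fasta"),
        attB_core_offset=sec["attB_core_offset"],
        attP=_seq("attP", "attP_fasta"),
        attP_core_offset=sec["attP_core_offset"],
        **kwargs,
    )


def file_sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
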