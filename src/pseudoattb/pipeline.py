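"""End-to-end orchestration: detect → collate → motif → scan → richness.

The pipeline consumes either real inputs (reference, plasmid and
transformant FASTAs named in the config) or a ``[simulation]`` block, and
writes every artifact into an output directory: the site table (TSV + BED),
the motif (MEME text), scan hits (TSV + BED), richness estimates (JSON +
curve TSV) and a provenance block recording the seed, resolved config and
input hashes.  Identical config and seed give byte-identical outputs apart
from the provenance timestamp.
"""

from __future__ import annotations

import datetime
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import junction_detect, motif_scan, richness, synthetic_data
from .att_model import CanonicalAttSet
from .io_formats import (SequenceRecord, canonical_from_config, file_sha256,
                         read_fasta, write_bed, write_fasta, write_gff3,
                         write_meme_motif)

log = logging.getLogger("pseudoattb")

__all__ = ["PipelineReport", "run_pipeline"]


@dataclass
class PipelineReport:
    """All pipeline outputs for one run."""

    site_table: pd.DataFrame
    events: list
    site_calls: list
    motif: motif_scan.MotifModel | None
    hits: list
    richness_estimates: dict
    provenance: dict
    outdir: Path


def _genome_background(seq: str) -> np.ndarray:
    counts = np.array([seq.count(b) for b in "ACGT"], float)
    if counts.sum() == 0:
        return np.full(4, 0.25)
    return counts / counts.sum()


def _simulation_inputs(cfg: dict, canonical: CanonicalAttSet, seed: int | None):
    sim = dict(cfg["simulation"])
    if seed is not None:
        sim["seed"] = seed
    if "identity_profile" in sim:
        sim["identity_profile"] = tuple(sim["identity_profile"])
    if "weight_model" in sim and not isinstance(sim["weight_model"], str):
        sim["weight_model"] = tuple(sim["weight_model"])
    config = synthetic_data.SimConfig(**sim)
    host, sites = synthetic_data.generate_host(config, canonical)
    plasmid, p_core0 = synthetic_data.make_plasmid(config, canonical)
    transformants = synthetic_data.simulate_transformants(
        host, sites, plasmid, p_core0, config, canonical)
    return config, host, plasmid, sites, transformants


def run_pipeline(cfg: dict, outdir: str | Path, seed: int | None = None,
                 base_dir: str | Path = ".") -> PipelineReport:
    """Run the full analysis described by a validated config dict.

    With a ``[simulation]`` section the synthetic benchmark is generated
    (and its truth tables written); otherwise ``[inputs]`` must name the
    reference, plasmid and transformant FASTA files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    canonical = canonical_from_config(cfg, base_dir)
    det = cfg.get("detection", {})
    anchor_k = det.get("anchor_k", 21)
    provenance: dict = {
        "seed": seed,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest(),
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "inputs": {},
    }

    truth_sites = None
    if "simulation" in cfg:
        sim_config, reference, plasmid, truth_sites, transformants = \
            _simulation_inputs(cfg, canonical, seed)
        write_fasta([reference], outdir / "host.fasta")
        write_fasta([plasmid], outdir / "plasmid.fasta")
        write_fasta([t.genome for t in transformants], outdir / "transformants.fasta")
        synthetic_data.write_truth_tables(truth_sites, transformants, outdir,
                                          genome_id=reference.id)
        contig_sets = [([t.genome], t.transformant_id, t.reaction)
                       for t in transformants]
        provenance["simulation"] = {"seed": sim_config.seed,
                                    "n_sites": sim_config.n_sites,
                                    "n_transformants": sim_config.n_transformants}
    else:
        inputs = cfg["inputs"]
        ref_path = Path(base_dir) / inputs["reference"]
        plasmid_path = Path(base_dir) / inputs["plasmid"]
        reference = read_fasta(ref_path)[0]
        plasmid = read_fasta(plasmid_path)[0]
        provenance["inputs"] = {"reference": file_sha256(ref_path),
                                "plasmid": file_sha256(plasmid_path)}
        contig_sets = []
        for path in inputs["transformants"]:
            recs = read_fasta(Path(base_dir) / path)
            contig_sets.append((recs, Path(path).stem, ""))

    # detect + collate
    events = []
    for contigs, tid, reaction in contig_sets:
        events.extend(junction_detect.find_insertions(
            contigs, reference, plasmid.sequence, anchor_k=anchor_k,
            transformant_id=tid, reaction=reaction))
    calls = junction_detect.collate_sites(events, reference, canonical)
    table = junction_detect.site_table(calls)
    with open(outdir / "site_table.tsv", "w") as fh:
        fh.write("# coordinates: 1-based inclusive\n")
        table.to_csv(fh, sep="\t", index=False)
    write_bed([(reference.id,
                c.ref_core_position - 1 - canonical.minimal_arm_left,
                c.ref_core_position + 1 + canonical.minimal_arm_right,
                c.site_id, c.event_count, c.strand) for c in calls],
              outdir / "sites.bed")
    write_gff3([(reference.id, "pseudo_attB_site",
                 c.ref_core_position - canonical.minimal_arm_left,
                 c.ref_core_position + 1 + canonical.minimal_arm_right,
                 c.event_count, c.strand,
                 f"ID={c.site_id};events={c.event_count}") for c in calls],
               outdir / "sites.gff3")

    # motif + scan
    motif = None
    hits: list = []
    scan_cfg = cfg.get("scan", {})
    motif_cfg = cfg.get("motif", {})
    if len(calls) >= 2:
        background = _genome_background(reference.sequence)
        motif = motif_scan.build_motif(
            [c.window_minimal for c in calls],
            pseudocount=motif_cfg.get("pseudocount", 0.5),
            background=background,
            width=motif_cfg.get("width", 34))
        write_meme_motif(motif, outdir / "motif.meme.txt")
        dist = motif_scan.exact_pvalues(motif)
        hits = motif_scan.scan_genome(
            reference, motif, dist,
            threshold=scan_cfg.get("threshold", 1e-8),
            strands=scan_cfg.get("strands", "both"),
            require_core=scan_cfg.get("require_core", False))
        hit_df = pd.DataFrame(
            [{"sequence_name": h.genome_id, "start": h.start,
              "stop": (h.start + motif.width - 1 - 1) % len(reference.sequence) + 1,
              "strand": h.strand, "score": round(h.score, 4),
              "p_value": f"{h.p_value:.3e}", "matched_sequence": h.sequence}
             for h in hits])
        with open(outdir / "scan_hits.tsv", "w") as fh:
            fh.write("# coordinates: 1-based inclusive\n")
            hit_df.to_csv(fh, sep="\t", index=False)
        write_bed([(h.genome_id, h.start - 1,
                    h.start - 1 + motif.width, f"hit{i + 1}",
                    round(h.score, 3), h.strand) for i, h in enumerate(hits)],
                  outdir / "scan_hits.bed")
    else:
        log.warning("fewer than 2 sites: motif and scan stages skipped")

    # richness
    estimates: dict = {}
    if calls:
        abund = richness.AbundanceVector(tuple(c.event_count for c in calls))
        curve = richness.rarefaction_curve(abund)
        pd.DataFrame({"n": curve.n, "expected_richness":
                      np.round(curve.expected_richness, 4)}).to_csv(
            outdir / "rarefaction_curve.tsv", sep="\t", index=False)
        estimates = {
            "S_obs": abund.S_obs,
            "N_events": abund.N,
            "F1_singletons": abund.F1,
            "F2_doubletons": abund.F2,
        }
        import warnings as _warnings
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            estimates["chao1_classic"] = round(richness.chao1(abund), 2)
        estimates["chao1_bias_corrected"] = round(
            richness.chao1(abund, bias_corrected=True), 2)
        if abund.N >= 4:
            fit = richness.fit_asymptote(
                curve, model=cfg.get("richness", {}).get("model", "exponential"))
            estimates["asymptote_model"] = fit.model
            estimates["asymptote_S_max"] = round(fit.s_max, 2)
            estimates["asymptote_B"] = round(fit.b, 2)
        (outdir / "richness.json").write_text(
            json.dumps(estimates, indent=2, sort_keys=True) + "\n")
    else:
        log.warning("no sites detected: richness stage skipped")

    (outdir / "provenance.json").write_text(
        json.dumps(provenance, indent=2, sort_keys=True, default=str) + "\n")
    return PipelineReport(site_table=table, events=events, site_calls=calls,
                          motif=motif, hits=hits, richness_estimates=estimates,
                          provenance=provenance, outdir=outdir)
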