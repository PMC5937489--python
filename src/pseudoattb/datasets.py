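"""Published pseudo-attB insertion-site statistics.

The table below reproduces the observed pRT801 insertion-site statistics
for *Nocardia terpenica* AUSMDU00012715: 27 sequenced transformants mapping
to 19 distinct pseudo-attB sites, with per-site identity counts to the
canonical ΦBT1 attB of *S. coelicolor* over the full 73 bp site, the 36 bp
minimal site and the 9 bp attB–attP crossover, the number of independent
integration events per site, and the genome position of each site (1-based,
anchor of the core GT).

These numbers are observation inputs (the published per-site summary), used
for aggregation, richness estimation and consistency checks; the underlying
read sets are not required.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["nocardia_terpenica_sites", "nocardia_terpenica_events"]

_ROWS = [
    # site, count_full(/73), count_minimal(/36), count_crossover(/9), events, position, annotation
    ("Nt-1", 26, 19, 5, 1, 731398, "MsrR family regulator"),
    ("Nt-2", 20, 14, 4, 1, 751814, "Disulfide bond forming protein"),
    ("Nt-3", 26, 17, 6, 4, 1066609, "Polyketide synthase"),
    ("Nt-4", 28, 19, 6, 1, 1505104, "Carboxymethylenebutenolidase"),
    ("Nt-5", 30, 17, 3, 1, 1826014, "Non-coding region"),
    ("Nt-6", 22, 13, 5, 2, 3715745, "Non-coding region"),
    ("Nt-7", 34, 20, 5, 1, 3939350, "FtsX-like permease"),
    ("Nt-8", 27, 15, 6, 1, 4126594, "Hypothetical protein"),
    ("Nt-9", 25, 13, 3, 1, 4286641, "Hypothetical protein"),
    ("Nt-10", 25, 17, 4, 2, 5761121, "Hypothetical protein"),
    ("Nt-11", 20, 14, 4, 1, 7436287, "FadD15 fatty acid ligase"),
    ("Nt-12", 26, 16, 3, 1, 7530197, "Hypothetical protein"),
    ("Nt-13", 25, 13, 3, 1, 7795264, "Putative deoxyribonuclease YcfH"),
    ("Nt-14", 25, 19, 5, 1, 7823861, "Non-coding region"),
    ("Nt-15", 25, 12, 4, 1, 8033744, "Telomeric repeat binding factor 2"),
    ("Nt-16", 35, 21, 6, 1, 8246408, "MNT1/THI5-like protein"),
    ("Nt-17", 31, 16, 4, 4, 8620438, "Non-ribosomal peptide synthetase"),
    ("Nt-18", 22, 14, 5, 1, 8670073, "Hypothetical protein"),
    ("Nt-19", 23, 14, 4, 1, 8971553, "Phosphomevalonate kinase"),
]


def nocardia_terpenica_sites() -> pd.DataFrame:
    """The published N. terpenica pseudo-attB site summary as a DataFrame."""
    return pd.DataFrame(_ROWS, columns=[
        "site", "count_full", "count_minimal", "count_crossover",
        "events", "position", "annotation"])


def nocardia_terpenica_events() -> pd.DataFrame:
    """The same observations expanded to one row per integration event
    (27 events over 19 sites; multiplicities 4, 4, 2, 2 and 15 singletons)."""
    sites = nocardia_terpenica_sites()
    rows = []
    for _, r in sites.iterrows():
        for j in range(r["events"]):
            rows.append({"site": r["site"], "position": r["position"],
                         "event_index": j + 1})
    return pd.DataFrame(rows)
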