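"""Motif construction, exact p-values, genome scanning."""

import itertools

import numpy as np
import pytest

import pseudoattb as pab
from pseudoattb.att_model import AttWindow, revcomp
from pseudoattb.io_formats import SequenceRecord
from pseudoattb.motif_scan import (MotifModel, build_motif, exact_pvalues,
                                   scan_genome)

RNG = np.random.default_rng(77)


def gt_window(rng=RNG, width=36, core=17):
    s = list(rng.choice(list("ACGT"), width))
    s[core], s[core + 1] = "G", "T"
    return AttWindow(sequence="".join(s), genome_id="w", core_position=core + 1,
                     strand="+", arm_left=core, arm_right=width - core - 2)


class TestBuildMotif:
    def test_identical_windows_pseudocount_zero(self):
        w = gt_window()
        m = build_motif([w] * 5, pseudocount=0.0)
        assert m.width == 34
        # consensus columns carry count n, all others 0
        assert (m.counts.max(axis=1) == 5).all()
        assert (m.counts.sum(axis=1) == 5).all()
        assert m.consensus == w.sequence[1:35]

    def test_core_columns_track_the_gt(self):
        windows = [gt_window() for _ in range(8)]
        m = build_motif(windows)
        c = m.core_columns[0]
        assert (c, c + 1) == (16, 17)  # 0-based; positions 17,18 of 34
        assert m.counts[c, 2] == 8 and m.counts[c + 1, 3] == 8  # all G, all T

    def test_information_content_matches_closed_form(self):
        windows = [gt_window() for _ in range(10)]
        bg = np.array([0.16, 0.34, 0.34, 0.16])
        m = build_motif(windows, pseudocount=0.5, background=bg)
        ic = m.information_content()
        p = (m.counts + 0.5 * bg) / (10 + 0.5)
        oracle = np.array([sum(p[j, b] * np.log2(p[j, b] / bg[b])
                               for b in range(4)) for j in range(34)])
        np.testing.assert_allclose(ic, oracle, atol=1e-12)

    def test_own_consensus_scores_maximal(self):
        windows = [gt_window() for _ in range(12)]
        m = build_motif(windows)
        assert m.score(m.consensus) == pytest.approx(m.max_score())

    def test_input_validation(self):
        with pytest.raises(ValueError, match="at least 2"):
            build_motif([gt_window()])
        w1, w2 = gt_window(), gt_window(width=30, core=14)
        with pytest.raises(ValueError, match="differ"):
            build_motif([w1, w2])


class TestExactPvalues:
    def test_width_one_best_letter_quartile(self):
        m = MotifModel(counts=np.array([[8.0, 0, 0, 0]]),
                       background=np.full(4, 0.25), pseudocount=0.5)
        d = exact_pvalues(m)
        best_bin = int(np.rint(m.log_odds[0].max() / d.granularity))
        assert d.pvalue(best_bin) == pytest.approx(0.25)

    @pytest.mark.parametrize("width", [3, 6])
    def test_dp_equals_exhaustive_enumeration(self, width):
        rng = np.random.default_rng(5)
        counts = rng.integers(0, 15, size=(width, 4)).astype(float)
        bg = np.array([0.3, 0.2, 0.2, 0.3])
        m = MotifModel(counts=counts, background=bg, pseudocount=0.5, nsites=15)
        d = exact_pvalues(m, granularity=1e-3)
        bins = np.rint(m.log_odds / 1e-3).astype(int)
        tail_oracle = {}
        pmf = {}
        for word in itertools.product(range(4), repeat=width):
            s = int(sum(bins[j, b] for j, b in enumerate(word)))
            pmf[s] = pmf.get(s, 0.0) + float(np.prod([bg[b] for b in word]))
        acc = 0.0
        for s in sorted(pmf, reverse=True):
            acc += pmf[s]
            tail_oracle[s] = acc
        for s, t in tail_oracle.items():
            assert d.pvalue(s) == pytest.approx(t, abs=1e-12)

    def test_tail_properties(self):
        m = build_motif([gt_window() for _ in range(6)],
                        background=np.array([0.2, 0.3, 0.3, 0.2]))
        d = exact_pvalues(m)
        assert d.pmf.sum() == pytest.approx(1.0, abs=1e-9)
        assert (np.diff(d.tail) <= 1e-15).all()  # non-increasing in score
        assert d.pvalue(d.min_bin) == pytest.approx(1.0)

    def test_background_must_be_stochastic(self):
        with pytest.raises(ValueError, match="background"):
            MotifModel(counts=np.ones((4, 4)), background=np.array([1, 1, 1, 1.0]))


@pytest.fixture(scope="module")
def trained():
    rng = np.random.default_rng(9)
    windows = [gt_window(rng) for _ in range(3)] * 6  # sharp motif
    m = build_motif(windows)
    return m, exact_pvalues(m)


class TestScanGenome:
    def test_planted_consensus_is_the_unique_hit(self, trained):
        m, d = trained
        rng = np.random.default_rng(10)
        bg = "".join(rng.choice(list("ACGT"), 20_000))
        planted_at = 5_000  # 0-based start
        genome = SequenceRecord(
            id="g", sequence=bg[:planted_at] + m.consensus + bg[planted_at:])
        hits = scan_genome(genome, m, d, threshold=1e-8)
        assert len(hits) == 1
        assert hits[0].start == planted_at + 1 and hits[0].strand == "+"
        assert hits[0].sequence == m.consensus

    def test_threshold_one_reports_every_position(self, trained):
        m, d = trained
        genome = SequenceRecord(id="g", sequence="ACGT" * 100)
        hits = scan_genome(genome, m, d, threshold=1.0)
        assert len(hits) == 2 * (400 - m.width + 1)

    def test_revcomp_genome_mirrors_hits(self, trained):
        m, d = trained
        rng = np.random.default_rng(11)
        bg = "".join(rng.choice(list("ACGT"), 5_000))
        genome = SequenceRecord(id="g", sequence=bg[:1000] + m.consensus
                                + bg[1000:2000] + revcomp(m.consensus) + bg[2000:])
        fwd = scan_genome(genome, m, d, threshold=1e-6)
        flipped = SequenceRecord(id="g", sequence=revcomp(genome.sequence))
        rev = scan_genome(flipped, m, d, threshold=1e-6)
        L = len(genome.sequence)
        mirrored = sorted((L - (h.start - 1) - m.width + 1,
                           {"+": "-", "-": "+"}[h.strand]) for h in rev)
        assert mirrored == sorted((h.start, h.strand) for h in fwd)
        assert len(fwd) >= 2

    def test_circular_wrap_finds_origin_spanning_site(self, trained):
        m, d = trained
        rng = np.random.default_rng(12)
        bg = "".join(rng.choice(list("ACGT"), 3_000))
        # place consensus across the origin: last 20 bases + first 14
        cons = m.consensus
        seq = cons[20:] + bg[14:3_000 - 20] + cons[:20]
        genome = SequenceRecord(id="g", sequence=seq, topology="circular")
        hits = scan_genome(genome, m, d, threshold=1e-8)
        assert any(h.start == len(seq) - 20 + 1 and h.strand == "+" for h in hits)

    def test_background_hit_rate_within_poisson_bounds(self, trained):
        """On a random genome the number of hits at a loose cutoff follows
        the exact tail probability at that cutoff (Poisson check)."""
        m, d = trained
        rng = np.random.default_rng(13)
        L = 150_000
        genome = SequenceRecord(id="g", sequence="".join(rng.choice(list("ACGT"), L)))
        threshold = 1e-4
        hits = scan_genome(genome, m, d, threshold=threshold)
        # expected rate: the achieved tail probability at the cutoff bin
        passing = np.nonzero(d.tail <= threshold)[0]
        p_achieved = float(d.tail[passing[0]])
        lam = 2 * (L - m.width + 1) * p_achieved
        assert abs(len(hits) - lam) <= 3 * np.sqrt(lam) + 1

    def test_require_core_filters_non_gt_hits(self, trained):
        m, d = trained
        rng = np.random.default_rng(14)
        bg = "".join(rng.choice(list("ACGT"), 4_000))
        c = m.core_columns[0]
        no_core = m.consensus[:c] + "AA" + m.consensus[c + 2:]
        genome = SequenceRecord(id="g", sequence=bg[:500] + no_core + bg[500:])
        loose = scan_genome(genome, m, d, threshold=1e-4)
        strict = scan_genome(genome, m, d, threshold=1e-4, require_core=True)
        assert any(h.start == 501 for h in loose)
        assert not any(h.start == 501 for h in strict)

    def test_planted_site_sensitivity_reported(self, canonical, small_sim):
        """Scanning the synthetic host recovers planted sites among hits;
        sensitivity is a reported fraction, not asserted at 100%."""
        host, sites = small_sim["host"], small_sim["sites"]
        windows = [pab.extract_window(host.sequence, s.core_position, s.strand,
                                      17, 17, circular=True) for s in sites]
        counts = np.array([host.sequence.count(b) for b in "ACGT"], float)
        m = build_motif(windows, background=counts / counts.sum())
        d = exact_pvalues(m)
        hits = scan_genome(host, m, d, threshold=1e-8)
        hit_cores = {h.start + 16 if h.strand == "+" else h.start + 17
                     for h in hits}
        sensitivity = len(hit_cores & {s.core_position for s in sites}) / len(sites)
        assert 0.0 <= sensitivity <= 1.0
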