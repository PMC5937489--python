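"""Insertion-event recovery and site collation."""

import numpy as np
import pytest

import pseudoattb as pab
from pseudoattb.att_model import revcomp
from pseudoattb.junction_detect import (InsertionEvent, collate_sites,
                                        find_insertions, site_table)

JF = 30  # junction flank captured either side of the core


def centered_attL_attR(event, attB_arms, attP_arms):
    """Extract the attL/attR windows from an event's junction strings,
    in site orientation."""
    lj, rj = event.left_junction, event.right_junction
    if event.orientation == "-":
        lj, rj = revcomp(rj), revcomp(lj)
    attL = lj[JF - attB_arms[0]: JF + 2 + attP_arms[1]]
    attR = rj[JF - attP_arms[0]: JF + 2 + attB_arms[1]]
    return attL, attR


class TestFindInsertions:
    def test_reference_identical_contig_yields_nothing(self, small_sim):
        host = small_sim["host"]
        events = find_insertions([host], host,
                                 small_sim["plasmid"].sequence)
        assert events == []

    def test_unrelated_contig_skipped_with_warning(self, small_sim, caplog):
        rng = np.random.default_rng(0)
        junk = pab.SequenceRecord(id="junk",
                                  sequence="".join(rng.choice(list("ACGT"), 2000)))
        with caplog.at_level("WARNING"):
            events = find_insertions([junk], small_sim["host"],
                                     small_sim["plasmid"].sequence)
        assert events == [] and "matches neither" in caplog.text

    def test_anchor_k_minimum(self, small_sim):
        t = small_sim["transformants"][0]
        with pytest.raises(ValueError, match="anchor_k"):
            find_insertions([t.genome], small_sim["host"],
                            small_sim["plasmid"].sequence, anchor_k=10)

    def test_single_insertion_recovered_exactly(self, small_sim):
        truth_sites = {s.site_id: s for s in small_sim["sites"]}
        t = small_sim["transformants"][0]
        events = find_insertions([t.genome], small_sim["host"],
                                 small_sim["plasmid"].sequence,
                                 transformant_id=t.transformant_id)
        assert len(events) == 1
        (e,) = events
        s = truth_sites[t.site_id]
        assert e.ref_core_position == s.core_position
        assert e.orientation == s.strand
        assert e.precise

    def test_reversed_contig_is_normalized(self, small_sim):
        truth_sites = {s.site_id: s for s in small_sim["sites"]}
        t = small_sim["transformants"][1]
        flipped = pab.SequenceRecord(id=t.transformant_id,
                                     sequence=revcomp(t.genome.sequence))
        (e,) = find_insertions([flipped], small_sim["host"],
                               small_sim["plasmid"].sequence)
        s = truth_sites[t.site_id]
        assert (e.ref_core_position, e.orientation) == (s.core_position, s.strand)

    def test_perfect_recall_and_no_spurious_events(self, benchmark_sim,
                                                   benchmark_events):
        """Noise-free benchmark: every simulated event found at the exact
        coordinate and orientation, flagged precise, nothing extra."""
        truth_sites = {s.site_id: s for s in benchmark_sim["sites"]}
        truth = {t.transformant_id: truth_sites[t.site_id]
                 for t in benchmark_sim["transformants"]}
        assert len(benchmark_events) == len(truth) >= 100
        for e in benchmark_events:
            s = truth[e.transformant_id]
            assert e.ref_core_position == s.core_position
            assert e.orientation == s.strand
            assert e.precise

    def test_junction_strings_equal_att_products(self, benchmark_sim,
                                                 benchmark_events):
        """The observed junction sequences are exactly the predicted attL and
        attR products for the chosen site, in site orientation."""
        truth = {t.transformant_id: t for t in benchmark_sim["transformants"]}
        can = pab.synthetic_canonical_att()
        attP_arms = (can.attP_core_offset,
                     len(can.attP) - can.attP_core_offset - 2)
        for e in benchmark_events:
            t = truth[e.transformant_id]
            attL, attR = centered_attL_attR(e, (17, 17), attP_arms)
            assert attL == t.attL and attR == t.attR

    def test_multi_insertion_transformant_reported_as_two_events(
            self, small_sim, canonical):
        """A contig carrying two independent insertions yields two events."""
        host = small_sim["host"]
        pl, c0 = small_sim["plasmid"], small_sim["plasmid_core0"]
        s1, s2 = small_sim["sites"][0], small_sim["sites"][4]
        from pseudoattb.synthetic_data import integrate
        once = integrate(host.sequence, s1.core_position - 1, s1.strand,
                         pl.sequence, c0)
        # second surgery on the already-integrated genome (coordinates shift
        # by the plasmid length for sites right of the first insertion)
        shift = len(pl.sequence) if s2.core_position > s1.core_position else 0
        g2 = s2.core_position - 1 + shift
        twice = integrate(once, g2, s2.strand, pl.sequence, c0)
        rec = pab.SequenceRecord(id="double", sequence=twice)
        events = find_insertions([rec], host, pl.sequence)
        got = {(e.ref_core_position, e.orientation) for e in events}
        assert got == {(s1.core_position, s1.strand),
                       (s2.core_position, s2.strand)}


class TestCollateSites:
    def _fake_events(self, positions, strands, n_each):
        events = []
        i = 0
        for pos, strand, n in zip(positions, strands, n_each):
            for _ in range(n):
                events.append(InsertionEvent(
                    transformant_id=f"T{i:03d}", ref_core_position=pos,
                    orientation=strand, left_junction="", right_junction="",
                    precise=True, reaction=f"rxn-{i % 5}"))
                i += 1
        return events

    def test_single_event_single_site(self, benchmark_sim, canonical):
        e = self._fake_events([benchmark_sim["sites"][0].core_position],
                              [benchmark_sim["sites"][0].strand], [1])
        calls = collate_sites(e, benchmark_sim["host"], canonical)
        assert len(calls) == 1 and calls[0].event_count == 1

    def test_grouping_matches_bruteforce_pairwise_clustering(
            self, benchmark_sim, benchmark_events, canonical):
        calls = collate_sites(benchmark_events, benchmark_sim["host"], canonical)
        # O(n^2) oracle: two events belong together iff identical key
        evs = list(benchmark_events)
        clusters = []
        for e in evs:
            for cl in clusters:
                if (cl[0].ref_core_position == e.ref_core_position
                        and cl[0].orientation == e.orientation):
                    cl.append(e)
                    break
            else:
                clusters.append([e])
        assert sorted(len(c) for c in clusters) == \
            sorted(c.event_count for c in calls)
        assert len(clusters) == len(calls)

    def test_event_counts_sum_to_input_events(self, benchmark_sim,
                                              benchmark_events, canonical):
        calls = collate_sites(benchmark_events, benchmark_sim["host"], canonical)
        assert sum(c.event_count for c in calls) == len(benchmark_events)

    def test_order_invariance_up_to_position_sort(self, benchmark_sim,
                                                  benchmark_events, canonical):
        host = benchmark_sim["host"]
        fwd = collate_sites(benchmark_events, host, pab.synthetic_canonical_att())
        rev = collate_sites(list(reversed(benchmark_events)), host,
                            pab.synthetic_canonical_att())
        assert [(c.ref_core_position, c.strand, c.event_count) for c in fwd] == \
            [(c.ref_core_position, c.strand, c.event_count) for c in rev]
        # site ids are ordinal by ascending position
        assert [c.ref_core_position for c in fwd] == \
            sorted(c.ref_core_position for c in fwd)

    def test_published_multiplicity_pattern_collates_to_19_sites(
            self, benchmark_sim, canonical, observed_counts):
        """27 events with per-site multiplicities 4,4,2,2 and 15 singletons
        collate to 19 sites with matching event counts."""
        positions = [1000 + 500 * i for i in range(19)]
        events = self._fake_events(positions, ["+"] * 19,
                                   sorted(observed_counts, reverse=True))
        calls = collate_sites(events, benchmark_sim["host"], canonical)
        assert len(calls) == 19
        assert sum(c.event_count for c in calls) == 27
        assert sum(1 for c in calls if c.event_count == 1) == 15
        table = site_table(calls)
        assert list(table.columns[:4]) == ["site", "position", "strand", "events"]
        # nesting invariant holds for every scored site
        assert (table["count_full"] >= table["count_minimal"]).all()
        assert (table["count_minimal"] >= table["count_crossover"]).all()

    def test_reaction_diversity_reported_not_filtered(self, benchmark_sim,
                                                      canonical):
        pos = benchmark_sim["sites"][0].core_position
        strand = benchmark_sim["sites"][0].strand
        events = self._fake_events([pos], [strand], [4])
        calls = collate_sites(events, benchmark_sim["host"], canonical)
        assert calls[0].event_count == 4 and calls[0].n_reactions == 4
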