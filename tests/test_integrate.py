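from itertools import combinations

import pytest
from hypothesis import given, settings, strategies as st

from chromanchor.formats_io import (
    AssemblyLayout,
    ContigRow,
    GapRow,
    GeneticMap,
    Marker,
    MarkerAlignment,
    ScaffoldLayout,
)
from chromanchor.integrate import (
    AnchoredScaffold,
    IntegrationParams,
    PlacedMarker,
    SplitRequest,
    assign_linkage_groups,
    build_chromonome,
    detect_interleavings,
    filter_alignments,
    orient_scaffold,
    order_scaffolds,
    reverse_complement,
    run_integration,
    select_consistent_markers,
    split_scaffold,
)

P = IntegrationParams()


def aln(marker, scaffold="s1", pos=100, mism=0, gaps=0, cov=1.0, unique=True):
    return MarkerAlignment(marker, scaffold, pos, "+", mism, gaps, cov, unique)


def pm(mid, bp, cm):
    return PlacedMarker(mid, bp, cm)


def anchored(markers, scaffold_id="host", lg="LG1", length=10_000, layout=None):
    retained, hint, excl = select_consistent_markers(markers)
    a = AnchoredScaffold(scaffold_id, lg, length, retained, excl, layout=layout)
    a.orientation = orient_scaffold(a, P, hint)
    return a


# ---------------------------------------------------------------------------
# alignment filtering
# ---------------------------------------------------------------------------

class TestFilterAlignments:
    def test_five_mismatches_no_gaps_kept(self):
        kept, rejected = filter_alignments([aln("m1", mism=5)], P)
        assert len(kept) == 1 and not rejected

    def test_gap_open_counts_four_mismatches(self):
        # 2 substitutions + 1 gap open scores 2 + 4 = 6 > 5
        kept, rejected = filter_alignments([aln("m1", mism=2, gaps=1)], P)
        assert not kept and rejected[0][1] == "mismatch-score"

    def test_equal_best_multimapper_rejected_non_unique(self):
        alns = [aln("m1", "s1", unique=False), aln("m1", "s2", unique=False)]
        kept, rejected = filter_alignments(alns, P)
        assert not kept and [r for _, r in rejected] == ["non-unique", "non-unique"]

    def test_low_coverage_rejected(self):
        kept, rejected = filter_alignments([aln("m1", cov=0.98)], P)
        assert not kept and rejected[0][1] == "low-coverage"

    def test_reason_is_first_failing_criterion(self):
        kept, rejected = filter_alignments([aln("m1", mism=9, cov=0.5, unique=False)], P)
        assert rejected[0][1] == "non-unique"

    def test_empty_input(self):
        assert filter_alignments([], P) == ([], [])


# ---------------------------------------------------------------------------
# linkage-group assignment
# ---------------------------------------------------------------------------

def _map(*markers):
    return GeneticMap([Marker(m, lg, cm) for m, lg, cm in markers])


class TestAssignLinkageGroups:
    def test_majority_wins_minority_excluded(self):
        gmap = _map(("a", "LG1", 0), ("b", "LG1", 1), ("c", "LG1", 2), ("d", "LG2", 5))
        alns = [aln(m, "s1", pos=i * 100 + 1) for i, m in enumerate("abcd")]
        assignment, markers, excluded = assign_linkage_groups(gmap, alns)
        assert assignment == {"s1": "LG1"}
        assert [m.marker_id for m in markers["s1"]] == ["a", "b", "c"]
        assert excluded == [("d", "s1", "lg-conflict")]

    def test_single_group_no_conflict(self):
        gmap = _map(("a", "LG4", 0), ("b", "LG4", 3))
        assignment, markers, excluded = assign_linkage_groups(
            gmap, [aln("a", pos=10), aln("b", pos=20)]
        )
        assert assignment == {"s1": "LG4"} and not excluded

    def test_exact_tie_leaves_scaffold_unassigned(self):
        gmap = _map(("a", "LG1", 0), ("b", "LG1", 1), ("c", "LG2", 0), ("d", "LG2", 1))
        assignment, markers, excluded = assign_linkage_groups(
            gmap, [aln(m, pos=i + 1) for i, m in enumerate("abcd")]
        )
        assert assignment == {} and markers == {}
        assert {r for _, _, r in excluded} == {"lg-tie"} and len(excluded) == 4


# ---------------------------------------------------------------------------
# monotone marker selection
# ---------------------------------------------------------------------------

def brute_force_selection(cms):
    """Exhaustive oracle: maximum monotone subsequence, non-decreasing
    preferred on size ties, lexicographically smallest index set."""
    n = len(cms)

    def best(ok):
        for r in range(n, 0, -1):
            hits = [
                c
                for c in combinations(range(n), r)
                if all(ok(cms[a], cms[b]) for a, b in zip(c, c[1:]))
            ]
            if hits:
                return min(hits)
        return ()

    up = best(lambda a, b: a <= b)
    down = best(lambda a, b: a >= b)
    if len(up) > len(down):
        return list(up), "+"
    if len(down) > len(up):
        return list(down), "-"
    return list(up), "tie"


class TestSelectConsistentMarkers:
    def test_already_monotone_all_retained(self):
        ms = [pm("a", 10, 1.0), pm("b", 20, 2.0), pm("c", 30, 3.0)]
        retained, hint, excluded = select_consistent_markers(ms)
        assert retained == ms and hint == "+" and not excluded

    def test_single_outlier_dropped_with_earlier_bp_tiebreak(self):
        ms = [pm("a", 10, 0.0), pm("b", 20, 5.0), pm("c", 30, 3.0), pm("d", 40, 10.0)]
        retained, hint, excluded = select_consistent_markers(ms)
        assert [m.cm for m in retained] == [0.0, 5.0, 10.0]
        assert hint == "+"
        assert [m.marker_id for m, _ in excluded] == ["c"]
        assert excluded[0][1] == "order-conflict"

    def test_decreasing_map_gives_negative_hint(self):
        ms = [pm("a", 10, 10.0), pm("b", 20, 5.0), pm("c", 30, 0.0)]
        retained, hint, excluded = select_consistent_markers(ms)
        assert retained == ms and hint == "-" and not excluded

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            select_consistent_markers([])

    def test_single_marker_always_retained(self):
        retained, hint, excluded = select_consistent_markers([pm("a", 5, 3.0)])
        assert len(retained) == 1 and hint == "tie" and not excluded

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 6).map(float), min_size=1, max_size=12))
    def test_matches_exhaustive_enumeration(self, cms):
        ms = [pm(f"m{i}", (i + 1) * 10, c) for i, c in enumerate(cms)]
        retained, hint, _ = select_consistent_markers(ms)
        oracle_idx, oracle_hint = brute_force_selection(cms)
        assert [m.marker_id for m in retained] == [f"m{i}" for i in oracle_idx]
        assert hint == oracle_hint


# ---------------------------------------------------------------------------
# orientation
# ---------------------------------------------------------------------------

class TestOrientScaffold:
    def test_increasing_cm_positive(self):
        a = anchored([pm("a", 100, 10.0), pm("b", 900, 12.0)])
        assert a.orientation == "+"

    def test_decreasing_cm_negative(self):
        a = anchored([pm("a", 100, 12.0), pm("b", 900, 10.0)])
        assert a.orientation == "-"

    def test_single_map_position_unknown(self):
        a = anchored([pm("a", 100, 7.3), pm("b", 900, 7.3)])
        assert a.orientation == "unknown"


# ---------------------------------------------------------------------------
# ordering and interleaving
# ---------------------------------------------------------------------------

class TestOrderScaffolds:
    def test_sorted_by_mean_cm(self):
        a = anchored([pm("a", 1, 0.0), pm("b", 99, 5.0)], "sA")
        b = anchored([pm("c", 1, 10.0), pm("d", 99, 12.0)], "sB")
        c = anchored([pm("e", 1, 6.0), pm("f", 99, 9.0)], "sC")
        assert [s.scaffold_id for s in order_scaffolds([a, b, c])] == ["sA", "sC", "sB"]

    def test_tie_broken_by_descending_length(self):
        big = anchored([pm("a", 1, 4.0)], "big", length=9_000)
        small = anchored([pm("b", 1, 4.0)], "small", length=2_000)
        assert [s.scaffold_id for s in order_scaffolds([small, big])] == ["big", "small"]

    def test_single_scaffold_identity(self):
        a = anchored([pm("a", 1, 1.0)], "only")
        assert order_scaffolds([a]) == [a]


class TestDetectInterleavings:
    def test_guest_between_host_markers_requests_split(self):
        host = anchored([pm("h1", 1000, 10.0), pm("h2", 9000, 20.0)], "host")
        guest = anchored([pm("g1", 50, 15.0)], "guest", length=2_000)
        (req,) = detect_interleavings(order_scaffolds([host, guest]))
        assert req.host_id == "host"
        assert (req.left_marker.marker_id, req.right_marker.marker_id) == ("h1", "h2")
        assert req.guests == ("guest",)

    def test_guest_outside_host_span_no_split(self):
        host = anchored([pm("h1", 1000, 10.0), pm("h2", 9000, 20.0)], "host")
        guest = anchored([pm("g1", 50, 25.0)], "guest", length=2_000)
        assert detect_interleavings(order_scaffolds([host, guest])) == []

    def test_non_overlapping_hosts_no_split(self):
        a = anchored([pm("a1", 1, 0.0), pm("a2", 9000, 5.0)], "sA")
        b = anchored([pm("b1", 1, 10.0), pm("b2", 9000, 15.0)], "sB")
        assert detect_interleavings(order_scaffolds([a, b])) == []


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------

def _host_layout(gaps):
    """10 kb scaffold with the given (start0, end0) gap windows."""
    rows, pos = [], 0
    for i, (gs, ge) in enumerate(gaps, start=1):
        rows.append(ContigRow(pos, gs, f"ctg{i}", 1, gs - pos, "+"))
        rows.append(GapRow(gs, ge, "N", "scaffold", "yes", "paired-ends"))
        pos = ge
    rows.append(ContigRow(pos, 10_000, f"ctg{len(gaps) + 1}", 1, 10_000 - pos, "+"))
    return ScaffoldLayout("host", 10_000, rows)


class TestSplitScaffold:
    def request(self, host):
        return SplitRequest("host", host.retained[0], host.retained[1], ("guest",))

    def test_cut_in_largest_gap(self):
        # gaps at bp 4000-4099 (100 bp) and 6000-6499 (500 bp): cut in the larger
        lay = _host_layout([(3999, 4099), (5999, 6499)])
        host = anchored([pm("h1", 1000, 10.0), pm("h2", 9000, 20.0)], "host", layout=lay)
        f1, f2, rec = split_scaffold(host, self.request(host))
        assert (f1.length, f2.length) == (5999, 3501)  # bp 1-5999 and 6500-10000
        assert (rec.cut_start, rec.cut_end) == (6000, 6499)
        assert rec.gap_dropped == 500 and not rec.low_confidence
        assert rec.fragment_ids == ("host_1", "host_2")
        assert f2.source_start == 6500 and f2.source_end == 10_000
        # markers rebased onto fragments
        assert f1.retained[0].bp == 1000 and f2.retained[0].bp == 9000 - 6499

    def test_single_gap_between_markers(self):
        lay = _host_layout([(4999, 5099)])
        host = anchored([pm("h1", 1000, 10.0), pm("h2", 9000, 20.0)], "host", layout=lay)
        _, _, rec = split_scaffold(host, self.request(host))
        assert (rec.cut_start, rec.cut_end) == (5000, 5099) and not rec.low_confidence

    def test_no_gap_falls_back_to_midpoint(self):
        lay = _host_layout([])
        host = anchored([pm("h1", 1000, 10.0), pm("h2", 9000, 20.0)], "host", layout=lay)
        f1, f2, rec = split_scaffold(host, self.request(host))
        assert f1.length == 5000 and f2.length == 5000
        assert rec.low_confidence and rec.gap_dropped == 0

    def test_split_conserves_non_gap_length(self):
        lay = _host_layout([(3999, 4099), (5999, 6499)])
        host = anchored([pm("h1", 1000, 10.0), pm("h2", 9000, 20.0)], "host", layout=lay)
        f1, f2, rec = split_scaffold(host, self.request(host))
        contig = lambda s: sum(r.length for r in s.layout.rows if isinstance(r, ContigRow))
        assert contig(f1) + contig(f2) == sum(
            r.length for r in lay.rows if isinstance(r, ContigRow)
        )

    def test_markers_off_host_rejected(self):
        lay = _host_layout([])
        host = anchored([pm("h1", 1000, 10.0), pm("h2", 9000, 20.0)], "host", layout=lay)
        bad = SplitRequest("host", pm("x", 123, 1.0), pm("y", 456, 2.0), ("g",))
        with pytest.raises(ValueError):
            split_scaffold(host, bad)


# ---------------------------------------------------------------------------
# chromonome construction
# ---------------------------------------------------------------------------

def _simple_inputs(lengths, orientations, seqs=None):
    layout = AssemblyLayout({})
    per_lg = {"LG1": []}
    sequences = {}
    for i, (L, o) in enumerate(zip(lengths, orientations), start=1):
        sid = f"s{i}"
        layout.scaffolds[sid] = ScaffoldLayout(sid, L, [ContigRow(0, L, f"{sid}_c", 1, L, "+")])
        sequences[sid] = (seqs or {}).get(sid, "ACGT" * (L // 4) + "A" * (L % 4))
        a = AnchoredScaffold(
            sid, "LG1", L, [pm(f"m{i}", 1, float(i))], layout=layout.scaffolds[sid]
        )
        a.orientation = o
        per_lg["LG1"].append(a)
    return per_lg, layout, sequences


class TestBuildChromonome:
    def test_spacer_arithmetic(self):
        per_lg, layout, seqs = _simple_inputs([5000, 3000], ["+", "+"])
        chromonome, chrom_seqs, agp = build_chromonome(per_lg, layout, seqs, P)
        assert chromonome.chromosome_length("LG1") == 8100
        assert len(chrom_seqs["LG1"]) == 8100
        assert "N" * 100 in chrom_seqs["LG1"]
        assert chrom_seqs["LG1"].count("N") == 100

    def test_single_fragment_no_spacer(self):
        per_lg, layout, seqs = _simple_inputs([5000], ["+"])
        _, chrom_seqs, _ = build_chromonome(per_lg, layout, seqs, P)
        assert chrom_seqs["LG1"] == seqs["s1"]

    def test_negative_fragment_reverse_complemented(self):
        seq = "ACGTACGTTGCA"
        per_lg, layout, seqs = _simple_inputs([12], ["-"], {"s1": seq})
        _, chrom_seqs, _ = build_chromonome(per_lg, layout, seqs, P)
        assert chrom_seqs["LG1"] == reverse_complement(seq) == "TGCAACGTACGT"

    def test_unknown_orientation_emitted_forward(self):
        per_lg, layout, seqs = _simple_inputs([400], ["unknown"])
        chromonome, chrom_seqs, _ = build_chromonome(per_lg, layout, seqs, P)
        assert chrom_seqs["LG1"] == seqs["s1"]
        p = chromonome.placements[0]
        assert p.orientation == "+" and not p.orientation_known

    def test_missing_sequence_errors(self):
        per_lg, layout, seqs = _simple_inputs([400], ["+"])
        del seqs["s1"]
        with pytest.raises(KeyError):
            build_chromonome(per_lg, layout, seqs, P)

    def test_unplaced_scaffolds_carried_through_agp(self):
        per_lg, layout, seqs = _simple_inputs([400, 300], ["+", "+"])
        per_lg["LG1"] = per_lg["LG1"][:1]  # leave s2 unplaced
        chromonome, _, agp = build_chromonome(per_lg, layout, seqs, P)
        assert chromonome.unplaced == ["s2"]
        assert agp["s2"].rows == layout["s2"].rows


# ---------------------------------------------------------------------------
# end-to-end
# ---------------------------------------------------------------------------

class TestRunIntegration:
    def test_zero_mappable_markers_leaves_everything_unplaced(self):
        per_lg, layout, seqs = _simple_inputs([400, 300], ["+", "+"])
        gmap = _map(("a", "LG1", 0.0))
        result = run_integration(gmap, layout, [], seqs)
        assert result.chromonome.chromosomes == {}
        assert sorted(result.chromonome.unplaced) == ["s1", "s2"]
        assert result.n_markers_retained == 0

    def test_marker_accounting_conserved(self, truth_noisy, result_noisy):
        n_unique_mapped = len(
            {a.marker_id for a in truth_noisy.alignments if a.is_unique}
        )
        assert (
            result_noisy.n_markers_retained + result_noisy.n_markers_excluded
            == n_unique_mapped
        )

    def test_every_scaffold_placed_or_unplaced_exactly_once(self, truth_clean, result_clean):
        placed_roots = {p.scaffold_id for p in result_clean.chromonome.placements}
        unplaced = set(result_clean.chromonome.unplaced)
        assert placed_roots | unplaced == set(truth_clean.scaffold_sequences)
        assert not placed_roots & unplaced

    def test_retained_cm_non_decreasing_along_chromosomes(self, result_clean):
        for lg, scaffolds in result_clean.anchored.items():
            trail = []
            for s in scaffolds:
                cms = [m.cm for m in s.retained]
                if s.orientation == "-":
                    cms = cms[::-1]
                trail.extend(cms)
            assert trail == sorted(trail), f"cM not monotone along {lg}"

    def test_weakly_anchored_scaffolds_never_oriented(self, result_noisy):
        for scaffolds in result_noisy.anchored.values():
            for s in scaffolds:
                if len({m.cm for m in s.retained}) < 2:
                    assert s.orientation == "unknown"

    def test_outputs_deterministic(self, truth_clean, result_clean):
        again = run_integration(
            truth_clean.genetic_map,
            truth_clean.layout,
            truth_clean.alignments,
            truth_clean.scaffold_sequences,
        )
        assert again.chromosome_sequences == result_clean.chromosome_sequences
        assert again.chromonome.placements == result_clean.chromonome.placements
        assert again.splits == result_clean.splits
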