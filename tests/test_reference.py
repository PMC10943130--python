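"""Unit tests of the scan-based BSJ-ORF builder against hand-worked cases
and small independent oracles."""

import numpy as np
import pytest

from circbsj.io import CircRNARecord
from circbsj.reference import (
    CodingElement,
    ConcatenatedScan,
    ElementKind,
    build_reference,
    build_scans,
    concatenation_factor,
    detect_infinite,
    enumerate_elements,
    find_translatable_spans,
    translate_span,
    trim_window,
)

STOPS = {"TAA", "TAG", "TGA"}


class TestConcatenationFactor:
    @pytest.mark.parametrize("L,k", [(735, 2), (301, 4), (9, 2), (10, 4), (11, 4)])
    def test_two_copies_for_integral_codons_else_four(self, L, k):
        assert concatenation_factor(L) == k

    def test_non_positive_length_raises(self):
        with pytest.raises(ValueError):
            concatenation_factor(0)


class TestBuildScans:
    def test_scan_geometry(self, make_circ):
        scans = build_scans(make_circ("ACGTACGTAC"))  # L=10 -> k=4
        assert [s.start_frame for s in scans] == [0, 1, 2]
        for s in scans:
            assert len(s.seq) == 40
            assert s.bsj_coords == (10, 20, 30)

    def test_frame_invariant_circle_gets_two_copies(self, make_circ):
        scans = build_scans(make_circ("ACGTACGTA"))  # L=9 -> k=2
        for s in scans:
            assert len(s.seq) == 18
            assert s.bsj_coords == (9,)


class TestEnumerateElements:
    def test_sorted_with_tie_order(self, make_circ):
        # junction at 9 coincides with the second copy's leading stop codon:
        # the stop sorts before the junction, closing the interval first
        scan = build_scans(make_circ("TAAGCGATG"))[0]
        elements = enumerate_elements(scan)
        at_junction = [e.kind for e in elements if e.coord == 9]
        assert at_junction == [ElementKind.STP, ElementKind.BSJ]
        assert [e.kind for e in elements if e.coord == 6] == [ElementKind.ATG]
        coords = [e.coord for e in elements]
        assert coords == sorted(coords)

    def test_scan_without_atg_has_only_stp_bsj(self, make_circ):
        scan = build_scans(make_circ("TAATAATAA"))[0]
        kinds = {e.kind for e in enumerate_elements(scan)}
        assert ElementKind.ATG not in kinds

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_naive_per_position_codon_scan(self, seed, make_circ):
        rng = np.random.default_rng(seed)
        L = int(rng.integers(30, 61))
        seq = "".join(rng.choice(list("ACGT"), L))
        circ = make_circ(seq)
        for scan in build_scans(circ):
            got = {(e.coord, e.kind) for e in enumerate_elements(scan)}
            naive = {(j, ElementKind.BSJ) for j in scan.bsj_coords}
            for c in range(len(scan.seq) - 2):
                if (c - scan.start_frame) % 3:
                    continue
                codon = scan.seq[c : c + 3]
                if codon == "ATG":
                    naive.add((c, ElementKind.ATG))
                elif codon in STOPS or "N" in codon:
                    naive.add((c, ElementKind.STP))
            assert got == naive


def _spans_bruteforce(elements, scan):
    """Independent interval enumeration over all (stop, BSJ, ATG) combinations."""
    stops = sorted(e.coord for e in elements if e.kind is ElementKind.STP)
    atgs = sorted(e.coord for e in elements if e.kind is ElementKind.ATG)
    bsjs = sorted(e.coord for e in elements if e.kind is ElementKind.BSJ)
    out = set()
    for j in bsjs:
        prev = max([s for s in stops if s < j or (s == j)], default=None)
        # a stop at the junction coordinate closes the interval before the BSJ
        prev_coord = max([s for s in stops if s <= j], default=-1)
        cands = [a for a in atgs if prev_coord < a < j]
        if not cands:
            continue
        nxt = min([s for s in stops if s > j], default=None)
        out.add((min(cands), j, nxt))
    return out


class TestFindTranslatableSpans:
    def test_documented_element_pattern(self, make_circ):
        scan = ConcatenatedScan("c", 4, "A" * 2800, (2722,), start_frame=1)
        elements = [
            CodingElement(2350, ElementKind.STP),
            CodingElement(2368, ElementKind.ATG),
            CodingElement(2722, ElementKind.BSJ),
            CodingElement(2770, ElementKind.STP),
        ]
        spans = find_translatable_spans(elements, scan)
        assert len(spans) == 1
        s = spans[0]
        assert (s.start_atg, s.end_stop, s.bsj_list) == (2368, 2770, (2722,))
        assert s.upstream_bounded and s.downstream_bounded and not s.infinite

    def test_no_atg_before_bsj_discards(self):
        scan = ConcatenatedScan("c", 4, "A" * 200, (100,), start_frame=1)
        elements = [
            CodingElement(40, ElementKind.STP),
            CodingElement(100, ElementKind.BSJ),
            CodingElement(130, ElementKind.STP),
        ]
        assert find_translatable_spans(elements, scan) == []

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_bruteforce_interval_enumeration(self, seed, make_circ):
        rng = np.random.default_rng(100 + seed)
        L = int(rng.integers(30, 91))
        seq = "".join(rng.choice(list("ACGT"), L))
        circ = make_circ(seq)
        for scan in build_scans(circ):
            elements = enumerate_elements(scan)
            got = {
                (s.start_atg, s.bsj_list[0], s.end_stop if s.downstream_bounded else None)
                for s in find_translatable_spans(elements, scan)
            }
            assert got == _spans_bruteforce(elements, scan)


class TestTranslateAndTrim:
    def test_minimal_two_residue_window(self, make_circ):
        # L=12 frame-invariant: Met codon right before the junction, a stop
        # right after the junction codon -> translated span is just "M?"
        #          0    3    6    9      junction  12(copy2 pos0) 15=stop(TAT->? no)
        seq = "GCT" + "TAA" + "GCA" + "ATG"  # codon3 is a stop; codon9 = ATG
        # second copy: codon at 12 = GCT (A), codon at 15 = TAA stop
        circ = make_circ(seq)
        scans = build_scans(circ)
        scan = scans[0]
        spans = [
            s
            for s in find_translatable_spans(enumerate_elements(scan), scan)
            if s.bsj_list == (12,)
        ]
        assert len(spans) == 1
        aa, idx, width = translate_span(scan, spans[0])
        assert aa == "MA" and width == 2 and idx == (0, 1)
        w = trim_window(aa, idx, width, circ_id="c1", frame=0)
        assert w.aa_seq == "MA"
        assert w.bsj_span == (1, 2)
        assert w.upstream_flank == 0 and w.downstream_flank == 0

    def test_span_shorter_than_codon_raises(self):
        scan = ConcatenatedScan("c", 2, "ATGTAA", (3,), 0)
        from circbsj.reference import TranslatableSpan

        bad = TranslatableSpan(0, 2, (3,), False, True, True)
        with pytest.raises(ValueError):
            translate_span(scan, bad)

    def test_met_closer_than_flank_shortens_upstream(self):
        aa = "MX" + "A" * 100
        w = trim_window(aa, (1,), 1, circ_id="c", frame=1)
        assert w.upstream_flank == 1
        assert w.downstream_flank == 24
        assert len(w.aa_seq) == 26


class TestDetectInfinite:
    def test_stop_in_every_frame_all_false(self, make_circ):
        # TAA starts at offsets 0, 4 and 8: one stop per fixed frame
        assert detect_infinite(make_circ("TAACTAACTAAC")) == (False, False, False)

    def test_frame_invariant_stop_free_frame_flagged(self, make_circ):
        # L=9; frame 0 codons: ATG GCA GCA (no stop); frames 1/2 irrelevant
        circ = make_circ("ATGGCAGCA")
        flags = detect_infinite(circ)
        assert flags[0] is True

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_long_unroll_oracle(self, seed, make_circ):
        rng = np.random.default_rng(200 + seed)
        L = int(rng.integers(30, 91))
        seq = "".join(rng.choice(list("ACGT"), L))
        circ = make_circ(seq)
        unrolled = seq * 7  # > 6L in all frames
        expected = []
        for f in range(3):
            hit = any(
                unrolled[c : c + 3] in STOPS
                for c in range(f, f + 6 * L, 3)
            )
            expected.append(not hit)
        if L % 3:
            # frames cycle: one flag for the whole circle
            assert len(set(expected)) == 1
        assert detect_infinite(circ) == tuple(expected)


class TestBuildReference:
    def test_circ_without_atg_yields_nothing(self, make_circ):
        assert build_reference([make_circ("GCTGCAGCTGCA")]) == []

    def test_empty_input_empty_reference(self):
        assert build_reference([]) == []

    def test_window_invariants_on_random_circs(self, make_circ):
        rng = np.random.default_rng(42)
        circs = [
            CircRNARecord(f"r{i}", "".join(rng.choice(list("ACGT"), int(rng.integers(30, 301)))))
            for i in range(80)
        ]
        windows = build_reference(circs)
        assert windows, "expected some windows from 80 random circRNAs"
        for w in windows:
            assert 2 <= len(w.aa_seq) <= 49
            assert "*" not in w.aa_seq
            assert 1 <= w.bsj_span[0] <= w.bsj_span[1] <= len(w.aa_seq)
            if w.width == 1:
                assert w.upstream_flank <= 24 and w.downstream_flank <= 24
            else:
                assert w.width == 2
                assert w.upstream_flank <= 23 and w.downstream_flank <= 23
                assert len(w.aa_seq) <= 48

    def test_identical_windows_kept_per_source_circ(self, make_circ):
        # same sequence under two ids: multi-circRNA evidence is retained
        seq = "ATGGCAGCA" * 3
        wins = build_reference([CircRNARecord("a", seq), CircRNARecord("b", seq)])
        assert {w.source_circ for w in wins} == {"a", "b"}

    def test_determinism(self, make_circ):
        rng = np.random.default_rng(5)
        circs = [
            CircRNARecord(f"d{i}", "".join(rng.choice(list("ACGT"), 120)))
            for i in range(20)
        ]
        w1 = build_reference(circs)
        w2 = build_reference(circs)
        assert w1 == w2


class TestRollingCircleAnalog:
    """Synthetic analog of a 735-nt frame-invariant circRNA whose frame-0
    reading is stop-free: rolling-circle translation with full-flank windows."""

    def _analog(self):
        rng = np.random.default_rng(735)
        non_stop = [c for c in (a + b + d for a in "ACGT" for b in "ACGT" for d in "ACGT")
                    if c not in STOPS]
        codons = [non_stop[i] for i in rng.integers(0, len(non_stop), 245)]
        codons[100] = "ATG"
        return CircRNARecord("synthetic_cdc73_like", "".join(codons))

    def test_infinite_frame_detected_and_window_at_cap(self):
        circ = self._analog()
        assert circ.length_nt == 735
        assert detect_infinite(circ)[0] is True
        wins = [w for w in build_reference([circ]) if w.frame == 0]
        assert len(wins) == 1
        w = wins[0]
        assert w.infinite is True
        assert w.window_id == "synthetic_cdc73_like_0"
        assert w.width == 2  # junction between codons in the invariant frame
        assert len(w.aa_seq) == 48
        assert w.bsj_span == (24, 25)
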