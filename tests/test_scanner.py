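"""The palmprint detector: motif placement, order, heuristics, extraction."""

import numpy as np
import pytest

from palmprint.pssm import MotifHit
from palmprint.scanner import (HeuristicConfig, REPORT_COLUMNS, extract_palmprint,
                               find_motifs, hit_to_row, resolve_order, scan_aa,
                               scan_nt, score_palmprint, write_report)
from palmprint.seqio import SeqRecord
from palmprint.simulate import encode_nt, make_decoy, make_positive, sample_background


def _hits(starts, lengths=(12, 14, 13), scores=(10.0, 10.0, 10.0)):
    return {m: MotifHit(group="g", motif_label=m, start=s, length=l, score=sc)
            for m, s, l, sc in zip("ABC", starts, lengths, scores)}


class TestResolveOrder:
    def test_canonical(self):
        assert resolve_order(_hits((10, 60, 110))) == "ABC"

    def test_permuted(self):
        # C first, then A, then B
        assert resolve_order(_hits((60, 110, 10))) == "CAB"

    def test_bac_rejected(self):
        assert resolve_order(_hits((60, 10, 110))) == "rejected"

    def test_overlap_rejected(self):
        assert resolve_order(_hits((10, 15, 110))) == "rejected"

    def test_missing_motif_rejected(self):
        h = _hits((10, 60, 110))
        del h["B"]
        assert resolve_order(h) == "rejected"


class TestScorePalmprint:
    CFG = HeuristicConfig()

    def test_all_in_band_no_penalty(self):
        # v1 = 60-24 = 36, v2 = 110-74 = 36, pp = 123-10 = 113: all in band
        adj, reasons = score_palmprint(_hits((10, 58, 110)), "ABC", self.CFG)
        assert reasons == []
        assert adj == pytest.approx(30.0)

    def test_motif_below_floor_rejected(self):
        adj, reasons = score_palmprint(
            _hits((10, 58, 110), scores=(10.0, 10.0, 1.9)), "ABC", self.CFG)
        assert "motif_score_below_min:C" in reasons

    def test_short_v1_costs_five(self):
        # A ends at 21 (0-based excl 22); B at 52 -> v1 = 30 < 35
        adj, reasons = score_palmprint(_hits((10, 52, 105)), "ABC", self.CFG)
        assert reasons == []
        assert adj == pytest.approx(25.0)

    def test_v1_at_34_costs_exactly_one_penalty(self):
        adj, _ = score_palmprint(_hits((10, 56, 110)), "ABC", self.CFG)
        assert adj == pytest.approx(25.0)     # 30 - 5, not 30 - 10

    def test_missing_motif_reason(self):
        h = _hits((10, 58, 110))
        del h["B"]
        _, reasons = score_palmprint(h, "ABC", self.CFG)
        assert reasons == ["motif_missing:B"]

    def test_band_penalties_accumulate(self):
        # v1 = 150-22 = 128 > 120 and pp = 213-10 = 203 > 160: two penalties
        adj, reasons = score_palmprint(_hits((10, 150, 200)), "ABC", self.CFG)
        assert reasons == []
        assert adj == pytest.approx(30.0 - 10.0)


class TestFindMotifs:
    def test_planted_consensus_offsets(self, non_rt_sets, rng):
        s = non_rt_sets[0]
        cons = {m: s.pssms[m].consensus() for m in "ABC"}
        frame = (sample_background(10, rng) + cons["A"] + sample_background(40, rng)
                 + cons["B"] + sample_background(25, rng) + cons["C"]
                 + sample_background(10, rng))
        found = find_motifs(frame, s)
        assert found["A"][0].start == 10
        assert found["B"][0].start == 10 + len(cons["A"]) + 40
        assert found["C"][0].start == 10 + len(cons["A"]) + 40 + len(cons["B"]) + 25

    def test_short_frame_empty_map(self, non_rt_sets):
        assert find_motifs("MKLVAGHRTW", non_rt_sets[0]) == {}

    def test_all_x_frame_scores_zero(self, non_rt_sets):
        found = find_motifs("X" * 50, non_rt_sets[0])
        assert set(found) == {"A", "B", "C"}
        assert all(h[0].score == 0.0 for h in found.values())


class TestScanAa:
    def test_planted_abc_truth_recovered(self, non_rt_sets, rng):
        s = non_rt_sets[1]
        rec, truth = make_positive(s, rng, v1_len=40, v2_len=25, order="ABC")
        hit = scan_aa(rec, non_rt_sets)
        assert hit.group == s.group
        assert hit.order == "ABC"
        assert (hit.v1_len, hit.v2_len) == (40, 25)
        assert (hit.pp_start, hit.pp_end) == (truth.pp_start, truth.pp_end)
        assert {m: hit.motifs[m][0] for m in "ABC"} == truth.motif_starts
        assert hit.confidence == "high"

    def test_planted_cab_palmprint_extent(self, non_rt_sets, rng):
        s = non_rt_sets[0]
        rec, truth = make_positive(s, rng, v1_len=40, v2_len=25, order="CAB")
        hit = scan_aa(rec, [s])
        assert hit.order == "CAB"
        # palmprint runs from the first letter of C to the last letter of B
        assert hit.pp_start == hit.motifs["C"][0]
        assert hit.pp_end == hit.motifs["B"][1]
        assert (hit.pp_start, hit.pp_end) == (truth.pp_start, truth.pp_end)

    def test_rt_set_flagged(self, sets, rt_set, rng):
        rec, _ = make_positive(rt_set, rng)
        hit = scan_aa(rec, sets)
        assert hit.group == rt_set.group and hit.is_rt

    def test_winning_set_has_highest_raw_score(self, non_rt_sets, rng):
        for s in non_rt_sets:
            rec, _ = make_positive(s, rng)
            hit = scan_aa(rec, non_rt_sets)
            assert hit.group == s.group

    def test_empty_set_list_errors(self, rng):
        rec = make_decoy(100, rng)
        with pytest.raises(ValueError):
            scan_aa(rec, [])

    def test_wrong_alphabet_errors(self, sets):
        rec = SeqRecord(id="x", seq="ACGTACGTACGT", alphabet="nt")
        with pytest.raises(ValueError):
            scan_aa(rec, sets)

    def test_tiling_invariant(self, non_rt_sets, rng):
        for _ in range(10):
            s = non_rt_sets[int(rng.integers(len(non_rt_sets)))]
            order = "ABC" if rng.random() < 0.5 else "CAB"
            rec, _ = make_positive(s, rng, v1_len=int(rng.integers(35, 60)),
                                   v2_len=int(rng.integers(15, 40)), order=order)
            hit = scan_aa(rec, non_rt_sets)
            motif_total = sum(e - st + 1 for st, e, _ in hit.motifs.values())
            assert hit.pp_len == motif_total + hit.v1_len + hit.v2_len

    def test_determinism(self, non_rt_sets, rng):
        rec, _ = make_positive(non_rt_sets[0], rng)
        assert scan_aa(rec, non_rt_sets) == scan_aa(rec, non_rt_sets)

    def test_threshold_monotonicity(self, non_rt_sets, rng):
        records = []
        for i in range(15):
            s = non_rt_sets[int(rng.integers(len(non_rt_sets)))]
            rec, _ = make_positive(s, rng, temperature=1.5,
                                   record_id=f"p{i}")
            records.append(rec)
        counts = []
        for thr in (5.0, 20.0, 60.0, 120.0, 200.0):
            cfg = HeuristicConfig(high_confidence_threshold=thr)
            counts.append(sum(
                h is not None and h.confidence == "high"
                for h in (scan_aa(r, non_rt_sets, cfg) for r in records)))
        assert counts == sorted(counts, reverse=True)

    def test_exhaustive_mode_rescues_overlapping_optima(self, non_rt_sets, rng):
        """A higher-scoring stray copy of motif A after C breaks the greedy
        placement; considering top-k placements per motif recovers the hit."""
        s = non_rt_sets[0]
        cons = {m: s.pssms[m].consensus() for m in "ABC"}
        weak_a = "A" + cons["A"][1:]   # one substitution: scores below consensus
        frame = (sample_background(5, rng) + weak_a + sample_background(40, rng)
                 + cons["B"] + sample_background(25, rng) + cons["C"]
                 + sample_background(5, rng) + cons["A"])
        rec = SeqRecord(id="trap", seq=frame, alphabet="aa")
        assert scan_aa(rec, [s], HeuristicConfig(top_k=1)) is None
        hit = scan_aa(rec, [s], HeuristicConfig(top_k=4))
        assert hit is not None and hit.order == "ABC"
        assert hit.motifs["A"][0] == 6


class TestScanNt:
    def test_round_trip_all_frames(self, non_rt_sets, rng):
        s = non_rt_sets[1]
        rec, _ = make_positive(s, rng)
        aa_hit = scan_aa(rec, non_rt_sets)
        for frame in (1, 2, 3):
            for strand in "+-":
                nt = encode_nt(rec, rng, frame=frame, strand=strand)
                hit = scan_nt(nt, non_rt_sets)
                assert hit.pp_seq == aa_hit.pp_seq
                assert hit.raw_score == pytest.approx(aa_hit.raw_score)
                assert hit.adjusted_score == pytest.approx(aa_hit.adjusted_score)
                assert hit.strand == strand
                assert hit.frame == (frame if strand == "+" else -frame)

    def test_nt_coordinates_contain_palmprint(self, non_rt_sets, rng):
        from palmprint.seqio import reverse_complement, six_frame_translate
        rec, _ = make_positive(non_rt_sets[0], rng)
        nt = encode_nt(rec, rng, frame=2, strand="-")
        hit = scan_nt(nt, non_rt_sets)
        sub = nt.seq[hit.nt_start - 1:hit.nt_end]
        if hit.strand == "-":
            sub = reverse_complement(sub)
        assert six_frame_translate(sub + "AAA")[0].aa_seq[:hit.pp_len] == hit.pp_seq

    def test_too_short_errors(self, sets, rng):
        rec = SeqRecord(id="tiny", seq="ACGTACGT", alphabet="nt")
        with pytest.raises(ValueError):
            scan_nt(rec, sets)

    def test_stop_codon_in_motif_vetoes(self, non_rt_sets, rng):
        s = non_rt_sets[0]
        rec, truth = make_positive(s, rng)
        # corrupt motif B with a stop in the protein, then encode
        mid = truth.motif_starts["B"] + 5
        seq = rec.seq[:mid] + "*" + rec.seq[mid + 1:]
        broken = SeqRecord(id="broken", seq=seq, alphabet="aa")
        nt = encode_nt(broken, rng, frame=1, strand="+")
        hit = scan_nt(nt, [s])
        assert hit is None or hit.confidence == "low"


class TestExtractPalmprint:
    def test_length_tiling(self, non_rt_sets, rng):
        rec, _ = make_positive(non_rt_sets[1], rng, v1_len=40, v2_len=25)
        hit = scan_aa(rec, non_rt_sets)
        pp = extract_palmprint(hit)
        assert len(pp.seq) == 12 + 40 + 14 + 25 + 13 == 104
        assert pp.id == f"{rec.id}:{hit.pp_start}-{hit.pp_end}:+1"

    def test_rescan_idempotent(self, non_rt_sets, rng):
        rec, _ = make_positive(non_rt_sets[0], rng, order="ABC")
        hit = scan_aa(rec, non_rt_sets)
        pp = extract_palmprint(hit)
        rehit = scan_aa(pp, non_rt_sets)
        assert rehit.group == hit.group and rehit.order == hit.order
        shift = hit.pp_start - 1
        for m in "ABC":
            assert rehit.motifs[m][0] == hit.motifs[m][0] - shift

    def test_rejected_hit_errors(self, non_rt_sets, rng):
        rec, _ = make_positive(non_rt_sets[0], rng)
        hit = scan_aa(rec, non_rt_sets)
        hit.reject_reasons = ["motif_score_below_min:A"]
        with pytest.raises(ValueError):
            extract_palmprint(hit)


class TestReport:
    def test_report_round_numbers(self, non_rt_sets, rng, tmp_path):
        rec, _ = make_positive(non_rt_sets[0], rng)
        hit = scan_aa(rec, non_rt_sets)
        row = hit_to_row(hit)
        assert len(row) == len(REPORT_COLUMNS)
        assert row[REPORT_COLUMNS.index("confidence")] == "high"
        out = tmp_path / "r.tsv"
        write_report([(rec.id, hit), ("miss", None)], out)
        lines = out.read_text().splitlines()
        assert lines[0].split("\t") == REPORT_COLUMNS
        assert lines[2].split("\t")[0] == "miss"
        assert lines[2].split("\t")[1] == "."
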