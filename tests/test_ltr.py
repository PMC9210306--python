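"""LTR discovery: probe search, repeat pairing, consensus, ORFs, classes."""

import numpy as np
import pytest

from genome_workbench import ltr, synthetic as syn
from genome_workbench.records import LTRElement, SeedHit, SequenceRecord, revcomp


def _rng(label):
    return syn.rng_for(99, label)


class TestProbeSearch:
    def test_exact_substring_single_hit(self):
        rng = _rng("a")
        probe = syn.random_seq(300, rng)
        g = [SequenceRecord("g", syn.random_seq(5000, rng) + probe
                            + syn.random_seq(5000, rng))]
        hits = ltr.probe_search(g, probe)
        assert len(hits) == 1
        h = hits[0]
        assert (h.start, h.end, h.strand) == (5000, 5300, "+")
        assert h.identity == 100.0

    def test_reverse_complement_hits_minus_strand_same_span(self):
        rng = _rng("b")
        probe = syn.random_seq(300, rng)
        g = [SequenceRecord("g", syn.random_seq(5000, rng) + revcomp(probe)
                            + syn.random_seq(5000, rng))]
        hits = ltr.probe_search(g, probe)
        assert len(hits) == 1
        assert (hits[0].start, hits[0].end, hits[0].strand) == (5000, 5300, "-")

    def test_three_divergent_sites_all_found(self):
        rng = _rng("c")
        probe = syn.random_seq(600, rng)
        parts = [syn.random_seq(4000, rng)]
        for _ in range(3):
            parts.append(syn.mutate(probe, 0.05, rng))
            parts.append(syn.random_seq(4000, rng))
        g = [SequenceRecord("g", "".join(parts))]
        hits = ltr.probe_search(g, probe, min_identity=85)
        assert len(hits) == 3
        assert all(h.identity >= 90 for h in hits)

    def test_empty_genome_and_bad_probes(self):
        assert ltr.probe_search([], "ACGT" * 30) == []
        with pytest.raises(ValueError):
            ltr.probe_search([], "ACGT")  # < 50 bp
        with pytest.raises(ValueError):
            ltr.probe_search([], "N" * 100)

    def test_identity_threshold_monotonicity(self):
        rng = _rng("d")
        probe = syn.random_seq(400, rng)
        parts = [syn.random_seq(2000, rng)]
        for div in (0.0, 0.05, 0.12):
            parts += [syn.mutate(probe, div, rng), syn.random_seq(2000, rng)]
        g = [SequenceRecord("g", "".join(parts))]
        n = [len(ltr.probe_search(g, probe, min_identity=t))
             for t in (80, 90, 99)]
        assert n[0] >= n[1] >= n[2]


class TestSmithWatermanOracle:
    """probe_search must agree with brute-force local alignment (<= 50 kb)."""

    @staticmethod
    def oracle(genome_seq, probe, min_identity, min_length):
        from Bio import Align

        hits = []
        for strand in "+-":
            q = probe if strand == "+" else revcomp(probe)
            aligner = Align.PairwiseAligner(
                mode="local", match_score=1, mismatch_score=-2,
                open_gap_score=-4, extend_gap_score=-1)
            work = genome_seq
            while True:
                aln = aligner.align(work, q)[0]
                if aln.score < min_length * 0.5:
                    break
                ts = int(aln.aligned[0][0][0])
                te = int(aln.aligned[0][-1][1])
                m = 0
                for (t0, t1), (q0, q1) in zip(aln.aligned[0], aln.aligned[1]):
                    m += sum(work[t0 + i] == q[q0 + i] for i in range(t1 - t0))
                span = max(te - ts,
                           int(aln.aligned[1][-1][1] - aln.aligned[1][0][0]))
                if te - ts >= min_length and 100 * m / span >= min_identity:
                    hits.append((ts, te, strand))
                work = work[:ts] + "N" * (te - ts) + work[te:]
        return sorted(hits)

    def test_hit_sets_agree_on_50kb_genome(self):
        rng = _rng("sw")
        probe = syn.random_seq(600, rng)
        g = (syn.random_seq(15_000, rng) + probe + syn.random_seq(8_000, rng)
             + syn.mutate(probe, 0.05, rng) + syn.random_seq(8_000, rng)
             + revcomp(syn.mutate(probe, 0.10, rng))
             + syn.random_seq(17_000, rng))
        mine = ltr.probe_search([SequenceRecord("g", g)], probe,
                                min_identity=85, min_length=100)
        expected = self.oracle(g, probe, 85, 100)
        assert len(mine) == len(expected) == 3
        for (ts, te, strand) in expected:
            matched = [h for h in mine if h.strand == strand
                       and min(h.end, te) - max(h.start, ts)
                       > 0.9 * max(te - ts, h.end - h.start)]
            assert len(matched) == 1

    def test_no_spurious_hits_on_repeat_free_genome(self):
        rng = _rng("sw0")
        probe = syn.random_seq(600, rng)
        g = syn.random_seq(50_000, rng)
        mine = ltr.probe_search([SequenceRecord("g", g)], probe,
                                min_identity=85, min_length=100)
        assert mine == []
        assert self.oracle(g, probe, 85, 100) == []


class TestFlankingRepeatPairs:
    def test_repeat_free_window_yields_nothing(self):
        rng = _rng("e")
        g = [SequenceRecord("g", syn.random_seq(60_000, rng))]
        hit = SeedHit("g", 30_000, 30_500, "+", 100.0, 500.0)
        assert ltr.find_flanking_repeat_pairs(g, [hit]) == []

    def test_planted_zero_divergence_pair_recovered(self):
        spec = syn.PlantedElementSpec("intact", ltr_length=400,
                                      ltr_pair_divergence=0.0, orf_length=4500)
        cfg = syn.SimulationConfig(seed=21, genome_length=200_000,
                                   element_specs=[spec])
        genome, truth = syn.gen_nuclear_genome(cfg)
        e = truth.elements[0]
        hit = SeedHit("chr1", e["internal"][0] + 500, e["internal"][0] + 1500,
                      "+", 100.0, 1000.0)
        cands = ltr.find_flanking_repeat_pairs(genome, [hit])
        assert len(cands) == 1
        c = cands[0]
        for got, want in zip(c.ltr5_span + c.ltr3_span,
                             e["ltr5"] + e["ltr3"]):
            assert abs(got - want) <= 5
        assert c.ltr_pair_identity >= 99.0

    def test_distant_elements_never_cross_paired(self):
        specs = [
            syn.PlantedElementSpec("intact", insertion_site=("chr1", 40_000)),
            syn.PlantedElementSpec("intact", insertion_site=("chr1", 76_000)),
        ]
        cfg = syn.SimulationConfig(seed=22, genome_length=160_000,
                                   element_specs=specs)
        genome, truth = syn.gen_nuclear_genome(cfg)
        hits = [SeedHit("chr1", e["internal"][0] + 500,
                        e["internal"][0] + 1500, "+", 100.0, 1000.0)
                for e in truth.elements]
        cands = ltr.find_flanking_repeat_pairs(genome, hits, max_span=15_000)
        assert len(cands) == 2
        for c in cands:
            assert c.end - c.start <= 15_000


class TestConsensus:
    def _candidates_from_copies(self, copies, gap=300):
        rng = _rng("cons")
        parts, spans = [], []
        pos = 0
        for c in copies:
            parts.append(c)
            spans.append((pos, pos + len(c)))
            pos += len(c)
            spacer = syn.random_seq(gap, rng)
            parts.append(spacer)
            pos += gap
        genome = [SequenceRecord("g", "".join(parts))]
        cands = [
            LTRElement("g", "+", spans[i], spans[i + 1])
            for i in range(0, len(spans) - 1, 2)
        ]
        return genome, cands

    def test_identical_copies_reproduce_copy(self):
        rng = _rng("cons1")
        master = syn.random_seq(400, rng)
        genome, cands = self._candidates_from_copies([master] * 10)
        cons = ltr.build_consensus_ltr(cands, genome)
        assert cons.seq == master
        assert cons.support == 10
        assert all(f == 1.0 for f in cons.column_majority)

    def test_majority_base_wins_single_divergent_member(self):
        rng = _rng("cons2")
        master = syn.random_seq(400, rng)
        variant = ("A" if master[200] != "A" else "G").join(
            [master[:200], master[201:]])
        genome, cands = self._candidates_from_copies([master] * 8 + [variant] * 2)
        cons = ltr.build_consensus_ltr(cands, genome)
        assert cons.seq == master

    def test_consensus_close_to_master_at_3pct_divergence(self):
        rng = _rng("cons3")
        master = syn.random_seq(400, rng)
        copies = [syn.mutate(master, 0.03, rng) for _ in range(50)]
        genome, cands = self._candidates_from_copies(copies)
        cons = ltr.build_consensus_ltr(cands, genome)
        dist = 100.0 - ltr._pair_identity(cons.seq, master)
        assert dist <= 1.0

    def test_fewer_than_two_members_is_error(self):
        rng = _rng("cons4")
        genome = [SequenceRecord("g", syn.random_seq(1000, rng))]
        with pytest.raises(ValueError):
            ltr.build_consensus_ltr(
                [LTRElement("g", "+", (0, 400))], genome)

    def test_empty_consensus_rejected(self):
        with pytest.raises(ValueError):
            ltr.scan_consensus([], "")


class TestFindOrfs:
    def test_planted_stop_free_frame_found(self):
        rng = _rng("orf1")
        orf = syn.random_orf(4500, rng)
        seq = syn.random_seq(1000, rng) + "TAA" + orf + "TAG" + \
            syn.random_seq(1000, rng)
        rec = SequenceRecord("g", seq)
        found = ltr.find_orfs(rec, (0, len(seq)), "+", min_length=3000)
        assert found and found[0].length >= 4500

    def test_random_sequence_rarely_has_3kb_orf(self):
        hits = 0
        for seed in range(100):
            rng = syn.rng_for(seed, "orf-null")
            rec = SequenceRecord("g", syn.random_seq(3000, rng))
            if ltr.find_orfs(rec, (0, 3000), "+", min_length=3000):
                hits += 1
        assert hits <= 2  # expected longest ORF in random 3 kb is far below 3 kb

    def test_min_length_zero_tiles_the_frame(self):
        rng = _rng("orf2")
        rec = SequenceRecord("g", syn.random_seq(3001, rng))
        for frame in range(3):
            segs = [o for o in ltr.find_orfs(rec, (0, 3001), "+", min_length=0)
                    if o.frame == frame]
            n_codons = (3001 - frame) // 3
            stops = sum(1 for i in range(frame, 3001 - 2, 3)
                        if rec.seq[i:i + 3] in ltr.STOP_CODONS)
            total_seg = sum(o.length for o in segs)
            # segments plus stop codons tile the frame (zero-length segments
            # between adjacent stops contribute nothing)
            assert total_seg + 3 * stops == 3 * n_codons

    def test_minus_strand_coordinates_map_back(self):
        rng = _rng("orf3")
        orf = syn.random_orf(3300, rng)
        plus = syn.random_seq(500, rng) + "TAA" + orf + "TAG" + \
            syn.random_seq(500, rng)
        rec = SequenceRecord("g", revcomp(plus))
        found = ltr.find_orfs(rec, (0, len(plus)), "-", min_length=3000)
        assert found
        s, e = found[0].start, found[0].end
        assert revcomp(rec.seq[s:e]) == orf


class TestClassification:
    def test_full_panel_recovered(self, element_genome):
        cfg, genome, truth = element_genome
        hits = ltr.probe_search(genome, truth.probe)
        cands = ltr.find_flanking_repeat_pairs(genome, hits)
        cons = ltr.build_consensus_ltr(cands, genome)
        elements = ltr.classify_elements(
            ltr.scan_consensus(genome, cons), genome,
            consensus_length=len(cons.seq))
        assert len(elements) == len(truth.elements)
        for e, t in zip(elements, truth.elements):
            assert e.class_label == t["class_label"]
            # truncated LTR copies have genuinely ambiguous end boundaries
            tol = 35 if t.get("ltr3_truncated") else 10
            assert abs(e.start - t["start"]) <= tol
            assert abs(e.end - t["end"]) <= tol

    def test_single_hit_is_solo(self):
        rng = _rng("cl1")
        g = [SequenceRecord("g", syn.random_seq(10_000, rng))]
        els = ltr.classify_elements(
            [SeedHit("g", 2000, 2400, "+", 99.0, 400.0)], g,
            consensus_length=400)
        assert [e.class_label for e in els] == ["solo"]

    def test_orf_of_exactly_3000_is_not_intact(self):
        # boundary: the intact rule is strictly greater than 3 kb
        rng = _rng("cl2")
        ltr_seq = syn.random_seq(400, rng)
        orf = syn.random_orf(3000, rng)
        internal = ("TAATAATAA" + syn.random_seq(99, rng) + "TAA" + orf
                    + "TAA" + syn.random_seq(99, rng) + "TAATAATAA")
        seq = syn.random_seq(2000, rng) + ltr_seq + internal + ltr_seq \
            + syn.random_seq(2000, rng)
        g = [SequenceRecord("g", seq)]
        h1 = SeedHit("g", 2000, 2400, "+", 100.0, 400.0)
        s2 = 2400 + len(internal)
        h2 = SeedHit("g", s2, s2 + 400, "+", 100.0, 400.0)
        els = ltr.classify_elements([h1, h2], g, consensus_length=400)
        assert len(els) == 1
        assert els[0].orf_length == 3000
        assert els[0].class_label == "degenerate"
        # and one codon longer is intact
        orf2 = syn.random_orf(3003, rng)
        internal2 = internal.replace(orf, orf2)
        seq2 = seq.replace(internal, internal2)
        g2 = [SequenceRecord("g", seq2)]
        h2b = SeedHit("g", s2 + 3, s2 + 403, "+", 100.0, 400.0)
        els2 = ltr.classify_elements([h1, h2b], g2, consensus_length=400)
        assert els2[0].class_label == "intact"

    def test_strand_symmetry_of_classification(self):
        spec = syn.PlantedElementSpec("intact")
        cfg = syn.SimulationConfig(seed=31, genome_length=120_000,
                                   element_specs=[spec])
        genome, truth = syn.gen_nuclear_genome(cfg)
        flipped = [SequenceRecord("chr1", revcomp(genome[0].seq))]
        L = len(genome[0])
        cons = truth.master_ltr
        fwd = ltr.classify_elements(ltr.scan_consensus(genome, cons), genome,
                                    consensus_length=len(cons))
        rev = ltr.classify_elements(ltr.scan_consensus(flipped, cons), flipped,
                                    consensus_length=len(cons))
        assert len(fwd) == len(rev) == 1
        assert fwd[0].class_label == rev[0].class_label == "intact"
        assert abs(rev[0].start - (L - fwd[0].end)) <= 2
        assert abs(rev[0].end - (L - fwd[0].start)) <= 2
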