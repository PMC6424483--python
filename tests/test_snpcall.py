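"""Dual-evidence variant calling: pileups, filters, intersection, summaries."""

import random

import pytest

from txsnp import snpcall
from txsnp.io_formats import AlignmentRecord, TranscriptRecord


def aln(rid, tid="t1", start=1, ops=None, mapq=40, seq="ACGTACGTAC",
        quals=None, mate=1, reverse=False):
    return AlignmentRecord(
        read_id=rid, transcript_id=tid, start=start,
        aligned_ops=ops or [("match", len(seq))], mapq=mapq, sequence=seq,
        base_qualities=quals or (30,) * len(seq), mate=mate,
        is_reverse=reverse)


class TestRemoveDuplicates:
    def test_identical_placements_collapse_to_best_mapq(self):
        a = aln("r1", mapq=10)
        b = aln("r2", mapq=50)
        kept = snpcall.remove_duplicates([a, b])
        assert [k.read_id for k in kept] == ["r2"]
        assert a.is_duplicate and not b.is_duplicate

    def test_same_start_different_span_both_kept(self):
        a = aln("r1", ops=[("match", 10)])
        b = aln("r2", ops=[("match", 8), ("softclip", 2)])
        assert len(snpcall.remove_duplicates([a, b])) == 2

    def test_random_placements_match_grouping_oracle(self):
        rng = random.Random(0)
        alns = []
        for i in range(60):
            start = rng.randint(1, 4)
            span = rng.choice([8, 10])
            ops = [("match", span)]
            if span == 8:
                ops.append(("softclip", 2))
            alns.append(aln(f"r{i}", start=start, ops=ops,
                            mapq=rng.randint(0, 60),
                            mate=rng.choice([1, 2]),
                            reverse=rng.choice([True, False])))
        kept = snpcall.remove_duplicates(list(alns))
        # oracle: brute-force grouping over the defining tuple
        groups = {}
        for a in alns:
            key = (a.transcript_id, a.start, a.reference_span, a.mate,
                   a.is_reverse)
            groups.setdefault(key, []).append(a)
        assert len(kept) == len(groups)
        for g in groups.values():
            best_mapq = max(a.mapq for a in g)
            survivor = [a for a in g if not a.is_duplicate]
            assert len(survivor) == 1
            assert survivor[0].mapq == best_mapq


class TestPileup:
    transcripts = [TranscriptRecord("t1", "ACGTACGTACGTACGTACGT")]

    def test_three_perfect_reads_give_depth_three_on_ref(self):
        alns = [aln(f"r{i}", seq="ACGTACGTAC") for i in range(3)]
        piles = snpcall.pileup(alns, self.transcripts)
        cols = list(piles["t1"].columns())
        assert cols[0].depth == 3
        assert cols[0].hq_counts == (3, 0, 0, 0)   # all on ref base A

    def test_low_quality_base_counts_depth_but_not_hq(self):
        alns = [aln("r1", seq="A" * 10, quals=(10,) * 10)]
        piles = snpcall.pileup(alns, self.transcripts, hq_threshold=20)
        col = next(piles["t1"].columns())
        assert col.depth == 1 and sum(col.hq_counts) == 0

    def test_softclip_and_deletion_semantics(self):
        # 2S4M2D2M: clipped bases invisible; deleted positions lose depth
        a = aln("r1", start=3,
                ops=[("softclip", 2), ("match", 4), ("deletion", 2),
                     ("match", 2)],
                seq="GGGTACAC", quals=(30,) * 8)
        piles = snpcall.pileup([a], self.transcripts)
        depth = piles["t1"].depth
        assert list(depth[:12]) == [0, 0, 1, 1, 1, 1, 0, 0, 1, 1, 0, 0]

    def test_alignment_past_transcript_end_names_read(self):
        a = aln("runaway", start=15, seq="ACGTACGTAC")
        with pytest.raises(ValueError, match="runaway"):
            snpcall.pileup([a], self.transcripts)

    def test_pileup_matches_brute_force_recount(self, pipeline):
        """Cross-check a handful of transcripts against a per-base recount
        done directly from the alignment records."""
        piles = snpcall.pileup(pipeline.t2t_dedup, pipeline.transcripts)
        t = pipeline.transcripts[0]
        brute_depth = [0] * len(t)
        brute_hq = {b: [0] * len(t) for b in "ACGT"}
        for a in pipeline.t2t_dedup:
            if a.transcript_id != t.transcript_id:
                continue
            rpos, qpos = a.start - 1, 0
            for op, n in a.aligned_ops:
                if op in ("softclip", "insertion"):
                    qpos += n
                elif op == "deletion":
                    rpos += n
                else:
                    for i in range(n):
                        brute_depth[rpos + i] += 1
                        if a.base_qualities[qpos + i] >= 20:
                            brute_hq[a.sequence[qpos + i]][rpos + i] += 1
                    rpos += n
                    qpos += n
        pile = piles[t.transcript_id]
        assert list(pile.depth) == brute_depth
        for bi, b in enumerate("ACGT"):
            assert list(pile.hq[bi]) == brute_hq[b]


class TestCallVariants:
    ref = {"t1": "A" * 50}

    def col(self, depth, alt_hq, pos=10):
        # ref A; alt counts go to G
        return snpcall.PileupColumn("t1", pos, depth,
                                    (max(0, depth - alt_hq - 2), 0, alt_hq,
                                     0))

    def test_t2t_boundary_depth8_alt2_called(self):
        calls = snpcall.call_variants([self.col(8, 2)], self.ref, "T2T")
        assert len(calls) == 1 and calls[0].alt == "G"

    def test_g2t_depth19_not_called(self):
        assert snpcall.call_variants([self.col(19, 5)], self.ref, "G2T") == []

    def test_g2t_depth20_alt3_called(self):
        assert len(snpcall.call_variants([self.col(20, 3)], self.ref,
                                         "G2T")) == 1

    def test_depth_201_excluded_for_both_sources(self):
        for source in ("T2T", "G2T"):
            assert snpcall.call_variants([self.col(201, 50)], self.ref,
                                         source) == []

    def test_alt_tie_breaks_alphabetically(self):
        col = snpcall.PileupColumn("t1", 5, 20, (10, 4, 4, 0))
        (call,) = snpcall.call_variants([col], self.ref, "T2T")
        assert call.alt == "C"

    def test_unknown_source_rejected(self):
        with pytest.raises(ValueError, match="unknown source"):
            snpcall.call_variants([], self.ref, "X2T")

    def test_raising_hq_threshold_never_adds_calls(self, pipeline):
        transcripts = pipeline.transcripts

        def n_calls(hq):
            piles = snpcall.pileup(pipeline.t2t_dedup, transcripts,
                                   hq_threshold=hq)
            cols = [c for p in piles.values() for c in p.columns()]
            return len(snpcall.call_variants(cols, transcripts, "T2T"))

        counts = [n_calls(hq) for hq in (10, 20, 31)]
        assert counts == sorted(counts, reverse=True)


class TestIntersection:
    def mk(self, tid, pos, ref, alt, source):
        return snpcall.VariantCall(tid, pos, ref, alt, 30, 5, source)

    def test_identical_singletons_intersect(self):
        t = [self.mk("t1", 5, "A", "G", "T2T")]
        g = [self.mk("t1", 5, "A", "G", "G2T")]
        (snp,) = snpcall.intersect_calls(t, g)
        assert snp.key == ("t1", 5, "A", "G")
        assert snp.depth_t2t == snp.depth_g2t == 30

    def test_same_position_different_alt_excluded(self):
        t = [self.mk("t1", 5, "A", "G", "T2T")]
        g = [self.mk("t1", 5, "A", "C", "G2T")]
        assert snpcall.intersect_calls(t, g) == []

    def test_random_sets_match_set_oracle(self):
        rng = random.Random(3)
        universe = [("t%d" % rng.randint(1, 4), rng.randint(1, 30), "A", alt)
                    for alt in "CGT" for _ in range(25)]
        t_keys = set(rng.sample(universe, 30))
        g_keys = set(rng.sample(universe, 30))
        t = [self.mk(*k, "T2T") for k in t_keys]
        g = [self.mk(*k, "G2T") for k in g_keys]
        got = {s.key for s in snpcall.intersect_calls(t, g)}
        assert got == (t_keys & g_keys)
        assert len(got) <= min(len(t_keys), len(g_keys))


class TestSummary:
    def test_published_common_snp_density(self):
        s = snpcall.SnpSummary(n_contigs_with_snps=11_769,
                               n_contigs_reference=18_479,
                               n_snps=60_414, assembly_bp=20_316_164)
        assert round(s.snps_per_transcript, 2) == 5.13

    def test_published_g2t_transcript_fraction(self):
        s = snpcall.SnpSummary(n_contigs_with_snps=15_593,
                               n_contigs_reference=18_479,
                               n_snps=131_188, assembly_bp=20_316_163)
        assert round(s.pct_transcripts_with_snps, 2) == 84.38
        assert round(s.snps_per_transcript, 2) == 8.41

    def test_zero_calls_give_zero_rates(self):
        ref = [TranscriptRecord("t1", "ACGT")]
        s = snpcall.summarize([], ref)
        assert s.snps_per_transcript == 0.0
        assert s.mutation_rate_snps_per_bp == 0.0

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            snpcall.summarize([], [])


class TestMappingRate:
    def test_half_aligned(self):
        alns = [aln(f"r{i}") for i in range(5)]
        assert snpcall.mapping_rate(alns, 10) == 50.0

    def test_all_aligned_is_100(self):
        alns = [aln(f"r{i}", mate=m) for i in range(3) for m in (1, 2)]
        assert snpcall.mapping_rate(alns, 6) == 100.0

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            snpcall.mapping_rate([], 0)

    def test_simulator_run_matches_recount(self, pipeline):
        reads = pipeline.reads
        rate = snpcall.mapping_rate(reads.t2t_alignments, reads.n_rna_reads)
        recount = 100.0 * len({(a.read_id, a.mate)
                               for a in reads.t2t_alignments}) \
            / reads.n_rna_reads
        assert rate == recount
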