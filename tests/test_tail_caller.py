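"""Query building, read-end mapping and mature 3'-tail calling."""

import numpy as np
import pysam
import pytest

from conftest import brute_force_tail_candidates
from sdscan._alphabet import revcomp_dna
from sdscan.synthetic import make_rdna, simulate_16s_reads
from sdscan.tail_caller import (
    AmbiguousCoreError,
    EmptyInputError,
    MatureTailCall,
    MultiplicityParseError,
    NoCoreError,
    NoTailCallError,
    TailPileup,
    TailQuery,
    build_query,
    call_prominent_tail,
    detect_secondary_tails,
    map_read_ends,
    parse_fasta_plus,
)


@pytest.fixture(scope="module")
def rdna_query():
    rdna, terminus = make_rdna(length=1500, seed=4)
    return rdna, terminus, build_query(rdna)


class TestBuildQuery:
    def test_full_flanks_give_205nt_query(self, rdna_query):
        rdna, _, q = rdna_query
        assert len(q.seq) == 205
        assert q.core_offset == 100
        assert q.seq[100:105] == "CCTCC"
        assert not (q.truncated_5p or q.truncated_3p)

    def test_core_near_start_truncates_and_flags(self):
        seq = "A" * 30 + "CCTCC" + "G" * 300
        q = build_query(seq)
        assert q.truncated_5p and not q.truncated_3p
        assert q.core_offset == 30
        assert len(q.seq) == 30 + 5 + 100

    def test_multiple_cores_require_occurrence_index(self):
        seq = "A" * 120 + "CCTCC" + "G" * 120 + "CCTCC" + "A" * 120
        with pytest.raises(AmbiguousCoreError):
            build_query(seq)
        q = build_query(seq, occurrence=1)
        assert q.seq[q.core_offset : q.core_offset + 5] == "CCTCC"

    def test_absent_core_raises(self):
        with pytest.raises(NoCoreError):
            build_query("A" * 400)


class TestMapReadEnds:
    def test_exact_substring_with_multiplicity(self, rdna_query):
        _, _, q = rdna_query
        read = q.seq[91:121]  # 30 nt, ends at query position 120
        pileup = map_read_ends([(read, 7)], q)
        assert pileup.counts[120] == 7
        assert pileup.counts.sum() == 7
        assert pileup.total_mapped == 7

    def test_below_min_match_is_unmapped(self, rdna_query):
        _, _, q = rdna_query
        read = q.seq[97:121]  # 24 nt < min_match
        pileup = map_read_ends([(read, 1)], q)
        assert pileup.counts.sum() == 0

    def test_revcomp_read_end_matches_brute_force(self, rdna_query):
        """A reverse-orientation read marks the same fragment 3' end that a
        brute-force alignment of the reverse-complemented read gives."""
        _, _, q = rdna_query
        frag = q.seq[60:100]  # sense fragment, 3' end at 99
        read = revcomp_dna(frag)
        pileup = map_read_ends([(read, 1)], q)
        # brute force: align revcomp(read) (the sense fragment) at every
        # ungapped offset, find the perfect hit, take its right edge
        sense = revcomp_dna(read)
        hits = [
            i + len(sense) - 1
            for i in range(len(q.seq) - len(sense) + 1)
            if q.seq[i : i + len(sense)] == sense
        ]
        assert hits == [99]
        assert pileup.counts[99] == 1

    def test_orientation_invariance(self, sim_reads_bundle):
        rdna = sim_reads_bundle["rdna"]
        q = build_query(rdna)
        reads = sim_reads_bundle["reads"][:50]
        fwd = map_read_ends(reads, q)
        rev = map_read_ends([(revcomp_dna(s), c) for s, c in reads], q)
        assert np.array_equal(fwd.counts, rev.counts)

    def test_pileup_conservation(self, sim_reads_bundle):
        q = build_query(sim_reads_bundle["rdna"])
        pileup = map_read_ends(sim_reads_bundle["reads"], q)
        assert pileup.counts.sum() == pileup.total_mapped
        assert pileup.total_mapped <= sum(c for _, c in sim_reads_bundle["reads"])

    def test_empty_read_set_raises(self, rdna_query):
        with pytest.raises(EmptyInputError):
            map_read_ends([], rdna_query[2])

    def test_malformed_multiplicity_header_names_read(self, tmp_path):
        fa = tmp_path / "reads.fa"
        fa.write_text(">readX\nACGTACGTACGTACGTACGTACGTACGT\n")
        with pytest.raises(MultiplicityParseError, match="readX"):
            parse_fasta_plus(str(fa))

    def test_sam_ingestion_matches_internal_mapper(self, rdna_query, tmp_path):
        _, _, q = rdna_query
        sam = tmp_path / "reads.sam"
        header = {"HD": {"VN": "1.6"}, "SQ": [{"LN": len(q.seq), "SN": "query"}]}
        with pysam.AlignmentFile(str(sam), "w", header=header) as fh:
            for start, length in [(91, 30), (60, 40), (150, 30)]:
                a = pysam.AlignedSegment(fh.header)
                a.query_name = f"r{start}"
                a.query_sequence = q.seq[start : start + length]
                a.reference_id = 0
                a.reference_start = start
                a.cigarstring = f"{length}M"
                a.mapping_quality = 60
                a.flag = 0
                fh.write(a)
        pileup = map_read_ends(str(sam), q)
        assert pileup.counts[120] == 1
        assert pileup.counts[99] == 1
        assert pileup.counts[179] == 1
        assert pileup.total_mapped == 3


def _pileup(counts_map, query: TailQuery) -> TailPileup:
    counts = np.zeros(len(query.seq), dtype=np.int64)
    for pos, c in counts_map.items():
        counts[pos] = c
    return TailPileup(counts=counts, total_mapped=int(counts.sum()), query=query)


class TestCallProminentTail:
    def test_call_agrees_with_brute_force_criteria(self, rdna_query):
        rdna, terminus, q = rdna_query
        t_query = 107  # 3' end of the planted GATCACCTCCTTT on the query
        rng = np.random.default_rng(8)
        counts_map = {t_query: 50}
        for pos in range(t_query + 1, t_query + 8):
            counts_map[pos] = int(rng.integers(0, 2))
        pileup = _pileup(counts_map, q)
        call = call_prominent_tail(pileup)
        cands = brute_force_tail_candidates(pileup.counts, q.seq, q.core_offset)
        assert (call.terminus, call.peak_count) == max(cands, key=lambda c: c[1])
        assert call.terminus == t_query
        assert call.tail_seq == "GAUCACCUCCUUU"
        assert "CCUCC" in call.tail_seq
        assert call.peak_count > call.downstream_sum

    def test_all_zero_pileup_raises(self, rdna_query):
        with pytest.raises(NoTailCallError):
            call_prominent_tail(_pileup({}, rdna_query[2]))

    def test_peak_without_core_rejected_next_best_called(self, rdna_query):
        _, _, q = rdna_query
        # motif starts at 95 on this query; a terminus at 100 implies the
        # tail GAUCAC, which lacks the CCUCC core -> rejected
        pileup = _pileup({100: 1000, 107: 50}, q)
        call = call_prominent_tail(pileup)
        assert call.terminus == 107

    def test_downstream_criterion_rejects_buried_peak(self, rdna_query):
        _, _, q = rdna_query
        pileup = _pileup(
            {107: 50, 108: 30, 109: 30, 110: 25, 111: 20, 112: 25, 113: 20, 114: 40},
            q,
        )
        with pytest.raises(NoTailCallError, match="best failing"):
            call_prominent_tail(pileup)


class TestSecondaryTails:
    def test_thirty_percent_secondary_detected(self, rdna_query):
        _, _, q = rdna_query
        pileup = _pileup({107: 100, 105: 30}, q)
        primary = call_prominent_tail(pileup)
        assert primary.terminus == 107
        secondary = detect_secondary_tails(pileup, primary)
        assert [(c.terminus, c.peak_count) for c in secondary] == [(105, 30)]
        assert secondary[0].tail_seq == "GAUCACCUCCU"  # the heterogeneity case

    def test_ten_percent_secondary_below_threshold(self, rdna_query):
        _, _, q = rdna_query
        pileup = _pileup({107: 100, 105: 10}, q)
        primary = call_prominent_tail(pileup)
        assert detect_secondary_tails(pileup, primary) == []

    def test_secondary_rechecks_both_criteria(self, rdna_query):
        _, _, q = rdna_query
        # candidate at 30% of primary but buried in downstream signal
        pileup = _pileup({107: 100, 104: 30, 105: 20, 106: 25}, q)
        primary = call_prominent_tail(pileup)
        secondary = detect_secondary_tails(pileup, primary)
        assert all(c.terminus != 104 for c in secondary)


class TestCallerRecovery:
    def test_planted_terminus_recovered(self, sim_reads_bundle):
        rdna = sim_reads_bundle["rdna"]
        q = build_query(rdna)
        pileup = map_read_ends(sim_reads_bundle["reads"], q)
        call = call_prominent_tail(pileup)
        # translate the genomic terminus into query coordinates
        offset = rdna.index(q.seq)
        assert call.terminus + offset == sim_reads_bundle["terminus"]

    def test_zero_noise_single_site(self):
        rdna, terminus = make_rdna(seed=21)
        from sdscan.synthetic import ReadNoise

        reads, _ = simulate_16s_reads(
            rdna, terminus, depth=200, seed=21,
            noise=ReadNoise(signal_frac=1.0, upstream_uniform_frac=0.0),
        )
        q = build_query(rdna)
        pileup = map_read_ends(reads, q)
        assert (pileup.counts > 0).sum() == 1
        assert pileup.counts.max() == 200
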