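import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pamscan import (
    SequenceRecord,
    build_seed_index,
    count_kmers_dense,
    decode_kmer,
    encode_kmer,
    mark_specific,
    oracle_count_substring,
    scan_candidates,
)

SITE = "ACTTCTTCGTCCAACTTCTTCGG"  # seed GTCCAACTTCTT


def scan_all(records):
    candidates = []
    for rec in records:
        candidates.extend(scan_candidates(rec))
    return candidates


class TestEncodeKmer:
    @pytest.mark.parametrize(
        "kmer, code",
        [
            ("AAAAAAAAAAAA", 0),
            ("AAAAAAAAAAAT", 3),
            ("TTTTTTTTTTTT", 4**12 - 1),
        ],
    )
    def test_known_codes(self, kmer, code):
        assert encode_kmer(kmer) == code

    def test_non_acgt_rejected(self):
        with pytest.raises(ValueError):
            encode_kmer("AAAAAAAAAAAN")

    @given(kmer=st.text(alphabet="ACGT", min_size=12, max_size=12))
    @settings(max_examples=200, derandomize=True)
    def test_decode_inverts_encode(self, kmer):
        assert decode_kmer(encode_kmer(kmer), 12) == kmer


class TestBuildSeedIndex:
    @pytest.mark.parametrize("mode", ["substring", "candidate"])
    def test_single_site_counts_once(self, mode):
        records = [SequenceRecord("s", "TTTTT" + SITE)]
        candidates = scan_all(records)
        index = build_seed_index(records, candidates, mode=mode)
        assert index.count("GTCCAACTTCTT") == 1

    @pytest.mark.parametrize("mode", ["substring", "candidate"])
    def test_tandem_duplication_counts_twice_and_blocks_specificity(self, mode):
        records = [SequenceRecord("s", SITE + SITE)]
        candidates = scan_all(records)
        index = build_seed_index(records, candidates, mode=mode)
        assert index.count("GTCCAACTTCTT") == 2
        marked = mark_specific(candidates, index)
        assert all(site.specific is False for site in marked
                   if site.seed == "GTCCAACTTCTT")

    def test_substring_mode_sees_occurrences_outside_pam_context(self):
        # the seed recurs in a second record without any PAM: substring mode
        # counts it, candidate mode does not
        records = [
            SequenceRecord("s1", "TTTTT" + SITE),
            SequenceRecord("s2", "GTCCAACTTCTT" + "AAAA"),
        ]
        candidates = scan_all(records)
        substring = build_seed_index(records, candidates, mode="substring")
        candidate = build_seed_index(records, candidates, mode="candidate")
        assert substring.count("GTCCAACTTCTT") == 2
        assert candidate.count("GTCCAACTTCTT") == 1

    def test_substring_counts_match_naive_oracle_on_random_5kb(self):
        rng = np.random.default_rng(181818)
        seq = "".join(rng.choice(list("ACGT"), size=5000))
        records = [SequenceRecord("s", seq)]
        candidates = scan_all(records)
        assert candidates, "5 kb of random sequence must contain PAM sites"
        index = build_seed_index(records, candidates, mode="substring")
        for seed in {c.seed for c in candidates}:
            assert index.count(seed) == oracle_count_substring(seq, seed)

    def test_records_required_when_candidates_present(self):
        candidates = scan_all([SequenceRecord("s", "TTTTT" + SITE)])
        with pytest.raises(ValueError):
            build_seed_index([], candidates, mode="substring")

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            build_seed_index([], [], mode="exact")

    def test_empty_candidates_give_empty_index(self):
        index = build_seed_index([SequenceRecord("s", "AAAA")], [], mode="substring")
        assert index.counts == {}


class TestMarkSpecific:
    def test_singleton_candidate_is_specific(self):
        records = [SequenceRecord("s", "TTTTT" + SITE)]
        candidates = scan_all(records)
        mark_specific(candidates, build_seed_index(records, candidates))
        assert [c.specific for c in candidates] == [True]

    def test_shared_seed_pair_nonspecific_lone_seed_specific(self):
        # two sites share one seed (distinct prefixes), a third has its own
        seed_a, seed_b = "ACGTACGTACGT", "TGCATGCATGCA"
        records = [
            SequenceRecord(
                "s",
                "AAAAAAAA" + seed_a + "TGG"
                + "TTTT"
                + "CCCCCCCC" + seed_a + "AGG"
                + "TTTT"
                + "AAAACCCC" + seed_b + "TGG",
            )
        ]
        candidates = [c for c in scan_all(records) if c.seed in (seed_a, seed_b)]
        flags = [
            c.specific
            for c in mark_specific(
                candidates, build_seed_index(records, candidates, mode="candidate")
            )
        ]
        assert flags == [False, False, True]

    def test_seed_missing_from_index_is_contract_violation(self):
        records = [SequenceRecord("s", "TTTTT" + SITE)]
        candidates = scan_all(records)
        stale_index = build_seed_index(
            [SequenceRecord("x", "A" * 30)], [], mode="substring"
        )
        with pytest.raises(ValueError):
            mark_specific(candidates, stale_index)


class TestDatasetLevelInvariants:
    @given(
        seqs=st.lists(st.text(alphabet="ACGT", min_size=23, max_size=120),
                      min_size=1, max_size=4),
        extra=st.text(alphabet="ACGT", min_size=0, max_size=120),
    )
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_appending_sequence_never_creates_specificity(self, seqs, extra):
        records = [SequenceRecord(f"s{i}", s) for i, s in enumerate(seqs)]
        candidates = scan_all(records)
        if not candidates:
            return
        before = build_seed_index(records, candidates, mode="substring")
        grown = records + [SequenceRecord("extra", extra)] if extra else records
        after = build_seed_index(grown, candidates, mode="substring")
        for seed, count in before.counts.items():
            assert after.counts[seed] >= count

    @given(
        seqs=st.lists(st.text(alphabet="ACGT", min_size=23, max_size=120),
                      min_size=1, max_size=4),
    )
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_candidate_counts_bounded_by_substring_counts(self, seqs):
        records = [SequenceRecord(f"s{i}", s) for i, s in enumerate(seqs)]
        candidates = scan_all(records)
        if not candidates:
            return
        substring = build_seed_index(records, candidates, mode="substring")
        candidate = build_seed_index(records, candidates, mode="candidate")
        for seed, n in candidate.counts.items():
            assert n <= substring.counts[seed]


class TestCountKmersDense:
    def test_overlapping_occurrences_counted(self):
        counts = count_kmers_dense(["AAAAA"], 2)
        assert counts[encode_kmer("AA")] == 4

    def test_windows_with_ambiguity_skipped(self):
        counts = count_kmers_dense(["AANAA"], 2)
        assert counts[encode_kmer("AA")] == 2
        assert counts.sum() == 2

    def test_short_sequences_contribute_nothing(self):
        assert count_kmers_dense(["A", ""], 2).sum() == 0
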