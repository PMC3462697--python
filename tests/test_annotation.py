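import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirdiff.annotation import (ContaminantIndex, LibraryProfile, MatureMiRNA,
                                MiRNAAnnotator, SEED_LENGTH, annotate_library,
                                load_catalog, low_abundance_filter,
                                match_mirna, reverse_complement,
                                screen_contaminants)
from mirdiff.io_preprocess import CollapsedSeq


def brute_force_match(seq, catalog):
    """Independent reference matcher: character-by-character comparison."""
    seq = seq.upper().replace("U", "T")
    hits = []
    for m in catalog:
        seed = m.seq[:SEED_LENGTH]
        if len(seq) >= SEED_LENGTH:
            ok = all(a == b for a, b in zip(seq[:SEED_LENGTH], seed))
        else:
            ok = all(a == b for a, b in zip(seq, seed[:len(seq)]))
        if ok and "N" not in seq:
            hits.append(m.name)
    return hits


class TestContaminantIndex:
    REF = [("ref1", "ACGTACGTACGTACGTACGT")]

    def test_substring_is_a_hit(self):
        index = ContaminantIndex(self.REF)
        assert "GTACGTACGT" in index

    def test_non_substring_is_not(self):
        index = ContaminantIndex(self.REF)
        assert "TTTTTTTTTT" not in index

    def test_reverse_complement_hit_only_with_both_strands(self):
        query = reverse_complement("GGATCCTTAGCACGTGATCA"[2:14])
        ref = [("r", "GGATCCTTAGCACGTGATCA")]
        assert query in ContaminantIndex(ref, both_strands=True)
        assert query not in ContaminantIndex(ref, both_strands=False)

    def test_empty_reference_set_raises(self):
        with pytest.raises(ValueError):
            ContaminantIndex([])

    def test_screen_partitions_and_preserves_counts(self):
        index = ContaminantIndex(self.REF)
        seqs = [CollapsedSeq("GTACGTACGT", 5), CollapsedSeq("TTTTTTTTTT", 3)]
        kept, removed = screen_contaminants(seqs, index)
        assert kept == [seqs[1]] and removed == [seqs[0]]
        assert sum(c.count for c in kept + removed) == 8

    def test_no_index_keeps_everything(self):
        seqs = [CollapsedSeq("ACGTACGTAC", 1)]
        kept, removed = screen_contaminants(seqs, None)
        assert kept == seqs and removed == []


class TestMatchMirna:
    def test_isomir_with_extra_3prime_bases_matches(self, small_catalog):
        # first 17 nt equal mir-a-5p's seed; trailing 3 nt unchecked
        assert match_mirna("TGAGGTAGTAGGTTGTATAG", small_catalog) == ["mir-a-5p"]

    def test_short_read_matches_seed_prefix(self, small_catalog):
        assert match_mirna("TGAGGTAGTAGGTT", small_catalog) == ["mir-a-5p"]

    def test_single_seed_mismatch_rejects(self, small_catalog):
        assert match_mirna("TGAGCTAGTAGGTTGTATAG", small_catalog) == []

    def test_u_and_case_insensitive(self, small_catalog):
        assert match_mirna("ugagguaguagguuguauag", small_catalog) == ["mir-a-5p"]

    def test_n_never_matches(self, small_catalog):
        assert match_mirna("TGAGGTAGTAGGTTGTATNG", small_catalog) == []

    def test_length_out_of_range_raises(self, small_catalog):
        with pytest.raises(ValueError):
            match_mirna("ACGTACGTA", small_catalog)  # 9 nt
        with pytest.raises(ValueError):
            match_mirna("A" * 29, small_catalog)

    def test_five_prime_offset_allows_internal_start(self, small_catalog):
        shifted = small_catalog[0].seq[2:]  # starts 2 nt inside the mature
        assert match_mirna(shifted, small_catalog) == []
        assert match_mirna(shifted, small_catalog, max_5p_offset=2) == \
            ["mir-a-5p"]

    def test_matching_prefix_consistency(self, small_catalog):
        # any >=17 nt match implies its 17-nt prefix matches standalone
        seq = "TGAGGTAGTAGGTTGTATAGT"
        assert match_mirna(seq, small_catalog)
        assert match_mirna(seq[:SEED_LENGTH], small_catalog)

    @given(st.data())
    @settings(max_examples=300, deadline=None)
    def test_agrees_with_brute_force(self, data):
        rng_seed = data.draw(st.integers(0, 2**31 - 1))
        rng = np.random.default_rng(rng_seed)
        catalog = []
        base = "".join(rng.choice(list("ACGT"), size=22))
        for i in range(data.draw(st.integers(1, 8))):
            if i and rng.random() < 0.3:
                seq = base  # duplicate seeds exercise multi-hits
            else:
                seq = "".join(rng.choice(list("ACGT"), size=int(rng.integers(17, 25))))
            catalog.append(MatureMiRNA(f"m{i}", seq))
        # half the queries are perturbed catalog prefixes, half random
        if rng.random() < 0.5:
            src = catalog[int(rng.integers(len(catalog)))].seq
            n = int(rng.integers(10, 29))
            query = (src * 2)[:n]
            if rng.random() < 0.5:  # plant a mismatch
                pos = int(rng.integers(0, min(n, SEED_LENGTH)))
                query = query[:pos] + "ACGT"[int(rng.integers(4))] + query[pos + 1:]
        else:
            query = "".join(rng.choice(list("ACGT"), size=int(rng.integers(10, 29))))
        assert sorted(match_mirna(query, catalog)) == \
            sorted(brute_force_match(query, catalog))


class TestAnnotateLibrary:
    def test_isomir_variants_merge(self, small_catalog):
        seqs = [
            CollapsedSeq("TGAGGTAGTAGGTTGTATAGT", 3),   # canonical
            CollapsedSeq("TGAGGTAGTAGGTTGTATA", 5),     # 3' shortened
        ]
        profile = annotate_library(seqs, small_catalog)
        assert profile.per_mirna == {"mir-a-5p": 8}
        assert len(profile.isomir_breakdown["mir-a-5p"]) == 2
        profile.validate()

    def test_unmatched_counted_as_unassigned(self, small_catalog):
        seqs = [CollapsedSeq("GGGGGTAGTAGGTTGTATAGT", 4)]
        profile = annotate_library(seqs, small_catalog)
        assert profile.per_mirna == {}
        assert profile.unassigned == 4

    def test_ambiguous_discarded_by_default(self, small_catalog):
        twin = MatureMiRNA("mir-a-twin-5p", small_catalog[0].seq[:17] + "GGG")
        catalog = small_catalog + [twin]
        seqs = [CollapsedSeq(small_catalog[0].seq, 2)]
        profile = annotate_library(seqs, catalog)
        assert profile.per_mirna == {}
        assert profile.ambiguous_discarded == 2
        both = annotate_library(seqs, catalog, ambiguity="all")
        assert both.per_mirna == {"mir-a-5p": 2, "mir-a-twin-5p": 2}
        first = annotate_library(seqs, catalog, ambiguity="first")
        assert first.per_mirna == {"mir-a-5p": 2}

    def test_duplicate_catalog_names_raise(self, small_catalog):
        catalog = small_catalog + [MatureMiRNA("mir-a-5p", "T" * 17 + "ACG")]
        with pytest.raises(ValueError, match="duplicate"):
            annotate_library([], catalog)

    def test_count_conservation(self, small_catalog, rng):
        seqs = []
        for i in range(200):
            if rng.random() < 0.5:
                m = small_catalog[int(rng.integers(3))]
                n = int(rng.integers(14, 25))
                seqs.append(CollapsedSeq((m.seq + "AC")[:n], int(rng.integers(1, 9))))
            else:
                seqs.append(CollapsedSeq(
                    "".join(rng.choice(list("ACGT"), size=20)),
                    int(rng.integers(1, 9))))
        profile = annotate_library(collapse_dedup(seqs), small_catalog)
        total_in = sum(c.count for c in collapse_dedup(seqs))
        total_out = (sum(profile.per_mirna.values()) + profile.unassigned
                     + profile.ambiguous_discarded)
        assert total_in == total_out

    def test_catalog_entries_shorter_than_seed_rejected(self, tmp_path):
        fa = tmp_path / "cat.fasta"
        fa.write_text(">tiny\nACGUACGU\n>ok-5p\nUGAGGUAGUAGGUUGUAUAGUU\n")
        catalog = load_catalog(fa)
        assert [m.name for m in catalog] == ["ok-5p"]
        assert catalog[0].seq == "TGAGGTAGTAGGTTGTATAGTT"  # U -> T


def collapse_dedup(seqs):
    merged = {}
    for cs in seqs:
        merged[cs.seq] = merged.get(cs.seq, 0) + cs.count
    return [CollapsedSeq(s, c) for s, c in merged.items()]


class TestLowAbundanceFilter:
    def _profile(self, counts, total):
        return LibraryProfile(library_id="L", total_raw_reads=total,
                              total_clean_reads=sum(counts.values()),
                              per_mirna=dict(counts))

    def test_cumulative_pool_rule(self):
        p = self._profile({"a": 1, "b": 1, "c": 100000}, 1_000_000)
        kept, dropped = low_abundance_filter([p], pool_fraction=1e-4)
        assert set(dropped) == {"a", "b"}  # cumulative 2 <= 100
        assert kept == ["c"]

    def test_pool_stops_at_first_overflow(self):
        # ascending: a(1), b(60), c(60): a fits (1 <= 100), a+b fits (61),
        # a+b+c would be 121 > 100 -> only a and b dropped
        p = self._profile({"a": 1, "b": 60, "c": 60, "d": 5000}, 1_000_000)
        _, dropped = low_abundance_filter([p], pool_fraction=1e-4)
        assert set(dropped) == {"a", "b"}

    def test_zero_fraction_drops_nothing(self):
        p = self._profile({"a": 1, "b": 2}, 100)
        kept, dropped = low_abundance_filter([p], pool_fraction=0.0)
        assert dropped == [] and kept == ["a", "b"]

    def test_single_mirna_never_dropped(self):
        p = self._profile({"only": 5}, 10)
        kept, dropped = low_abundance_filter([p], pool_fraction=0.5)
        assert kept == ["only"] and dropped == []

    def test_per_mirna_mode(self):
        p = self._profile({"a": 1, "b": 1, "c": 100000}, 1_000_000)
        _, dropped = low_abundance_filter([p], pool_fraction=1e-4,
                                          mode="per_mirna")
        assert set(dropped) == {"a", "b"}

    def test_kept_set_shared_across_libraries(self):
        p1 = self._profile({"a": 1, "b": 500}, 10_000)
        p2 = self._profile({"a": 0, "b": 700}, 10_000)
        kept, dropped = low_abundance_filter([p1, p2], pool_fraction=1e-3)
        assert kept == ["b"] and dropped == ["a"]


class TestAnnotatorEstimator:
    def test_fit_transform_with_contaminants(self, small_catalog, tmp_path):
        decoy = tmp_path / "decoy.fasta"
        decoy.write_text(">d\nTTTACCCATTGGACCATTACGGATCAGT\n")
        ann = MiRNAAnnotator(catalog=small_catalog,
                             contaminants=[decoy]).fit()
        seqs = [
            CollapsedSeq(small_catalog[1].seq, 6),
            CollapsedSeq("ACCCATTGGACCATTACG", 9),  # decoy substring
        ]
        profile = ann.transform(seqs, library_id="lib1")
        assert profile.per_mirna == {"mir-b-3p": 6}
        assert ann.n_removed_contaminant_ == 9
        assert profile.total_clean_reads == 6

    def test_sklearn_param_interface(self, small_catalog):
        ann = MiRNAAnnotator(catalog=small_catalog, ambiguity="all")
        assert ann.get_params()["ambiguity"] == "all"
        ann.set_params(ambiguity="first").fit()
        assert ann.ambiguity == "first"
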