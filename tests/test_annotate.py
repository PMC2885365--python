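import numpy as np
import pytest

from mirprof.annotate import (
    build_kmer_index,
    category_composition,
    choose_k,
    map_unmatched_to_genome,
    mismatch_match,
    run_elimination,
)
from mirprof.formats_io import (
    Gene,
    GeneModel,
    GenomeRegion,
    ReferenceSet,
    reverse_complement,
)
from mirprof.preprocess import SmallRNATag

from .oracles import hamming_hits


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestKmerIndex:
    def test_posting_count_single_reference(self):
        ref = ReferenceSet("r", "ncRNA", [("x", "ACGTACGT")])
        assert build_kmer_index(ref, 4).n_postings() == 5  # 8 - 4 + 1

    def test_absent_kmer_lookup_empty(self):
        ref = ReferenceSet("r", "ncRNA", [("x", "ACGTACGT")])
        assert build_kmer_index(ref, 4).lookup("TTTT") == []

    def test_posting_count_matches_enumeration(self, rng):
        records = [(f"r{i}", _random_seq(rng, int(rng.integers(20, 80))))
                   for i in range(10)]
        ref = ReferenceSet("rand", "ncRNA", records)
        k = 6
        expected = sum(max(0, len(s) - k + 1) for _, s in records)
        assert build_kmer_index(ref, k).n_postings() == expected

    def test_short_reference_warns(self):
        ref = ReferenceSet("r", "ncRNA", [("x", "ACG")])
        with pytest.warns(UserWarning):
            build_kmer_index(ref, 8)


class TestMismatchMatch:
    def test_two_mismatch_hit_found(self):
        ref = ReferenceSet("r", "mature_miRNA", [("m", "GGGGACGTACGTACGGGG")])
        idx = build_kmer_index(ref, 3)
        hits = mismatch_match("ACGTACGAAC", idx, max_mismatches=2)
        assert hits and all(h.mismatches <= 2 for h in hits)

    def test_exact_substring_zero_mismatches(self):
        ref = ReferenceSet("r", "mature_miRNA", [("m", "TTTACGTACGTACTTT")])
        idx = build_kmer_index(ref, 3)
        hits = mismatch_match("ACGTACGTAC", idx)
        assert any(h.mismatches == 0 and h.offset == 3 for h in hits)

    def test_equals_hamming_oracle_on_random_instances(self, rng):
        """Seeded matcher must return exactly the sliding-window Hamming set."""
        ref_seq = _random_seq(rng, 2000)
        ref = ReferenceSet("r", "ncRNA", [("g", ref_seq)])
        idx = build_kmer_index(ref, choose_k(22))
        for _ in range(60):
            if rng.random() < 0.5:
                tag = _random_seq(rng, 22)
            else:  # plant a mutated copy so hits actually occur
                start = int(rng.integers(0, 2000 - 22))
                tag = list(ref_seq[start : start + 22])
                for pos in rng.choice(22, size=int(rng.integers(0, 4)), replace=False):
                    tag[pos] = str(rng.choice(list("ACGT")))
                tag = "".join(tag)
            got = {(h.offset, h.mismatches) for h in mismatch_match(tag, idx)}
            assert got == hamming_hits(tag, ref_seq)

    def test_n_counts_as_mismatch(self):
        ref = ReferenceSet("r", "ncRNA", [("g", "AAAAAAANAAAAAA")])
        idx = build_kmer_index(ref, 3)
        hits = {(h.offset, h.mismatches) for h in mismatch_match("AAAAAAAAA", idx)}
        assert hits == hamming_hits("AAAAAAAAA", "AAAAAAANAAAAAA")
        assert all(m >= 1 for o, m in hits if o in (0, 1, 2, 3, 4, 5))


def _tags(seqs):
    return [SmallRNATag(i + 1, s, f, "S") for i, (s, f) in enumerate(seqs)]


class TestElimination:
    REFS = [
        ReferenceSet("mir", "mature_miRNA", [("mir-1", "ACGTACGTACGTACGTACGTAC")]),
        ReferenceSet("nc", "ncRNA", [("nc-1", "ACGTACGTACGTACGTACGTAC"),
                                     ("nc-2", "TTTTGGGGCCCCAAAATTTTGG")]),
    ]

    def test_first_stage_wins(self):
        tags = _tags([("ACGTACGTACGTACGTACGTAC", 5)])
        records, unmatched, _ = run_elimination(tags, self.REFS)
        assert records[0].category == "mature_miRNA"
        assert not unmatched

    def test_unmatched_pool(self):
        tags = _tags([("CACACACACACACACACACA", 2)])
        records, unmatched, _ = run_elimination(tags, self.REFS)
        assert records[0].category == "unannotated"
        assert [t.id for t in unmatched] == [1]

    def test_partition_and_conservation(self, rng):
        seqs = [("ACGTACGTACGTACGTACGTAC", 7), ("TTTTGGGGCCCCAAAATTTTGG", 3),
                ("CACACACACACACACACACA", 2)]
        tags = _tags(seqs)
        records, unmatched, _ = run_elimination(tags, self.REFS)
        assert len(records) == len(tags)  # exactly one record per tag
        comp = category_composition(records, tags)
        assert sum(comp.values()) == pytest.approx(100.0)
        freq = {t.id: t.frequency for t in tags}
        by_cat = {}
        for r in records:
            by_cat[r.category] = by_cat.get(r.category, 0) + freq[r.tag_id]
        assert sum(by_cat.values()) == sum(f for _, f in seqs)

    def test_empty_reference_set_skipped(self):
        refs = [ReferenceSet("empty", "rRNA_mRNA", [])] + self.REFS
        tags = _tags([("ACGTACGTACGTACGTACGTAC", 1)])
        with pytest.warns(UserWarning):
            records, _, _ = run_elimination(tags, refs)
        assert records[0].category == "mature_miRNA"


class TestGenomeMapping:
    GENOME = {"chr1": "T" * 100 + "ACGGATTCACGGATTCACGGAT" + "G" * 100
              + "CCCCAGGGTTTCAGATCAAGGT" + "A" * 100}
    MODEL = GeneModel([
        Gene("g1", GenomeRegion("chr1", 80, 180),
             [GenomeRegion("chr1", 80, 95), GenomeRegion("chr1", 160, 180)])
    ])

    def test_intronic_hit(self):
        tags = _tags([("ACGGATTCACGGATTCACGGAT", 4)])
        hits = map_unmatched_to_genome(tags, self.GENOME, self.MODEL)
        assert len(hits) == 1
        h = hits[0]
        assert (h.start, h.end, h.strand, h.label) == (100, 122, "+", "intronic")

    def test_minus_strand_hit(self):
        tag_seq = reverse_complement("CCCCAGGGTTTCAGATCAAGGT")
        tags = _tags([(tag_seq, 2)])
        hits = map_unmatched_to_genome(tags, self.GENOME, self.MODEL)
        assert len(hits) == 1
        assert hits[0].strand == "-" and hits[0].label == "intergenic"

    def test_absent_tag_dropped(self):
        tags = _tags([("GTCAGTCAGTCAGTCAGTCA", 1)])
        assert map_unmatched_to_genome(tags, self.GENOME, self.MODEL) == []


class TestComposition:
    def test_all_mirna(self):
        tags = _tags([("ACGTACGTACGTACGTACGTAC", 9)])
        records, _, _ = run_elimination(tags, TestElimination.REFS)
        comp = category_composition(records, tags)
        assert comp == {"mature_miRNA": 100.0}

    def test_planted_60_20_20_composition(self):
        refs = [
            ReferenceSet("mir", "mature_miRNA", [("m", "ACGTACGTACGTACGTACGTAC")]),
            ReferenceSet("nc", "ncRNA", [("n", "TTTTGGGGCCCCAAAATTTTGG")]),
            ReferenceSet("rr", "rRNA_mRNA", [("r", "GAGAGACTCTCTGAGAGACTCT")]),
        ]
        tags = _tags([
            ("ACGTACGTACGTACGTACGTAC", 60),
            ("TTTTGGGGCCCCAAAATTTTGG", 20),
            ("GAGAGACTCTCTGAGAGACTCT", 20),
        ])
        records, _, _ = run_elimination(tags, refs)
        comp = category_composition(records, tags)
        assert comp == pytest.approx(
            {"mature_miRNA": 60.0, "ncRNA": 20.0, "rRNA_mRNA": 20.0}
        )
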