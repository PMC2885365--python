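import numpy as np
import pytest

from mirprof.discovery import PrecursorCandidate
from mirprof.families_clusters import (
    FamilyMember,
    MiRNAFamily,
    assign_names,
    cluster_loci,
    deduplicate_across_samples,
    designate_members,
    group_by_precursor,
    seed_kinship,
)
from mirprof.formats_io import GenomeRegion

from .oracles import cluster_components


def _cand(chrom, start, end, tag_id, arm, freq, seq="ACGTACGTACGTACGTACGTAC",
          strand="+", sample="S1"):
    n = end - start
    return PrecursorCandidate(
        locus=GenomeRegion(chrom, start, end, strand),
        sequence=seq[:n].ljust(n, "A"),
        srna_span=(0, min(n, 22)),
        tag_id=tag_id,
        frequency=freq,
        sample=sample,
        arm=arm,
        accepted=True,
    )


class TestGrouping:
    def test_overlapping_windows_one_family(self):
        cands = [
            _cand("c1", 100, 260, 1, "five_prime", 50),
            _cand("c1", 140, 300, 2, "three_prime", 7),
        ]
        fams = group_by_precursor(cands)
        assert len(fams) == 1
        assert len(fams[0].members) == 2
        assert (fams[0].locus.start, fams[0].locus.end) == (100, 300)

    def test_disjoint_windows_separate_families(self):
        cands = [
            _cand("c1", 100, 260, 1, "five_prime", 5),
            _cand("c1", 1000, 1160, 2, "five_prime", 5),
        ]
        assert len(group_by_precursor(cands)) == 2

    def test_strand_separates_families(self):
        cands = [
            _cand("c1", 100, 260, 1, "five_prime", 5, strand="+"),
            _cand("c1", 100, 260, 2, "five_prime", 5, strand="-"),
        ]
        assert len(group_by_precursor(cands)) == 2

    def test_rejected_candidates_excluded(self):
        cand = _cand("c1", 100, 260, 1, "loop", 5)
        cand.accepted = False
        assert group_by_precursor([cand]) == []

    def test_family_of_four(self):
        cands = [
            _cand("c1", 100, 260, 1, "five_prime", 280, seq="A" * 22),
            _cand("c1", 101, 261, 2, "five_prime", 40, seq="C" * 22),
            _cand("c1", 102, 262, 3, "five_prime", 1, seq="G" * 22),
            _cand("c1", 103, 263, 4, "three_prime", 7, seq="T" * 22),
        ]
        (fam,) = group_by_precursor(cands)
        assert len(fam.members) == 4
        assert fam.representative.frequency == 280
        assert sorted(m.frequency for m in fam.isomirs) == [1, 40]
        assert [m.frequency for m in fam.stars] == [7]


class TestDesignation:
    def _family(self, freqs_arms):
        members = [
            FamilyMember(i + 1, f"SEQ{i}", arm, f) for i, (f, arm) in enumerate(freqs_arms)
        ]
        return MiRNAFamily("p1", GenomeRegion("c1", 0, 100), members)

    def test_representative_isomir_star_split(self):
        fam = designate_members(self._family(
            [(280, "five_prime"), (40, "five_prime"), (1, "five_prime"),
             (7, "three_prime")]
        ))
        assert fam.representative.frequency == 280
        assert {m.frequency for m in fam.isomirs} == {40, 1}
        assert {m.frequency for m in fam.stars} == {7}

    def test_single_member(self):
        fam = designate_members(self._family([(3, "five_prime")]))
        assert fam.representative.frequency == 3
        assert fam.isomirs == [] and fam.stars == []

    def test_tie_breaks_lexicographically(self):
        members = [FamilyMember(1, "TTTT", "five_prime", 9),
                   FamilyMember(2, "AAAA", "five_prime", 9)]
        fam = designate_members(MiRNAFamily("p", GenomeRegion("c", 0, 10), members))
        assert fam.representative.sequence == "AAAA"


class TestNaming:
    def _fam(self, start, rep_freq, star_freq=None, rep_arm="five_prime"):
        members = [FamilyMember(1, "AAAA", rep_arm, rep_freq)]
        if star_freq is not None:
            other = "three_prime" if rep_arm == "five_prime" else "five_prime"
            members.append(FamilyMember(2, "CCCC", other, star_freq))
        fam = MiRNAFamily("p", GenomeRegion("c1", start, start + 100), members)
        return designate_members(fam)

    def test_clear_predominance_star_naming(self):
        fams = assign_names([self._fam(0, 280, 7)])
        assert fams[0].name == "jnuhsa-1"
        assert fams[0].star_name == "jnuhsa-1*"

    def test_ambiguous_arms_5p_3p_naming(self):
        fams = assign_names([self._fam(0, 280, 7), self._fam(500, 5, 4)])
        assert fams[1].name == "jnuhsa-2-5p"
        assert fams[1].star_name == "jnuhsa-2-3p"

    def test_numbering_follows_locus_order_and_is_stable(self):
        fams = [self._fam(5000, 10), self._fam(0, 10)]
        named = assign_names(fams)
        assert [f.locus.start for f in named] == [0, 5000]
        assert [f.name for f in named] == ["jnuhsa-1", "jnuhsa-2"]
        named2 = assign_names(list(reversed(fams)))
        assert [f.name for f in named2] == [f.name for f in named]


class TestDeduplication:
    def test_same_locus_merged_across_samples(self):
        f1 = designate_members(MiRNAFamily(
            "a", GenomeRegion("c1", 100, 260),
            [FamilyMember(1, "AAAA", "five_prime", 50, "N1")],
        ))
        f2 = designate_members(MiRNAFamily(
            "b", GenomeRegion("c1", 105, 265),
            [FamilyMember(9, "AAAA", "five_prime", 20, "K562")],
        ))
        merged = deduplicate_across_samples([[f1], [f2]])
        assert len(merged) == 1
        assert {m.sample for m in merged[0].members} == {"N1", "K562"}
        assert merged[0].name == "jnuhsa-1"

    def test_disjoint_loci_union(self):
        f1 = designate_members(MiRNAFamily(
            "a", GenomeRegion("c1", 100, 260),
            [FamilyMember(1, "AAAA", "five_prime", 50, "N1")],
        ))
        f2 = designate_members(MiRNAFamily(
            "b", GenomeRegion("c1", 5000, 5160),
            [FamilyMember(9, "CCCC", "five_prime", 20, "K562")],
        ))
        merged = deduplicate_across_samples([[f1], [f2]])
        assert len(merged) == 2
        assert len({f.name for f in merged}) == 2


class TestSeedKinship:
    KNOWN = {
        "mir-a": "TGAGGTAGTAGGTTGTATAGTT",
        "mir-b": "TGAGGTAGTAGATTGTATAGTT",  # same seed as mir-a (nt 2-8)
        "mir-c": "CATTGCACTTGTCTCGGTCTGA",
    }

    def test_shared_seed_reported(self):
        assert seed_kinship("TGAGGTAGCCCCCCCCCCCCCC", self.KNOWN) == ["mir-a", "mir-b"]

    def test_unique_seed_empty(self):
        assert seed_kinship("AACCGGTTAACCGGTTAACCGG", self.KNOWN) == []

    def test_short_mature_no_seed(self):
        assert seed_kinship("ACGTACG", self.KNOWN) == []

    def test_equals_bruteforce_scan(self, rng):
        novel = "".join(rng.choice(list("ACGT"), size=22))
        brute = sorted(
            k for k, v in self.KNOWN.items() if v[1:8] == novel[1:8]
        )
        assert seed_kinship(novel, self.KNOWN) == brute


class TestClustering:
    def _loci(self, spans, chrom="c1"):
        return [
            (f"m{i}", GenomeRegion(chrom, s, e), False) for i, (s, e) in enumerate(spans)
        ]

    def test_within_gap_same_cluster(self):
        loci = self._loci([(0, 100), (1100, 1200)])
        assert len(cluster_loci(loci, max_gap=20000)) == 1

    def test_beyond_gap_separate(self):
        loci = self._loci([(0, 100), (25100, 25200)])
        assert len(cluster_loci(loci, max_gap=20000)) == 2

    def test_transitive_chaining(self):
        loci = self._loci([(0, 100), (15100, 15200), (30200, 30300)])
        clusters = cluster_loci(loci, max_gap=20000)
        assert len(clusters) == 1 and len(clusters[0].members) == 3

    def test_boundary_inclusive(self):
        loci = self._loci([(0, 100), (20100, 20200)])  # gap exactly 20 kb
        assert len(cluster_loci(loci, max_gap=20000)) == 1

    def test_kind_labels(self):
        loci = [("k1", GenomeRegion("c1", 0, 100), False),
                ("n1", GenomeRegion("c1", 500, 600), True),
                ("n2", GenomeRegion("c2", 0, 100), True)]
        clusters = {c.chrom: c.kind for c in cluster_loci(loci)}
        assert clusters == {"c1": "mixed", "c2": "novel_only"}

    def test_equals_connected_components_oracle(self, rng):
        for _ in range(30):
            n = int(rng.integers(2, 30))
            chroms = rng.choice(["c1", "c2"], size=n)
            starts = rng.integers(0, 200_000, size=n)
            loci = []
            for i in range(n):
                s = int(starts[i])
                loci.append((f"m{i}", GenomeRegion(str(chroms[i]), s, s + 80),
                             bool(rng.random() < 0.5)))
            got = cluster_loci(loci, max_gap=20_000)
            got_sets = sorted(
                sorted(loci.index(m) for m in c.members) for c in got
            )
            expected = sorted(cluster_components(loci, 20_000))
            assert got_sets == expected
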