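import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from l1scout import discovery as disc
from l1scout.discovery import (
    CandidateFlank,
    DetectionParams,
    SignatureHit,
    build_genome_index,
    discover_sites,
    extract_flank,
    find_signature,
    infer_insertion_site,
    place_flank,
)
from l1scout.seqio import SequenceRecord, reverse_complement

SIG = DetectionParams().signature
PARAMS = DetectionParams()


def naive_occurrences(seq: str, pattern: str) -> list[int]:
    return [i for i in range(len(seq) - len(pattern) + 1) if seq[i : i + len(pattern)] == pattern]


def naive_find_signature(read: SequenceRecord, params: DetectionParams) -> set[tuple[int, str]]:
    out = set()
    for pattern, strand in ((params.signature, "+"), (reverse_complement(params.signature), "-")):
        out |= {(i, strand) for i in naive_occurrences(read.seq, pattern)}
    return out


class TestFindSignature:
    def test_hit_at_read_start(self):
        read = SequenceRecord("r", SIG + "TTTTTTTTTT")
        (hit,) = find_signature(read)
        assert (hit.offset, hit.strand, hit.pattern) == (0, "+", SIG)

    def test_no_occurrence(self):
        assert find_signature(SequenceRecord("r", "ACGT" * 12)) == []

    def test_minus_strand_hit(self):
        read = SequenceRecord("r", "AC" + reverse_complement(SIG) + "GT")
        (hit,) = find_signature(read)
        assert (hit.offset, hit.strand) == (2, "-")

    def test_spiked_reads_match_naive_scan(self):
        rng = random.Random(5)
        for _ in range(200):
            seq = list("".join(rng.choices("ACGT", k=48)))
            off = rng.randint(0, 48 - len(SIG))
            pat = SIG if rng.random() < 0.5 else reverse_complement(SIG)
            seq[off : off + len(SIG)] = pat
            read = SequenceRecord("r", "".join(seq))
            got = {(h.offset, h.strand) for h in find_signature(read)}
            assert got == naive_find_signature(read, PARAMS)
            assert got  # the spike is always found

    @settings(derandomize=True, max_examples=150)
    @given(st.text(alphabet="ACGT", max_size=60), st.integers(0, 50), st.booleans())
    def test_equals_naive_scan(self, padding, cut, fwd):
        # embed the pattern at an arbitrary position inside random sequence
        cut = min(cut, len(padding))
        pat = SIG if fwd else reverse_complement(SIG)
        read = SequenceRecord("r", padding[:cut] + pat + padding[cut:])
        got = {(h.offset, h.strand) for h in find_signature(read)}
        assert got == naive_find_signature(read, PARAMS)


class TestExtractFlank:
    def test_plus_strand_arithmetic(self):
        flank30 = "ACGT" * 7 + "AC"
        read = SequenceRecord("r", flank30 + SIG + "TTTT")
        (hit,) = find_signature(read)
        flank = extract_flank(read, hit)
        assert flank.seq == flank30
        assert flank.length == 30
        assert flank.status == "pending"

    def test_short_flank_is_discarded(self):
        read = SequenceRecord("r", "A" * 20 + SIG + "C" * 10)
        (hit,) = find_signature(read)
        assert extract_flank(read, hit).status == "too_short"

    def test_minus_strand_recovers_original_flank(self):
        rng = random.Random(3)
        for _ in range(20):
            flank = "".join(rng.choices("ACGT", k=27))
            tail = "".join(rng.choices("ACGT", k=5))
            read = SequenceRecord("r", reverse_complement(flank + SIG + tail))
            hits = [h for h in find_signature(read) if h.strand == "-"]
            assert hits, "construction must contain a minus-strand signature"
            assert extract_flank(read, hits[0]).seq == flank

    def test_foreign_hit_rejected(self):
        read = SequenceRecord("r", SIG)
        with pytest.raises(ValueError):
            extract_flank(read, SignatureHit("other", 0, "+", SIG))


class TestGenomeIndex:
    def test_small_example(self):
        idx = build_genome_index([SequenceRecord("g", "ACGTACGT")], k=8)
        # k == contig length: single k-mer; ACGTACGT is its own reverse complement
        assert sorted(idx.lookup("ACGTACGT")) == [("g", 1, "+"), ("g", 1, "-")]

    def test_plus_occurrences(self):
        idx = disc.GenomeIndex(8)
        idx.add_contig(SequenceRecord("g", "AAAACCCCAAAACCCC"))
        assert [(c, p) for c, p, s in idx.lookup("AAAACCCC") if s == "+"] == [("g", 1), ("g", 9)]

    def test_absent_kmer(self):
        idx = build_genome_index([SequenceRecord("g", "A" * 30)], k=10)
        assert idx.lookup("ACGTACGTAC") == []

    def test_short_contig_contributes_nothing(self):
        idx = build_genome_index([SequenceRecord("tiny", "ACGT")], k=10)
        assert "tiny" not in idx.contigs

    def test_lookup_matches_naive_scan(self):
        rng = random.Random(9)
        genome = "".join(rng.choices("ACGT", k=10_000))
        k = 12
        idx = build_genome_index([SequenceRecord("g", genome)], k=k)
        for _ in range(100):
            i = rng.randint(0, len(genome) - k)
            kmer = genome[i : i + k]
            expected = {(p + 1, "+") for p in naive_occurrences(genome, kmer)}
            expected |= {(p + 1, "-") for p in naive_occurrences(genome, reverse_complement(kmer))}
            assert {(p, s) for _, p, s in idx.lookup(kmer)} == expected


def _random_genome(rng, n):
    return "".join(rng.choices("ACGT", k=n))


class TestPlaceFlank:
    def test_unique_locus_single_placement(self):
        rng = random.Random(21)
        genome = _random_genome(rng, 5000)
        flank = CandidateFlank("r", genome[1000:1030])
        idx = build_genome_index([SequenceRecord("g", genome)], k=22)
        assert place_flank(flank, idx) == [("g", 1001, 1030, "+")]

    def test_duplicated_locus_is_non_unique(self):
        rng = random.Random(22)
        core = _random_genome(rng, 30)
        genome = _random_genome(rng, 1000) + core + _random_genome(rng, 1000) + core + _random_genome(rng, 500)
        idx = build_genome_index([SequenceRecord("g", genome)], k=22)
        placements = place_flank(CandidateFlank("r", core), idx)
        assert len(placements) == 2

    def test_absent_flank_unplaced(self):
        rng = random.Random(23)
        idx = build_genome_index([SequenceRecord("g", _random_genome(rng, 3000))], k=22)
        random_flank = CandidateFlank("r", _random_genome(rng, 28))
        assert place_flank(random_flank, idx) == []

    def test_minus_strand_placement(self):
        rng = random.Random(24)
        genome = _random_genome(rng, 4000)
        flank = CandidateFlank("r", reverse_complement(genome[2000:2030]))
        idx = build_genome_index([SequenceRecord("g", genome)], k=22)
        assert place_flank(flank, idx) == [("g", 2001, 2030, "-")]

    def test_too_short_flank_rejected(self):
        idx = build_genome_index([SequenceRecord("g", "ACGT" * 100)], k=8)
        short = CandidateFlank("r", "ACGT", status="too_short")
        with pytest.raises(ValueError):
            place_flank(short, idx, DetectionParams(min_flank=8, seed_len=8))


class TestInferInsertionSite:
    def test_plus_strand_convention(self):
        flank = CandidateFlank("r", "A" * 30)
        site = infer_insertion_site(flank, ("chr1", 971, 1000, "+"), SignatureHit("r", 30, "+", SIG))
        assert (site.contig, site.position, site.l1_orientation) == ("chr1", 1000, "+")

    def test_minus_strand_convention(self):
        flank = CandidateFlank("r", "A" * 30)
        site = infer_insertion_site(flank, ("chr1", 501, 530, "-"), SignatureHit("r", 0, "-", SIG))
        assert (site.contig, site.position, site.l1_orientation) == ("chr1", 500, "-")

    def test_same_junction_reads_share_key(self, small_trio, small_truth_keys):
        sites = discover_sites(small_trio.reads["child"], small_trio.genome)
        assert len({s.key for s in sites}) == len(sites)
        multi = [s for s in sites if len(s.supporting_reads) > 1]
        assert multi, "deep coverage must yield multi-read sites that merged"


class TestDiscoverSites:
    def test_recovers_planted_sites_exactly(self, small_trio, small_truth_keys):
        """With error-free reads every recovered position is exact and no
        spurious site appears."""
        sites = discover_sites(small_trio.reads["child"], small_trio.genome)
        keys = {s.key for s in sites}
        assert keys <= small_truth_keys
        child_positive = {
            (t.contig, t.observed_position, t.l1_orientation)
            for t in small_trio.truth
            if t.genotypes["child"] != "absent"
        }
        assert keys == child_positive

    def test_reported_flanks_unique_in_reference(self, small_trio):
        sites = discover_sites(small_trio.reads["child"], small_trio.genome)
        ref = {c.id: c.seq for c in small_trio.genome}
        for site in sites:
            flank = site.flank_seq
            n = 0
            for seq in ref.values():
                n += len(naive_occurrences(seq, flank))
                n += len(naive_occurrences(seq, reverse_complement(flank)))
            assert n == 1, f"flank of {site.key} occurs {n} times in the reference"

    def test_reference_resident_element_not_reported(self, small_trio):
        """A junction whose reference continuation is the signature itself is
        an element already present in the reference, not a novel insertion."""
        rng = random.Random(31)
        left = _random_genome(rng, 400)
        right = _random_genome(rng, 400)
        genome = [SequenceRecord("g", left + SIG + right)]
        junction_read = SequenceRecord("r1", left[-30:] + SIG + "TT")
        assert discover_sites([junction_read], genome) == []

    def test_empty_read_set(self, small_trio):
        assert discover_sites([], small_trio.genome) == []

    def test_strand_symmetry(self, small_trio):
        """Reverse-complementing every read must not change the site list."""
        reads = small_trio.reads["child"]
        flipped = [SequenceRecord(r.id, reverse_complement(r.seq)) for r in reads]
        original = discover_sites(reads, small_trio.genome)
        mirrored = discover_sites(flipped, small_trio.genome)
        assert [s.key for s in original] == [s.key for s in mirrored]
        assert [sorted(s.supporting_reads) for s in original] == [
            sorted(s.supporting_reads) for s in mirrored
        ]

    def test_sites_sorted(self, small_trio):
        sites = discover_sites(small_trio.reads["child"], small_trio.genome)
        assert [s.key for s in sites] == sorted(s.key for s in sites)


class TestDetectionParams:
    def test_marker_must_prefix_signature(self):
        with pytest.raises(ValueError):
            DetectionParams(marker="CCTCCCC")

    def test_seed_len_bounded_by_min_flank(self):
        with pytest.raises(ValueError):
            DetectionParams(min_flank=20, seed_len=22)


def test_sites_tsv_roundtrip(tmp_path, small_trio):
    sites = discover_sites(small_trio.reads["child"], small_trio.genome)
    p = tmp_path / "sites.tsv"
    disc.write_sites_tsv(p, sites)
    back = disc.read_sites_tsv(p)
    assert [s.key for s in back] == [s.key for s in sites]
    assert [s.flank_seq for s in back] == [s.flank_seq for s in sites]
    assert [len(s.supporting_reads) for s in back] == [len(s.supporting_reads) for s in sites]
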