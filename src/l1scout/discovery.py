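"""Discovery of non-reference full-length L1 insertion junctions.

The method: a full-length L1 begins with a conserved 14-mer
(``GGGGAGGAGCCAAG``) at the extreme 5' end of its 5' UTR, so every read
containing that 14-mer (either strand) also contains the insertion junction.
For each such read, the sequence 5' of the element is extracted as the
candidate flank; flanks shorter than 25 bp, or not unique in the reference,
are discarded. Unique flanks yield 1-based junction coordinates: the
reported position is the reference base immediately 5' of the insert on the
plus strand.

Placement uses an internal exact-seed (default 22-mer) and full-flank
extension mapper rather than an external aligner; uniqueness means exactly
one placement on either strand at the configured mismatch tolerance.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from l1scout.seqio import SequenceRecord, reverse_complement

logger = logging.getLogger(__name__)

DEFAULT_SIGNATURE = "GGGGAGGAGCCAAG"
DEFAULT_MARKER = "GGGGAGG"


@dataclass(frozen=True)
class DetectionParams:
    """Tunable parameters of junction discovery.

    signature
        Exact pattern marking the L1 5' end; searched on both strands.
    min_flank
        Minimum flank length (bp) required to attempt genome placement.
    marker
        Short 5'-end marker used when classifying junction-spanning reads
        and in targeted rescue probes; must be a prefix of ``signature``.
    seed_len
        Exact seed length of the internal mapper.
    max_placement_mismatches
        Mismatches tolerated when extending a seed to the full flank.
    """

    signature: str = DEFAULT_SIGNATURE
    min_flank: int = 25
    marker: str = DEFAULT_MARKER
    seed_len: int = 22
    max_placement_mismatches: int = 0

    def __post_init__(self) -> None:
        if len(self.signature) < len(self.marker):
            raise ValueError("signature must be at least as long as marker")
        if not self.signature.startswith(self.marker):
            raise ValueError("marker must be a prefix of signature")
        if self.min_flank < 1:
            raise ValueError("min_flank must be >= 1")
        if self.seed_len > self.min_flank:
            raise ValueError("seed_len must not exceed min_flank")
        if self.max_placement_mismatches < 0:
            raise ValueError("max_placement_mismatches must be >= 0")


@dataclass(frozen=True)
class SignatureHit:
    """One exact occurrence of the signature (or its reverse complement).

    ``offset`` is 0-based within the read as stored; strand '-' means the
    reverse complement of the signature was matched.
    """

    read_id: str
    offset: int
    strand: str
    pattern: str


@dataclass
class CandidateFlank:
    """The non-L1 sequence 5' of a junction, oriented so its 3' end abuts
    the L1 5' end."""

    read_id: str
    seq: str
    status: str = "pending"  # accepted | too_short | non_unique | unplaced | pending

    @property
    def length(self) -> int:
        return len(self.seq)


Placement = tuple[str, int, int, str]  # contig, start, end (1-based incl.), strand


class GenomeIndex:
    """Exact k-mer index over the plus strand of a reference.

    Minus-strand occurrences are resolved at lookup time by querying the
    reverse complement of the k-mer, so each k-mer is stored once.
    """

    def __init__(self, k: int):
        if k < 8:
            raise ValueError("seed length must be >= 8")
        self.k = k
        self._index: dict[str, list[tuple[str, int]]] = defaultdict(list)
        self.contigs: dict[str, str] = {}

    def add_contig(self, record: SequenceRecord) -> None:
        self.contigs[record.id] = record.seq
        seq, k = record.seq, self.k
        for i in range(len(seq) - k + 1):
            self._index[seq[i : i + k]].append((record.id, i + 1))

    def lookup(self, kmer: str) -> list[tuple[str, int, str]]:
        """All occurrences of ``kmer`` as (contig, 1-based position, strand).

        A '-' occurrence at position p means the k-mer matches the reverse
        complement of the reference window starting at p.
        """
        if len(kmer) != self.k:
            raise ValueError(f"query length {len(kmer)} != index k {self.k}")
        out = [(c, p, "+") for c, p in self._index.get(kmer, ())]
        rc = reverse_complement(kmer)
        out += [(c, p, "-") for c, p in self._index.get(rc, ())]
        return out

    def sequence(self, contig: str, start: int, end: int) -> str:
        """Reference plus-strand slice, 1-based inclusive."""
        return self.contigs[contig][start - 1 : end]


def build_genome_index(genome: Iterable[SequenceRecord], k: int) -> GenomeIndex:
    index = GenomeIndex(k)
    for rec in genome:
        if len(rec.seq) < k:
            continue
        index.add_contig(rec)
    return index


def find_signature(read: SequenceRecord, params: DetectionParams = DetectionParams()) -> list[SignatureHit]:
    """All exact occurrences of the signature on either strand of a read.

    Overlapping occurrences are all reported; the result is sorted by
    offset. A '-' hit records where the reverse complement of the signature
    sits in the read as stored.
    """
    hits: list[SignatureHit] = []
    for pattern, strand in ((params.signature, "+"), (reverse_complement(params.signature), "-")):
        start = read.seq.find(pattern)
        while start != -1:
            hits.append(SignatureHit(read.id, start, strand, pattern))
            start = read.seq.find(pattern, start + 1)
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def extract_flank(read: SequenceRecord, hit: SignatureHit, params: DetectionParams = DetectionParams()) -> CandidateFlank:
    """Extract the candidate flank 5' of the L1 junction from a read.

    For a '+' hit the flank is the read prefix before the signature; for a
    '-' hit it is the reverse complement of the read suffix after the
    matched pattern. Either way the returned sequence reads toward the L1
    5' end (its 3'-most base abuts the junction).
    """
    if hit.read_id != read.id:
        raise ValueError(f"hit for {hit.read_id!r} does not belong to read {read.id!r}")
    if hit.strand == "+":
        flank_seq = read.seq[: hit.offset]
    else:
        flank_seq = reverse_complement(read.seq[hit.offset + len(hit.pattern) :])
    flank = CandidateFlank(read.id, flank_seq)
    if flank.length < params.min_flank:
        flank.status = "too_short"
    return flank


def _mismatches(a: str, b: str, limit: int) -> int:
    n = 0
    for x, y in zip(a, b):
        if x != y:
            n += 1
            if n > limit:
                return n
    return n


def place_flank(
    flank: CandidateFlank,
    index: GenomeIndex,
    params: DetectionParams = DetectionParams(),
) -> list[Placement]:
    """Place a flank on the reference by exact seed + full-length extension.

    The seed is the flank's 3'-terminal ``seed_len``-mer (the bases nearest
    the junction). Every distinct full-flank match with at most
    ``max_placement_mismatches`` differences is returned, both strands.
    The caller interprets the count: 0 -> unplaced, 1 -> accepted,
    >1 -> non_unique.
    """
    if flank.status == "too_short":
        raise ValueError("cannot place a flank shorter than min_flank")
    k = params.seed_len
    L = flank.length
    seed = flank.seq[-k:]
    mm = params.max_placement_mismatches
    placements: set[Placement] = set()
    for contig, pos, strand in index.lookup(seed):
        if strand == "+":
            # seed occupies the flank's 3' end: flank ends at pos + k - 1
            end = pos + k - 1
            start = end - L + 1
            if start < 1:
                continue
            window = index.sequence(contig, start, end)
            if len(window) == L and _mismatches(window, flank.seq, mm) <= mm:
                placements.add((contig, start, end, "+"))
        else:
            # flank matches the minus strand; its 3' end maps to `pos`
            start = pos
            end = start + L - 1
            window = index.sequence(contig, start, end)
            if len(window) == L and _mismatches(reverse_complement(window), flank.seq, mm) <= mm:
                placements.add((contig, start, end, "-"))
    return sorted(placements)


@dataclass
class InsertionSite:
    """A genome-placed 5' junction of a putative full-length L1 insertion.

    ``position`` is the 1-based coordinate of the reference base immediately
    5' (plus strand) of the inserted sequence. ``l1_orientation`` '+' means
    the element's 5'->3' direction equals the reference plus strand.
    Identity is (contig, position, l1_orientation).
    """

    contig: str
    position: int
    l1_orientation: str
    supporting_reads: list[str] = field(default_factory=list)
    flank_seq: str = ""

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.contig, self.position, self.l1_orientation)

    def __post_init__(self) -> None:
        if self.l1_orientation not in ("+", "-"):
            raise ValueError("l1_orientation must be '+' or '-'")


def infer_insertion_site(flank: CandidateFlank, placement: Placement, hit: SignatureHit) -> InsertionSite:
    """Convert a uniquely placed flank into junction coordinates.

    A flank placed on the plus strand ends at the base just before the
    insert, so the site position is the placement end. A flank placed on
    the minus strand starts at the first base after the insert, so the site
    position is placement start - 1 and the element points toward
    decreasing coordinates (orientation '-').
    """
    contig, start, end, strand = placement
    if strand == "+":
        return InsertionSite(contig, end, "+", [flank.read_id], flank.seq)
    if strand == "-":
        if start < 2:
            raise ValueError("minus-strand flank at contig start leaves no junction base")
        return InsertionSite(contig, start - 1, "-", [flank.read_id], flank.seq)
    raise ValueError(f"invalid placement strand {strand!r}")


def _select_hit(hits: Sequence[SignatureHit]) -> Optional[SignatureHit]:
    """Pick one junction per read: the leftmost plus-strand hit if any,
    else the rightmost minus-strand hit.

    A 48-nt read cannot meaningfully support two junctions, so extra hits
    are ignored.
    """
    plus = [h for h in hits if h.strand == "+"]
    if plus:
        return plus[0]
    minus = [h for h in hits if h.strand == "-"]
    if minus:
        return minus[-1]
    return None


def _reference_carries_insert(site: InsertionSite, index: GenomeIndex, signature: str) -> bool:
    """True when the reference itself continues from the junction into the
    signature, i.e. the element is present in the reference and the site is
    not a novel insertion."""
    contig_len = len(index.contigs[site.contig])
    if site.l1_orientation == "+":
        start = site.position + 1
        window = index.sequence(site.contig, start, min(start + len(signature) - 1, contig_len))
        return window == signature
    start = site.position - len(signature) + 1
    if start < 1:
        return False
    window = index.sequence(site.contig, start, site.position)
    return window == reverse_complement(signature)


@dataclass
class DiscoveryStats:
    """Filter-funnel counters logged by :func:`discover_sites`."""

    reads_scanned: int = 0
    reads_with_signature: int = 0
    flanks_too_short: int = 0
    flanks_non_unique: int = 0
    flanks_unplaced: int = 0
    flanks_accepted: int = 0
    sites_in_reference: int = 0
    sites_emitted: int = 0


def discover_sites(
    reads: Iterable[SequenceRecord],
    genome: list[SequenceRecord] | GenomeIndex,
    params: DetectionParams = DetectionParams(),
    stats: Optional[DiscoveryStats] = None,
) -> list[InsertionSite]:
    """Run the full junction-discovery pipeline over a read set.

    Composes signature search, flank extraction, the length and uniqueness
    filters, and junction inference; merges reads supporting the same
    (contig, position, orientation); drops junctions already present in the
    reference; returns sites sorted by (contig, position).
    """
    index = genome if isinstance(genome, GenomeIndex) else build_genome_index(genome, params.seed_len)
    if stats is None:
        stats = DiscoveryStats()
    sites: dict[tuple[str, int, str], InsertionSite] = {}
    for read in reads:
        stats.reads_scanned += 1
        hits = find_signature(read, params)
        if not hits:
            continue
        stats.reads_with_signature += 1
        hit = _select_hit(hits)
        flank = extract_flank(read, hit, params)
        if flank.status == "too_short":
            stats.flanks_too_short += 1
            continue
        placements = place_flank(flank, index, params)
        if not placements:
            flank.status = "unplaced"
            stats.flanks_unplaced += 1
            continue
        if len(placements) > 1:
            flank.status = "non_unique"
            stats.flanks_non_unique += 1
            continue
        flank.status = "accepted"
        stats.flanks_accepted += 1
        try:
            site = infer_insertion_site(flank, placements[0], hit)
        except ValueError:
            continue
        if _reference_carries_insert(site, index, params.signature):
            stats.sites_in_reference += 1
            continue
        existing = sites.get(site.key)
        if existing is None:
            sites[site.key] = site
        else:
            if read.id not in existing.supporting_reads:
                existing.supporting_reads.append(read.id)
            if len(site.flank_seq) > len(existing.flank_seq):
                existing.flank_seq = site.flank_seq
    out = sorted(sites.values(), key=lambda s: (s.contig, s.position, s.l1_orientation))
    stats.sites_emitted = len(out)
    return out


# ---------------------------------------------------------------------------
# TSV report

SITE_COLUMNS = ["contig", "position", "l1_orientation", "n_supporting_reads", "flank_seq"]


def write_sites_tsv(path, sites: Iterable[InsertionSite]) -> None:
    with open(path, "w") as out:
        out.write("\t".join(SITE_COLUMNS) + "\n")
        for s in sites:
            out.write(
                f"{s.contig}\t{s.position}\t{s.l1_orientation}\t"
                f"{len(s.supporting_reads)}\t{s.flank_seq}\n"
            )


def read_sites_tsv(path) -> list[InsertionSite]:
    sites = []
    with open(path) as handle:
        header = handle.readline().rstrip("\n").split("\t")
        col = {c: i for i, c in enumerate(header)}
        for line in handle:
            f = line.rstrip("\n").split("\t")
            sites.append(
                InsertionSite(
                    f[col["contig"]],
                    int(f[col["position"]]),
                    f[col["l1_orientation"]],
                    [f"read{i}" for i in range(int(f[col["n_supporting_reads"]]))]
                    if "n_supporting_reads" in col
                    else ["unknown"],
                    f[col["flank_seq"]] if "flank_seq" in col else "",
                )
            )
    return sites
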