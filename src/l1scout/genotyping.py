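"""Per-sample genotyping of L1 insertion sites and trio inheritance.

For a discovered site the genotyper re-examines every read of every sample.
A read anchored by the site's unique 5' flank is insertion-bearing when its
continuation past the junction matches the L1 5'-end marker, and
reference-continuous when the continuation matches the reference. Reads at
the opposite junction carrying a poly-A run inconsistent with the reference
are additional insertion evidence (the element's 3' poly-A tail); this rule
can be restricted to the parent samples to mirror shallow-coverage practice,
where parents often lack 5'-junction reads.

Genotype codes follow the field's shorthand: ``+/-`` (both insertion and
reference reads seen), ``Y`` (only insertion reads: apparently homozygous or
at least present), ``N`` (only reference reads: no insertion evidence), and
``?/?`` (no informative reads at all).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional, Sequence

from l1scout.discovery import DetectionParams, InsertionSite
from l1scout.seqio import SequenceRecord, reverse_complement


class ReadClass(Enum):
    L1_PLUS_SIGNATURE = "L1_plus_signature"
    L1_PLUS_POLYA = "L1_plus_polyA"
    L1_MINUS = "L1_minus"
    UNINFORMATIVE = "uninformative"


@dataclass(frozen=True)
class PolyAParams:
    """Poly-A tail evidence thresholds.

    A junction-adjacent run of ``min_run`` bases with at most ``max_nonA``
    non-A characters counts as a tail, but only when it disagrees with the
    reference at half or more of its positions (a genomic A-tract is not
    evidence). ``enabled_samples`` limits the rule to named samples; None
    enables it everywhere.
    """

    min_run: int = 10
    max_nonA: int = 1
    enabled_samples: Optional[frozenset[str]] = None

    def __post_init__(self) -> None:
        if self.min_run < 5:
            raise ValueError("min_run must be >= 5")
        if self.max_nonA >= self.min_run:
            raise ValueError("max_nonA must be < min_run")

    def enabled_for(self, sample: str) -> bool:
        return self.enabled_samples is None or sample in self.enabled_samples


MIN_CONTINUATION = 7  # junction evidence needs at least the 7-nt marker length


def detect_polyA(
    segment: str,
    ref_segment: str,
    params: PolyAParams = PolyAParams(),
    orientation: str = "+",
) -> bool:
    """Decide whether a junction-adjacent segment shows a non-reference
    poly-A run.

    ``segment`` and ``ref_segment`` are positionally aligned windows
    starting at the same reference coordinate; for orientation '-' both are
    reverse-complemented first (an element on the minus strand leaves a
    T-run on the plus strand).
    """
    if orientation == "-":
        segment = reverse_complement(segment)
        ref_segment = reverse_complement(ref_segment)
    run = segment[: params.min_run]
    if len(run) < params.min_run:
        return False
    if sum(1 for c in run if c != "A") > params.max_nonA:
        return False
    ref_run = ref_segment[: params.min_run]
    if len(ref_run) < params.min_run:
        return False
    diffs = sum(1 for a, b in zip(run, ref_run) if a != b)
    return 2 * diffs >= params.min_run


@dataclass
class RefWindows:
    """Reference plus-strand context around a junction at position t:
    ``left`` ends at t, ``right`` starts at t + 1."""

    left: str
    right: str


def reference_windows(site: InsertionSite, contigs: dict[str, str], window: int = 48) -> RefWindows:
    seq = contigs[site.contig]
    t = site.position
    return RefWindows(left=seq[max(0, t - window) : t], right=seq[t : t + window])


def _hamming_at_most(a: str, b: str, limit: int) -> bool:
    n = 0
    for x, y in zip(a, b):
        if x != y:
            n += 1
            if n > limit:
                return False
    return True


def _classify_flank_continuation(continuation: str, signature: str, ref_continuation: str) -> ReadClass:
    n = len(continuation)
    if n < MIN_CONTINUATION:
        return ReadClass.UNINFORMATIVE
    m = min(n, len(signature))
    if continuation[:m] == signature[:m]:
        return ReadClass.L1_PLUS_SIGNATURE
    m2 = min(n, len(ref_continuation))
    if m2 >= MIN_CONTINUATION and _hamming_at_most(continuation[:m2], ref_continuation[:m2], 1):
        return ReadClass.L1_MINUS
    return ReadClass.UNINFORMATIVE


POLYA_ANCHOR_LEN = 12  # reference bases needed to anchor a tail-junction read


def _polyA_class(
    oriented: str,
    site: InsertionSite,
    windows: RefWindows,
    polya: PolyAParams,
) -> bool:
    """Check one read orientation for tail-junction poly-A evidence."""
    if site.l1_orientation == "+":
        # tail junction on the plus strand: [A-run][reference right of t]
        anchor = windows.right[:POLYA_ANCHOR_LEN]
        if len(anchor) < POLYA_ANCHOR_LEN:
            return False
        i = oriented.find(anchor)
        if i < polya.min_run or i > len(windows.left):
            return False
        ref_segment = windows.left[len(windows.left) - i :] + windows.right[: len(oriented) - i]
        # align the run so it abuts the junction: compare reversed strings
        return detect_polyA(oriented[:i][::-1], ref_segment[:i][::-1], polya, orientation="+")
    # '-' element: tail junction is [reference left of t][T-run] on plus strand
    anchor = windows.left[-POLYA_ANCHOR_LEN:]
    if len(anchor) < POLYA_ANCHOR_LEN:
        return False
    j = oriented.find(anchor)
    if j == -1:
        return False
    junction = j + POLYA_ANCHOR_LEN
    tail = oriented[junction:]
    if len(tail) < polya.min_run or len(tail) > len(windows.right):
        return False
    ref_segment = windows.right[: len(tail)]
    return detect_polyA(tail, ref_segment, polya, orientation="-")


def classify_read(
    read: SequenceRecord,
    site: InsertionSite,
    flank: str,
    ref_windows: RefWindows,
    params: DetectionParams = DetectionParams(),
    polya: PolyAParams = PolyAParams(),
    polya_enabled: bool = True,
    strict: bool = False,
) -> ReadClass:
    """Classify one read against one locus.

    The read is oriented to the locus flank (exact match, either strand);
    the continuation past the junction decides the class: L1 5'-end marker
    -> insertion-bearing; reference continuation (>= 7 bases, <= 1
    mismatch) -> reference-continuous; a non-reference poly-A run at the
    tail junction -> insertion-bearing by poly-A (when enabled); anything
    else is uninformative.
    """
    if site.l1_orientation == "+":
        ref_continuation = ref_windows.right
    else:
        ref_continuation = reverse_complement(ref_windows.left)
    orientations = (read.seq, reverse_complement(read.seq))
    seen_flank = False
    for oriented in orientations:
        pos = oriented.find(flank)
        if pos != -1:
            seen_flank = True
            continuation = oriented[pos + len(flank) :]
            cls = _classify_flank_continuation(continuation, params.signature, ref_continuation)
            if cls is not ReadClass.UNINFORMATIVE:
                return cls
    if polya_enabled:
        for oriented in orientations:
            if _polyA_class(oriented, site, ref_windows, polya):
                return ReadClass.L1_PLUS_POLYA
    if strict and not seen_flank:
        raise ValueError(f"read {read.id!r} does not contain the locus flank")
    return ReadClass.UNINFORMATIVE


@dataclass
class LocusGenotype:
    """Evidence tallies and the called code for one sample at one site."""

    sample: str
    site_key: tuple[str, int, str]
    n_plus_signature: int = 0
    n_plus_polyA: int = 0
    n_minus: int = 0
    call: str = "?/?"
    low_confidence: bool = False

    @property
    def n_plus(self) -> int:
        return self.n_plus_signature + self.n_plus_polyA


def call_genotype(
    tallies: dict[ReadClass, int],
    sample: str,
    site_key: tuple[str, int, str] = ("", 0, "+"),
    min_reads: int = 1,
) -> LocusGenotype:
    """Call the genotype code from per-class read tallies.

    ``+/-`` needs both insertion and reference reads; ``Y`` only insertion
    reads; ``N`` only reference reads; ``?/?`` neither. When the stronger
    side has fewer than ``min_reads`` reads the call is flagged
    low-confidence rather than withheld.
    """
    gt = LocusGenotype(
        sample,
        site_key,
        n_plus_signature=tallies.get(ReadClass.L1_PLUS_SIGNATURE, 0),
        n_plus_polyA=tallies.get(ReadClass.L1_PLUS_POLYA, 0),
        n_minus=tallies.get(ReadClass.L1_MINUS, 0),
    )
    if gt.n_plus >= 1 and gt.n_minus >= 1:
        gt.call = "+/-"
    elif gt.n_plus >= 1:
        gt.call = "Y"
    elif gt.n_minus >= 1:
        gt.call = "N"
    else:
        gt.call = "?/?"
    gt.low_confidence = max(gt.n_plus, gt.n_minus) < min_reads
    return gt


def genotype_site(
    site: InsertionSite,
    reads: Iterable[SequenceRecord],
    contigs: dict[str, str],
    sample: str,
    params: DetectionParams = DetectionParams(),
    polya: PolyAParams = PolyAParams(),
    min_reads: int = 1,
) -> LocusGenotype:
    """Tally junction-spanning reads of one sample at one site and call."""
    windows = reference_windows(site, contigs)
    enabled = polya.enabled_for(sample)
    tallies: dict[ReadClass, int] = {}
    # anchor on the junction-proximal min_flank bases: short reads rarely
    # contain a longer stored flank in full, and the 3'-terminal bases are
    # the ones that abut the junction
    flank = site.flank_seq[-params.min_flank :]
    for read in reads:
        cls = classify_read(read, site, flank, windows, params, polya, polya_enabled=enabled)
        if cls is not ReadClass.UNINFORMATIVE:
            tallies[cls] = tallies.get(cls, 0) + 1
    return call_genotype(tallies, sample, site.key, min_reads)


def targeted_junction_search(
    reads: Iterable[SequenceRecord],
    flank_fragment: str,
    params: DetectionParams = DetectionParams(),
) -> list[str]:
    """Rescue search at an apparent de-novo locus.

    Builds the probe ``flank_fragment + marker`` (10-15 nt of unique flank
    followed by the first 7 L1 bases) and returns the ids of every read
    containing the probe or its reverse complement. Matching reads support
    the insertion even when their flank falls below the 25-bp placement
    requirement.
    """
    if not 10 <= len(flank_fragment) <= 15:
        raise ValueError(
            f"flank fragment must be 10-15 nt, got {len(flank_fragment)}"
        )
    probe = flank_fragment + params.marker
    probe_rc = reverse_complement(probe)
    hits = []
    for read in reads:
        if probe in read.seq or probe_rc in read.seq:
            hits.append(read.id)
    return hits


@dataclass
class TrioResult:
    """Three genotype calls at one site plus the inheritance verdict."""

    site_key: tuple[str, int, str]
    child: LocusGenotype
    father: LocusGenotype
    mother: LocusGenotype
    verdict: str = "unresolved"  # inherited | de_novo_candidate | absent | unresolved


def analyze_trio(child: LocusGenotype, father: LocusGenotype, mother: LocusGenotype) -> TrioResult:
    """Decide whether a child insertion was inherited or is a de-novo
    candidate.

    A de-novo candidate requires positive evidence of absence ("N") in both
    parents; a parent with no informative reads ("?/?") leaves the site
    unresolved rather than implicating a new insertion.
    """
    if not (child.site_key == father.site_key == mother.site_key):
        raise ValueError("genotypes refer to different sites")
    result = TrioResult(child.site_key, child, father, mother)
    if child.n_plus >= 1:
        if father.n_plus >= 1 or mother.n_plus >= 1:
            result.verdict = "inherited"
        elif father.call == "N" and mother.call == "N":
            result.verdict = "de_novo_candidate"
        else:
            result.verdict = "unresolved"
    else:
        result.verdict = "absent" if child.call == "N" else "unresolved"
    return result


def genotype_trio(
    sites: Sequence[InsertionSite],
    sample_reads: dict[str, list[SequenceRecord]],
    genome: Iterable[SequenceRecord] | dict[str, str],
    roles: tuple[str, str, str] = ("child", "father", "mother"),
    params: DetectionParams = DetectionParams(),
    polya: PolyAParams = PolyAParams(),
    min_reads: int = 1,
) -> list[TrioResult]:
    """Genotype every site in every sample and assess inheritance.

    ``roles`` names the (child, father, mother) keys of ``sample_reads``.
    """
    contigs = genome if isinstance(genome, dict) else {r.id: r.seq for r in genome}
    child_name, father_name, mother_name = roles
    results = []
    for site in sites:
        gts = {
            name: genotype_site(site, sample_reads[name], contigs, name, params, polya, min_reads)
            for name in roles
        }
        results.append(analyze_trio(gts[child_name], gts[father_name], gts[mother_name]))
    return results


def paper_mode_polya(father: str, mother: str, base: PolyAParams = PolyAParams()) -> PolyAParams:
    """Poly-A evidence restricted to the parents, as in shallow pilot data
    where the daughter always had a 5'-junction read but parents often did
    not."""
    return PolyAParams(base.min_run, base.max_nonA, frozenset({father, mother}))


GENOTYPE_COLUMNS = [
    "contig", "position", "l1_orientation",
    "child_call", "father_call", "mother_call",
    "child_counts", "father_counts", "mother_counts",
    "verdict",
]


def write_genotypes_tsv(path, results: Iterable[TrioResult]) -> None:
    def counts(gt: LocusGenotype) -> str:
        return f"{gt.n_plus_signature},{gt.n_plus_polyA},{gt.n_minus}"

    with open(path, "w") as out:
        out.write("\t".join(GENOTYPE_COLUMNS) + "\n")
        for r in results:
            contig, pos, orient = r.site_key
            out.write(
                f"{contig}\t{pos}\t{orient}\t"
                f"{r.child.call}\t{r.father.call}\t{r.mother.call}\t"
                f"{counts(r.child)}\t{counts(r.father)}\t{counts(r.mother)}\t"
                f"{r.verdict}\n"
            )
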