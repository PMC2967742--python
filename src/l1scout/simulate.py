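"""Deterministic synthetic trio generator with per-site truth records.

The generator emulates the study design the detection method targets: a
reference genome free of the element, a ~6 kb full-length L1 cassette whose
5' end carries the conserved 14-nt signature and whose 3' end is a poly-A
tail, insertions planted per haplotype at Mendelian trio genotypes, and
fixed-length short reads (default 48 nt, error-free) drawn uniformly from
both haplotypes of each sample.

Everything is a pure function of the configuration, including the seed, so
identical configurations produce byte-identical FASTA/FASTQ/truth outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import numpy as np

from l1scout.discovery import DEFAULT_SIGNATURE
from l1scout.seqio import SequenceRecord, reverse_complement

BASES = np.array(list("ACGT"))

L1_INTERNAL_PRIMER_RC_OFFSET = 300
"""0-based cassette offset at which the reverse complement of the
element-internal validation oligo is embedded (within the 5' UTR region, so
insertion-allele PCR products stay short)."""

_L1_INTERNAL_PRIMER = "TGAACCCGGTACCTCAGATG"


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic trio.

    Defaults mirror the pilot-data regime the method was designed for:
    48-nt reads, ~6 kb full-length elements, 20 polymorphic sites on a
    100 kb two-contig genome at 30x diploid coverage, no read errors, and
    no de-novo child-only sites.
    """

    genome_len: int = 100_000
    n_contigs: int = 2
    gc: float = 0.41
    n_sites: int = 20
    cassette_len: int = 6000
    polyA_len: int = 30
    tsd_len: int = 0
    read_len: int = 48
    coverage: float = 30.0
    error_rate: float = 0.0
    seed: int = 42
    de_novo_fraction: float = 0.0
    signature: str = DEFAULT_SIGNATURE
    min_flank: int = 25

    def __post_init__(self) -> None:
        if self.read_len < self.min_flank + len(self.signature):
            raise ValueError(
                "read_len must be >= min_flank + signature length, else no "
                "read can carry both a placeable flank and the full signature"
            )
        if self.cassette_len < len(self.signature) + self.polyA_len:
            raise ValueError("cassette_len must fit the signature and the poly-A tail")
        if not 0.0 <= self.gc <= 1.0:
            raise ValueError("gc must be a fraction")
        if not 0.0 <= self.de_novo_fraction <= 1.0:
            raise ValueError("de_novo_fraction must be a fraction")


@dataclass
class TruthRecord:
    """Ground truth for one planted site.

    ``position`` is the biological insertion point (reference base
    immediately 5' of the insert); ``observed_position`` is the junction a
    5'-flank caller should report, which differs from ``position`` only
    when a target-site duplication shifts the apparent '-' junction.
    ``genotypes`` maps sample name to het/hom/absent.
    """

    contig: str
    position: int
    observed_position: int
    l1_orientation: str
    genotypes: dict[str, str]
    inherited_from: str  # father | mother | both | de_novo | none


SAMPLES = ("child", "father", "mother")


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(BASES[rng.choice(4, size=n, p=p)])


def _signature_free(seq: str, signature: str) -> bool:
    return signature not in seq and reverse_complement(signature) not in seq


def make_cassette(config: SimulationConfig, rng: Optional[np.random.Generator] = None) -> SequenceRecord:
    """Synthetic full-length L1 stand-in: signature, random body carrying
    the internal validation-primer site, then the poly-A tail.

    The body is resampled until the signature occurs exactly once (at the
    5' end) on either strand, so junction discovery cannot be confounded by
    internal matches. A real L1 consensus FASTA may replace the cassette in
    the pipeline.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    sig = config.signature
    body_len = config.cassette_len - len(sig) - config.polyA_len
    primer_rc = reverse_complement(_L1_INTERNAL_PRIMER)
    while True:
        body = list(_random_seq(rng, body_len, config.gc))
        off = L1_INTERNAL_PRIMER_RC_OFFSET - len(sig)
        if 0 <= off <= body_len - len(primer_rc):
            body[off : off + len(primer_rc)] = primer_rc
        seq = sig + "".join(body) + "A" * config.polyA_len
        if seq.count(sig) == 1 and reverse_complement(sig) not in seq:
            return SequenceRecord("L1_cassette", seq)


def make_genome(config: SimulationConfig, rng: Optional[np.random.Generator] = None) -> list[SequenceRecord]:
    """Random signature-free reference contigs at the requested GC."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    lengths = [config.genome_len // config.n_contigs] * config.n_contigs
    lengths[-1] += config.genome_len - sum(lengths)
    contigs = []
    for i, n in enumerate(lengths, 1):
        while True:
            seq = _random_seq(rng, n, config.gc)
            if _signature_free(seq, config.signature):
                break
        contigs.append(SequenceRecord(f"contig{i}", seq))
    return contigs


def _draw_parent_genotype(rng: np.random.Generator) -> str:
    # realistic polymorphic-site regime: most non-reference L1 sites are
    # segregating at intermediate frequency -> het 0.5, hom 0.25, absent 0.25
    return str(rng.choice(["het", "hom", "absent"], p=[0.5, 0.25, 0.25]))


_N_ALLELES = {"het": 1, "hom": 2, "absent": 0}


@dataclass
class TrioSimulation:
    """All artifacts of one simulated trio."""

    config: SimulationConfig
    genome: list[SequenceRecord]
    cassette: SequenceRecord
    truth: list[TruthRecord]
    haplotypes: dict[str, tuple[list[SequenceRecord], list[SequenceRecord]]]
    reads: dict[str, list[SequenceRecord]] = field(default_factory=dict)


def plant_trio(
    genome: list[SequenceRecord],
    cassette: SequenceRecord,
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> TrioSimulation:
    """Choose sites, draw Mendelian trio genotypes, and splice the cassette
    into the six haplotypes.

    Every non-de-novo site is redrawn until the child carries at least one
    allele (the study ascertains sites through the child), keeping the
    truth set fully discoverable from child reads. An insertion at
    reference position t (1-based) with target-site duplication d places
    ``ref[..t] + element + ref[t-d+1..t] + ref[t+1..]``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    min_sep = 2 * config.read_len + config.tsd_len + 60
    edge = config.read_len + 10

    # site placement: uniform over contigs by length, rejection on spacing
    positions: list[tuple[str, int]] = []
    weights = np.array([len(c) for c in genome], dtype=float)
    weights /= weights.sum()
    attempts = 0
    while len(positions) < config.n_sites:
        attempts += 1
        if attempts > 1000 * config.n_sites:
            raise ValueError("could not place sites with the required spacing")
        ci = int(rng.choice(len(genome), p=weights))
        contig = genome[ci]
        if len(contig) < 2 * edge + 1:
            continue
        pos = int(rng.integers(edge, len(contig) - edge))
        if all(c != contig.id or abs(p - pos) >= min_sep for c, p in positions):
            positions.append((contig.id, pos))
    positions.sort()

    n_de_novo = int(round(config.de_novo_fraction * config.n_sites))
    de_novo_idx = set(rng.choice(config.n_sites, size=n_de_novo, replace=False).tolist())

    truth: list[TruthRecord] = []
    # per-haplotype insertion lists: sample -> [hap0 sites, hap1 sites]
    hap_sites: dict[str, tuple[list, list]] = {s: ([], []) for s in SAMPLES}
    for idx, (contig, pos) in enumerate(positions):
        orientation = "+" if rng.random() < 0.5 else "-"
        if idx in de_novo_idx:
            father_gt, mother_gt, child_gt = "absent", "absent", "het"
            child_alleles = (1, 0) if rng.random() < 0.5 else (0, 1)
            inherited = "de_novo"
        else:
            while True:
                father_gt = _draw_parent_genotype(rng)
                mother_gt = _draw_parent_genotype(rng)
                from_father = _N_ALLELES[father_gt] > 0 and (
                    father_gt == "hom" or rng.random() < 0.5
                )
                from_mother = _N_ALLELES[mother_gt] > 0 and (
                    mother_gt == "hom" or rng.random() < 0.5
                )
                if from_father or from_mother:
                    break
            child_alleles = (int(from_father), int(from_mother))
            child_gt = ("absent", "het", "hom")[sum(child_alleles)]
            inherited = {(True, True): "both", (True, False): "father", (False, True): "mother"}[
                (from_father, from_mother)
            ]
        observed = pos if orientation == "+" else pos - config.tsd_len
        truth.append(
            TruthRecord(
                contig, pos, observed, orientation,
                {"child": child_gt, "father": father_gt, "mother": mother_gt},
                inherited,
            )
        )
        site = (contig, pos, orientation)
        # child haplotype 0 is paternal, 1 is maternal
        if child_alleles[0]:
            hap_sites["child"][0].append(site)
        if child_alleles[1]:
            hap_sites["child"][1].append(site)
        for sample, gt in (("father", father_gt), ("mother", mother_gt)):
            n = _N_ALLELES[gt]
            if n >= 1:
                hap_sites[sample][0].append(site)
            if n == 2:
                hap_sites[sample][1].append(site)

    ref = {c.id: c.seq for c in genome}
    haplotypes: dict[str, tuple[list[SequenceRecord], list[SequenceRecord]]] = {}
    for sample in SAMPLES:
        pair = []
        for h in (0, 1):
            contigs_out = []
            per_contig: dict[str, list] = {}
            for contig, pos, orientation in hap_sites[sample][h]:
                per_contig.setdefault(contig, []).append((pos, orientation))
            for cid, seq in ref.items():
                inserts = sorted(per_contig.get(cid, []), reverse=True)
                hap_seq = seq
                for pos, orientation in inserts:
                    element = cassette.seq if orientation == "+" else reverse_complement(cassette.seq)
                    tsd = seq[pos - config.tsd_len : pos] if config.tsd_len else ""
                    hap_seq = hap_seq[:pos] + element + tsd + hap_seq[pos:]
                contigs_out.append(SequenceRecord(f"{sample}_h{h + 1}_{cid}", hap_seq))
            pair.append(contigs_out)
        haplotypes[sample] = (pair[0], pair[1])
    return TrioSimulation(config, genome, cassette, truth, haplotypes)


def simulate_reads(
    haplotype_pair: tuple[list[SequenceRecord], list[SequenceRecord]],
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
    sample: str = "sample",
) -> list[SequenceRecord]:
    """Uniform fixed-length single-end reads from both haplotypes.

    Read count = round(coverage * total haplotype length / (2 * read_len)),
    i.e. ``coverage`` is diploid depth. Start positions are uniform over
    valid windows, strand is random, and substitutions occur independently
    at ``error_rate``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    contigs = [c for hap in haplotype_pair for c in hap if len(c) >= config.read_len]
    total_len = sum(len(c) for hap in haplotype_pair for c in hap)
    n_reads = int(round(config.coverage * total_len / (2 * config.read_len)))
    starts_per_contig = np.array([len(c) - config.read_len + 1 for c in contigs], dtype=float)
    p = starts_per_contig / starts_per_contig.sum()
    reads: list[SequenceRecord] = []
    choices = rng.choice(len(contigs), size=n_reads, p=p)
    for i, ci in enumerate(choices):
        contig = contigs[ci]
        start = int(rng.integers(0, len(contig) - config.read_len + 1))
        seq = contig.seq[start : start + config.read_len]
        if rng.random() < 0.5:
            seq = reverse_complement(seq)
        if config.error_rate > 0:
            seq_arr = np.frombuffer(seq.encode(), dtype="S1").copy()
            err = rng.random(config.read_len) < config.error_rate
            for j in np.nonzero(err)[0]:
                current = seq_arr[j].decode()
                alternatives = [b for b in "ACGT" if b != current]
                seq_arr[j] = alternatives[int(rng.integers(3))].encode()
            seq = seq_arr.tobytes().decode()
        reads.append(SequenceRecord(f"{sample}_r{i + 1}", seq, quals=[30] * config.read_len))
    return reads


def simulate_trio(config: SimulationConfig = SimulationConfig()) -> TrioSimulation:
    """Full deterministic simulation: genome, cassette, haplotypes, truth,
    and per-sample reads."""
    rng = np.random.default_rng(config.seed)
    genome = make_genome(config, rng)
    cassette = make_cassette(config, rng)
    sim = plant_trio(genome, cassette, config, rng)
    for sample in SAMPLES:
        sim.reads[sample] = simulate_reads(sim.haplotypes[sample], config, rng, sample=sample)
    return sim


TRUTH_COLUMNS = [
    "contig", "position", "observed_position", "l1_orientation",
    "child", "father", "mother", "inherited_from",
]


def write_truth_tsv(path, truth: Iterable[TruthRecord]) -> None:
    with open(path, "w") as out:
        out.write("\t".join(TRUTH_COLUMNS) + "\n")
        for t in truth:
            out.write(
                f"{t.contig}\t{t.position}\t{t.observed_position}\t{t.l1_orientation}\t"
                f"{t.genotypes['child']}\t{t.genotypes['father']}\t"
                f"{t.genotypes['mother']}\t{t.inherited_from}\n"
            )


def config_from_file(path) -> SimulationConfig:
    """Flat key=value configuration file -> SimulationConfig."""
    kwargs = {}
    fields_ = {f: t for f, t in SimulationConfig.__annotations__.items()}
    with open(path) as handle:
        for line in handle:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key not in fields_:
                raise ValueError(f"unknown simulation parameter {key!r}")
            if key == "signature":
                kwargs[key] = value
            elif key in ("gc", "coverage", "error_rate", "de_novo_fraction"):
                kwargs[key] = float(value)
            else:
                kwargs[key] = int(value)
    return SimulationConfig(**kwargs)
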