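"""Gene-context annotation, summary counts, site-set comparison, and
in-silico PCR.

An insertion is *intragenic* when its single junction coordinate falls
inside a gene span, and *sense* when the element's orientation equals the
gene's transcribed strand — the configuration in which the element's
bidirectional 5' UTR promoter is best placed to perturb the host gene.

The package bundles, as plain TSV fixtures, the published trio call set
(22 sites), the follow-up comparison list (8 sites unique to this method),
and the allele-specific validation primer pairs, so the headline counts are
executable checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Optional, Sequence

import pandas as pd

from l1scout.discovery import InsertionSite
from l1scout.seqio import GeneInterval, reverse_complement


@dataclass
class SiteAnnotation:
    """Gene context of one insertion site.

    ``sense`` is defined only for intragenic sites: the element is on the
    sense strand of the gene iff the two orientation fields agree. When
    several genes overlap the point, all are listed and the first by start
    coordinate is primary.
    """

    site_key: tuple[str, int, str]
    context: str  # intragenic | intergenic
    gene: Optional[GeneInterval] = None
    sense: Optional[str] = None  # sense | antisense
    all_genes: list[GeneInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.context == "intergenic" and (self.gene is not None or self.sense is not None):
            raise ValueError("intergenic sites carry no gene or sense label")


def annotate_site(site: InsertionSite, genes: Sequence[GeneInterval]) -> SiteAnnotation:
    """Classify one site against a gene annotation (point-in-span test)."""
    overlapping = sorted(
        (g for g in genes if g.contains(site.contig, site.position)),
        key=lambda g: (g.start, g.end, g.name),
    )
    if not overlapping:
        return SiteAnnotation(site.key, "intergenic")
    primary = overlapping[0]
    sense = "sense" if site.l1_orientation == primary.strand else "antisense"
    return SiteAnnotation(site.key, "intragenic", primary, sense, overlapping)


def summarize_sites(annotations: Iterable[SiteAnnotation]) -> dict[str, int]:
    """Tally total, intragenic, and sense-intragenic sites."""
    total = intragenic = sense = 0
    for ann in annotations:
        total += 1
        if ann.context == "intragenic":
            intragenic += 1
            if ann.sense == "sense":
                sense += 1
    return {"total": total, "intragenic": intragenic, "sense_intragenic": sense}


def compare_site_sets(
    all_sites: Sequence[InsertionSite],
    confirmed_subset: Sequence[InsertionSite],
) -> dict[str, list[InsertionSite]]:
    """Partition ``all_sites`` by (contig, position) membership in an
    independently confirmed set."""
    def keys(sites: Sequence[InsertionSite]) -> set[tuple[str, int]]:
        ks = [(s.contig, s.position) for s in sites]
        if len(set(ks)) != len(ks):
            raise ValueError("duplicate (contig, position) keys in site list")
        return set(ks)

    confirmed_keys = keys(confirmed_subset)
    keys(all_sites)
    confirmed, additional = [], []
    for s in all_sites:
        (confirmed if (s.contig, s.position) in confirmed_keys else additional).append(s)
    return {"confirmed": confirmed, "additional": additional}


@dataclass(frozen=True)
class PrimerPair:
    """An allele-specific PCR primer pair.

    ``fwd`` is written 5'->3' on the template plus strand; ``rev`` is
    written 5'->3' on the minus strand (so its reverse complement appears
    on the plus strand of the template).
    """

    fwd: str
    rev: str
    label: str = ""

    def __post_init__(self) -> None:
        if len(self.fwd) < 15 or len(self.rev) < 15:
            raise ValueError("primers must be at least 15 nt")


def insilico_pcr(template: str, primers: PrimerPair, max_product: int = 5000) -> list[int]:
    """Compute exact-match PCR product lengths on a template.

    For every plus-strand occurrence of ``fwd`` at 1-based position i and
    every occurrence of ``reverse_complement(rev)`` starting at j >= i, the
    product spans i .. j + len(rev) - 1; lengths above ``max_product`` are
    dropped. Returns all product lengths, sorted.
    """
    t = template.upper()
    fwd = primers.fwd.upper()
    rev_rc = reverse_complement(primers.rev)

    def occurrences(pattern: str) -> list[int]:
        out, start = [], t.find(pattern)
        while start != -1:
            out.append(start + 1)
            start = t.find(pattern, start + 1)
        return out

    products = []
    rev_sites = occurrences(rev_rc)
    for i in occurrences(fwd):
        for j in rev_sites:
            if j >= i:
                length = (j + len(primers.rev) - 1) - i + 1
                if length <= max_product:
                    products.append(length)
    return sorted(products)


# ---------------------------------------------------------------------------
# Bundled fixtures (published trio call set and follow-up comparison)

def _data_path(name: str):
    return resources.files("l1scout.data").joinpath(name)


def _read_tsv(name: str) -> pd.DataFrame:
    with resources.as_file(_data_path(name)) as p:
        return pd.read_csv(p, sep="\t")


def load_reported_sites() -> pd.DataFrame:
    """The published 22-site trio call set: per-site trio genotype codes,
    element orientation, and gene context."""
    return _read_tsv("reported_insertions.tsv")


def load_additional_sites() -> pd.DataFrame:
    """The 8 sites found by this approach but not by the independent
    follow-up study of the same samples."""
    return _read_tsv("followup_additional_insertions.tsv")


def load_primer_pairs() -> list[PrimerPair]:
    """Allele-specific validation primer pairs (with the element-internal
    reverse oligo for insertion alleles)."""
    df = _read_tsv("validation_primers.tsv")
    return [PrimerPair(r.fwd, r.rev, r.label) for r in df.itertuples()]


L1_INTERNAL_PRIMER = "TGAACCCGGTACCTCAGATG"
"""Element-internal reverse oligo used for every insertion-allele reaction."""


def sites_from_table(df: pd.DataFrame) -> list[InsertionSite]:
    """Build InsertionSite objects from a call-set table (fixture or report)."""
    orient = df["l1_orientation"] if "l1_orientation" in df else ["+"] * len(df)
    return [
        InsertionSite(str(c), int(p), str(o), ["reported"])
        for c, p, o in zip(df["contig"], df["position"], orient)
    ]


def annotations_from_table(df: pd.DataFrame) -> list[SiteAnnotation]:
    """Re-derive SiteAnnotations from a call-set table's own gene columns.

    A row is intragenic iff it names a gene locus; sense iff the element
    and gene orientations agree. Gene spans are not in the table, so a
    1-bp placeholder interval at the site position carries the gene name
    and strand.
    """
    anns = []
    for row in df.itertuples():
        key = (str(row.contig), int(row.position), str(row.l1_orientation))
        gene_name = getattr(row, "gene_locus", None)
        if gene_name is None or (isinstance(gene_name, float) and pd.isna(gene_name)):
            anns.append(SiteAnnotation(key, "intergenic"))
            continue
        gene = GeneInterval(
            key[0], key[1], key[1], str(row.gene_orientation), str(gene_name),
            gene_id=None if pd.isna(row.entrez_id) else str(int(row.entrez_id)),
        )
        sense = "sense" if key[2] == gene.strand else "antisense"
        anns.append(SiteAnnotation(key, "intragenic", gene, sense, [gene]))
    return anns


ANNOTATION_COLUMNS = [
    "contig", "position", "l1_orientation", "context", "gene_locus",
    "gene_id", "gene_orientation", "sense",
]


def write_annotations_tsv(path, annotations: Iterable[SiteAnnotation]) -> None:
    with open(path, "w") as out:
        out.write("\t".join(ANNOTATION_COLUMNS) + "\n")
        for a in annotations:
            contig, pos, orient = a.site_key
            if a.gene is not None:
                gene_cols = f"{a.gene.name}\t{a.gene.gene_id or ''}\t{a.gene.strand}\t{a.sense}"
            else:
                gene_cols = "\t\t\t"
            out.write(f"{contig}\t{pos}\t{orient}\t{a.context}\t{gene_cols}\n")
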