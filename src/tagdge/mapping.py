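"""Annotating clean tags against the reference tag library.

Mapping allows at most one mismatch (to absorb polymorphisms between the
sampled animals and the reference databases) and cascades unassigned tags
to the mitochondrial and then the nuclear genome; whatever remains is
*unknown*.  Exact hits beat 1-mismatch hits, sense hits beat antisense
hits, and a tag matching several distinct genes at its best tier is
ambiguous and contributes nothing to gene-level counts.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable

from Bio.Seq import reverse_complement

from .reference import ANTISENSE, SENSE, TAG_LENGTH, ReferenceTag, ReferenceTagLibrary
from .tags import CleanTagLibrary

GENE_UNAMBIGUOUS = "gene_unambiguous"
GENE_AMBIGUOUS = "gene_ambiguous"
ANTISENSE_GENE = "antisense_gene"
MITOCHONDRION = "mitochondrion"
GENOME = "genome"
UNKNOWN = "unknown"

_BASES = "ACGT"


@dataclass(frozen=True)
class TagAnnotation:
    """The single category assigned to one unique clean tag."""

    tag_seq: str
    category: str
    count: int = 0
    gene_id: str | None = None
    strand: str | None = None
    mismatches: int = 0
    position_rank: int | None = None


@dataclass(frozen=True)
class MappingSummary:
    """Census of clean tags over annotation categories, as copy-weighted
    totals and unique-tag counts, with percentages of the clean totals.

    ``tags_mapped_to_gene`` covers every tag assigned to the reference
    library (unambiguous, ambiguous, and antisense hits);
    ``unambiguous_tags_mapped_to_gene`` is the sense-unambiguous subset
    that feeds gene expression counts.
    """

    total_clean: int
    unique_clean: int
    tags_mapped_to_gene: int
    unique_tags_mapped_to_gene: int
    unambiguous_tags_mapped_to_gene: int
    unique_unambiguous_tags_mapped_to_gene: int
    tags_mapped_to_mitochondrion: int
    unique_tags_mapped_to_mitochondrion: int
    tags_mapped_to_genome: int
    unique_tags_mapped_to_genome: int
    unknown_tags: int
    unique_unknown_tags: int

    def _pct(self, num: int, denom: int) -> float:
        return round(100.0 * num / denom, 2) if denom else 0.0

    @property
    def pct_tags_mapped_to_gene(self) -> float:
        return self._pct(self.tags_mapped_to_gene, self.total_clean)

    @property
    def pct_unique_tags_mapped_to_gene(self) -> float:
        return self._pct(self.unique_tags_mapped_to_gene, self.unique_clean)

    @property
    def pct_unambiguous_tags_mapped_to_gene(self) -> float:
        return self._pct(self.unambiguous_tags_mapped_to_gene, self.total_clean)

    @property
    def pct_unique_unambiguous_tags_mapped_to_gene(self) -> float:
        return self._pct(self.unique_unambiguous_tags_mapped_to_gene,
                         self.unique_clean)

    @property
    def pct_unknown_tags(self) -> float:
        return self._pct(self.unknown_tags, self.total_clean)

    @property
    def pct_unique_unknown_tags(self) -> float:
        return self._pct(self.unique_unknown_tags, self.unique_clean)


@dataclass(frozen=True)
class GeneCount:
    """Unambiguous sense clean-tag copies assigned to one gene."""

    gene_id: str
    count: int


def hamming1_neighbors(tag_seq: str) -> Iterable[str]:
    """All 63 sequences at Hamming distance exactly 1 from a 21-nt tag."""
    for i, base in enumerate(tag_seq):
        for sub in _BASES:
            if sub != base:
                yield tag_seq[:i] + sub + tag_seq[i + 1:]


def _classify_hits(tag_seq: str, hits: list[ReferenceTag],
                   count: int, mismatches: int) -> TagAnnotation:
    genes = {h.gene_id for h in hits}
    sense_hits = [h for h in hits if h.strand == SENSE]
    if len(genes) > 1:
        return TagAnnotation(tag_seq, GENE_AMBIGUOUS, count, mismatches=mismatches)
    best = sense_hits or hits  # sense beats antisense within the one gene
    category = GENE_UNAMBIGUOUS if sense_hits else ANTISENSE_GENE
    rank = min(h.position_rank for h in best)
    return TagAnnotation(tag_seq, category, count, gene_id=best[0].gene_id,
                         strand=best[0].strand, mismatches=mismatches,
                         position_rank=rank)


def map_tag(tag_seq: str, library: ReferenceTagLibrary,
            max_mismatch: int = 1, count: int = 0) -> TagAnnotation | None:
    """Assign one tag within the reference library, or None for no hit.

    Exact matches take precedence over 1-mismatch matches; within the best
    tier a single sense gene gives ``gene_unambiguous``, a single
    antisense-only gene gives ``antisense_gene``, and several distinct
    genes give ``gene_ambiguous``.
    """
    if len(tag_seq) != TAG_LENGTH:
        raise ValueError(f"tag must be {TAG_LENGTH} nt, got {len(tag_seq)}")
    hits = library.entries.get(tag_seq)
    if hits:
        return _classify_hits(tag_seq, hits, count, mismatches=0)
    if max_mismatch >= 1:
        mm_hits: list[ReferenceTag] = []
        for neighbor in hamming1_neighbors(tag_seq):
            mm_hits.extend(library.entries.get(neighbor, ()))
        if mm_hits:
            return _classify_hits(tag_seq, mm_hits, count, mismatches=1)
    return None


def _genome_kmer_set(sequence: str) -> set[str]:
    seq = sequence.upper()
    rc = reverse_complement(seq)
    kmers = set()
    for s in (seq, rc):
        for i in range(len(s) - TAG_LENGTH + 1):
            window = s[i:i + TAG_LENGTH]
            if "N" not in window:
                kmers.add(window)
    return kmers


def map_library(
    clean: CleanTagLibrary,
    library: ReferenceTagLibrary,
    mito: str | None = None,
    genome: str | None = None,
    max_mismatch: int = 1,
) -> tuple[list[TagAnnotation], MappingSummary, list[GeneCount]]:
    """Annotate every unique clean tag through the full cascade.

    Cascade order: reference library (<=1 mismatch) -> mitochondrial
    genome -> nuclear genome -> unknown.  Genome hits are exact substring
    matches on either strand.  Gene counts sum copy numbers of
    sense-unambiguous tags only; antisense evidence is reported separately
    via :func:`antisense_report`.
    """
    if library.n_total_tags == 0:
        raise ValueError("reference library is empty")
    mito_kmers = _genome_kmer_set(mito) if mito else set()
    genome_kmers = _genome_kmer_set(genome) if genome else set()

    annotations: list[TagAnnotation] = []
    for tag_seq in sorted(clean.counts):
        count = clean.counts[tag_seq]
        ann = map_tag(tag_seq, library, max_mismatch=max_mismatch, count=count)
        if ann is None:
            if tag_seq in mito_kmers:
                ann = TagAnnotation(tag_seq, MITOCHONDRION, count)
            elif tag_seq in genome_kmers:
                ann = TagAnnotation(tag_seq, GENOME, count)
            else:
                ann = TagAnnotation(tag_seq, UNKNOWN, count)
        annotations.append(ann)

    summary = summarize_annotations(annotations)
    gene_totals: dict[str, int] = defaultdict(int)
    for ann in annotations:
        if ann.category == GENE_UNAMBIGUOUS:
            gene_totals[ann.gene_id] += ann.count
    gene_counts = [GeneCount(g, c) for g, c in sorted(gene_totals.items())]
    return annotations, summary, gene_counts


def summarize_annotations(annotations: list[TagAnnotation]) -> MappingSummary:
    gene_cats = {GENE_UNAMBIGUOUS, GENE_AMBIGUOUS, ANTISENSE_GENE}

    def tally(pred):
        sel = [a for a in annotations if pred(a)]
        return sum(a.count for a in sel), len(sel)

    total, unique = tally(lambda a: True)
    gene_t, gene_u = tally(lambda a: a.category in gene_cats)
    unamb_t, unamb_u = tally(lambda a: a.category == GENE_UNAMBIGUOUS)
    mito_t, mito_u = tally(lambda a: a.category == MITOCHONDRION)
    geno_t, geno_u = tally(lambda a: a.category == GENOME)
    unk_t, unk_u = tally(lambda a: a.category == UNKNOWN)
    return MappingSummary(
        total_clean=total, unique_clean=unique,
        tags_mapped_to_gene=gene_t, unique_tags_mapped_to_gene=gene_u,
        unambiguous_tags_mapped_to_gene=unamb_t,
        unique_unambiguous_tags_mapped_to_gene=unamb_u,
        tags_mapped_to_mitochondrion=mito_t,
        unique_tags_mapped_to_mitochondrion=mito_u,
        tags_mapped_to_genome=geno_t, unique_tags_mapped_to_genome=geno_u,
        unknown_tags=unk_t, unique_unknown_tags=unk_u,
    )


def tag_position_profile(
    annotations: list[TagAnnotation],
) -> tuple[dict[int, int], float]:
    """Copy-weighted histogram of reference position ranks of mapped tags.

    Returns the histogram and the weight fraction at rank 1 (in the
    standard bead-capture protocol nearly all signal should sit at the
    3'-most site of each transcript).
    """
    hist: dict[int, int] = defaultdict(int)
    for ann in annotations:
        if ann.position_rank is not None:
            hist[ann.position_rank] += ann.count
    total = sum(hist.values())
    frac_rank1 = hist.get(1, 0) / total if total else 0.0
    return dict(hist), frac_rank1


def antisense_report(
    annotations: list[TagAnnotation],
) -> list[tuple[str, int, int]]:
    """Genes with antisense tag evidence: (gene, unique tags, copy total),
    sorted by copy total descending."""
    uniq: dict[str, int] = defaultdict(int)
    copies: dict[str, int] = defaultdict(int)
    for ann in annotations:
        if ann.category == ANTISENSE_GENE:
            uniq[ann.gene_id] += 1
            copies[ann.gene_id] += ann.count
    return sorted(((g, uniq[g], copies[g]) for g in uniq),
                  key=lambda row: (-row[2], row[0]))


# ---------------------------------------------------------------------------
# I/O

#: Row labels of the library-characteristics table, in print order.
SUMMARY_ROWS = (
    ("Tags Mapped to Gene", "tags_mapped_to_gene", "unique_tags_mapped_to_gene"),
    ("Unambiguous Tags Mapped to Gene", "unambiguous_tags_mapped_to_gene",
     "unique_unambiguous_tags_mapped_to_gene"),
    ("Tags Mapped to Mitochondrion", "tags_mapped_to_mitochondrion",
     "unique_tags_mapped_to_mitochondrion"),
    ("Tags Mapped to Genome", "tags_mapped_to_genome",
     "unique_tags_mapped_to_genome"),
    ("Unknown Tags", "unknown_tags", "unique_unknown_tags"),
)


def write_summary_tsv(summary: MappingSummary, path) -> None:
    with open(path, "w") as fh:
        fh.write("#category\ttotal_tags\tunique_tags\n")
        fh.write(f"Clean Tags\t{summary.total_clean}\t{summary.unique_clean}\n")
        for label, tot_attr, uniq_attr in SUMMARY_ROWS:
            fh.write(f"{label}\t{getattr(summary, tot_attr)}\t"
                     f"{getattr(summary, uniq_attr)}\n")


def write_annotations_tsv(annotations: list[TagAnnotation], path) -> None:
    with open(path, "w") as fh:
        fh.write("#tag_seq\tcategory\tcount\tgene_id\tstrand\tmismatches\t"
                 "position_rank\n")
        for a in annotations:
            fh.write(f"{a.tag_seq}\t{a.category}\t{a.count}\t"
                     f"{a.gene_id or '.'}\t{a.strand or '.'}\t{a.mismatches}\t"
                     f"{a.position_rank if a.position_rank is not None else '.'}\n")


def write_gene_counts_tsv(gene_counts: list[GeneCount], path) -> None:
    with open(path, "w") as fh:
        fh.write("#gene_id\tcount\n")
        for gc in gene_counts:
            fh.write(f"{gc.gene_id}\t{gc.count}\n")


def read_gene_counts_tsv(path) -> dict[str, int]:
    counts: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            gene, count = line.rstrip("\n").split("\t")[:2]
            counts[gene] = int(count)
    return counts
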