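"""Virtual reference tag libraries from transcript databases.

A DGE/SAGE tag is the NlaIII recognition site ``CATG`` plus the 17 nt
immediately downstream, as released by MmeI (21 nt total).  The reference
tag library enumerates every such tag that a transcript database can
produce, on both strands, so that observed sequencer tags can be assigned
to genes.  Transcript databases of unequal reliability are merged under a
preset priority before digestion, keeping one record per gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import reverse_complement

logger = logging.getLogger(__name__)

TAG_LENGTH = 21
ANCHOR = "CATG"
_VALID_BASES = frozenset("ACGTN")

SENSE = "sense"
ANTISENSE = "antisense"


@dataclass(frozen=True)
class TranscriptRecord:
    """One transcript sequence with its database provenance.

    ``priority`` ranks the source database (1 = most trusted); it decides
    which record survives when several databases annotate the same gene.
    """

    gene_id: str
    source: str
    priority: int
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.gene_id}: empty sequence")
        if self.priority < 1:
            raise ValueError(f"{self.gene_id}: priority must be >= 1")
        bad = set(self.sequence.upper()) - _VALID_BASES
        if bad:
            raise ValueError(
                f"{self.gene_id}: non-nucleotide characters {sorted(bad)}"
            )


@dataclass(frozen=True)
class ReferenceTag:
    """A single virtual tag: CATG + 17 nt on one strand of a transcript.

    ``position_rank`` counts CATG sites from the 3' end of the strand the
    tag lies on; rank 1 is the 3'-most site with a full 17 nt downstream,
    i.e. the tag MmeI digestion actually leaves on the bead in the wet
    protocol.  ``offset`` is the 0-based position of the CATG start in the
    strand-oriented transcript sequence.
    """

    tag_seq: str
    gene_id: str
    strand: str
    position_rank: int
    offset: int
    source: str = ""

    def __post_init__(self) -> None:
        if len(self.tag_seq) != TAG_LENGTH or not self.tag_seq.startswith(ANCHOR):
            raise ValueError(f"malformed tag {self.tag_seq!r}")
        if self.position_rank < 1:
            raise ValueError("position_rank must be >= 1")


@dataclass
class ReferenceTagLibrary:
    """All virtual tags of a merged transcript database, keyed by sequence.

    A tag sequence associated with exactly one gene (regardless of how many
    positions within that gene produce it) is *unambiguous*; tags shared by
    several genes cannot identify a gene and are flagged ambiguous.
    """

    entries: dict[str, list[ReferenceTag]] = field(default_factory=dict)

    @property
    def n_total_tags(self) -> int:
        return len(self.entries)

    @property
    def n_unambiguous_tags(self) -> int:
        return sum(1 for hits in self.entries.values() if self.is_unambiguous_hits(hits))

    @staticmethod
    def is_unambiguous_hits(hits: list[ReferenceTag]) -> bool:
        return len({h.gene_id for h in hits}) == 1

    def is_unambiguous(self, tag_seq: str) -> bool:
        return self.is_unambiguous_hits(self.entries[tag_seq])

    def genes(self) -> set[str]:
        return {h.gene_id for hits in self.entries.values() for h in hits}


def _find_anchor_sites(seq: str) -> list[int]:
    """0-based offsets of every CATG occurrence (overlaps included)."""
    sites = []
    start = 0
    while True:
        i = seq.find(ANCHOR, start)
        if i < 0:
            return sites
        sites.append(i)
        start = i + 1


def digest_transcript(record: TranscriptRecord) -> list[ReferenceTag]:
    """In-silico NlaIII/MmeI digestion of one transcript, both strands.

    Every CATG with at least 17 nt downstream yields one 21-nt tag per
    strand it occurs on; sites too close to the 3' end yield nothing (MmeI
    cannot release a short tag).  Position ranks are assigned over the
    full-length-yielding sites from the 3' end, then tags containing N are
    discarded (their rank is consumed, keeping ranks of clean tags stable).
    """
    seq = record.sequence.upper()
    tags: list[ReferenceTag] = []
    for strand, oriented in ((SENSE, seq), (ANTISENSE, reverse_complement(seq))):
        full_sites = [i for i in _find_anchor_sites(oriented)
                      if i + TAG_LENGTH <= len(oriented)]
        # rank 1 = 3'-most full-length site on this strand
        for rank, off in enumerate(reversed(full_sites), start=1):
            tag = oriented[off:off + TAG_LENGTH]
            if "N" in tag:
                continue
            tags.append(ReferenceTag(tag, record.gene_id, strand, rank, off,
                                     record.source))
    return tags


def merge_databases(
    records: Iterable[TranscriptRecord],
    xref: Mapping[str, str] | None = None,
) -> list[TranscriptRecord]:
    """Collapse multi-database records to one transcript per gene.

    ``xref`` optionally maps source-specific identifiers to canonical gene
    ids; without it, identifiers are compared verbatim.  The record from
    the highest-priority (lowest number) source wins; within a priority
    level the first occurrence is kept and a warning is logged.
    """
    best: dict[str, TranscriptRecord] = {}
    for rec in records:
        key = xref.get(rec.gene_id, rec.gene_id) if xref else rec.gene_id
        prev = best.get(key)
        if prev is None:
            best[key] = rec
        elif rec.priority < prev.priority:
            best[key] = rec
        elif rec.priority == prev.priority:
            logger.warning(
                "gene %s appears twice at priority %d (%s, %s); keeping first",
                key, rec.priority, prev.source, rec.source,
            )
    return list(best.values())


def build_reference_library(records: Iterable[TranscriptRecord]) -> ReferenceTagLibrary:
    """Digest merged records and group the tags by sequence."""
    entries: dict[str, list[ReferenceTag]] = {}
    for rec in records:
        for tag in digest_transcript(rec):
            entries.setdefault(tag.tag_seq, []).append(tag)
    return ReferenceTagLibrary(entries)


def read_fasta_records(path, source: str, priority: int) -> list[TranscriptRecord]:
    """Load a transcript FASTA as records of one database source."""
    return [
        TranscriptRecord(r.id, source, priority, str(r.seq).upper())
        for r in SeqIO.parse(str(path), "fasta")
    ]


def write_library_tsv(library: ReferenceTagLibrary, path) -> None:
    """Write the library as TSV: one row per (tag, gene, strand, position)."""
    with open(path, "w") as fh:
        fh.write("#tag_seq\tgene_id\tstrand\tposition_rank\toffset\tambiguous\n")
        for tag_seq in sorted(library.entries):
            hits = library.entries[tag_seq]
            amb = int(not library.is_unambiguous_hits(hits))
            for h in hits:
                fh.write(f"{tag_seq}\t{h.gene_id}\t{h.strand}\t"
                         f"{h.position_rank}\t{h.offset}\t{amb}\n")


def read_library_tsv(path) -> ReferenceTagLibrary:
    entries: dict[str, list[ReferenceTag]] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            tag_seq, gene_id, strand, rank, offset = line.rstrip("\n").split("\t")[:5]
            entries.setdefault(tag_seq, []).append(
                ReferenceTag(tag_seq, gene_id, strand, int(rank), int(offset))
            )
    return ReferenceTagLibrary(entries)
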