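"""Raw-tag filtering, copy-number bookkeeping, and saturation analysis.

Raw sequencer tags pass through a fixed filter cascade — adaptor reads,
low-quality reads, then single-copy tags — to give the *clean tag
library* on which all downstream quantification runs.  The ledger records
how many reads each step removed, and always conserves the raw total.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
from Bio import SeqIO

DEFAULT_MIN_QUALITY = 10
#: Table-style copy-number bins; the first bin is inclusive (>=2), the rest strict.
DEFAULT_COPY_THRESHOLDS = (2, 5, 10, 20, 50, 100)


@dataclass(frozen=True)
class TagRead:
    seq: str
    qualities: tuple[int, ...] | None = None


@dataclass
class RawTagSet:
    """The unfiltered read multiset of one sequencing library."""

    reads: list[TagRead]

    @property
    def n_raw(self) -> int:
        return len(self.reads)


@dataclass(frozen=True)
class FilterLedger:
    """Read-level accounting of the filter cascade.

    ``n_singleton`` counts reads whose tag had copy number 1 after the
    quality filter (each copy-1 tag removes exactly one read), so
    ``n_raw == n_adaptor + n_low_quality + n_singleton + n_clean`` holds
    on every input.
    """

    n_raw: int
    n_low_quality: int
    n_adaptor: int
    n_singleton: int
    n_clean: int

    def __post_init__(self) -> None:
        parts = (self.n_low_quality, self.n_adaptor, self.n_singleton, self.n_clean)
        if any(v < 0 for v in (self.n_raw,) + parts):
            raise ValueError("ledger counts must be non-negative")
        if self.n_raw != sum(parts):
            raise ValueError(
                f"ledger does not conserve reads: {self.n_raw} != {sum(parts)}"
            )

    @classmethod
    def from_removals(cls, n_raw: int, n_low_quality: int, n_adaptor: int,
                      n_singleton: int) -> "FilterLedger":
        """Derive the clean total from the raw total and per-step removals."""
        return cls(n_raw, n_low_quality, n_adaptor, n_singleton,
                   n_raw - n_low_quality - n_adaptor - n_singleton)


@dataclass
class CleanTagLibrary:
    """Unique clean tags with copy numbers (all >= 2)."""

    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = [t for t, c in self.counts.items() if c < 2]
        if bad:
            raise ValueError(f"clean library contains copy numbers < 2: {bad[:3]}")

    @property
    def total_clean(self) -> int:
        return sum(self.counts.values())

    @property
    def n_unique(self) -> int:
        return len(self.counts)


@dataclass
class SaturationCurve:
    """Rarefaction of the tag stream: distinct tags/genes vs tags sequenced."""

    points: list[tuple[int, int, int, float]]  # (n_sampled, n_genes, n_tags, pct_tags_of_final)


def _is_low_quality(read: TagRead, min_quality: int) -> bool:
    if "N" in read.seq:
        return True
    if read.qualities is not None and min(read.qualities) < min_quality:
        return True
    return False


def filter_raw_tags(
    raw: RawTagSet,
    adaptor_seqs: Sequence[str] = (),
    min_quality: int = DEFAULT_MIN_QUALITY,
) -> tuple[CleanTagLibrary, FilterLedger]:
    """Run the filter cascade: adaptor -> low quality -> singleton.

    A read is an adaptor read if it contains any of ``adaptor_seqs`` as a
    substring; low-quality if it contains N or any base below
    ``min_quality`` (the N rule alone applies when no qualities are
    given).  Singleton status is evaluated on the multiset that survives
    the first two filters, so the definition of "copy number 1" is fixed.
    """
    n_adaptor = 0
    n_low_quality = 0
    survivors: list[str] = []
    for read in raw.reads:
        if adaptor_seqs and any(a in read.seq for a in adaptor_seqs):
            n_adaptor += 1
        elif _is_low_quality(read, min_quality):
            n_low_quality += 1
        else:
            survivors.append(read.seq)
    counts = Counter(survivors)
    n_singleton = sum(1 for c in counts.values() if c == 1)
    clean = CleanTagLibrary({t: c for t, c in counts.items() if c >= 2})
    ledger = FilterLedger(raw.n_raw, n_low_quality, n_adaptor, n_singleton,
                          clean.total_clean)
    return clean, ledger


def copy_number_distribution(
    lib: CleanTagLibrary,
    thresholds: Sequence[int] = DEFAULT_COPY_THRESHOLDS,
) -> list[tuple[int, int, int]]:
    """Per copy-number bin, total copies and distinct tags above it.

    The first threshold is inclusive (copy number >= t, normally >= 2 so
    it restates the clean totals); subsequent thresholds are strict (> t),
    mirroring the conventional library-characteristics table.
    """
    if list(thresholds) != sorted(thresholds):
        raise ValueError("thresholds must be ascending")
    rows = []
    for i, t in enumerate(thresholds):
        if i == 0:
            sel = [c for c in lib.counts.values() if c >= t]
        else:
            sel = [c for c in lib.counts.values() if c > t]
        rows.append((t, sum(sel), len(sel)))
    return rows


def saturation_analysis(
    read_stream: Sequence[str],
    step: int,
    mapping: Callable[[str], str | None] | None = None,
    seed: int = 0,
) -> SaturationCurve:
    """Rarefaction curve of distinct unique tags (and genes) vs depth.

    The stream is shuffled once with ``seed`` (sampling without
    replacement, emulating cumulative sequencing), then scanned in
    prefixes of ``step`` reads.  ``mapping`` resolves a tag to a gene id
    (or None for unmapped); when given, distinct genes are tracked too.
    The last point always covers the full stream.
    """
    if step < 1:
        raise ValueError("step must be >= 1")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(read_stream))
    shuffled = [read_stream[i] for i in order]

    checkpoints = list(range(step, len(shuffled), step)) + [len(shuffled)]
    seen_tags: set[str] = set()
    seen_genes: set[str] = set()
    raw_points = []
    pos = 0
    for cp in checkpoints:
        for seq in shuffled[pos:cp]:
            seen_tags.add(seq)
            if mapping is not None:
                gene = mapping(seq)
                if gene is not None:
                    seen_genes.add(gene)
        pos = cp
        raw_points.append((cp, len(seen_genes), len(seen_tags)))
    final_tags = raw_points[-1][2] if raw_points else 0
    points = [
        (n, g, t, 100.0 * t / final_tags if final_tags else 0.0)
        for n, g, t in raw_points
    ]
    return SaturationCurve(points)


# ---------------------------------------------------------------------------
# I/O

def read_fastq_tags(path) -> RawTagSet:
    """Load tags sequenced as FASTQ reads, keeping per-base qualities."""
    reads = [
        TagRead(str(r.seq).upper(),
                tuple(r.letter_annotations["phred_quality"]))
        for r in SeqIO.parse(str(path), "fastq")
    ]
    return RawTagSet(reads)


def read_tag_counts_tsv(path) -> RawTagSet:
    """Load a two-column (tag, count) table, expanding counts to reads."""
    reads: list[TagRead] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            seq, count = line.split("\t")[:2]
            reads.extend([TagRead(seq)] * int(count))
    return RawTagSet(reads)


def write_clean_library_tsv(lib: CleanTagLibrary, path) -> None:
    with open(path, "w") as fh:
        fh.write("#tag_seq\tcount\n")
        for tag in sorted(lib.counts, key=lambda t: (-lib.counts[t], t)):
            fh.write(f"{tag}\t{lib.counts[tag]}\n")


def read_clean_library_tsv(path) -> CleanTagLibrary:
    counts: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            tag, count = line.rstrip("\n").split("\t")[:2]
            counts[tag] = int(count)
    return CleanTagLibrary(counts)
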