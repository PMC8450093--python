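"""Read-processing front end: adapter trimming, length filter, exact-match
strand-aware mapping, and category assignment.

Mapping is exact (0 mismatches): a read hits a target on '+' if its sequence
is a substring of the target, and on '-' if its reverse complement is.  Reads
containing N never match.  All hits are returned sorted by
(target name, start, strand), and classification resolves multi-target reads
by a fixed class priority: risiRNA (antisense to the rDNA unit or 5S) >
sense rRNA > sense mRNA > antisense mRNA.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

from .reference import DecoySet, RdnaUnit
from .seqtools import DEFAULT_ADAPTER, READ_ALPHABET, revcomp

CATEGORIES = ("risiRNA", "sense_rRNA", "sense_mRNA", "antisense_mRNA", "unmapped")

DEFAULT_MIN_LEN = 18
DEFAULT_MAX_LEN = 30
DEFAULT_MIN_OVERLAP = 8

_SEED_K = 18  # seed length for the k-mer index; below this, fall back to scanning


@dataclass(frozen=True)
class ReadRecord:
    """A sequenced read, 5'->3'."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        bad = set(self.sequence) - READ_ALPHABET
        if bad:
            raise ValueError(f"read {self.id}: invalid characters {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True, order=True)
class AlignmentRecord:
    """Exact placement of a read on a target's plus-strand coordinates."""

    target: str
    start: int
    end: int
    strand: str  # '+' read == target substring; '-' read == its revcomp
    read_id: str = field(compare=False, default="")

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid interval [{self.start}, {self.end})")


@dataclass(frozen=True)
class ClassifiedRead:
    read: ReadRecord
    category: str
    alignment: AlignmentRecord | None


@dataclass
class CategoryCounts:
    """Per-category read tallies; total_mapped excludes unmapped reads."""

    risiRNA: int = 0
    sense_rRNA: int = 0
    sense_mRNA: int = 0
    antisense_mRNA: int = 0
    unmapped: int = 0

    @property
    def total_mapped(self) -> int:
        return self.risiRNA + self.sense_rRNA + self.sense_mRNA + self.antisense_mRNA

    @property
    def total(self) -> int:
        return self.total_mapped + self.unmapped

    def as_dict(self) -> dict[str, int]:
        return {c: getattr(self, c) for c in CATEGORIES}


# ---------------------------------------------------------------------------
# Trimming and filtering


def trim_adapter(
    read: ReadRecord,
    adapter: str = DEFAULT_ADAPTER,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> ReadRecord:
    """Truncate at the leftmost exact match of the adapter's first
    ``min_overlap`` nt; the read is returned unchanged when no match exists."""
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    if not adapter:
        return read
    key = adapter[:min_overlap]
    idx = read.sequence.find(key)
    if idx < 0:
        return read
    return ReadRecord(id=read.id, sequence=read.sequence[:idx])


def length_filter(
    reads: Iterable[ReadRecord],
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
) -> list[ReadRecord]:
    """Keep reads with min_len <= length <= max_len (both ends inclusive)."""
    if min_len > max_len:
        raise ValueError(f"min_len {min_len} > max_len {max_len}")
    return [r for r in reads if min_len <= r.length <= max_len]


# ---------------------------------------------------------------------------
# Mapping


def _find_all(haystack: str, needle: str) -> Iterator[int]:
    start = 0
    while True:
        i = haystack.find(needle, start)
        if i < 0:
            return
        yield i
        start = i + 1


class ReferenceIndex:
    """Seed-and-verify exact matcher over the unit plus all decoys.

    An 18-mer index of every target's plus strand seeds candidate placements;
    each candidate is verified by full string comparison.  Reads shorter than
    the seed fall back to a direct substring scan.
    """

    def __init__(self, unit: RdnaUnit, decoys: DecoySet):
        self.unit = unit
        self.decoys = decoys
        self.targets: dict[str, str] = {unit.name: unit.sequence, **decoys.transcripts}
        self.rrna_targets = frozenset({unit.name}) | decoys.rrna_names
        self._index: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for name, seq in self.targets.items():
            for i in range(len(seq) - _SEED_K + 1):
                self._index[seq[i : i + _SEED_K]].append((name, i))

    def _hits_for_strand(self, seq: str, strand: str, read_id: str) -> list[AlignmentRecord]:
        hits = []
        n = len(seq)
        if n >= _SEED_K:
            for name, pos in self._index.get(seq[:_SEED_K], ()):
                target = self.targets[name]
                if target[pos : pos + n] == seq:
                    hits.append(AlignmentRecord(name, pos, pos + n, strand, read_id))
        else:
            for name, target in self.targets.items():
                for pos in _find_all(target, seq):
                    hits.append(AlignmentRecord(name, pos, pos + n, strand, read_id))
        return hits

    def map_read(self, read: ReadRecord) -> list[AlignmentRecord]:
        """All exact placements of the read on both strands of every target."""
        if not read.sequence or "N" in read.sequence:
            return []
        hits = self._hits_for_strand(read.sequence, "+", read.id)
        hits += self._hits_for_strand(revcomp(read.sequence), "-", read.id)
        hits.sort(key=lambda h: (h.target, h.start, h.strand))
        return hits


def map_read(
    read: ReadRecord,
    unit: RdnaUnit,
    decoys: DecoySet,
    index: ReferenceIndex | None = None,
) -> list[AlignmentRecord]:
    """Convenience wrapper; pass a prebuilt :class:`ReferenceIndex` in loops."""
    if index is None:
        index = ReferenceIndex(unit, decoys)
    return index.map_read(read)


# ---------------------------------------------------------------------------
# Classification


def classify(
    read: ReadRecord,
    hits: Sequence[AlignmentRecord],
    rrna_targets: frozenset[str],
) -> ClassifiedRead:
    """Assign the read to exactly one category by class priority.

    Priority: antisense on a rRNA target (risiRNA) > sense on a rRNA target >
    sense on an mRNA decoy > antisense on an mRNA decoy.  The chosen alignment
    is the first hit of the winning class in (target, start, strand) order.
    """
    if not hits:
        return ClassifiedRead(read, "unmapped", None)

    def first(pred):
        for h in hits:
            if pred(h):
                return h
        return None

    chosen = first(lambda h: h.target in rrna_targets and h.strand == "-")
    if chosen is not None:
        return ClassifiedRead(read, "risiRNA", chosen)
    chosen = first(lambda h: h.target in rrna_targets and h.strand == "+")
    if chosen is not None:
        return ClassifiedRead(read, "sense_rRNA", chosen)
    chosen = first(lambda h: h.strand == "+")
    if chosen is not None:
        return ClassifiedRead(read, "sense_mRNA", chosen)
    return ClassifiedRead(read, "antisense_mRNA", hits[0])


def count_categories(classified: Iterable[ClassifiedRead]) -> CategoryCounts:
    counts = Counter(c.category for c in classified)
    unknown = set(counts) - set(CATEGORIES)
    if unknown:
        raise ValueError(f"unknown categories {sorted(unknown)}")
    return CategoryCounts(**{c: counts.get(c, 0) for c in CATEGORIES})


def count_by_target(classified: Iterable[ClassifiedRead]) -> dict[str, int]:
    """Mapped-read tallies per target name."""
    counts: Counter[str] = Counter()
    for c in classified:
        if c.alignment is not None:
            counts[c.alignment.target] += 1
    return dict(counts)


def run_pipeline(
    reads: Iterable[ReadRecord],
    index: ReferenceIndex,
    adapter: str = DEFAULT_ADAPTER,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
) -> list[ClassifiedRead]:
    """trim -> length-filter -> map -> classify, in order."""
    trimmed = (trim_adapter(r, adapter, min_overlap) for r in reads)
    kept = length_filter(trimmed, min_len, max_len)
    return [classify(r, index.map_read(r), index.rrna_targets) for r in kept]
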