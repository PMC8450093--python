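"""rDNA transcription-unit coordinate system and decoy transcriptome.

The ~50 genomic rDNA repeats are collapsed to a single representative unit
whose plus strand is the sense pre-rRNA.  Coordinates are 0-based, half-open
(BED convention).  The unit is tiled, in order and without gaps, by the seven
canonical regions 5'ETS / 18S / ITS1 / 5.8S / ITS2 / 26S / 3'ETS.

Decoy transcripts (a 5S rRNA and several protein-coding mRNAs) are generated
so that no decoy shares any >=18 nt substring, on either strand, with the
unit — which makes exact-match read classification unambiguous.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .seqtools import DEFAULT_ADAPTER, kmers, random_seq_avoiding, revcomp

REGION_NAMES = ("5ETS", "18S", "ITS1", "5.8S", "ITS2", "26S", "3ETS")

#: Schematic stand-in lengths echoing the relative sizes of the C. elegans
#: regions; user-overridable everywhere they are consumed.
DEFAULT_REGION_LENGTHS: dict[str, int] = {
    "5ETS": 700,
    "18S": 1750,
    "ITS1": 500,
    "5.8S": 160,
    "ITS2": 350,
    "26S": 3500,
    "3ETS": 150,
}

#: Minimum substring length whose cross-target uniqueness is enforced.
UNIQUENESS_K = 18


class ReferenceError(ValueError):
    """Raised on invalid reference sequences or annotations."""


@dataclass(frozen=True)
class RegionInterval:
    """Named half-open interval [start, end) on the rDNA unit."""

    name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ReferenceError(f"invalid interval {self.name}: [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class RdnaUnit:
    """One representative rDNA repeat unit with its ordered region tiling."""

    name: str
    sequence: str
    regions: tuple[RegionInterval, ...]
    _starts: tuple[int, ...] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ReferenceError("empty reference sequence")
        bad = set(self.sequence) - set("ACGT")
        if bad:
            raise ReferenceError(f"sequence contains non-ACGT characters: {sorted(bad)}")
        if not self.regions:
            raise ReferenceError("no region annotations")
        if self.regions[0].start != 0:
            raise ReferenceError("gap at 5' end: first region does not start at 0")
        prev = self.regions[0]
        for cur in self.regions[1:]:
            if cur.start < prev.end:
                raise ReferenceError(f"overlapping regions: {prev.name} and {cur.name}")
            if cur.start > prev.end:
                raise ReferenceError(f"gap between regions {prev.name} and {cur.name}")
            prev = cur
        if prev.end > len(self.sequence):
            raise ReferenceError(f"region {prev.name} exceeds sequence length {len(self.sequence)}")
        if prev.end < len(self.sequence):
            raise ReferenceError("gap at 3' end: regions do not cover the full sequence")
        object.__setattr__(self, "_starts", tuple(r.start for r in self.regions))

    def __len__(self) -> int:
        return len(self.sequence)

    def locate(self, position: int) -> str:
        """Name of the region whose [start, end) contains ``position``."""
        if not 0 <= position < len(self.sequence):
            raise ReferenceError(f"position {position} out of range [0, {len(self.sequence)})")
        i = bisect.bisect_right(self._starts, position) - 1
        return self.regions[i].name

    def region(self, name: str) -> RegionInterval:
        for r in self.regions:
            if r.name == name:
                return r
        raise KeyError(name)

    @property
    def region_names(self) -> tuple[str, ...]:
        return tuple(r.name for r in self.regions)


@dataclass(frozen=True)
class DecoySet:
    """Sense decoy transcripts: 5S rRNA plus protein-coding mRNAs.

    ``rrna_names`` marks which transcripts count as rRNA for classification
    (5S only; 5.8S/18S/26S live inside the unit itself).
    """

    transcripts: dict[str, str]
    rrna_names: frozenset[str] = frozenset({"5S"})

    def __post_init__(self) -> None:
        for name, seq in self.transcripts.items():
            bad = set(seq) - set("ACGT")
            if bad:
                raise ReferenceError(f"decoy {name} contains non-ACGT characters")
        unknown = self.rrna_names - self.transcripts.keys()
        if unknown:
            raise ReferenceError(f"rRNA decoy names not present: {sorted(unknown)}")

    @property
    def mrna_names(self) -> tuple[str, ...]:
        return tuple(n for n in self.transcripts if n not in self.rrna_names)


def locate(unit: RdnaUnit, position: int) -> str:
    """Module-level alias for :meth:`RdnaUnit.locate`."""
    return unit.locate(position)


# ---------------------------------------------------------------------------
# I/O


def load_reference(fasta_path: str | Path, bed_path: str | Path) -> RdnaUnit:
    """Load the unit sequence (single-record FASTA) and its BED4 tiling."""
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise ReferenceError(f"empty FASTA: {fasta_path}")
    if len(records) != 1:
        raise ReferenceError(f"expected exactly one record in {fasta_path}, found {len(records)}")
    rec = records[0]
    sequence = str(rec.seq).upper()

    regions: list[RegionInterval] = []
    with open(bed_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ReferenceError(f"{bed_path}:{lineno}: need BED4 (chrom start end name)")
            chrom, start, end, name = fields[:4]
            if chrom != rec.id:
                raise ReferenceError(
                    f"{bed_path}:{lineno}: chrom {chrom!r} does not match FASTA record {rec.id!r}"
                )
            regions.append(RegionInterval(name=name, start=int(start), end=int(end)))
    if not regions:
        raise ReferenceError(f"no BED records in {bed_path}")
    regions.sort(key=lambda r: r.start)
    return RdnaUnit(name=rec.id, sequence=sequence, regions=tuple(regions))


def write_reference(unit: RdnaUnit, fasta_path: str | Path, bed_path: str | Path) -> None:
    """Write the unit as FASTA + BED4; lossless round trip with load_reference."""
    rec = SeqRecord(Seq(unit.sequence), id=unit.name, description="")
    SeqIO.write([rec], str(fasta_path), "fasta")
    with open(bed_path, "w") as fh:
        for r in unit.regions:
            fh.write(f"{unit.name}\t{r.start}\t{r.end}\t{r.name}\n")


def write_decoys(decoys: DecoySet, fasta_path: str | Path) -> None:
    recs = [SeqRecord(Seq(s), id=n, description="") for n, s in decoys.transcripts.items()]
    SeqIO.write(recs, str(fasta_path), "fasta")


def load_decoys(fasta_path: str | Path, rrna_names=("5S",)) -> DecoySet:
    transcripts = {r.id: str(r.seq).upper() for r in SeqIO.parse(str(fasta_path), "fasta")}
    if not transcripts:
        raise ReferenceError(f"empty decoy FASTA: {fasta_path}")
    present_rrna = frozenset(n for n in rrna_names if n in transcripts)
    return DecoySet(transcripts=transcripts, rrna_names=present_rrna)


# ---------------------------------------------------------------------------
# Default reference builder


def build_default_reference(
    seed: int,
    region_lengths: dict[str, int] | None = None,
    n_mrna: int = 6,
    mrna_length_range: tuple[int, int] = (500, 2000),
    unit_name: str = "rDNA_unit",
) -> tuple[RdnaUnit, DecoySet]:
    """Deterministic pseudo-random reference: one rDNA unit plus decoys.

    The unit and every decoy avoid the default 3' adapter's 8 nt prefix (both
    strands) so adapter trimming never cuts inside a genuine insert, and the
    decoys share no >=18 nt substring with the unit on either strand, so
    exact-match classification on simulated reads is unambiguous.
    """
    if region_lengths is None:
        region_lengths = dict(DEFAULT_REGION_LENGTHS)
    missing = [n for n in REGION_NAMES if n not in region_lengths]
    if missing:
        raise ReferenceError(f"missing region lengths for {missing}")

    rng = np.random.default_rng(seed)
    adapter_key = DEFAULT_ADAPTER[:8]
    forbidden_adapter = frozenset({adapter_key})

    # Every UNIQUENESS_K-mer across all sequences and both strands is kept
    # globally unique, so every read of >= UNIQUENESS_K nt has exactly one
    # exact placement and strand assignment is never ambiguous.
    seen_kmers: set[str] = set()

    def admit(seq: str) -> bool:
        fwd = set(kmers(seq, UNIQUENESS_K))
        rev = set(kmers(revcomp(seq), UNIQUENESS_K))
        n_pos = 2 * (len(seq) - UNIQUENESS_K + 1)
        if len(fwd) + len(rev) != n_pos or fwd & rev:
            return False  # internal duplicate or self reverse-palindrome
        if (fwd | rev) & seen_kmers:
            return False
        seen_kmers.update(fwd, rev)
        return True

    def make_sequence(length: int) -> str:
        while True:
            seq = random_seq_avoiding(rng, length, forbidden_adapter, k=len(adapter_key))
            if admit(seq):
                return seq

    total = sum(region_lengths[n] for n in REGION_NAMES)
    unit_seq = make_sequence(total)

    regions = []
    pos = 0
    for name in REGION_NAMES:
        regions.append(RegionInterval(name=name, start=pos, end=pos + region_lengths[name]))
        pos += region_lengths[name]
    unit = RdnaUnit(name=unit_name, sequence=unit_seq, regions=tuple(regions))

    transcripts: dict[str, str] = {"5S": make_sequence(120)}
    lo, hi = mrna_length_range
    for i in range(1, n_mrna + 1):
        length = int(rng.integers(lo, hi + 1))
        transcripts[f"mRNA_{i}"] = make_sequence(length)

    decoys = DecoySet(transcripts=transcripts, rrna_names=frozenset({"5S"}))
    return unit, decoys
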