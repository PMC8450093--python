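"""risiRNA abundance, region, size, 5'-nucleotide and coverage summaries.

The library-size denominator is the bespoke "normalization number": total
mapped reads minus sense rRNA reads minus sense mRNA reads — i.e. exactly the
antisense (risiRNA + antisense mRNA) portion of the library — which excludes
degradation fragments of sense transcripts from the scaling basis.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .classify import AlignmentRecord, CategoryCounts, ClassifiedRead
from .reference import RdnaUnit


class QuantError(ValueError):
    pass


def normalization_factor(counts: CategoryCounts) -> int:
    """total mapped − sense rRNA − sense mRNA (== risiRNA + antisense mRNA)."""
    factor = counts.total_mapped - counts.sense_rRNA - counts.sense_mRNA
    if factor <= 0:
        raise QuantError("empty normalization basis: no antisense reads in library")
    return factor


def risirna_rpm(counts: CategoryCounts) -> float:
    """risiRNA reads per million of the normalization factor."""
    return 1e6 * counts.risiRNA / normalization_factor(counts)


def midpoint(aln: AlignmentRecord) -> int:
    """Alignment midpoint, ties broken toward the lower coordinate."""
    return (aln.start + aln.end - 1) // 2


def region_proportions(
    alignments: Sequence[AlignmentRecord], unit: RdnaUnit
) -> dict[str, float]:
    """Fraction of risiRNA reads whose alignment midpoint falls in each region.

    All-zero (and flagged undefined by callers) when there are no reads.
    """
    props = {name: 0.0 for name in unit.region_names}
    if not alignments:
        return props
    counts: Counter[str] = Counter()
    for aln in alignments:
        if aln.strand != "-":
            raise QuantError(f"read {aln.read_id}: region proportions expect antisense alignments")
        counts[unit.locate(midpoint(aln))] += 1
    total = len(alignments)
    for name, n in counts.items():
        props[name] = n / total
    return props


def length_histogram(
    lengths: Iterable[int],
    min_len: int = 18,
    max_len: int = 30,
) -> dict[int, int]:
    """Read-length counts over the clean-read range; total == read count."""
    hist = {length: 0 for length in range(min_len, max_len + 1)}
    for n in lengths:
        if n not in hist:
            raise QuantError(f"read length {n} outside histogram range [{min_len}, {max_len}]")
        hist[n] += 1
    return hist


def first_nt_preference(sequences: Iterable[str]) -> dict[str, float]:
    """Fraction of reads starting with each of A/C/G/T, as sequenced.

    For an antisense read the first base equals the complement of the unit
    plus-strand base at (alignment end − 1).  Reads starting with N are
    excluded from the denominator.
    """
    counts = {nt: 0 for nt in "ACGT"}
    n_used = 0
    for seq in sequences:
        if not seq:
            continue
        first = seq[0]
        if first == "N":
            continue
        counts[first] += 1
        n_used += 1
    if n_used == 0:
        return {nt: 0.0 for nt in "ACGT"}
    return {nt: c / n_used for nt, c in counts.items()}


def coverage_track(alignments: Sequence[AlignmentRecord], unit: RdnaUnit) -> np.ndarray:
    """Per-base antisense read depth over the unit; sums to total read nt."""
    cov = np.zeros(len(unit), dtype=np.int64)
    for aln in alignments:
        if aln.end > len(unit):
            raise QuantError(f"alignment [{aln.start}, {aln.end}) exceeds unit length {len(unit)}")
        cov[aln.start : aln.end] += 1
    return cov


def coverage_to_bedgraph(coverage: np.ndarray, name: str) -> list[tuple[str, int, int, int]]:
    """Merge equal-depth runs into bedGraph intervals (zero runs included)."""
    out: list[tuple[str, int, int, int]] = []
    if len(coverage) == 0:
        return out
    run_start = 0
    cur = int(coverage[0])
    for i in range(1, len(coverage)):
        v = int(coverage[i])
        if v != cur:
            out.append((name, run_start, i, cur))
            run_start, cur = i, v
    out.append((name, run_start, len(coverage), cur))
    return out


def write_bedgraph(lines: list[tuple[str, int, int, int]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, value in lines:
            fh.write(f"{chrom}\t{start}\t{end}\t{value}\n")


@dataclass
class RisiRNAProfile:
    """Bundle of all per-library risiRNA summaries."""

    norm_factor: int
    risirna_count: int
    risirna_rpm: float
    region_proportions: dict[str, float]
    length_hist: dict[int, int]
    first_nt: dict[str, float]
    coverage: np.ndarray = field(repr=False)
    defined: bool = True  # False when the library has zero risiRNA reads

    def to_dict(self) -> dict:
        return {
            "norm_factor": self.norm_factor,
            "risirna_count": self.risirna_count,
            "risirna_rpm": self.risirna_rpm,
            "region_proportions": self.region_proportions,
            "length_hist": {str(k): v for k, v in self.length_hist.items()},
            "first_nt": self.first_nt,
            "defined": self.defined,
        }

    def write_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")


def build_profile(
    classified: Sequence[ClassifiedRead],
    unit: RdnaUnit,
    min_len: int = 18,
    max_len: int = 30,
) -> RisiRNAProfile:
    """Assemble the full profile from classified (already filtered) reads."""
    from .classify import count_categories

    counts = count_categories(classified)
    risi = [c for c in classified if c.category == "risiRNA"]
    risi_on_unit = [c.alignment for c in risi if c.alignment.target == unit.name]

    factor = normalization_factor(counts)
    rpm = risirna_rpm(counts)
    props = region_proportions(risi_on_unit, unit)
    hist = length_histogram((c.read.length for c in risi), min_len, max_len)
    first = first_nt_preference(c.read.sequence for c in risi)
    cov = coverage_track(risi_on_unit, unit)

    return RisiRNAProfile(
        norm_factor=factor,
        risirna_count=counts.risiRNA,
        risirna_rpm=rpm,
        region_proportions=props,
        length_hist=hist,
        first_nt=first,
        coverage=cov,
        defined=counts.risiRNA > 0,
    )
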