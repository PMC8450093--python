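"""Synthetic small-RNA libraries and replicate qPCR Ct tables.

Libraries mix five read categories — antisense reads from the rDNA unit
(risiRNA), sense rRNA degradation fragments (unit or 5S), sense/antisense
mRNA fragments, and unmappable random sequence — under a multinomial over
category fractions, with genotype-specific region weights for risiRNA
placement, a length distribution peaked at 22 nt, and a configurable 5'-G
probability.  Every read is logged to a truth table.

risiRNA reads are exact reverse complements of unit substrings; the 5'-G
bias is realised by conditioning the placement on the identity of the 5'
base (G with probability exactly ``p_first_G``) rather than by overwriting
the base, so that noise-free reads always map back perfectly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .classify import ReadRecord
from .reference import DecoySet, RdnaUnit
from .seqtools import DEFAULT_ADAPTER, revcomp

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: Default read-length distribution: mass concentrated at 22 nt.
DEFAULT_LENGTH_DIST: dict[int, float] = {
    18: 0.01, 19: 0.02, 20: 0.05, 21: 0.12, 22: 0.55,
    23: 0.12, 24: 0.06, 25: 0.03, 26: 0.02, 27: 0.01,
    28: 0.01, 29: 0.00, 30: 0.00,
}

DEFAULT_P_FIRST_G = 0.75


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class LibraryProfile:
    """Parameters of one simulated small-RNA library."""

    n_reads: int
    frac_risirna: float
    frac_sense_rrna: float
    frac_sense_mrna: float
    frac_antisense_mrna: float
    frac_unmapped: float
    region_weights: Mapping[str, float]
    length_dist: Mapping[int, float] = field(default_factory=lambda: dict(DEFAULT_LENGTH_DIST))
    p_first_g: float = DEFAULT_P_FIRST_G
    seed: int = 0
    name: str = "custom"

    def __post_init__(self) -> None:
        if self.n_reads < 0:
            raise SimulationError("n_reads must be >= 0")
        fracs = self.category_fractions
        if abs(sum(fracs.values()) - 1.0) > 1e-9:
            raise SimulationError(f"category fractions sum to {sum(fracs.values())}, not 1")
        if any(f < 0 for f in fracs.values()):
            raise SimulationError("category fractions must be non-negative")
        if abs(sum(self.region_weights.values()) - 1.0) > 1e-9:
            raise SimulationError("region weights must sum to 1")
        if any(w < 0 for w in self.region_weights.values()):
            raise SimulationError("region weights must be non-negative")
        if not all(16 <= length <= 35 for length in self.length_dist):
            raise SimulationError("length_dist support must lie within [16, 35]")
        if abs(sum(self.length_dist.values()) - 1.0) > 1e-9:
            raise SimulationError("length_dist must sum to 1")
        if not 0.0 <= self.p_first_g <= 1.0:
            raise SimulationError("p_first_g must be in [0, 1]")

    @property
    def category_fractions(self) -> dict[str, float]:
        return {
            "risiRNA": self.frac_risirna,
            "sense_rRNA": self.frac_sense_rrna,
            "sense_mRNA": self.frac_sense_mrna,
            "antisense_mRNA": self.frac_antisense_mrna,
            "unmapped": self.frac_unmapped,
        }


# ---------------------------------------------------------------------------
# Presets

_PRESET_PACKAGE = "risipipe.presets"


def available_presets() -> list[str]:
    files = resources.files(_PRESET_PACKAGE)
    return sorted(p.name[:-5] for p in files.iterdir() if p.name.endswith(".json"))


def load_preset(name: str, n_reads: int, seed: int = 0) -> LibraryProfile:
    """Load a named genotype preset and bind library size and seed to it."""
    try:
        text = resources.files(_PRESET_PACKAGE).joinpath(f"{name}.json").read_text()
    except FileNotFoundError:
        raise SimulationError(f"unknown preset {name!r}; available: {available_presets()}")
    cfg = json.loads(text)
    return profile_from_config(cfg, n_reads=n_reads, seed=seed, name=name)


def profile_from_config(
    cfg: Mapping, n_reads: int, seed: int = 0, name: str = "custom"
) -> LibraryProfile:
    fr = cfg["fractions"]
    length_dist = {int(k): float(v) for k, v in cfg.get(
        "length_dist", {str(k): v for k, v in DEFAULT_LENGTH_DIST.items()}
    ).items()}
    return LibraryProfile(
        n_reads=n_reads,
        frac_risirna=fr["risiRNA"],
        frac_sense_rrna=fr["sense_rRNA"],
        frac_sense_mrna=fr["sense_mRNA"],
        frac_antisense_mrna=fr["antisense_mRNA"],
        frac_unmapped=fr["unmapped"],
        region_weights=dict(cfg["region_weights"]),
        length_dist=length_dist,
        p_first_g=float(cfg.get("p_first_G", DEFAULT_P_FIRST_G)),
        seed=seed,
        name=name,
    )


# ---------------------------------------------------------------------------
# Library simulation


class _AntisensePlacer:
    """Uniform placement of antisense reads inside a region, conditioned on
    the identity of the read's 5' base.

    The 5' base of an antisense read equals complement(unit[end-1]), so it is
    G exactly when the unit plus-strand base at end-1 is C.  Per region we
    keep sorted arrays of C and non-C positions; conditioning is a searchsorted
    subrange plus one uniform draw — equivalent to rejection sampling but O(1).
    """

    def __init__(self, unit: RdnaUnit):
        self.unit = unit
        seq = np.frombuffer(unit.sequence.encode(), dtype=np.uint8)
        is_c = seq == ord("C")
        self._g_pos: dict[str, np.ndarray] = {}
        self._ng_pos: dict[str, np.ndarray] = {}
        for r in unit.regions:
            pos = np.arange(r.start, r.end)
            mask = is_c[r.start : r.end]
            self._g_pos[r.name] = pos[mask]
            self._ng_pos[r.name] = pos[~mask]

    def sample(
        self, rng: np.random.Generator, region_name: str, length: int, want_g: bool
    ) -> tuple[int, int, str]:
        region = self.unit.region(region_name)
        if region.length < length:
            raise SimulationError(
                f"region {region_name} ({region.length} nt) shorter than read length {length}"
            )
        lo_end = region.start + length - 1  # inclusive range of end-1 positions
        hi_end = region.end - 1
        pool = self._g_pos[region_name] if want_g else self._ng_pos[region_name]
        i0, i1 = np.searchsorted(pool, (lo_end, hi_end + 1))
        if i0 == i1:  # no position with the wanted base; fall back to the other
            pool = self._ng_pos[region_name] if want_g else self._g_pos[region_name]
            i0, i1 = np.searchsorted(pool, (lo_end, hi_end + 1))
        last = int(pool[int(rng.integers(i0, i1))])
        start, end = last - length + 1, last + 1
        return start, end, revcomp(self.unit.sequence[start:end])


def simulate_library(
    profile: LibraryProfile,
    unit: RdnaUnit,
    decoys: DecoySet,
) -> tuple[list[ReadRecord], pd.DataFrame]:
    """Simulate reads plus a one-row-per-read truth table.

    Deterministic given ``profile.seed``.  Truth columns: read_id, category,
    target, region, start, end, strand, length.
    """
    rng = np.random.default_rng(profile.seed)
    fracs = profile.category_fractions
    cats = list(fracs)
    n = profile.n_reads
    n_per_cat = rng.multinomial(n, [fracs[c] for c in cats])

    # interleave categories deterministically so read ids are category-agnostic
    order = np.repeat(np.arange(len(cats)), n_per_cat)
    rng.shuffle(order)

    lengths = np.array(sorted(profile.length_dist), dtype=int)
    probs = np.array([profile.length_dist[int(k)] for k in lengths])
    probs = probs / probs.sum()
    length_all = rng.choice(lengths, size=n, p=probs) if n else np.empty(0, dtype=int)

    region_names = [rn for rn, w in profile.region_weights.items() if w > 0]
    region_probs = np.array([profile.region_weights[rn] for rn in region_names])
    region_probs = region_probs / region_probs.sum()
    max_len = int(lengths.max()) if len(lengths) else 0
    for rn in region_names:
        if unit.region(rn).length < max_len:
            raise SimulationError(f"region {rn} is shorter than the maximum read length {max_len}")

    n_risi = int(n_per_cat[cats.index("risiRNA")])
    if n_risi and not region_names:
        raise SimulationError("risiRNA fraction > 0 but no region weights given")
    risi_regions = iter(
        rng.choice(len(region_names), size=n_risi, p=region_probs) if n_risi else ()
    )
    risi_want_g = iter(rng.random(n_risi) < profile.p_first_g)
    placer = _AntisensePlacer(unit)

    sense_pool = [(unit.name, unit.sequence)] + [
        (t, decoys.transcripts[t]) for t in sorted(decoys.rrna_names)
    ]
    sense_w = np.array([len(s) for _, s in sense_pool], dtype=float)
    sense_w /= sense_w.sum()
    n_sense = int(n_per_cat[cats.index("sense_rRNA")])
    sense_targets = iter(
        rng.choice(len(sense_pool), size=n_sense, p=sense_w) if n_sense else ()
    )
    mrna_names = list(decoys.mrna_names)
    n_mrna_reads = int(
        n_per_cat[cats.index("sense_mRNA")] + n_per_cat[cats.index("antisense_mRNA")]
    )
    if n_mrna_reads and not mrna_names:
        raise SimulationError("mRNA fraction > 0 but decoy set has no mRNAs")
    mrna_targets = iter(
        rng.integers(0, len(mrna_names), size=n_mrna_reads) if n_mrna_reads and mrna_names else ()
    )

    reads: list[ReadRecord] = []
    rows: list[tuple] = []
    for i, cat_idx in enumerate(order):
        cat = cats[cat_idx]
        read_id = f"read_{i:07d}"
        length = int(length_all[i])
        target = region = ""
        start = end = -1
        strand = "."

        if cat == "risiRNA":
            region = region_names[int(next(risi_regions))]
            start, end, seq = placer.sample(rng, region, length, bool(next(risi_want_g)))
            target, strand = unit.name, "-"
        elif cat == "sense_rRNA":
            target, tseq = sense_pool[int(next(sense_targets))]
            start = int(rng.integers(0, len(tseq) - length + 1))
            end = start + length
            seq = tseq[start:end]
            strand = "+"
            if target == unit.name:
                region = unit.locate((start + end - 1) // 2)
        elif cat in ("sense_mRNA", "antisense_mRNA"):
            target = mrna_names[int(next(mrna_targets))]
            tseq = decoys.transcripts[target]
            start = int(rng.integers(0, len(tseq) - length + 1))
            end = start + length
            seq = tseq[start:end]
            strand = "+"
            if cat == "antisense_mRNA":
                seq = revcomp(seq)
                strand = "-"
        else:  # unmapped: random sequence guaranteed not to hit any target
            seq = _random_unmapped(rng, length, unit, decoys)

        reads.append(ReadRecord(id=read_id, sequence=seq))
        rows.append((read_id, cat, target, region, start, end, strand, length))

    truth = pd.DataFrame(
        rows, columns=["read_id", "category", "target", "region", "start", "end", "strand", "length"]
    )
    return reads, truth


def _random_unmapped(
    rng: np.random.Generator, length: int, unit: RdnaUnit, decoys: DecoySet, max_tries: int = 100
) -> str:
    targets = [unit.sequence] + list(decoys.transcripts.values())
    adapter_key = DEFAULT_ADAPTER[:8]
    for _ in range(max_tries):
        idx = rng.integers(0, 4, size=length)
        seq = "".join("ACGT"[i] for i in idx)
        rc = revcomp(seq)
        if adapter_key in seq or adapter_key in rc:
            continue
        if any(seq in t or rc in t for t in targets):
            continue
        return seq
    raise SimulationError("could not generate an unmappable read")


# ---------------------------------------------------------------------------
# Adapters and FASTQ I/O


def attach_adapters(
    reads: Iterable[ReadRecord],
    three_prime_adapter: str = DEFAULT_ADAPTER,
    read_length: int | None = None,
) -> list[ReadRecord]:
    """Append the 3' adapter to every insert, optionally truncating the
    result to a fixed sequencing read length."""
    bad = set(three_prime_adapter) - set("ACGT")
    if bad:
        raise SimulationError(f"adapter must be DNA (ACGT); found {sorted(bad)}")
    out = []
    for r in reads:
        seq = r.sequence + three_prime_adapter
        if read_length is not None:
            seq = seq[:read_length]
        out.append(ReadRecord(id=r.id, sequence=seq))
    return out


def write_fastq(reads: Iterable[ReadRecord], path: str | Path) -> None:
    """Phred+33 FASTQ with constant quality 'I' (quality is never used)."""
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{'I' * r.length}\n")


def read_fastq(path: str | Path) -> list[ReadRecord]:
    from Bio import SeqIO

    return [ReadRecord(id=rec.id, sequence=str(rec.seq).upper())
            for rec in SeqIO.parse(str(path), "fastq")]


# ---------------------------------------------------------------------------
# qPCR simulation


@dataclass(frozen=True)
class QpcrDesign:
    """Replicate ChIP/RIP-qPCR design with known true enrichments.

    ``enrichments`` maps (sample, treatment, locus) to the true fraction of
    the total input recovered in the IP, so that noise-free percent-input
    equals 100 x enrichment.
    """

    enrichments: Mapping[tuple[str, str, str], float]
    input_fraction: float = 0.01
    replicates: int = 4
    ct_noise_sd: float = 0.15
    seed: int = 0
    base_ct: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if self.replicates < 2:
            raise SimulationError("replicates must be >= 2")
        if not 0.0 < self.input_fraction < 1.0:
            raise SimulationError("input_fraction must be in (0, 1)")
        if any(e <= 0 for e in self.enrichments.values()):
            raise SimulationError("enrichments must be > 0")

    def locus_base_ct(self, locus: str) -> float:
        if self.base_ct and locus in self.base_ct:
            return float(self.base_ct[locus])
        # deterministic, locus-specific but seed-independent baseline
        return 18.0 + (sum(ord(c) for c in locus) % 7)


def simulate_qpcr(design: QpcrDesign) -> pd.DataFrame:
    """Simulate input and IP wells; Gaussian noise on the Ct scale,
    amplification efficiency fixed at 2.

    Ct_IP = Ct_input − log2(1/input_fraction) − log2(enrichment) + noise, so
    the dilution-corrected percent-input recovers 100 x enrichment exactly at
    zero noise.  Columns: sample, treatment, locus, role, fraction_input,
    replicate, ct.
    """
    rng = np.random.default_rng(design.seed)
    rows = []
    for (sample, treatment, locus), enrich in design.enrichments.items():
        ct_in_base = design.locus_base_ct(locus)
        for rep in range(1, design.replicates + 1):
            ct_input = ct_in_base + float(rng.normal(0.0, design.ct_noise_sd))
            ct_ip = (
                ct_input
                - np.log2(1.0 / design.input_fraction)
                - np.log2(enrich)
                + float(rng.normal(0.0, design.ct_noise_sd))
            )
            rows.append((sample, treatment, locus, "input", design.input_fraction, rep, ct_input))
            rows.append((sample, treatment, locus, "IP", np.nan, rep, ct_ip))
    return pd.DataFrame(
        rows, columns=["sample", "treatment", "locus", "role", "fraction_input", "replicate", "ct"]
    )


def write_ct_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_ct_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"sample", "treatment", "locus", "role", "fraction_input", "replicate", "ct"}
    missing = required - set(df.columns)
    if missing:
        raise SimulationError(f"Ct table missing columns: {sorted(missing)}")
    return df
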