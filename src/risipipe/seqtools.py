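"""Low-level nucleotide-string helpers shared across modules."""

from __future__ import annotations

import numpy as np

DNA_ALPHABET = "ACGT"
READ_ALPHABET = frozenset("ACGTN")

#: 3' sequencing adapter in DNA alphabet (RNA adapter with U -> T).
DEFAULT_ADAPTER = "TCGTATGCCGTCTTCTGCTTG"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def kmers(seq: str, k: int):
    """Yield every k-mer of ``seq`` (empty if len(seq) < k)."""
    for i in range(len(seq) - k + 1):
        yield seq[i : i + k]


def random_seq(rng: np.random.Generator, length: int) -> str:
    """Uniform random DNA string of the given length."""
    idx = rng.integers(0, 4, size=length)
    return "".join(DNA_ALPHABET[i] for i in idx)


def random_seq_avoiding(
    rng: np.random.Generator,
    length: int,
    forbidden: frozenset[str] | set[str],
    k: int,
    max_tries: int = 1000,
) -> str:
    """Random DNA string none of whose k-mers (either strand) is forbidden.

    Regenerates the whole string on a hit; collision probability is tiny for
    the sizes used here, so this terminates almost immediately.
    """
    if not forbidden:
        return random_seq(rng, length)
    for _ in range(max_tries):
        seq = random_seq(rng, length)
        if not _hits_forbidden(seq, forbidden, k):
            return seq
    raise RuntimeError(f"could not generate a {length} nt sequence avoiding {len(forbidden)} k-mers")


def _hits_forbidden(seq: str, forbidden, k: int) -> bool:
    rc = revcomp(seq)
    for s in (seq, rc):
        for km in kmers(s, k):
            if km in forbidden:
                return True
    return False
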