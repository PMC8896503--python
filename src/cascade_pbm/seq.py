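"""Small DNA-sequence utilities shared across the package."""

from __future__ import annotations

import numpy as np

ALPHABET = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGT string."""
    return seq.translate(_COMPLEMENT)[::-1]


def validate_dna(seq: str, name: str = "sequence") -> str:
    """Upper-case and validate a DNA string; raise on any non-ACGT base."""
    seq = seq.upper()
    bad = set(seq) - set(ALPHABET)
    if bad:
        raise ValueError(
            f"invalid base in {name}: {sorted(bad)} (only A/C/G/T allowed)"
        )
    return seq


def random_dna(n: int, rng: np.random.Generator) -> str:
    """i.i.d. uniform ACGT string of length n."""
    return "".join(rng.choice(list(ALPHABET), size=n))


def encode(seq: str) -> np.ndarray:
    """Integer-encode an ACGT string (A=0, C=1, G=2, T=3)."""
    return np.fromiter((BASE_INDEX[b] for b in seq), dtype=np.int64, count=len(seq))
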