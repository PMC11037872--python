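"""Low-level nucleotide sequence utilities shared across modules.

Sequences cross module boundaries as plain upper-case ACGT strings; internally
most operations run on uint8 arrays with the 2-bit encoding A=0, C=1, G=2, T=3.
"""

from __future__ import annotations

import numpy as np

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i
    _ENCODE[_b + 32] = _i  # lower case

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def encode(seq: str) -> np.ndarray:
    """Encode an ACGT string as a uint8 array (A=0, C=1, G=2, T=3)."""
    arr = _ENCODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if arr.max(initial=0) > 3:
        bad = chr(np.frombuffer(seq.encode(), dtype=np.uint8)[arr > 3][0])
        raise ValueError(f"non-ACGT character {bad!r} in sequence")
    return arr


def decode(arr: np.ndarray) -> str:
    return BASES[arr].tobytes().decode()


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    """Uniform random encoded sequence of the given length."""
    return rng.integers(0, 4, size=length, dtype=np.uint8)


def mutate(
    arr: np.ndarray, rate_per_10kbp: float, rng: np.random.Generator
) -> np.ndarray:
    """Substitute sites independently at ``rate_per_10kbp`` SNVs per 10 kbp.

    Each selected site is changed to one of the three *other* bases, so the
    realized SNV density equals the nominal rate in expectation.
    """
    out = arr.copy()
    p = rate_per_10kbp / 10_000.0
    if p <= 0:
        return out
    sites = np.nonzero(rng.random(arr.size) < p)[0]
    if sites.size:
        # shift by 1-3 mod 4 guarantees a different base
        out[sites] = (out[sites] + rng.integers(1, 4, size=sites.size)) % 4
    return out


def hamming(a: np.ndarray, b: np.ndarray) -> int:
    if a.size != b.size:
        raise ValueError("sequences differ in length")
    return int(np.count_nonzero(a != b))
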