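"""Small shared utilities: sequence encoding and variant normalization."""

from __future__ import annotations

import numpy as np

_ENC = np.full(256, 255, dtype=np.uint8)
for i, b in enumerate(b"ACGT"):
    _ENC[b] = i
    _ENC[b + 32] = i
_DEC = np.frombuffer(b"ACGT", dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """DNA string -> uint8 array with A,C,G,T -> 0..3."""
    return _ENC[np.frombuffer(seq.encode(), dtype=np.uint8)]


def decode(arr: np.ndarray) -> str:
    return _DEC[arr].tobytes().decode()


def revcomp_encoded(arr: np.ndarray) -> np.ndarray:
    return (3 - arr)[::-1]


def sliding_hamming(hay: np.ndarray, needle: np.ndarray) -> np.ndarray:
    """Hamming distance of ``needle`` against every offset of ``hay``.

    Returns an array of length len(hay) - len(needle) + 1 (empty if the
    haystack is shorter than the needle).
    """
    m, n = len(needle), len(hay)
    if n < m:
        return np.empty(0, dtype=np.int32)
    out = np.zeros(n - m + 1, dtype=np.int32)
    for j in range(m):
        out += hay[j : j + n - m + 1] != needle[j]
    return out


def left_normalize(seq: str, pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Left-align and minimalize a variant against its reference sequence.

    ``pos`` is 0-based; ``ref``/``alt`` are the VCF-style allele strings
    (``seq[pos:pos+len(ref)] == ref``). Indels are shifted to their leftmost
    equivalent placement, the standard normalization that makes the
    representation independent of where an aligner happened to open the gap.
    """
    changed = True
    while changed:
        changed = False
        if ref and alt and ref[-1] == alt[-1] and (len(ref) > 1 or len(alt) > 1):
            ref, alt = ref[:-1], alt[:-1]
            changed = True
        if (not ref or not alt) and pos > 0:
            base = seq[pos - 1]
            ref, alt = base + ref, base + alt
            pos -= 1
            changed = True
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def variant_key(contig: str, pos: int, ref: str, alt: str) -> str:
    """Canonical string key for a normalized variant."""
    return f"{contig}:{pos}:{ref}>{alt}"
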