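"""Small sequence helpers shared across modules.

Sequences are plain Python strings of uppercase A/C/G/T/N; hot paths in the
simulator work on uint8 numpy arrays and convert at the boundary.
"""

from __future__ import annotations

import numpy as np

_BASES = "ACGT"
_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# base <-> uint8 codes 0..3 (N -> 4)
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(_BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i
_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def seq_to_codes(seq: str) -> np.ndarray:
    """Encode a nucleotide string as uint8 codes (A=0 C=1 G=2 T=3 N=4)."""
    return _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def codes_to_seq(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode()


def random_seq(rng: np.random.Generator, length: int) -> str:
    return codes_to_seq(rng.integers(0, 4, size=length, dtype=np.uint8))
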