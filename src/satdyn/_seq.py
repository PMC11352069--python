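"""Low-level sequence utilities shared across modules.

Sequences are plain uppercase A/C/G/T strings at the API surface and
uint8 arrays (A=0, C=1, G=2, T=3) inside the alignment kernels.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterator

import numpy as np

_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i
    _ENCODE[_b + 32] = _i  # lowercase

_DECODE = np.frombuffer(b"ACGT", dtype=np.uint8)

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def encode(seq: str) -> np.ndarray:
    """Encode an A/C/G/T string as a uint8 array; rejects other characters."""
    arr = _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if arr.size and arr.max() > 3:
        bad = seq[int(np.argmax(arr > 3))]
        raise ValueError(f"non-ACGT character {bad!r} in sequence")
    return arr


def decode(arr: np.ndarray) -> str:
    return _DECODE[arr].tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def is_transition(a: int, b: int) -> bool:
    """A<->G and C<->T are transitions under the 0123=ACGT encoding."""
    return a != b and (a ^ b) == 2


def open_text(path: str | Path, mode: str = "rt"):
    """Open a possibly gzip-compressed text file."""
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq_pairs(r1: str | Path, r2: str | Path) -> Iterator[tuple[tuple, tuple]]:
    """Yield ((id1, seq1, qual1), (id2, seq2, qual2)) from a FASTQ pair."""
    with open_text(r1) as f1, open_text(r2) as f2:
        while True:
            rec1 = [f1.readline() for _ in range(4)]
            rec2 = [f2.readline() for _ in range(4)]
            if not rec1[0] and not rec2[0]:
                return
            if not rec1[0] or not rec2[0]:
                raise ValueError("paired FASTQ files have unequal record counts")
            yield (
                (rec1[0].rstrip()[1:], rec1[1].rstrip(), rec1[3].rstrip()),
                (rec2[0].rstrip()[1:], rec2[1].rstrip(), rec2[3].rstrip()),
            )
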