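"""Low-level nucleotide utilities shared by the scanners and the simulator.

Sequences are plain Python strings over the alphabet A/C/G/T/N (case
insensitive).  Internally they are encoded as ``uint8`` arrays with
A=0, C=1, G=2, T=3, N=4; the complement of a valid base ``b`` is ``3 - b``,
so two codes are Watson-Crick complementary iff they sum to 3 (which is
never true when either code is N).
"""

from __future__ import annotations

import numpy as np

A, C, G, T, N = 0, 1, 2, 3, 4

_COMPLEMENT_TABLE = str.maketrans("ACGTNacgtn", "TGCANtgcan")

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i
_CODE[ord("N")] = N
_CODE[ord("n")] = N

_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N maps to N)."""
    return seq.translate(_COMPLEMENT_TABLE)[::-1]


def encode(seq: str, name: str = "sequence") -> np.ndarray:
    """Encode a nucleotide string, raising ``ValueError`` on a non-ACGTN byte."""
    raw = np.frombuffer(seq.encode("ascii", errors="strict"), dtype=np.uint8)
    codes = _CODE[raw]
    if codes.max(initial=0) == 255:
        bad = chr(int(raw[codes == 255][0]))
        raise ValueError(f"{name} contains non-nucleotide character {bad!r}")
    return codes


def decode(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode("ascii")


def gc_content(seq: str) -> float:
    codes = encode(seq)
    acgt = codes < N
    if not acgt.any():
        return 0.0
    return float(((codes == G) | (codes == C)).sum() / acgt.sum())


def bool_runs(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Starts and lengths of maximal runs of ``True`` in a boolean array."""
    if mask.size == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    padded = np.concatenate(([False], mask, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return starts.astype(np.int64), (ends - starts).astype(np.int64)


def kmer_codes(
    codes: np.ndarray, k: int, reverse: bool = False, complement: bool = False
) -> np.ndarray:
    """Base-4 integer code of every k-mer window; -1 where the window holds an N.

    ``reverse`` encodes the reversed window, ``complement`` complements each
    base first; both together give the reverse-complement k-mer code.
    """
    n = len(codes)
    if n < k:
        return np.empty(0, dtype=np.int64)
    valid = codes < N
    c = np.where(valid, codes, 0).astype(np.int64)
    if complement:
        c = 3 - c
    out = np.zeros(n - k + 1, dtype=np.int64)
    ok = np.ones(n - k + 1, dtype=bool)
    positions = range(k - 1, -1, -1) if reverse else range(k)
    for j in positions:
        out = out * 4 + c[j : j + n - k + 1]
        ok &= valid[j : j + n - k + 1]
    out[~ok] = -1
    return out


def prefix_counts(mask: np.ndarray) -> np.ndarray:
    """Prefix sums with leading zero so that ``p[b] - p[a]`` counts in [a, b)."""
    out = np.zeros(len(mask) + 1, dtype=np.int64)
    np.cumsum(mask, out=out[1:])
    return out
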