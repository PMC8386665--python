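"""Exact k-mer encoding helpers shared by the repeat finder and comparator.

Bases are packed 2 bits each into uint64 codes (exact, no hashing), so code
equality is string equality for k <= 31.  Windows containing ``N`` are
assigned an invalid sentinel and never participate in matches.
"""

from __future__ import annotations

import numpy as np

_BASE_CODE = np.full(256, 255, dtype=np.uint8)
for i, b in enumerate("ACGT"):
    _BASE_CODE[ord(b)] = i

INVALID = np.uint64(0xFFFFFFFFFFFFFFFF)


def encode_bases(seq: str) -> np.ndarray:
    """Map a DNA string to uint8 codes (A,C,G,T -> 0..3; anything else 255)."""
    return _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def kmer_codes(seq: str, k: int) -> np.ndarray:
    """Exact 2-bit-packed codes for every k-mer of ``seq`` (k <= 31).

    Positions whose window contains a non-ACGT base get ``INVALID``.
    """
    if not 1 <= k <= 31:
        raise ValueError(f"k must be in [1, 31], got {k}")
    b = encode_bases(seq)
    n = len(b) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    codes = np.zeros(n, dtype=np.uint64)
    valid = np.ones(n, dtype=bool)
    for j in range(k):
        col = b[j : j + n]
        codes = (codes << np.uint64(2)) | (col & np.uint8(3)).astype(np.uint64)
        valid &= col != 255
    codes[~valid] = INVALID
    return codes


def self_pairs(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All position pairs (i < j) sharing a valid k-mer code.

    Size-2 groups (the overwhelming majority on a doubled circle) are paired
    fully vectorized; larger groups (repeat regions) fall back to a loop.
    """
    order = np.argsort(codes, kind="stable")
    s = codes[order]
    valid = s != INVALID
    order, s = order[valid], s[valid]
    if len(s) == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    starts = np.flatnonzero(np.concatenate(([True], s[1:] != s[:-1])))
    ends = np.concatenate((starts[1:], [len(s)]))
    sizes = ends - starts
    out_i: list[np.ndarray] = []
    out_j: list[np.ndarray] = []
    two = starts[sizes == 2]
    if len(two):
        a = order[two]
        b = order[two + 1]
        out_i.append(np.minimum(a, b))
        out_j.append(np.maximum(a, b))
    for st, en in zip(starts[sizes > 2], ends[sizes > 2]):
        grp = np.sort(order[st:en])
        n = len(grp)
        ii, jj = np.triu_indices(n, k=1)
        out_i.append(grp[ii])
        out_j.append(grp[jj])
    if not out_i:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    return (
        np.concatenate(out_i).astype(np.int64),
        np.concatenate(out_j).astype(np.int64),
    )


def cross_pairs(codes_a: np.ndarray, codes_b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All pairs (i, j) with ``codes_a[i] == codes_b[j]`` over valid codes.

    Intended for sparse sharing (e.g. a sequence against its reverse
    complement, where shared codes are confined to inverted repeats); loops
    only over shared code values.
    """
    va = codes_a != INVALID
    vb = codes_b != INVALID
    ua, pos_a = np.unique(codes_a[va], return_inverse=False), None
    shared = np.intersect1d(ua, np.unique(codes_b[vb]), assume_unique=True)
    if len(shared) == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    idx_a = np.flatnonzero(va)
    idx_b = np.flatnonzero(vb)
    sa_order = np.argsort(codes_a[va], kind="stable")
    sb_order = np.argsort(codes_b[vb], kind="stable")
    sa = codes_a[va][sa_order]
    sb = codes_b[vb][sb_order]
    out_i: list[np.ndarray] = []
    out_j: list[np.ndarray] = []
    a_lo = np.searchsorted(sa, shared, side="left")
    a_hi = np.searchsorted(sa, shared, side="right")
    b_lo = np.searchsorted(sb, shared, side="left")
    b_hi = np.searchsorted(sb, shared, side="right")
    for al, ah, bl, bh in zip(a_lo, a_hi, b_lo, b_hi):
        ai = idx_a[sa_order[al:ah]]
        bj = idx_b[sb_order[bl:bh]]
        gi, gj = np.meshgrid(ai, bj, indexing="ij")
        out_i.append(gi.ravel())
        out_j.append(gj.ravel())
    return (
        np.concatenate(out_i).astype(np.int64),
        np.concatenate(out_j).astype(np.int64),
    )


def unique_cross_pairs(
    codes_a: np.ndarray, codes_b: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Pairs (i, j) for codes occurring exactly once in each array (vectorized)."""
    va = codes_a != INVALID
    vb = codes_b != INVALID
    ua, ia, ca = np.unique(codes_a[va], return_index=True, return_counts=True)
    ub, ib, cb = np.unique(codes_b[vb], return_index=True, return_counts=True)
    ua, ia = ua[ca == 1], ia[ca == 1]
    ub, ib = ub[cb == 1], ib[cb == 1]
    _, sel_a, sel_b = np.intersect1d(ua, ub, assume_unique=True, return_indices=True)
    return (
        np.flatnonzero(va)[ia[sel_a]].astype(np.int64),
        np.flatnonzero(vb)[ib[sel_b]].astype(np.int64),
    )
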