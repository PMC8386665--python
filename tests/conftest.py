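"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from mitostruct.sequence import CircularSequence, revcomp


def random_circle(rng: np.random.Generator, length: int, id: str = "s") -> CircularSequence:
    return CircularSequence(id, "".join(rng.choice(list("ACGT"), length)), "circular")


def _runs(mask: np.ndarray, min_len: int):
    padded = np.concatenate(([False], mask, [False]))
    d = np.diff(padded.astype(np.int8))
    for a, b in zip(np.flatnonzero(d == 1), np.flatnonzero(d == -1)):
        if b - a >= min_len:
            yield int(a), int(b - a)


def repeat_oracle(s: CircularSequence, min_len: int) -> set[tuple]:
    """Quadratic brute-force repeated-pair search on a small circle.

    Compares the doubled sequence against itself (direct) and against its
    reverse complement (inverted) on every diagonal, collects maximal exact
    runs, normalizes modulo the length and keeps maximal pairs only.
    Independent of the seed-and-extend detector: no k-mer seeds, no
    chaining, no extension heuristics.
    """
    L = len(s)
    D = s.doubled()
    arr = np.frombuffer(D.encode(), dtype=np.uint8)
    rc = np.frombuffer(revcomp(D).encode(), dtype=np.uint8)
    n = len(arr)
    raw: set[tuple] = set()
    for d in range(1, n):
        m = arr[: n - d] == arr[d:]
        for a, length in _runs(m, min_len):
            b = a + d
            if (b - a) % L == 0:
                continue
            raw.add(tuple(sorted((a % L, b % L))) + (min(length, L), "direct"))
    for d in range(-(n - 1), n):
        if d >= 0:
            m = arr[: n - d] == rc[d:]
            oa = 0
        else:
            m = arr[-d:] == rc[: n + d]
            oa = -d
        for a0, length in _runs(m, min_len):
            a = a0 + oa
            j0 = a0 + d if d >= 0 else a0
            b = n - (j0 + length)
            lo, hi = sorted((a, b))
            if lo + length > hi:  # palindromic self-overlap, not a pair
                continue
            raw.add(tuple(sorted((lo % L, hi % L))) + (min(length, L), "inverted"))
    keep: set[tuple] = set()
    for k in sorted(raw, key=lambda k: -k[2]):
        a, b, l, o = k
        contained = False
        for a2, b2, l2, o2 in keep:
            if o2 != o or l > l2:
                continue
            offa, offb = (a - a2) % L, (b - b2) % L
            if o == "direct" and offa == offb and offa + l <= l2:
                contained = True
            if o == "inverted" and offa == (l2 - (offb + l)) % L and offa + l <= l2:
                contained = True
        if not contained:
            keep.add(k)
    return keep


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20_240_101)
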