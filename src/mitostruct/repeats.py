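"""Detection of large repeated pairs within a single molecule.

This is the self-comparison step of the pipeline: large repeats (direct or
inverted) are what mediate homologous recombination in plant mitogenomes, so
everything downstream (sub-genomic circle enumeration, junction validation)
starts from the pairs reported here.

The detector is seed-and-extend: exact k-mer seeds on the doubled sequence
(so repeats spanning the circular origin are seen contiguously), greedy
merging of co-diagonal seed runs (gaps up to ``max_gap`` count as
mismatches), exact tip extension, and deduplication of the doubled-sequence
images modulo the molecule length.  Identity is matches / alignment columns.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from ._kmers import cross_pairs, kmer_codes, self_pairs
from .sequence import CircularSequence, Interval, revcomp, subsequence

__all__ = [
    "RepeatPair",
    "RepeatParams",
    "REPEAT_FAMILY_LENGTHS",
    "find_repeats",
    "find_short_repeats",
    "match_families",
]

#: Size classes of the four named large-repeat families of potato
#: mitogenomes (bp).  Family labels are matched by length within +/-10% of
#: any listed variant; R1 and R2 carry the expanded (13,435 bp) and reduced
#: (7,076 bp) variants seen in the wild-species mitogenome.
REPEAT_FAMILY_LENGTHS: dict[str, tuple[int, ...]] = {
    "R1": (11_916, 13_435),
    "R2": (7_502, 7_076),
    "R3": (4_513,),
    "R4": (1_589,),
}


@dataclass(frozen=True)
class RepeatPair:
    """Two copies of a repeat on one molecule.

    ``copyA``/``copyB`` are intervals on the parent (0-based, may wrap on
    circles); ``orientation`` is ``direct`` when both copies read the same
    strand and ``inverted`` when the second copy is the reverse complement
    of the first.  ``copyB.strand`` is ``-`` for inverted pairs.
    """

    copyA: Interval
    copyB: Interval
    orientation: str
    length: int
    identity: float
    family: str = "custom"
    molecule_id: str | None = None

    def __post_init__(self) -> None:
        if self.orientation not in ("direct", "inverted"):
            raise ValueError(f"bad orientation {self.orientation!r}")
        if not 0.0 < self.identity <= 1.0:
            raise ValueError(f"identity must be in (0, 1], got {self.identity}")


@dataclass(frozen=True)
class RepeatParams:
    """Tuning knobs for :func:`find_repeats`.

    ``min_len`` defaults to 1,000 bp — the size class above which plant
    mitochondrial repeats recombine frequently and reversibly.
    ``min_identity`` defaults to 0.98 because recombination-active repeats
    are near-identical.
    """

    min_len: int = 1000
    min_identity: float = 0.98
    seed_k: int = 21
    max_gap: int = 100

    def __post_init__(self) -> None:
        if self.min_len <= self.seed_k:
            raise ValueError("min_len must exceed seed_k")
        if not 0.0 < self.min_identity <= 1.0:
            raise ValueError("min_identity must be in (0, 1]")


@dataclass
class _Run:
    """A co-diagonal match run in doubled coordinates (a on D, b on partner)."""

    a: int  # start on first sequence
    b: int  # start on second sequence
    length: int
    mismatches: int


def _merge_diagonal_runs(
    pos_a: np.ndarray, pos_b: np.ndarray, k: int, max_gap: int
) -> list[_Run]:
    """Group seed hits by diagonal and merge near-adjacent ones into runs."""
    if len(pos_a) == 0:
        return []
    diag = pos_b - pos_a
    order = np.lexsort((pos_a, diag))
    pos_a, pos_b, diag = pos_a[order], pos_b[order], diag[order]
    runs: list[_Run] = []
    cur: _Run | None = None
    cur_diag = None
    for a, b, d in zip(pos_a.tolist(), pos_b.tolist(), diag.tolist()):
        if cur is not None and d == cur_diag and a <= cur.a + cur.length + max_gap:
            new_end = max(cur.a + cur.length, a + k)
            gap = max(0, a - (cur.a + cur.length))
            cur.mismatches += gap
            cur.length = new_end - cur.a
        else:
            if cur is not None:
                runs.append(cur)
            cur = _Run(a=int(a), b=int(b), length=k, mismatches=0)
            cur_diag = int(d)
    if cur is not None:
        runs.append(cur)
    return runs


def _run_identity(run: _Run, sa: str, sb: str) -> float:
    """Exact identity of a gap-free run: matching columns / run length."""
    a = np.frombuffer(sa[run.a : run.a + run.length].encode(), dtype=np.uint8)
    b = np.frombuffer(sb[run.b : run.b + run.length].encode(), dtype=np.uint8)
    n = min(len(a), len(b))
    if n == 0:
        return 0.0
    return float(np.count_nonzero(a[:n] == b[:n])) / run.length


def _tip_extend(run: _Run, sa: str, sb: str, limit: int) -> None:
    """Extend a run outward base-by-base while bases match exactly.

    ``limit`` caps the total run length (the molecule length on circles, so
    a perfect period never yields a run longer than the molecule).
    """
    while (
        run.a > 0
        and run.b > 0
        and run.length < limit
        and sa[run.a - 1] == sb[run.b - 1]
        and sa[run.a - 1] != "N"
    ):
        run.a -= 1
        run.b -= 1
        run.length += 1
    while (
        run.a + run.length < len(sa)
        and run.b + run.length < len(sb)
        and run.length < limit
        and sa[run.a + run.length] == sb[run.b + run.length]
        and sa[run.a + run.length] != "N"
    ):
        run.length += 1


def _interval_contains_mod(outer_start: int, outer_len: int, inner_start: int,
                           inner_len: int, L: int) -> bool:
    """Does [outer_start, +outer_len) contain [inner_start, +inner_len) mod L?"""
    if inner_len > outer_len:
        return False
    off = (inner_start - outer_start) % L
    return off + inner_len <= outer_len


def _canonical_pair(
    start1: int, start2: int, length: int, orientation: str, identity: float, L: int
) -> RepeatPair:
    """Order the two copies canonically (copyA first when walking clockwise
    from a gap position outside both copies) and build the RepeatPair."""
    s1, s2 = start1 % L, start2 % L
    # candidate gap points: the copy ends; pick one outside both copies
    gap = None
    for g in ((s1 + length) % L, (s2 + length) % L, 0):
        in1 = _interval_contains_mod(s1, length, g, 1, L)
        in2 = _interval_contains_mod(s2, length, g, 1, L)
        if not in1 and not in2:
            gap = g
            break
    if gap is None:
        gap = (s1 + length) % L
    r1, r2 = (s1 - gap) % L, (s2 - gap) % L
    if r1 > r2:
        s1, s2 = s2, s1
    strandB = "-" if orientation == "inverted" else "+"
    return RepeatPair(
        copyA=Interval(start=s1, length=length, strand="+"),
        copyB=Interval(start=s2, length=length, strand=strandB),
        orientation=orientation,
        length=length,
        identity=identity,
        family="custom",
    )


def _dedup_and_suppress(pairs: list[RepeatPair], L: int) -> list[RepeatPair]:
    """Drop duplicate images (mod L) and pairs contained in longer pairs."""
    seen: set[tuple] = set()
    unique: list[RepeatPair] = []
    for p in sorted(pairs, key=lambda p: (-p.length, p.copyA.start, p.copyB.start)):
        key = (p.copyA.start, p.copyB.start, p.length, p.orientation)
        if key in seen:
            continue
        seen.add(key)
        contained = False
        for q in unique:
            if q.orientation != p.orientation:
                continue
            if (
                _interval_contains_mod(q.copyA.start, q.length, p.copyA.start, p.length, L)
                and _interval_contains_mod(q.copyB.start, q.length, p.copyB.start, p.length, L)
            ) or (
                _interval_contains_mod(q.copyA.start, q.length, p.copyB.start, p.length, L)
                and _interval_contains_mod(q.copyB.start, q.length, p.copyA.start, p.length, L)
            ):
                contained = True
                break
        if not contained:
            unique.append(p)
    return unique


def find_repeats(s: CircularSequence, params: RepeatParams | None = None) -> list[RepeatPair]:
    """Find large repeated pairs within ``s`` on both strands.

    Circularity is handled by self-comparison of the doubled sequence with
    hit images deduplicated modulo the molecule length; the trivial
    whole-sequence self-hit never arises because same-position images are
    filtered.  Output is sorted by length, descending.
    """
    params = params or RepeatParams()
    L = len(s)
    if L < 2 * params.min_len:
        return []
    D = s.doubled() if s.is_circular else s.seq
    k = params.seed_k
    codes = kmer_codes(D, k)
    pairs: list[RepeatPair] = []

    # --- direct orientation: D vs D ---
    i, j = self_pairs(codes)
    if s.is_circular:
        keep = (j - i) != L  # doubling images of a position against itself
        i, j = i[keep], j[keep]
    runs = _merge_diagonal_runs(i, j, k, params.max_gap)
    runs = [r for r in runs if r.length >= params.min_len - params.max_gap]
    for r in runs:
        _tip_extend(r, D, D, limit=L if s.is_circular else len(D))
        ident = _run_identity(r, D, D)
        if r.length >= params.min_len and ident >= params.min_identity:
            if s.is_circular and (r.b - r.a) % L == 0:
                continue  # a perfect period image, not a distinct copy pair
            pairs.append(_canonical_pair(r.a, r.b, r.length, "direct", ident, L))

    # --- inverted orientation: D vs revcomp(D) ---
    R = revcomp(D)
    codes_r = kmer_codes(R, k)
    i, j = cross_pairs(codes, codes_r)
    runs = _merge_diagonal_runs(i, j, k, params.max_gap)
    runs = [r for r in runs if r.length >= params.min_len - params.max_gap]
    seen_inv: set[tuple] = set()
    for r in runs:
        _tip_extend(r, D, R, limit=L if s.is_circular else len(D))
        ident = _run_identity(r, D, R)
        if r.length < params.min_len or ident < params.min_identity:
            continue
        # map the R-side run back to original (+) coordinates
        b_orig = len(D) - (r.b + r.length)
        sA, sB = r.a % L, b_orig % L
        if sA == sB:
            continue  # a palindrome matched against its own image
        # copies must not overlap after circular normalization
        if _interval_contains_mod(sA, r.length, sB, 1, L) or _interval_contains_mod(
            sB, r.length, sA, 1, L
        ):
            continue
        key = tuple(sorted((sA, sB))) + (r.length,)
        if key in seen_inv:
            continue
        seen_inv.add(key)
        pairs.append(_canonical_pair(sA, sB, r.length, "inverted", ident, L))

    out = _dedup_and_suppress(pairs, L)
    out = [replace(p, molecule_id=s.id) for p in out]
    out.sort(key=lambda p: (-p.length, p.copyA.start))
    return out


def find_short_repeats(
    s: CircularSequence,
    region: Interval,
    min_len: int = 20,
    max_len: int = 200,
) -> list[RepeatPair]:
    """Exhaustive scan for short repeated pairs within ``region``.

    Used for breakpoint flanking-repeat discovery (the 40 bp class), where
    seeds of the large-repeat detector would be too coarse.  All maximal
    exact match runs (both orientations) between positions inside the region
    are reported, longest first.  Coordinates are absolute on ``s``.
    """
    window = subsequence(s, Interval(region.start, region.length, "+"))
    hits = _exhaustive_pairs(window, min_len)
    L = len(s)
    out = []
    for a, b, length, orientation in hits:
        if length > max_len:
            continue
        sA = (region.start + a) % L
        sB = (region.start + b) % L
        out.append(
            RepeatPair(
                copyA=Interval(sA, length, "+"),
                copyB=Interval(sB, length, "-" if orientation == "inverted" else "+"),
                orientation=orientation,
                length=length,
                identity=1.0,
                molecule_id=s.id,
            )
        )
    out.sort(key=lambda p: (-p.length, p.copyA.start))
    return out


def _exhaustive_pairs(seq: str, min_len: int) -> list[tuple[int, int, int, str]]:
    """All maximal exact repeated pairs in a (linear) window, by diagonal scan.

    Quadratic in the window length; intended for windows of a few kb.
    Returns (startA, startB, length, orientation) tuples.
    """
    n = len(seq)
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    rc = np.frombuffer(revcomp(seq).encode(), dtype=np.uint8)
    valid = arr != ord("N")
    hits: list[tuple[int, int, int, str]] = []
    # direct: compare seq against itself shifted by d
    for d in range(1, n):
        m = (arr[: n - d] == arr[d:]) & valid[: n - d] & valid[d:]
        for a, length in _true_runs(m, min_len):
            hits.append((a, a + d, length, "direct"))
    # inverted: compare seq against revcomp(seq) on all diagonals
    for d in range(-(n - 1), n):
        if d >= 0:
            m = (arr[: n - d] == rc[d:]) & valid[: n - d]
            offset_a = 0
        else:
            m = (arr[-d:] == rc[: n + d]) & valid[-d:]
            offset_a = -d
        for a0, length in _true_runs(m, min_len):
            a = a0 + offset_a
            # rc index of run start -> original coordinates of partner copy
            j0 = a + d if d >= 0 else a0
            b = n - (j0 + length)
            lo, hi = min(a, b), max(a, b)
            # partner copies must be distinct, non-overlapping stretches
            if lo + length <= hi:
                hits.append((lo, hi, length, "inverted"))
    # dedup inverted pairs (each found from both sides) and keep maximal only
    seen: set[tuple] = set()
    uniq = []
    for h in sorted(hits, key=lambda h: -h[2]):
        key = h
        if key in seen:
            continue
        seen.add(key)
        contained = any(
            o == h[3]
            and a2 <= h[0]
            and b2 <= h[1]
            and h[0] + h[2] <= a2 + l2
            and h[1] + h[2] <= b2 + l2
            and (h[0] - a2) == (h[1] - b2 if o == "direct" else (b2 + l2) - (h[1] + h[2]))
            for a2, b2, l2, o in uniq
        )
        if not contained:
            uniq.append(h)
    return uniq


def _true_runs(mask: np.ndarray, min_len: int) -> list[tuple[int, int]]:
    """(start, length) of maximal True runs of at least ``min_len``."""
    if len(mask) == 0:
        return []
    padded = np.concatenate(([False], mask, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return [(int(a), int(b - a)) for a, b in zip(starts, ends) if b - a >= min_len]


def match_families(
    pairs: list[RepeatPair],
    lexicon: dict[str, int | tuple[int, ...]] | None = None,
    tolerance: float = 0.10,
) -> list[RepeatPair]:
    """Assign family labels (R1-R4 by default) by length class (+/-10%).

    Lexicon values may be a single length or a tuple of known length
    variants; a pair outside every class is labelled ``custom``.
    """
    lexicon = lexicon or REPEAT_FAMILY_LENGTHS
    out = []
    for p in pairs:
        label = "custom"
        best = tolerance + 1
        for fam, lengths in lexicon.items():
            if isinstance(lengths, int):
                lengths = (lengths,)
            for flen in lengths:
                rel = abs(p.length - flen) / flen
                if rel <= tolerance and rel < best:
                    label, best = fam, rel
        out.append(replace(p, family=label))
    return out
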