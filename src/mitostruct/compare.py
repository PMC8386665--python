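"""Pairwise structural comparison of molecules.

Molecules are compared through gap-free synteny blocks anchored on k-mers
unique in both sequences (k = 31, near-unique at the 50-300 kb scale of
mitogenome molecules), merged along diagonals and extended while bases match
exactly.  Divergence therefore appears as block fragmentation rather than
gapped alignment — the questions asked of these comparisons are
presence/arrangement questions, not nucleotide-alignment ones.

Overlaps between blocks (which arise where a repeated segment, e.g. a short
breakpoint flank, is claimed by two neighbouring blocks) are resolved
longest-block-first: each block is trimmed against the *original* extents of
all longer blocks, on both molecules.  This deterministic rule assigns
shared flank copies to the collinear neighbours, so a translocated block is
reported at the length of the moved content itself, excluding its flanking
repeats.

Rearrangements are classified from the block arrangement: a strand-flipped
block is an inversion; a forward block off the maximum-weight collinear
chain is a translocation; sequence covered in only one molecule is an
insertion (extra in B) or deletion (absent from B).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ._kmers import kmer_codes, unique_cross_pairs
from .fileio import GffFeature
from .repeats import RepeatPair, _true_runs
from .sequence import CircularSequence, Interval, revcomp, subsequence

logger = logging.getLogger(__name__)

__all__ = [
    "SyntenyBlock",
    "SharedUniqueSummary",
    "RearrangementEvent",
    "anchor_blocks",
    "shared_unique",
    "detect_rearrangements",
    "breakpoint_flanks",
    "report_intergenic",
]

_ANCHOR_K = 31


@dataclass(frozen=True)
class SyntenyBlock:
    """A gap-free identical block: equal-length intervals on A and B.

    ``strand == '-'`` means the B-side interval matches the reverse
    complement of the A-side interval.  Both intervals are in forward
    coordinates of their own molecule.
    """

    ivA: Interval
    ivB: Interval
    strand: str
    length: int

    def __post_init__(self) -> None:
        if self.ivA.length != self.ivB.length or self.ivA.length != self.length:
            raise ValueError("synteny block sides must have equal length")


@dataclass(frozen=True)
class SharedUniqueSummary:
    shared: int
    uniqueA: int
    uniqueB: int


@dataclass(frozen=True)
class RearrangementEvent:
    type: str  # translocation | insertion | deletion | inversion
    block_a: Interval | None
    block_b: Interval | None
    block_length: int
    flank_repeat: RepeatPair | None = None


class _Raw:
    """Mutable working block; ``b`` lives in forward or RC space of B
    according to ``strand``."""

    __slots__ = ("a", "b", "length", "strand")

    def __init__(self, a: int, b: int, length: int, strand: str):
        self.a, self.b, self.length, self.strand = a, b, length, strand


# ---------------------------------------------------------------------------
# anchoring
# ---------------------------------------------------------------------------


def _circular_codes(s: CircularSequence, k: int) -> np.ndarray:
    """One code per k-mer start; circular molecules contribute every k-mer
    crossing the origin exactly once (positions in [0, L))."""
    ext = s.seq + (s.seq[: k - 1] if s.is_circular else "")
    return kmer_codes(ext, k)


def _merge_anchor_runs(
    pa: np.ndarray, pb: np.ndarray, k: int, LA: int, LB: int, circA: bool, circB: bool
) -> list[_Raw]:
    """Chain strictly consecutive anchors (step 1 on both sides, mod L)."""
    if len(pa) == 0:
        return []
    order = np.lexsort((pb, pa))
    pa, pb = pa[order], pb[order]
    runs: list[_Raw] = []
    open_runs: dict[tuple[int, int], _Raw] = {}
    for a, b in zip(pa.tolist(), pb.tolist()):
        run = open_runs.pop((a, b), None)
        if run is None:
            run = _Raw(a, b, k, "+")
            runs.append(run)
        else:
            run.length += 1
        na = (a + 1) % LA if circA else a + 1
        nb = (b + 1) % LB if circB else b + 1
        open_runs[(na, nb)] = run
    return runs


def _char(s: str, i: int, circ: bool) -> str | None:
    if circ:
        return s[i % len(s)]
    return s[i] if 0 <= i < len(s) else None


def _extend_run(run: _Raw, sa: str, sb: str, circA: bool, circB: bool, cap: int) -> None:
    """Grow a run in both directions while bases agree (N never matches)."""
    while run.length < cap:
        ca = _char(sa, run.a - 1, circA)
        cb = _char(sb, run.b - 1, circB)
        if ca is None or cb is None or ca != cb or ca == "N":
            break
        run.a -= 1
        run.b -= 1
        run.length += 1
    while run.length < cap:
        ca = _char(sa, run.a + run.length, circA)
        cb = _char(sb, run.b + run.length, circB)
        if ca is None or cb is None or ca != cb or ca == "N":
            break
        run.length += 1


def anchor_blocks(
    seqA: CircularSequence,
    seqB: CircularSequence,
    min_anchor: int = 100,
) -> list[SyntenyBlock]:
    """Gap-free synteny blocks between two molecules, both strands.

    Anchors are 31-mers unique in both sequences; circular molecules are
    handled with modular coordinates (blocks may wrap the origin).  Output
    blocks are non-overlapping within each molecule (longest-first overlap
    trimming) and at least ``min_anchor`` long.
    """
    k = _ANCHOR_K
    LA, LB = len(seqA), len(seqB)
    if LA < min_anchor or LB < min_anchor:
        return []
    cap = min(LA, LB)
    circA, circB = seqA.is_circular, seqB.is_circular
    codes_a = _circular_codes(seqA, k)
    raws: list[_Raw] = []

    for strand, partner in (("+", seqB.seq), ("-", revcomp(seqB.seq))):
        partner_cs = CircularSequence("p", partner, seqB.topology)
        ia, ib = unique_cross_pairs(codes_a, _circular_codes(partner_cs, k))
        runs = _merge_anchor_runs(ia, ib, k, LA, LB, circA, circB)
        for r in runs:
            r.length = min(r.length, cap)
            _extend_run(r, seqA.seq, partner, circA, circB, cap)
            r.strand = strand
        raws.extend(runs)

    # normalize coordinates and dedup images of the same maximal block
    seen: set[tuple] = set()
    uniq: list[_Raw] = []
    for r in sorted(raws, key=lambda r: (-r.length, r.a, r.b)):
        a = r.a % LA if circA else r.a
        b = r.b % LB if circB else r.b
        key = (a, b, r.length, r.strand)
        if key in seen:
            continue
        seen.add(key)
        contained = any(
            q.strand == r.strand
            and ((a - q.a) % LA if circA else a - q.a)
            == ((b - q.b) % LB if circB else b - q.b)
            and 0 <= ((a - q.a) % LA if circA else a - q.a)
            and ((a - q.a) % LA if circA else a - q.a) + r.length <= q.length
            for q in uniq
        )
        if not contained:
            uniq.append(_Raw(a, b, r.length, r.strand))

    trimmed = _trim_overlaps(uniq, LA, LB, circA, circB, min_anchor)

    out: list[SyntenyBlock] = []
    for r in trimmed:
        if r.strand == "+":
            b_orig = r.b
        else:
            b_orig = (LB - r.b - r.length) % LB if circB else LB - r.b - r.length
        out.append(
            SyntenyBlock(
                ivA=Interval(r.a, r.length, "+"),
                ivB=Interval(b_orig, r.length, r.strand),
                strand=r.strand,
                length=r.length,
            )
        )
    out.sort(key=lambda b: (b.ivA.start, b.ivB.start))
    return out


def _local_segments(
    p_start: int, p_len: int, q_start: int, q_len: int, L: int, circ: bool
) -> list[tuple[int, int]]:
    """Offsets within [0, p_len) covered by interval q (mod L when circular)."""
    if not circ:
        lo = max(p_start, q_start) - p_start
        hi = min(p_start + p_len, q_start + q_len) - p_start
        return [(lo, hi)] if lo < hi else []
    o = (q_start - p_start) % L
    segs = []
    end = o + q_len
    if o < p_len:
        segs.append((o, min(end, p_len)))
    if end > L:  # q wraps past the origin relative to p's frame
        hi = min(end - L, p_len)
        if hi > 0:
            segs.append((0, hi))
    return segs


def _b_forward_extent(r: _Raw, LB: int, circB: bool) -> tuple[int, int]:
    """B-side extent of a raw block in forward coordinates of B."""
    if r.strand == "+":
        return r.b, r.length
    start = (LB - r.b - r.length) % LB if circB else LB - r.b - r.length
    return start, r.length


def _trim_overlaps(
    raws: list[_Raw], LA: int, LB: int, circA: bool, circB: bool, min_len: int
) -> list[_Raw]:
    """Longest-first acceptance; each block is trimmed against the original
    extents of all longer blocks, on both the A and the B side."""
    order = sorted(raws, key=lambda r: (-r.length, r.a, r.b))
    accepted: list[_Raw] = []
    out: list[_Raw] = []
    for r in order:
        forbidden: list[tuple[int, int]] = []
        for q in accepted:
            forbidden += _local_segments(r.a, r.length, q.a, q.length, LA, circA)
            # B side: compare in forward coordinates of B, then map the
            # forbidden forward segment back into r's own offset axis
            rb_start, _ = _b_forward_extent(r, LB, circB)
            qb_start, qb_len = _b_forward_extent(q, LB, circB)
            segs = _local_segments(rb_start, r.length, qb_start, qb_len, LB, circB)
            if r.strand == "-":
                # forward offsets run opposite to r's RC-space offsets
                segs = [(r.length - hi, r.length - lo) for lo, hi in segs]
            forbidden += segs
        keep = _longest_free_run(r.length, forbidden)
        if keep is None or keep[1] - keep[0] < min_len:
            accepted.append(r)  # still shadows smaller blocks below it
            continue
        lo, hi = keep
        t = _Raw(
            (r.a + lo) % LA if circA else r.a + lo,
            (r.b + lo) % LB if circB else r.b + lo,
            hi - lo,
            r.strand,
        )
        accepted.append(r)
        out.append(t)
    return out


def _longest_free_run(
    length: int, forbidden: list[tuple[int, int]]
) -> tuple[int, int] | None:
    if not forbidden:
        return (0, length)
    merged: list[list[int]] = []
    for lo, hi in sorted((max(0, lo), min(length, hi)) for lo, hi in forbidden):
        if hi <= lo:
            continue
        if merged and lo <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    best = None
    prev = 0
    for lo, hi in merged + [[length, length]]:
        if lo - prev > 0 and (best is None or lo - prev > best[1] - best[0]):
            best = (prev, lo)
        prev = max(prev, hi)
    return best


# ---------------------------------------------------------------------------
# summaries and rearrangements
# ---------------------------------------------------------------------------


def shared_unique(blocks: list[SyntenyBlock], lenA: int, lenB: int) -> SharedUniqueSummary:
    """Shared/unique bp totals from non-overlapping gap-free blocks."""
    _assert_disjoint([b.ivA for b in blocks], lenA, "A")
    _assert_disjoint([b.ivB for b in blocks], lenB, "B")
    shared = sum(b.length for b in blocks)
    return SharedUniqueSummary(shared=shared, uniqueA=lenA - shared, uniqueB=lenB - shared)


def _marks(ivs: list[Interval], L: int) -> list[tuple[int, int]]:
    marks: list[tuple[int, int]] = []
    for iv in ivs:
        end = iv.start + iv.length
        if end <= L:
            marks.append((iv.start, end))
        else:
            marks.append((iv.start, L))
            marks.append((0, end - L))
    marks.sort()
    return marks


def _assert_disjoint(ivs: list[Interval], L: int, label: str) -> None:
    marks = _marks(ivs, L)
    for (_, e1), (s2, _) in zip(marks, marks[1:]):
        if s2 < e1:
            raise ValueError(f"synteny blocks overlap on molecule {label} at {s2}")


def detect_rearrangements(
    blocks: list[SyntenyBlock],
    seqA: CircularSequence,
    seqB: CircularSequence,
    min_event: int = 50,
) -> list[RearrangementEvent]:
    """Classify rearrangements from the block arrangement.

    Strand-flipped blocks are inversions.  Among forward blocks, the
    maximum-weight chain collinear in both molecules (circular order
    anchored on the longest block) is the syntenic backbone; any forward
    block off the chain is a translocation.  Uncovered regions of at least
    ``min_event`` bp are insertions (extra sequence in B) or deletions
    (sequence absent from B); shorter gaps are trimming artefacts of
    repeated flanks and are ignored.
    """
    LA, LB = len(seqA), len(seqB)
    events: list[RearrangementEvent] = []
    covered = sum(b.length for b in blocks)
    if covered < 0.5 * max(LA, LB):
        logger.warning(
            "synteny blocks cover %d bp of %d/%d — low-confidence comparison",
            covered,
            LA,
            LB,
        )
    for b in blocks:
        if b.strand == "-":
            events.append(
                RearrangementEvent(
                    type="inversion", block_a=b.ivA, block_b=b.ivB, block_length=b.length
                )
            )
    fwd = [b for b in blocks if b.strand == "+"]
    if fwd:
        chain = _max_weight_chain(fwd, LA, LB, seqA.is_circular, seqB.is_circular)
        for b in fwd:
            if b not in chain and b.length >= min_event:
                events.append(
                    RearrangementEvent(
                        type="translocation",
                        block_a=b.ivA,
                        block_b=b.ivB,
                        block_length=b.length,
                    )
                )
    for start, length in _uncovered([b.ivB for b in blocks], LB, seqB.is_circular):
        if length >= min_event:
            events.append(
                RearrangementEvent(
                    type="insertion",
                    block_a=None,
                    block_b=Interval(start, length, "+"),
                    block_length=length,
                )
            )
    for start, length in _uncovered([b.ivA for b in blocks], LA, seqA.is_circular):
        if length >= min_event:
            events.append(
                RearrangementEvent(
                    type="deletion",
                    block_a=Interval(start, length, "+"),
                    block_b=None,
                    block_length=length,
                )
            )
    return events


def _max_weight_chain(
    blocks: list[SyntenyBlock], LA: int, LB: int, circA: bool, circB: bool
) -> list[SyntenyBlock]:
    """Maximum-weight subset collinear in both molecules (weight = length)."""
    anchor = max(blocks, key=lambda b: b.length)
    a_key = (
        (lambda b: (b.ivA.start - anchor.ivA.start) % LA) if circA else (lambda b: b.ivA.start)
    )
    b_key = (
        (lambda b: (b.ivB.start - anchor.ivB.start) % LB) if circB else (lambda b: b.ivB.start)
    )
    order = sorted(blocks, key=a_key)
    bpos = [b_key(b) for b in order]
    n = len(order)
    weight = [b.length for b in order]
    best = list(weight)
    prev = [-1] * n
    for i in range(n):
        for j in range(i):
            if bpos[j] < bpos[i] and best[j] + weight[i] > best[i]:
                best[i] = best[j] + weight[i]
                prev[i] = j
    end = int(np.argmax(best))
    chain = []
    while end != -1:
        chain.append(order[end])
        end = prev[end]
    return chain


def _uncovered(ivs: list[Interval], L: int, circ: bool) -> list[tuple[int, int]]:
    """Maximal uncovered (start, length) arcs/segments of the molecule."""
    if not ivs:
        return [(0, L)]
    marks = _marks(ivs, L)
    merged: list[list[int]] = []
    for s, e in marks:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    gaps = [(e1, s2 - e1) for (_, e1), (s2, _) in zip(merged, merged[1:])]
    head = merged[0][0]
    tail = L - merged[-1][1]
    if circ:
        if head + tail > 0:
            gaps.append((merged[-1][1] % L, head + tail))
    else:
        if head > 0:
            gaps.append((0, head))
        if tail > 0:
            gaps.append((merged[-1][1], tail))
    return [g for g in gaps if g[1] > 0]


# ---------------------------------------------------------------------------
# breakpoint flanks and annotation reports
# ---------------------------------------------------------------------------


def breakpoint_flanks(
    event: RearrangementEvent,
    seqA: CircularSequence,
    seqB: CircularSequence,
    window: int = 500,
    min_len: int = 20,
) -> RepeatPair | None:
    """Short direct repeat flanking the event's block on both sides, if any.

    Scans ``window`` bp around each breakpoint (plus a margin inside the
    block, so a flank copy carried along with an inserted block is still
    seen) for the longest exact direct pair with one copy at each
    breakpoint.  Returns ``None`` when no pair of at least ``min_len`` bp
    flanks the block.
    """
    if event.type == "insertion":
        mol, block = seqB, event.block_b
    else:
        mol, block = seqA, event.block_a
    if block is None:
        return None
    L = len(mol)
    pad = min(window, block.length // 2)
    left_start = (block.start - window) % L
    left = subsequence(mol, Interval(left_start, window + pad, "+"))
    right_start = (block.start + block.length - pad) % L
    right = subsequence(mol, Interval(right_start, window + pad, "+"))
    hit = _longest_common_substring(left, right, min_len)
    if hit is None:
        return None
    off_l, off_r, length = hit
    copy_a = Interval((left_start + off_l) % L, length, "+")
    copy_b = Interval((right_start + off_r) % L, length, "+")
    return RepeatPair(
        copyA=copy_a,
        copyB=copy_b,
        orientation="direct",
        length=length,
        identity=1.0,
        molecule_id=mol.id,
    )


def _longest_common_substring(x: str, y: str, min_len: int) -> tuple[int, int, int] | None:
    """Longest exact common substring via diagonal scan; None if < min_len."""
    ax = np.frombuffer(x.encode(), dtype=np.uint8)
    ay = np.frombuffer(y.encode(), dtype=np.uint8)
    nx, ny = len(ax), len(ay)
    best: tuple[int, int, int] | None = None
    for d in range(-(nx - 1), ny):
        if d >= 0:
            m = ax[: min(nx, ny - d)] == ay[d : d + min(nx, ny - d)]
            ox, oy = 0, d
        else:
            m = ax[-d : -d + min(nx + d, ny)] == ay[: min(nx + d, ny)]
            ox, oy = -d, 0
        for start, length in _true_runs(m, min_len):
            if best is None or length > best[2]:
                best = (ox + start, oy + start, length)
    return best


def report_intergenic(
    annotations: list[GffFeature],
    gene_x: str,
    gene_y: str,
    molecule_length: int,
) -> int:
    """Intergenic distance (bp) between two named features on a circle.

    Returns the shorter of the two arcs separating the features' intervals
    (e.g. the marker region between a cob pseudogene fragment and rps10).
    """
    fx = _find_feature(annotations, gene_x)
    fy = _find_feature(annotations, gene_y)
    L = molecule_length
    gap1 = (fy.iv.start - (fx.iv.start + fx.iv.length)) % L
    gap2 = (fx.iv.start - (fy.iv.start + fy.iv.length)) % L
    return min(gap1, gap2)


def _find_feature(annotations: list[GffFeature], name: str) -> GffFeature:
    for f in annotations:
        if f.id == name or f.attributes.get("Name") == name:
            return f
    raise KeyError(f"no feature named {name!r} in annotations")
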