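"""Reverse read mapping: confirm predicted junctions with long reads.

A predicted recombinant junction is *supported* when at least ``min_reads``
long reads align across the breakpoint with at least ``min_anchor`` aligned
bases on each side.  The caveat built into repeat-mediated junctions: a
breakpoint placed inside a repeat copy is only confirmable when the anchors
clear the repeat ends, so the pipeline sizes junction flanks accordingly and
warns when ``min_anchor`` is smaller than the repeat length.

Mapping is intentionally simple: exact k-mer prefilter, then edlib
alignment of whichever of read/construct is shorter into the other (infix
mode).  Reads that only graze a construct end cannot span the breakpoint,
so the containment-style alignment loses nothing for support counting.  A
PAF import path is provided for alignments produced externally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import edlib
import numpy as np
import pandas as pd

from ._kmers import kmer_codes
from .fileio import PafRecord
from .recombination import Junction, enumerate_all, predict_junctions
from .repeats import RepeatParams, find_repeats
from .sequence import CircularSequence, revcomp

logger = logging.getLogger(__name__)

__all__ = [
    "AlignmentRecord",
    "JunctionSupport",
    "ValidationParams",
    "map_reads",
    "alignments_from_paf",
    "count_support",
    "validate_genome",
]


@dataclass(frozen=True)
class AlignmentRecord:
    """One read-to-target alignment (PAF-compatible coordinate convention)."""

    read_id: str
    target_id: str
    target_start: int
    target_end: int
    read_start: int
    read_end: int
    strand: str
    identity: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError(f"identity out of [0,1]: {self.identity}")
        if self.target_end < self.target_start or self.read_end < self.read_start:
            raise ValueError("alignment coordinates out of order")


@dataclass(frozen=True)
class JunctionSupport:
    junction_id: str
    n_spanning: int
    n_total: int
    supported: bool

    def __post_init__(self) -> None:
        if self.n_spanning > self.n_total:
            raise ValueError("n_spanning cannot exceed n_total")


@dataclass(frozen=True)
class ValidationParams:
    """Support-calling thresholds.

    ``min_anchor`` (bp aligned on each side of the breakpoint) defaults to
    500; ``min_reads`` to 3, a conventional long-read SV support floor;
    ``min_identity`` to 0.85.
    """

    min_anchor: int = 500
    min_reads: int = 3
    min_identity: float = 0.85
    seed_k: int = 15
    min_seed_hits: int = 3
    #: extra flank width beyond the anchor requirement when sizing junction
    #: constructs, so sequencing errors near an alignment end (which trim
    #: the well-matching span by a few bases) cannot push an anchored read
    #: just outside the spanning window
    flank_margin: int = 200


def _codes_set(seq: str, k: int) -> np.ndarray:
    return np.unique(kmer_codes(seq, k))


def map_reads(
    reads: Sequence[tuple[str, str]],
    constructs: Sequence[tuple[str, str]],
    params: ValidationParams | None = None,
) -> list[AlignmentRecord]:
    """Best alignment per read per construct, both strands, deterministic.

    ``reads`` and ``constructs`` are (id, sequence) pairs.  The shorter of
    read/construct is aligned as an infix of the longer (edlib "HW" mode);
    identity is 1 - edits / aligned-query-length.
    """
    params = params or ValidationParams()
    k = params.seed_k
    construct_codes = [(cid, cseq, _codes_set(cseq, k)) for cid, cseq in constructs]
    out: list[AlignmentRecord] = []
    for rid, rseq in sorted(reads, key=lambda r: r[0]):
        strands = {"+": rseq, "-": revcomp(rseq)}
        read_codes = {st: kmer_codes(sq, k) for st, sq in strands.items()}
        for cid, cseq, ccodes in construct_codes:
            best: AlignmentRecord | None = None
            for st, sq in strands.items():
                rc = read_codes[st]
                if len(rc) == 0 or len(ccodes) == 0:
                    continue
                hits = np.count_nonzero(
                    ccodes[
                        np.clip(np.searchsorted(ccodes, rc), 0, len(ccodes) - 1)
                    ]
                    == rc
                )
                if hits < params.min_seed_hits:
                    continue
                rec = _align_pair(rid, sq, cid, cseq, st)
                if rec is not None and (best is None or rec.identity > best.identity):
                    best = rec
            if best is not None:
                out.append(best)
    return out


_MISMATCH_PENALTY = 3


def _trim_alignment(cigar: str) -> tuple[int, int, int, int, float] | None:
    """Best locally-matching window of an edlib alignment path.

    Scores +1 per matching column and -3 per mismatch/indel column and
    keeps the maximum-scoring stretch (so a construct whose tail aligns
    against unrelated sequence is trimmed back to its well-matching core);
    the window ends are then snapped inward to the nearest run of 10
    consecutive matches, which makes the trimmed span exact on error-free
    reads (chance 10-mer matches against unrelated sequence are negligible).
    Returns (query_start, query_end, target_start, target_end, identity)
    or None when nothing matches.
    """
    # expand cigar into columns tagged with query/target consumption
    cols: list[tuple[bool, int, int]] = []  # (is_match, dq, dt)
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
            continue
        n = int(num)
        num = ""
        if ch == "=":
            cols.extend([(True, 1, 1)] * n)
        elif ch == "X":
            cols.extend([(False, 1, 1)] * n)
        elif ch == "I":  # consumes query
            cols.extend([(False, 1, 0)] * n)
        elif ch == "D":  # consumes target
            cols.extend([(False, 0, 1)] * n)
    best_score = 0
    best: tuple[int, int] | None = None
    score = 0
    start = 0
    for i, (match, _, _) in enumerate(cols):
        score += 1 if match else -_MISMATCH_PENALTY
        if score <= 0:
            score = 0
            start = i + 1
        elif score > best_score:
            best_score = score
            best = (start, i + 1)
    if best is None:
        return None
    best = _snap_to_match_runs(cols, best)
    if best is None:
        return None
    qpos = tpos = 0
    q0 = t0 = q1 = t1 = 0
    matches = columns = 0
    for i, (match, dq, dt) in enumerate(cols):
        if i == best[0]:
            q0, t0 = qpos, tpos
        qpos += dq
        tpos += dt
        if best[0] <= i < best[1]:
            columns += 1
            matches += int(match)
        if i == best[1] - 1:
            q1, t1 = qpos, tpos
            break
    return q0, q1, t0, t1, matches / columns


_SNAP_RUN = 10


def _snap_to_match_runs(
    cols: list[tuple[bool, int, int]], window: tuple[int, int]
) -> tuple[int, int] | None:
    """Move window ends inward to the first/last run of consecutive matches."""
    lo, hi = window
    run = 0
    new_lo = None
    for i in range(lo, hi):
        run = run + 1 if cols[i][0] else 0
        if run == _SNAP_RUN:
            new_lo = i - _SNAP_RUN + 1
            break
    if new_lo is None:
        return None
    run = 0
    new_hi = None
    for i in range(hi - 1, new_lo - 1, -1):
        run = run + 1 if cols[i][0] else 0
        if run == _SNAP_RUN:
            new_hi = i + _SNAP_RUN
            break
    if new_hi is None or new_hi <= new_lo:
        return None
    return new_lo, new_hi


def _align_pair(
    rid: str, rseq: str, cid: str, cseq: str, strand: str
) -> AlignmentRecord | None:
    construct_is_query = len(rseq) >= len(cseq)
    query, target = (cseq, rseq) if construct_is_query else (rseq, cseq)
    res = edlib.align(query, target, mode="HW", task="path")
    if res["editDistance"] < 0 or not res["locations"] or not res.get("cigar"):
        return None
    trimmed = _trim_alignment(res["cigar"])
    if trimmed is None:
        return None
    q0, q1, t0, t1, identity = trimmed
    t_off = res["locations"][0][0]
    t0 += t_off
    t1 += t_off
    if construct_is_query:
        construct_span = (q0, q1)
        read_span = (t0, t1)
    else:
        construct_span = (t0, t1)
        read_span = (q0, q1)
    read_start, read_end = read_span
    if strand == "-":
        read_start, read_end = len(rseq) - read_end, len(rseq) - read_start
    return AlignmentRecord(
        read_id=rid,
        target_id=cid,
        target_start=construct_span[0],
        target_end=construct_span[1],
        read_start=read_start,
        read_end=read_end,
        strand=strand,
        identity=identity,
    )


def alignments_from_paf(records: Iterable[PafRecord]) -> list[AlignmentRecord]:
    """Convert PAF rows (reads mapped to junction constructs) to records."""
    return [
        AlignmentRecord(
            read_id=r.query_name,
            target_id=r.target_name,
            target_start=r.target_start,
            target_end=r.target_end,
            read_start=r.query_start,
            read_end=r.query_end,
            strand=r.strand,
            identity=r.identity,
        )
        for r in records
    ]


def count_support(
    alignments: Sequence[AlignmentRecord],
    junctions: Sequence[Junction],
    params: ValidationParams | None = None,
) -> list[JunctionSupport]:
    """Per-junction spanning-read counts and supported calls.

    A read counts as spanning iff its alignment to the junction construct
    covers ``[mid - min_anchor, mid + min_anchor)`` at identity >=
    ``min_identity``, where ``mid`` is the breakpoint offset within the
    construct.  For a junction placed inside a repeat copy
    (``repeat_length > 0``) the window additionally widens by half the
    repeat length on each side, so the anchors must clear the repeat ends —
    a read that never leaves the repeat cannot confirm such a junction.
    """
    params = params or ValidationParams()
    by_id = {j.id: j for j in junctions}
    for j in junctions:
        need_left = j.repeat_length // 2 + params.min_anchor
        need_right = (j.repeat_length + 1) // 2 + params.min_anchor
        if need_left > j.midpoint or need_right > len(j.right):
            raise ValueError(
                f"anchor requirement ({need_left}/{need_right} bp) exceeds the "
                f"flank width of junction {j.id!r} ({j.midpoint}/{len(j.right)})"
            )
    aligned: dict[str, list[AlignmentRecord]] = {j.id: [] for j in junctions}
    for rec in alignments:
        if rec.target_id not in by_id:
            raise KeyError(
                f"alignment targets unknown junction {rec.target_id!r}"
            )
        aligned[rec.target_id].append(rec)
    out = []
    for j in junctions:
        good = [a for a in aligned[j.id] if a.identity >= params.min_identity]
        mid = j.midpoint
        lo = mid - (j.repeat_length // 2 + params.min_anchor)
        hi = mid + ((j.repeat_length + 1) // 2 + params.min_anchor)
        spanning = [
            a for a in good if a.target_start <= lo and a.target_end >= hi
        ]
        out.append(
            JunctionSupport(
                junction_id=j.id,
                n_spanning=len(spanning),
                n_total=len(good),
                supported=len(spanning) >= params.min_reads,
            )
        )
    return out


def validate_genome(
    molecules: Sequence[CircularSequence],
    reads: Sequence[tuple[str, str]],
    params: ValidationParams | None = None,
    repeat_params: RepeatParams | None = None,
    flank_w: int = 1000,
    repeat_pairs=None,
) -> pd.DataFrame:
    """End-to-end confirmation: repeats -> products -> junctions -> support.

    For each molecule, large repeats are detected (or taken from
    ``repeat_pairs``, a mapping of molecule id to pre-computed pairs),
    single-event products enumerated, novel-junction constructs built with
    flanks wide enough to clear the repeat copy
    (``max(flank_w, repeat_len // 2 + min_anchor)``), and spanning reads
    counted.  Returns a per-junction table.
    """
    params = params or ValidationParams()
    rows = []
    all_junctions: list[Junction] = []
    junction_meta: dict[str, tuple[str, str]] = {}
    for mol in molecules:
        pairs = (
            repeat_pairs.get(mol.id, [])
            if repeat_pairs is not None
            else find_repeats(mol, repeat_params)
        )
        if not pairs:
            continue
        for pair in pairs:
            if params.min_anchor < pair.length:
                logger.warning(
                    "molecule %s: min_anchor %d < repeat length %d; junction "
                    "flanks are widened so anchors clear the repeat ends",
                    mol.id,
                    params.min_anchor,
                    pair.length,
                )
        products = enumerate_all(mol, list(pairs))
        for prod in products:
            w_eff = max(
                flank_w,
                (prod.repeat_length + 1) // 2 + params.min_anchor + params.flank_margin,
            )
            if 2 * w_eff > len(prod):
                w_eff = len(prod) // 2
            junctions = [j for j in predict_junctions(prod, w_eff) if j.novel]
            for j in junctions:
                junction_meta[j.id] = (mol.id, prod.id)
            all_junctions.extend(junctions)
    if all_junctions:
        constructs = [(j.id, j.construct) for j in all_junctions]
        alignments = map_reads(reads, constructs, params)
        supports = count_support(alignments, all_junctions, params)
    else:
        supports = []
    for sup in supports:
        mol_id, prod_id = junction_meta[sup.junction_id]
        rows.append(
            {
                "molecule": mol_id,
                "product": prod_id,
                "junction": sup.junction_id,
                "n_total": sup.n_total,
                "n_spanning": sup.n_spanning,
                "supported": sup.supported,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["molecule", "product", "junction", "n_total", "n_spanning", "supported"],
    )
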