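"""Synthetic multipartite mitogenomes and long-read simulation.

The generator mirrors the four mitogenome architectures observed in the
10-clone potato panel:

* ``groupA``   — four circles; molecule 1a carries an inverted R1 pair and a
  direct R2 pair, molecule 1b a direct R2 pair, molecule 2 a direct R4 pair.
* ``groupB``   — three circles; molecule 1 carries direct R1 and R3 pairs,
  molecule 2 a direct R4 pair.
* ``clone10908`` — three circles; molecule 1 carries direct R1 and R2 pairs,
  molecule 2 a direct R4 pair.
* ``oka15``    — three circles; molecule 1 carries the expanded R1
  (13,435 bp) and reduced R2 (7,076 bp) pairs; molecule 2 has **no** large
  repeat.

Molecule lengths and repeat-family lengths default to the published per-clone
values (one representative column per group).  Background sequence is random
at GC 0.45; planted copies are exact duplicates unless a divergence knob is
set.  Planting enforces *distinct junction contexts*: the background base
adjacent to each planted copy is resampled if it would extend the exact
match, so detected repeat/block lengths equal the planted lengths exactly.

Long reads are drawn from a weighted mixture of circular templates with
lognormal lengths, uniform start and strand, and optional substitution and
indel errors; per-read provenance is recorded as machine-readable truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .repeats import RepeatPair
from .sequence import CircularSequence, Interval, revcomp

__all__ = [
    "GenomeProfile",
    "MoleculeSpec",
    "RepeatPlacement",
    "ReadSimParams",
    "SimRead",
    "TruthSet",
    "make_profile",
    "single_repeat_profile",
    "realize_genome",
    "make_translocation_pair",
    "make_insertion_pair",
    "simulate_reads",
    "write_fastq",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
#: background composition at GC 0.45 (A, C, G, T)
_BG_P = np.array([0.275, 0.225, 0.225, 0.275])

#: published sub-genomic circle sizes of molecule 2 are ~45 kb and ~67 kb;
#: the default R4 copy spacing (start-to-start) reproduces a 45,336 bp
#: sub-circle on the 112,834 bp molecule.
_R4_SPACING = 45_336


@dataclass(frozen=True)
class RepeatPlacement:
    """One planted repeat pair: family label, copy length, orientation and,
    optionally, fixed copy start positions (otherwise placed automatically)."""

    family: str
    length: int
    orientation: str  # direct | inverted
    start_a: int | None = None
    start_b: int | None = None
    spacing: int | None = None  # start-to-start distance copyA -> copyB


@dataclass(frozen=True)
class MoleculeSpec:
    name: str
    length: int
    repeats: tuple[RepeatPlacement, ...] = ()


@dataclass(frozen=True)
class GenomeProfile:
    name: str
    molecules: tuple[MoleculeSpec, ...]
    gc: float = 0.45

    def molecule(self, name: str) -> MoleculeSpec:
        for m in self.molecules:
            if m.name == name:
                return m
        raise KeyError(f"profile {self.name!r} has no molecule {name!r}")


@dataclass
class TruthSet:
    """Machine-readable truth for a realized genome / read set."""

    planted_pairs: list[RepeatPair] = field(default_factory=list)
    isoforms: dict[str, float] = field(default_factory=dict)
    junctions: list[dict] = field(default_factory=list)
    reads: list[dict] = field(default_factory=list)
    translocation: dict = field(default_factory=dict)


@dataclass(frozen=True)
class SimRead:
    id: str
    seq: str
    source_id: str
    start: int
    strand: str


@dataclass(frozen=True)
class ReadSimParams:
    """Long-read simulator settings.

    Lengths are lognormal(mu, sigma) in log-bp, clipped to
    ``[min_len, max_len]`` (exp(9.2) ~ 9.9 kb median by default — enough to
    span junction constructs without modelling a specific instrument).
    """

    coverage: float | None = 30.0
    n_reads: int | None = None
    length_mu: float = 9.2
    length_sigma: float = 0.4
    min_len: int = 2000
    max_len: int = 40_000
    sub_rate: float = 0.0
    indel_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for r in (self.sub_rate, self.indel_rate):
            if not 0.0 <= r <= 0.2:
                raise ValueError(f"error rates must be in [0, 0.2], got {r}")
        if self.coverage is None and self.n_reads is None:
            raise ValueError("one of coverage or n_reads is required")

    @property
    def mean_length(self) -> float:
        return math.exp(self.length_mu + self.length_sigma**2 / 2)


# ---------------------------------------------------------------------------
# profiles
# ---------------------------------------------------------------------------

_PROFILES: dict[str, list[tuple[str, int, list[tuple[str, int, str]]]]] = {
    # (molecule name, length bp, [(family, repeat length, orientation), ...])
    "groupA": [
        ("molecule 1a", 297_036, [("R1", 11_916, "inverted"), ("R2", 7_502, "direct")]),
        ("molecule 1b", 229_589, [("R2", 7_502, "direct")]),
        ("molecule 2", 112_834, [("R4", 1_589, "direct")]),
        ("molecule 3", 49_239, []),
    ],
    "groupB": [
        ("molecule 1", 284_385, [("R1", 11_916, "direct"), ("R3", 4_513, "direct")]),
        ("molecule 2", 113_443, [("R4", 1_589, "direct")]),
        ("molecule 3", 49_167, []),
    ],
    "clone10908": [
        ("molecule 1", 295_832, [("R1", 11_916, "direct"), ("R2", 7_502, "direct")]),
        ("molecule 2", 111_730, [("R4", 1_589, "direct")]),
        ("molecule 3", 49_265, []),
    ],
    "oka15": [
        ("molecule 1", 334_889, [("R1", 13_435, "direct"), ("R2", 7_076, "direct")]),
        ("molecule 2", 54_636, []),  # no R4 repeat in this mitogenome
        ("molecule 3", 49_277, []),
    ],
}


def make_profile(name: str, scale: float = 1.0) -> GenomeProfile:
    """Profile for a named architecture, optionally desk-scaled.

    ``scale`` in (0, 1] shrinks inter-feature spacers only — planted repeat
    lengths always stay at their published values, so length-based family
    matching behaves identically at any scale.
    """
    if name not in _PROFILES:
        raise KeyError(f"unknown profile {name!r}; choose from {sorted(_PROFILES)}")
    if not 0.0 < scale <= 1.0:
        raise ValueError(f"scale must be in (0, 1], got {scale}")
    molecules = []
    for mol_name, length, fams in _PROFILES[name]:
        feature_total = sum(2 * flen for _, flen, _ in fams)
        spacer_total = length - feature_total
        scaled_len = feature_total + round(scale * spacer_total)
        if scale == 1.0:
            scaled_len = length
        if scaled_len <= feature_total:
            raise ValueError(f"scale {scale} too small to fit features of {mol_name}")
        placements = []
        for fam, flen, orientation in fams:
            spacing = None
            if fam == "R4":
                spacing = flen + round(scale * (_R4_SPACING - flen))
            placements.append(RepeatPlacement(fam, flen, orientation, spacing=spacing))
        molecules.append(
            MoleculeSpec(name=mol_name, length=scaled_len, repeats=tuple(placements))
        )
    return GenomeProfile(name=name, molecules=tuple(molecules))


def single_repeat_profile(
    molecule_length: int,
    repeat_length: int,
    orientation: str,
    family: str = "custom",
    name: str = "custom",
    molecule_name: str = "molecule",
    spacing: int | None = None,
) -> GenomeProfile:
    """One circle with one planted repeat pair (fixture builder)."""
    return GenomeProfile(
        name=name,
        molecules=(
            MoleculeSpec(
                name=molecule_name,
                length=molecule_length,
                repeats=(
                    RepeatPlacement(family, repeat_length, orientation, spacing=spacing),
                ),
            ),
        ),
    )


# ---------------------------------------------------------------------------
# realization
# ---------------------------------------------------------------------------


def _random_bases(rng: np.random.Generator, n: int) -> np.ndarray:
    return _BASES[rng.choice(4, size=n, p=_BG_P)]


def _place_repeats(spec: MoleculeSpec) -> list[tuple[RepeatPlacement, int, int]]:
    """Deterministic non-overlapping copy positions for every placement."""
    L = spec.length
    placed: list[tuple[RepeatPlacement, int, int]] = []
    explicit = [p for p in spec.repeats if p.start_a is not None]
    auto = [p for p in spec.repeats if p.start_a is None]
    for p in explicit:
        placed.append((p, p.start_a, p.start_b))
    if auto:
        # lay copies out in the order A1, A2, ..., B1, B2, ... with equal
        # spacers; placements with a fixed spacing override copyB afterwards
        n_feat = 2 * len(auto)
        free = L - sum(2 * p.length for p in auto)
        if free < n_feat:
            raise ValueError(f"molecule {spec.name!r}: no room for planted repeats")
        spacer = free // (n_feat + 1)
        pos = spacer
        starts_a: dict[RepeatPlacement, int] = {}
        for p in auto:
            starts_a[p] = pos
            pos += p.length + spacer
        for p in auto:
            if p.spacing is not None:
                placed.append((p, starts_a[p], (starts_a[p] + p.spacing) % L))
            else:
                placed.append((p, starts_a[p], pos))
                pos += p.length + spacer
    # overlap check
    ivs = []
    for p, a, b in placed:
        ivs.append((a, p.length))
        ivs.append((b, p.length))
    for i, (s1, l1) in enumerate(ivs):
        for s2, l2 in ivs[i + 1 :]:
            if (s2 - s1) % L < l1 or (s1 - s2) % L < l2:
                raise ValueError(f"molecule {spec.name!r}: planted copies overlap")
    return placed


def _fix_boundary(arr: np.ndarray, pos: int, *forbidden: int,
                  rng: np.random.Generator) -> None:
    """Resample ``arr[pos]`` until it differs from every forbidden byte."""
    while any(arr[pos] == f for f in forbidden):
        arr[pos] = _random_bases(rng, 1)[0]


def realize_genome(
    profile: GenomeProfile,
    seed: int,
    divergence: float = 0.0,
) -> tuple[list[CircularSequence], TruthSet]:
    """Materialize a profile into sequences plus planted-repeat truth.

    Repeat copies are exact duplicates (identity 1.0) unless ``divergence``
    sets a per-base substitution rate on the second copy.  Deterministic
    under ``seed``.
    """
    rng = np.random.default_rng(seed)
    seqs: list[CircularSequence] = []
    truth = TruthSet()
    for spec in profile.molecules:
        L = spec.length
        arr = _random_bases(rng, L)
        placed = _place_repeats(spec)
        for p, a, b in placed:
            copy = _random_bases(rng, p.length)
            if divergence > 0:
                other = copy.copy()
                mut = np.flatnonzero(rng.random(p.length) < divergence)
                for i in mut:
                    choices = _BASES[_BASES != other[i]]
                    other[i] = rng.choice(choices)
            else:
                other = copy
            _write_mod(arr, a, copy)
            if p.orientation == "inverted":
                other = np.frombuffer(
                    revcomp(other.tobytes().decode()).encode(), dtype=np.uint8
                ).copy()
            _write_mod(arr, b, other)
        # enforce distinct junction contexts so exact matches end exactly
        # at the planted copy boundaries
        for p, a, b in placed:
            m = p.length
            if p.orientation == "direct":
                _fix_boundary(arr, (b - 1) % L, arr[(a - 1) % L], rng=rng)
                _fix_boundary(arr, (b + m) % L, arr[(a + m) % L], rng=rng)
            else:
                comp = {65: 84, 84: 65, 67: 71, 71: 67}
                _fix_boundary(arr, (b - 1) % L, comp[int(arr[(a + m) % L])], rng=rng)
                _fix_boundary(arr, (b + m) % L, comp[int(arr[(a - 1) % L])], rng=rng)
        mol_id = f"{profile.name}_{spec.name.replace(' ', '_')}"
        seqs.append(
            CircularSequence(
                id=mol_id,
                seq=arr.tobytes().decode(),
                topology="circular",
                molecule_name=spec.name,
            )
        )
        for p, a, b in placed:
            truth.planted_pairs.append(
                RepeatPair(
                    copyA=Interval(a % L, p.length, "+"),
                    copyB=Interval(
                        b % L, p.length, "-" if p.orientation == "inverted" else "+"
                    ),
                    orientation=p.orientation,
                    length=p.length,
                    identity=1.0 if divergence == 0 else 1.0 - divergence,
                    family=p.family,
                    molecule_id=mol_id,
                )
            )
    return seqs, truth


def _write_mod(arr: np.ndarray, start: int, data: np.ndarray) -> None:
    L = len(arr)
    start %= L
    end = start + len(data)
    if end <= L:
        arr[start:end] = data
    else:
        arr[start:] = data[: L - start]
        arr[: end - L] = data[L - start :]


# ---------------------------------------------------------------------------
# translocation / insertion fixtures
# ---------------------------------------------------------------------------


def make_translocation_pair(
    block_len: int = 774,
    flank_len: int = 40,
    seed: int = 0,
    molecule_length: int = 49_239,
) -> tuple[CircularSequence, CircularSequence, TruthSet]:
    """Two molecule-3-sized circles differing by one translocated block.

    Both molecules carry three copies of a short flank repeat ``F``; the
    translocatable block ``b`` sits between the first two ``F`` copies in A
    and between the last two in B::

        A = U F b F V F W
        B = U F V F b F W

    so each molecule has the block flanked by ``F`` on both sides, lengths
    are equal, and the move is explained by recombination between flank
    copies.  Boundary bases are resampled so exact matching ends exactly at
    the block/flank boundaries; all breakpoints are recorded in the truth.
    """
    rng = np.random.default_rng(seed)
    free = molecule_length - block_len - 3 * flank_len
    if free < 300:
        raise ValueError("molecule too small for block and flanks")
    len_u = round(free * 0.4)
    len_v = round(free * 0.3)
    len_w = free - len_u - len_v
    U = _random_bases(rng, len_u)
    V = _random_bases(rng, len_v)
    W = _random_bases(rng, len_w)
    F = _random_bases(rng, flank_len)
    b = _random_bases(rng, block_len)
    # distinct junction contexts (see module docstring): these keep the
    # maximal shared runs from extending past the intended boundaries
    _fix_boundary(b, 0, V[0], W[0], rng=rng)
    _fix_boundary(b, -1, U[-1], V[-1], rng=rng)
    seq_a = np.concatenate([U, F, b, F, V, F, W])
    seq_b = np.concatenate([U, F, V, F, b, F, W])
    a = CircularSequence("transA", seq_a.tobytes().decode(), "circular", "molecule 3")
    bmol = CircularSequence("transB", seq_b.tobytes().decode(), "circular", "molecule 3")
    truth = TruthSet(
        translocation={
            "block_length": block_len,
            "flank_length": flank_len,
            "block_a": (len_u + flank_len, block_len),
            "block_b": (len_u + flank_len + len_v + flank_len, block_len),
        }
    )
    return a, bmol, truth


def make_insertion_pair(
    block_len: int = 774,
    flank_len: int = 40,
    seed: int = 0,
    molecule_length: int = 111_730,
) -> tuple[CircularSequence, CircularSequence, TruthSet]:
    """A molecule-2-sized pair where B additionally carries the block.

    ``A = P F Q`` and ``B = P F b F Q``: the insertion adds the block plus
    one extra flank copy, so B is ``block_len + flank_len`` longer —
    mirroring the arrangement in which the inserted region makes the
    carrier molecule ~814 bp longer than its relatives.
    """
    rng = np.random.default_rng(seed)
    free = molecule_length - flank_len
    len_p = round(free * 0.5)
    len_q = free - len_p
    P = _random_bases(rng, len_p)
    Q = _random_bases(rng, len_q)
    F = _random_bases(rng, flank_len)
    b = _random_bases(rng, block_len)
    _fix_boundary(b, 0, Q[0], rng=rng)
    _fix_boundary(b, -1, P[-1], rng=rng)
    seq_a = np.concatenate([P, F, Q])
    seq_b = np.concatenate([P, F, b, F, Q])
    a = CircularSequence("insA", seq_a.tobytes().decode(), "circular", "molecule 2")
    bmol = CircularSequence("insB", seq_b.tobytes().decode(), "circular", "molecule 2")
    truth = TruthSet(
        translocation={
            "block_length": block_len,
            "flank_length": flank_len,
            "insertion_b": (len_p + flank_len, block_len + flank_len),
        }
    )
    return a, bmol, truth


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------


def simulate_reads(
    sources: list[tuple[CircularSequence, float]],
    params: ReadSimParams,
) -> tuple[list[SimRead], TruthSet]:
    """Draw long reads from a weighted mixture of circular templates.

    Start positions are uniform on the source circle (reads may wrap the
    origin); strands are uniform; substitution and indel errors are applied
    after extraction.  Per-read provenance goes into the returned truth.
    """
    abundances = np.array([ab for _, ab in sources], dtype=float)
    if not math.isclose(abundances.sum(), 1.0, abs_tol=1e-9):
        raise ValueError(f"abundances must sum to 1, got {abundances.sum()}")
    rng = np.random.default_rng(params.seed)
    min_source = min(len(s) for s, _ in sources)
    if params.min_len > min_source:
        raise ValueError(
            f"minimum read length {params.min_len} exceeds shortest template "
            f"({min_source} bp)"
        )
    if params.n_reads is not None:
        n = params.n_reads
    else:
        eff_len = sum(ab * len(s) for s, ab in sources)
        n = round(params.coverage * eff_len / params.mean_length)
    reads: list[SimRead] = []
    truth = TruthSet(isoforms={s.id: ab for s, ab in sources})
    for i in range(n):
        src_idx = rng.choice(len(sources), p=abundances)
        src, _ = sources[src_idx]
        L = len(src)
        length = int(
            np.clip(
                rng.lognormal(params.length_mu, params.length_sigma),
                params.min_len,
                min(params.max_len, L),
            )
        )
        start = int(rng.integers(0, L))
        strand = "+" if rng.random() < 0.5 else "-"
        raw = (src.doubled())[start : start + length]
        if strand == "-":
            raw = revcomp(raw)
        seq = _apply_errors(raw, params, rng)
        rid = f"read{i:06d}"
        reads.append(SimRead(id=rid, seq=seq, source_id=src.id, start=start, strand=strand))
        truth.reads.append(
            {
                "id": rid,
                "source": src.id,
                "start": start,
                "strand": strand,
                "length": length,
            }
        )
    return reads, truth


def _apply_errors(seq: str, params: ReadSimParams, rng: np.random.Generator) -> str:
    if params.sub_rate == 0 and params.indel_rate == 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    if params.sub_rate > 0:
        mut = np.flatnonzero(rng.random(len(arr)) < params.sub_rate)
        for i in mut:
            choices = _BASES[_BASES != arr[i]]
            arr[i] = rng.choice(choices)
    if params.indel_rate == 0:
        return arr.tobytes().decode()
    out = bytearray()
    half = params.indel_rate / 2
    for byte in arr:
        r = rng.random()
        if r < half:
            continue  # deletion
        out.append(byte)
        if r < params.indel_rate:
            out.append(int(rng.choice(_BASES)))  # insertion
    if not out:
        out.extend(arr.tobytes())
    return bytes(out).decode()


def write_fastq(path, reads: list[SimRead]) -> None:
    """Write simulated reads as FASTQ with a constant quality string."""
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id} source={r.source_id} start={r.start} strand={r.strand}\n")
            fh.write(r.seq + "\n+\n" + "I" * len(r.seq) + "\n")
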