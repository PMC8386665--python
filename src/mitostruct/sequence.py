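"""Sequence model and circular-coordinate arithmetic.

Every module in the package works with :class:`CircularSequence` and
:class:`Interval`.  Coordinates are 0-based, half-open, and — on circular
molecules — interpreted modulo the molecule length.  Linear molecules reject
any request that would wrap around the origin.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = [
    "ALPHABET",
    "CircularSequence",
    "Interval",
    "TopologyError",
    "revcomp",
    "rotate",
    "subsequence",
]

ALPHABET = frozenset("ACGTN")

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMP)[::-1]


class TopologyError(ValueError):
    """Raised when a wrap-around operation is requested on a linear molecule."""


@dataclass(frozen=True)
class Interval:
    """Half-open interval ``[start, start+length)`` on a parent molecule.

    ``start`` is 0-based; on circular parents the interval may extend past
    the origin (``start + length > parent length``), in which case positions
    are taken modulo the parent length.
    """

    start: int
    length: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.length < 1:
            raise ValueError(f"interval length must be >= 1, got {self.length}")
        if self.start < 0:
            raise ValueError(f"interval start must be >= 0, got {self.start}")

    def end(self, parent_length: int | None = None) -> int:
        """Exclusive end; reduced modulo ``parent_length`` when given."""
        e = self.start + self.length
        return e % parent_length if parent_length else e

    def wraps(self, parent_length: int) -> bool:
        return self.start + self.length > parent_length


@dataclass(frozen=True)
class CircularSequence:
    """A mitogenome molecule with an explicit topology flag.

    Parameters
    ----------
    id:
        Record identifier (FASTA id).
    seq:
        Uppercase DNA over ``{A, C, G, T, N}``.
    topology:
        ``"circular"`` or ``"linear"``.
    molecule_name:
        Optional human label such as ``"molecule 1a"``.
    """

    id: str
    seq: str
    topology: str = "linear"
    molecule_name: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.topology not in ("circular", "linear"):
            raise ValueError(f"topology must be circular|linear, got {self.topology!r}")
        if len(self.seq) < 1:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(self.seq) - ALPHABET
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains illegal characters: {sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def is_circular(self) -> bool:
        return self.topology == "circular"

    def doubled(self) -> str:
        """The sequence concatenated with itself (used for wrap-aware scans)."""
        return self.seq + self.seq


def subsequence(s: CircularSequence, iv: Interval) -> str:
    """Extract ``iv`` from ``s``; ``-`` strand returns the reverse complement.

    Wrap-around extraction is only allowed on circular molecules.
    """
    L = len(s)
    if iv.start >= L:
        raise ValueError(f"interval start {iv.start} out of range for length {L}")
    if iv.length > L:
        raise ValueError(f"interval length {iv.length} exceeds molecule length {L}")
    if iv.wraps(L):
        if not s.is_circular:
            raise TopologyError(
                f"interval [{iv.start}, {iv.start + iv.length}) wraps the origin "
                f"of linear sequence {s.id!r}"
            )
        out = s.doubled()[iv.start : iv.start + iv.length]
    else:
        out = s.seq[iv.start : iv.start + iv.length]
    return revcomp(out) if iv.strand == "-" else out


def rotate(s: CircularSequence, new_origin: int) -> CircularSequence:
    """Return ``s`` rotated so that position ``new_origin`` becomes position 0."""
    if not s.is_circular:
        raise TopologyError(f"cannot rotate linear sequence {s.id!r}")
    k = new_origin % len(s)
    return replace(s, seq=s.seq[k:] + s.seq[:k])
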