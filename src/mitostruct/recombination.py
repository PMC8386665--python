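"""Enumeration of homologous-recombination products on circular molecules.

A single crossover at a *direct* repeat pair splits the parent circle into
two sub-genomic circles whose lengths sum to the parent length; each child
keeps exactly one full repeat copy.  A crossover at an *inverted* pair
yields one equal-length isoform with the inter-repeat segment
reverse-complemented ("flip-flop" recombination).  Only single-crossover
products are enumerated: recombination at large repeats is recurrent and
reversible, and observed sub-genomic circles are single-event products; no
master-circle reconstruction is attempted.

Each product records the crossover breakpoints (placed at the repeat-copy
midpoints — for identical copies every crossover position inside the repeat
yields the same product sequence) from which junction constructs for
reverse read mapping are built.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .repeats import RepeatPair
from .sequence import CircularSequence, Interval, TopologyError, revcomp, subsequence

__all__ = [
    "IsoformProduct",
    "Junction",
    "canonical_circle",
    "enumerate_products",
    "enumerate_all",
    "predict_junctions",
]


@dataclass(frozen=True)
class Junction:
    """A breakpoint with ``w`` bp of flanking sequence on each side.

    The construct (``left + right``, length 2w) is what long reads are
    mapped against; the junction is *novel* iff the construct occurs on
    neither strand of the (doubled) parent sequence.
    """

    id: str
    left: str
    right: str
    position: int  # breakpoint coordinate on the product circle
    novel: bool
    provenance: str = ""
    #: length of the repeat copy the breakpoint sits inside (0 for a plain
    #: breakpoint); support counting widens its anchor requirement by half
    #: this amount so anchors clear the repeat ends
    repeat_length: int = 0

    @property
    def construct(self) -> str:
        return self.left + self.right

    @property
    def midpoint(self) -> int:
        """Breakpoint offset within the construct (== len(left))."""
        return len(self.left)


@dataclass(frozen=True)
class IsoformProduct:
    """One recombination product of a parent circle.

    ``composition`` lists parent intervals in product order; ``-`` strand
    intervals contribute their reverse complement.  ``breakpoints`` are the
    crossover positions in product coordinates (repeat-copy midpoints).
    """

    id: str
    product_type: str  # subgenomic_circle | inversion_isoform
    parent: CircularSequence
    composition: tuple[Interval, ...]
    breakpoints: tuple[int, ...]
    repeat_length: int
    seq: str = field(repr=False, default="")

    def __post_init__(self) -> None:
        if self.product_type not in ("subgenomic_circle", "inversion_isoform"):
            raise ValueError(f"bad product_type {self.product_type!r}")
        if not self.seq:
            built = "".join(subsequence(self.parent, iv) for iv in self.composition)
            object.__setattr__(self, "seq", built)

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def length(self) -> int:
        return len(self.seq)

    def as_sequence(self) -> CircularSequence:
        return CircularSequence(id=self.id, seq=self.seq, topology="circular")


def _check_circular(s: CircularSequence) -> None:
    if not s.is_circular:
        raise TopologyError(
            f"recombination products are only enumerated on circles; {s.id!r} is linear"
        )


def _overlap_mod(iv1: Interval, iv2: Interval, L: int) -> bool:
    off = (iv2.start - iv1.start) % L
    if off < iv1.length:
        return True
    off2 = (iv1.start - iv2.start) % L
    return off2 < iv2.length


def enumerate_products(s: CircularSequence, pair: RepeatPair) -> list[IsoformProduct]:
    """Products of one crossover at ``pair`` on circle ``s``.

    Direct pair -> exactly two sub-genomic circles; inverted pair -> exactly
    one inversion isoform.  All lengths are computed modulo the parent
    length.
    """
    _check_circular(s)
    L = len(s)
    a0, b0, m = pair.copyA.start, pair.copyB.start, pair.length
    if pair.orientation == "direct":
        d = (b0 - a0) % L
        arc1 = (d - m) % L  # copyA end -> copyB start
        arc2 = (L - d - m) % L  # copyB end -> copyA start
        products = []
        for idx, (copy_start, arc_start, arc_len) in enumerate(
            [(a0, (a0 + m) % L, arc1), (b0, (b0 + m) % L, arc2)], start=1
        ):
            comp = [Interval(copy_start, m, "+")]
            if arc_len > 0:
                comp.append(Interval(arc_start, arc_len, "+"))
            products.append(
                IsoformProduct(
                    id=f"{s.id}|sub{idx}@{a0}-{b0}",
                    product_type="subgenomic_circle",
                    parent=s,
                    composition=tuple(comp),
                    breakpoints=(m // 2,),
                    repeat_length=m,
                )
            )
        return products
    # inverted pair: invert the segment between the two crossover points
    c1 = (a0 + m // 2) % L
    c2 = (b0 + m // 2) % L
    len_y = (c2 - c1) % L  # segment to be reverse-complemented
    len_x = L - len_y
    comp = (Interval(c2, len_x, "+"), Interval(c1, len_y, "-"))
    return [
        IsoformProduct(
            id=f"{s.id}|inv@{a0}-{b0}",
            product_type="inversion_isoform",
            parent=s,
            composition=comp,
            breakpoints=(0, len_x),
            repeat_length=m,
        )
    ]


def enumerate_all(s: CircularSequence, pairs: list[RepeatPair]) -> list[IsoformProduct]:
    """Single-event products over all pairs, deduplicated as canonical circles.

    Pairs must be pairwise non-overlapping (recombination at overlapping
    repeat configurations is not supported).
    """
    _check_circular(s)
    L = len(s)
    for i, p in enumerate(pairs):
        for q in pairs[i + 1 :]:
            for iv1 in (p.copyA, p.copyB):
                for iv2 in (q.copyA, q.copyB):
                    if _overlap_mod(iv1, iv2, L):
                        raise ValueError(
                            f"overlapping repeat pairs on {s.id!r}: "
                            f"{iv1} vs {iv2} — unsupported configuration"
                        )
    out: list[IsoformProduct] = []
    seen: set[str] = set()
    for pair in pairs:
        for prod in enumerate_products(s, pair):
            key = canonical_circle(prod.seq)
            if key not in seen:
                seen.add(key)
                out.append(prod)
    return out


def predict_junctions(product: IsoformProduct, w: int = 1000) -> list[Junction]:
    """Junction constructs (w bp flanks) at each crossover of ``product``.

    Novelty is checked against both strands of the doubled parent: a
    sub-genomic circle has exactly one novel junction and an inversion
    isoform two, *provided* ``w`` reaches past the repeat copy ends
    (``2w > repeat length``); with shorter flanks the construct lies within
    the repeat and also occurs in the parent.
    """
    n = len(product)
    if 2 * w > n:
        raise ValueError(
            f"flank width {w} too large: construct 2w={2 * w} exceeds product "
            f"length {n}"
        )
    circle = product.as_sequence()
    parent_fwd = product.parent.doubled()
    parent_rev = revcomp(parent_fwd)
    out = []
    for idx, p in enumerate(product.breakpoints, start=1):
        left = subsequence(circle, Interval((p - w) % n, w, "+"))
        right = subsequence(circle, Interval(p % n, w, "+"))
        construct = left + right
        novel = construct not in parent_fwd and construct not in parent_rev
        out.append(
            Junction(
                id=f"{product.id}|j{idx}",
                left=left,
                right=right,
                position=p % n,
                novel=novel,
                provenance=f"product={product.id};breakpoint={p % n};w={w}",
                repeat_length=product.repeat_length,
            )
        )
    return out


def canonical_circle(seq: str) -> str:
    """Canonical form of a circular sequence: the lexicographically minimal
    rotation of whichever of (seq, revcomp(seq)) is smaller under rotation.

    Used to deduplicate products across tie-breaks and rotations.
    """
    return min(_min_rotation(seq), _min_rotation(revcomp(seq)))


def _min_rotation(s: str) -> str:
    """Booth's least-rotation algorithm, O(n)."""
    ss = s + s
    n = len(ss)
    f = [-1] * n
    k = 0
    for j in range(1, n):
        sj = ss[j]
        i = f[j - k - 1]
        while i != -1 and sj != ss[k + i + 1]:
            if sj < ss[k + i + 1]:
                k = j - i - 1
            i = f[i]
        if sj != ss[k + i + 1]:
            if sj < ss[k]:
                k = j
            f[j - k] = -1
        else:
            f[j - k] = i + 1
    return ss[k : k + len(s)]
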