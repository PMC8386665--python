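"""In silico PCR on circular templates and mtDNA/cytoplasm type calls.

Potato mtDNA types are distinguished by a marker PCR at the region between a
cob pseudogene fragment and rps10: a ~2.4 kb product is called α, ~1.6 kb
β, and no product γ.  Combined with the chloroplast type (T/S/W/A) this
yields the cytoplasm label used in potato breeding (e.g. W/γ, associated
with male sterility).  The primer sequences themselves are supplied by the
user (they are not part of this package); the machinery — site matching
with a mismatch budget and a 3'-exact requirement, convergent-pair product
enumeration modulo the circle length, and the size-class decision — is
implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import yaml

from .sequence import CircularSequence, Interval, revcomp, subsequence

__all__ = [
    "PrimerPair",
    "Amplicon",
    "MtDNATypeCall",
    "KNOWN_CYTOPLASM_TYPES",
    "find_sites",
    "amplify",
    "call_type",
    "combine_cytoplasm",
    "read_primer_config",
]

#: product size classes (bp) of the mtDNA-type marker PCR
ALPHA_PRODUCT = 2400
BETA_PRODUCT = 1600

#: cytoplasm (cpDNA/mtDNA) combinations observed in potato panels
KNOWN_CYTOPLASM_TYPES = frozenset({"T/β", "S/β", "W/α", "W/γ"})

_GREEK = {"alpha": "α", "beta": "β", "gamma": "γ"}


@dataclass(frozen=True)
class PrimerPair:
    name: str
    fwd: str
    rev: str
    max_mismatches: int = 2
    max_product: int = 5000

    def __post_init__(self) -> None:
        for p in (self.fwd, self.rev):
            if not 15 <= len(p) <= 35:
                raise ValueError(f"primer length must be 15-35 nt, got {len(p)}")
            if "N" in p or set(p) - set("ACGT"):
                raise ValueError(f"primer {p!r} must be over ACGT (no N)")


@dataclass(frozen=True)
class Amplicon:
    template_id: str
    fwd_site: Interval
    rev_site: Interval
    product_length: int
    product_seq: str


@dataclass(frozen=True)
class MtDNATypeCall:
    mt_type: str  # alpha | beta | gamma | unknown
    evidence: tuple[Amplicon, ...]
    cp_type: str | None = None
    cytoplasm: str | None = None


def find_sites(
    template: CircularSequence, primer: str, max_mismatches: int = 2
) -> list[Interval]:
    """All primer binding sites on both strands (circular wrap included).

    A site must match with at most ``max_mismatches`` and the 3'-terminal
    base of the primer must match exactly.  Returned intervals are in
    forward template coordinates; strand ``+`` means the primer anneals to
    the reverse complement strand and extends rightward (its 3' end at the
    interval end), strand ``-`` the opposite.
    """
    primer = primer.upper()
    m = len(primer)
    L = len(template)
    if m > L:
        return []
    scan = template.doubled() if template.is_circular else template.seq
    limit = L if template.is_circular else L - m + 1
    sites: list[Interval] = []
    parr = np.frombuffer(primer.encode(), dtype=np.uint8)
    sarr = np.frombuffer(scan.encode(), dtype=np.uint8)
    n = len(sarr) - m + 1
    mism = np.zeros(n, dtype=np.int32)
    for j in range(m):
        mism += sarr[j : j + n] != parr[j]
    # forward-strand sites: 3' end is the last primer base
    ok = (mism[:limit] <= max_mismatches) & (
        sarr[m - 1 : m - 1 + limit] == parr[m - 1]
    )
    for pos in np.flatnonzero(ok):
        sites.append(Interval(int(pos), m, "+"))
    # reverse-strand sites: primer matches revcomp; on the forward template
    # that is revcomp(primer), whose first base is the primer's 3' end
    rc = revcomp(primer)
    rarr = np.frombuffer(rc.encode(), dtype=np.uint8)
    mism = np.zeros(n, dtype=np.int32)
    for j in range(m):
        mism += sarr[j : j + n] != rarr[j]
    ok = (mism[:limit] <= max_mismatches) & (sarr[:limit] == rarr[0])
    for pos in np.flatnonzero(ok):
        sites.append(Interval(int(pos), m, "-"))
    sites.sort(key=lambda iv: (iv.start, iv.strand))
    return sites


def amplify(template: CircularSequence, pair: PrimerPair) -> list[Amplicon]:
    """All products of convergent fwd/rev site combinations.

    The product runs from the forward site's 5' end to the reverse site's
    5' end (measured modulo the circle length, in the direction the forward
    primer extends) and must not exceed ``max_product``.
    """
    L = len(template)
    fwd_sites = [
        iv for iv in find_sites(template, pair.fwd, pair.max_mismatches) if iv.strand == "+"
    ]
    rev_sites = [
        iv for iv in find_sites(template, pair.rev, pair.max_mismatches) if iv.strand == "-"
    ]
    out: list[Amplicon] = []
    for f in fwd_sites:
        for r in rev_sites:
            span = (r.start + r.length - f.start) % L if template.is_circular else (
                r.start + r.length - f.start
            )
            if span < f.length + r.length:
                continue  # sites overlap or diverge
            if span > pair.max_product:
                continue
            product = subsequence(template, Interval(f.start, span, "+"))
            out.append(
                Amplicon(
                    template_id=template.id,
                    fwd_site=f,
                    rev_site=r,
                    product_length=span,
                    product_seq=product,
                )
            )
    out.sort(key=lambda a: (a.product_length, a.fwd_site.start))
    return out


def call_type(amplicons: list[Amplicon], tolerance: float = 0.15) -> MtDNATypeCall:
    """mtDNA type from marker-PCR product sizes.

    No product -> gamma; a product within ``tolerance`` of 2,400 bp ->
    alpha; within tolerance of 1,600 bp -> beta; anything else — or
    products falling in two different classes — is unknown (with all
    products reported as evidence).
    """
    if not amplicons:
        return MtDNATypeCall(mt_type="gamma", evidence=())
    classes = set()
    for a in amplicons:
        if abs(a.product_length - ALPHA_PRODUCT) <= tolerance * ALPHA_PRODUCT:
            classes.add("alpha")
        elif abs(a.product_length - BETA_PRODUCT) <= tolerance * BETA_PRODUCT:
            classes.add("beta")
        else:
            classes.add("unknown")
    if len(classes) == 1 and "unknown" not in classes:
        return MtDNATypeCall(mt_type=classes.pop(), evidence=tuple(amplicons))
    return MtDNATypeCall(mt_type="unknown", evidence=tuple(amplicons))


def combine_cytoplasm(mt_type: str, cp_type: str) -> tuple[str, bool]:
    """Combined cytoplasm label ``"cp/mt"`` and whether it is a combination
    observed in potato (T/β, S/β, W/α, W/γ)."""
    if mt_type in ("unknown", None) or cp_type in (None, "", "unknown"):
        return "unknown", False
    label = f"{cp_type}/{_GREEK.get(mt_type, mt_type)}"
    return label, label in KNOWN_CYTOPLASM_TYPES


def read_primer_config(path) -> list[PrimerPair]:
    """Primer pairs from a YAML (list of mappings) or TSV file."""
    text = open(path).read()
    if str(path).endswith((".yaml", ".yml")):
        entries = yaml.safe_load(text)
    else:
        entries = []
        for line in text.splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            entry = {"name": parts[0], "fwd": parts[1], "rev": parts[2]}
            if len(parts) > 3:
                entry["max_mismatches"] = int(parts[3])
            if len(parts) > 4:
                entry["max_product"] = int(parts[4])
            entries.append(entry)
    return [PrimerPair(**e) for e in entries]
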