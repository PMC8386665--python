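"""Gene-content accounting for mitogenomes.

Covers ORF discovery on circles (six frames, origin-spanning frames handled
on the doubled sequence), internal-stop checks, per-category gene counts
from annotations, and presence/absence matrices across genomes.  The
category lexicon is the conserved potato mtDNA gene complement: ATP
synthases, NADH dehydrogenases, ribosomal proteins, cytochrome c biogenesis
genes, oxidases, succinate dehydrogenases, cob, matR, mttB, rRNAs, tRNAs,
plus ORFs, plastid-derived genes and Ψ-prefixed pseudogene fragments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .fileio import GffFeature
from .sequence import CircularSequence, Interval, revcomp

__all__ = [
    "CATEGORIES",
    "CONSERVED_GENES",
    "PHYLOGENY_MARKER_GENES",
    "PLASTID_DERIVED_GENES",
    "GeneAnnotation",
    "Orf",
    "InventoryReport",
    "annotation_from_gff",
    "find_orfs",
    "check_internal_stops",
    "summarize",
    "presence_absence",
    "group_specific",
]

CATEGORIES = (
    "atp",
    "nad",
    "rps_rpl",
    "ccm",
    "cox",
    "sdh",
    "cob",
    "matR",
    "mttB",
    "rRNA",
    "tRNA",
    "orf",
    "plastid_derived",
    "pseudo",
)

#: genes of plastidial origin found integrated in these mitogenomes
PLASTID_DERIVED_GENES = frozenset({"petA", "petG", "petL", "psbJ", "psbL", "rpl23"})

#: the conserved protein-coding/RNA gene complement common to potato mtDNA:
#: 5 atp, 9 nad, 11 ribosomal proteins, 4 ccm, 3 cox, 2 sdh, cob, matR,
#: mttB, 3 rRNAs and 22 tRNAs (tRNA ids vary per genome and are supplied by
#: annotations; the named set below lists the invariant genes)
CONSERVED_GENES: dict[str, tuple[str, ...]] = {
    "atp": ("atp1", "atp4", "atp6", "atp8", "atp9"),
    "nad": ("nad1", "nad2", "nad3", "nad4", "nad4L", "nad5", "nad6", "nad7", "nad9"),
    "rps_rpl": (
        "rps1",
        "rps3",
        "rps4",
        "rps10",
        "rps12",
        "rps13",
        "rps19",
        "rpl2",
        "rpl5",
        "rpl10",
        "rpl16",
    ),
    "ccm": ("ccmB", "ccmC", "ccmFC", "ccmFN"),
    "cox": ("cox1", "cox2", "cox3"),
    "sdh": ("sdh3", "sdh4"),
    "cob": ("cob",),
    "matR": ("matR",),
    "mttB": ("mttB",),
    "rRNA": ("rrn5", "rrn18", "rrn26"),
}

#: the 33 protein-coding genes common enough across published potato
#: mitogenomes to serve as the concatenated phylogenetic marker set
PHYLOGENY_MARKER_GENES: tuple[str, ...] = (
    "atp1", "atp4", "atp6", "atp8", "atp9",
    "ccmB", "ccmC", "ccmFc", "ccmFn",
    "cob", "cox1", "cox2", "cox3",
    "matR", "mttB",
    "nad3", "nad4L", "nad6", "nad7", "nad9",
    "rpl10", "rpl16", "rpl2", "rpl5",
    "rps1", "rps10", "rps12", "rps13", "rps19", "rps3", "rps4",
    "sdh3", "sdh4",
)

_STOPS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class GeneAnnotation:
    gene_id: str
    category: str
    iv: Interval
    molecule_id: str
    pseudo: bool = False

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r} for {self.gene_id!r}")


@dataclass(frozen=True)
class Orf:
    iv: Interval
    strand: str
    length_codons: int
    has_internal_stop: bool = False


@dataclass(frozen=True)
class InventoryReport:
    counts: dict[str, int]
    orfs: tuple[Orf, ...] = ()
    genome_id: str = ""


def categorize(gene_id: str) -> str:
    """Category of a gene id per the fixed lexicon; raises on unknown ids."""
    name = gene_id
    pseudo = name.startswith("Ψ") or name.lower().startswith("psi-")
    if pseudo:
        return "pseudo"
    if name in PLASTID_DERIVED_GENES:
        return "plastid_derived"
    lower = name.lower()
    if lower.startswith("atp"):
        return "atp"
    if lower.startswith("nad"):
        return "nad"
    if lower.startswith(("rps", "rpl")):
        return "rps_rpl"
    if lower.startswith("ccm"):
        return "ccm"
    if lower.startswith("cox"):
        return "cox"
    if lower.startswith("sdh"):
        return "sdh"
    if lower == "cob":
        return "cob"
    if lower == "matr":
        return "matR"
    if lower == "mttb":
        return "mttB"
    if lower.startswith("rrn") or "rrna" in lower:
        return "rRNA"
    if lower.startswith("trn"):
        return "tRNA"
    if lower.startswith("orf"):
        return "orf"
    raise KeyError(f"cannot categorize gene id {gene_id!r}; supply a category")


def annotation_from_gff(
    feats: list[GffFeature], categories: dict[str, str] | None = None
) -> list[GeneAnnotation]:
    """GFF features (type gene/mRNA/tRNA/rRNA/pseudogene) to annotations.

    ``categories`` may supply categories for ids the lexicon cannot guess.
    """
    categories = categories or {}
    out = []
    unknown = []
    for f in feats:
        if f.ftype not in ("gene", "mRNA", "tRNA", "rRNA", "pseudogene"):
            continue
        gid = f.id or f.attributes.get("Name", "?")
        pseudo = f.ftype == "pseudogene" or gid.startswith("Ψ")
        try:
            cat = categories.get(gid) or ("pseudo" if pseudo else categorize(gid))
        except KeyError:
            unknown.append(gid)
            continue
        out.append(
            GeneAnnotation(
                gene_id=gid, category=cat, iv=f.iv, molecule_id=f.seqid, pseudo=pseudo
            )
        )
    if unknown:
        raise KeyError(f"cannot categorize gene ids: {unknown!r}")
    return out


# ---------------------------------------------------------------------------
# ORFs
# ---------------------------------------------------------------------------


def find_orfs(
    s: CircularSequence,
    min_codons: int = 100,
    start_codons: tuple[str, ...] = ("ATG",),
) -> list[Orf]:
    """ATG-initiated, stop-terminated ORFs of > ``min_codons`` codons.

    Both strands and all six frames are scanned; circular sequences are
    scanned across the origin on the doubled sequence with duplicates
    removed modulo the length.  Codon counts exclude the stop codon; the
    ORF interval includes it.  Per frame, the first start after the
    previous stop opens the ORF (the maximal ATG-initiated form).
    """
    L = len(s)
    out: list[Orf] = []
    seen: set[tuple[int, str, int]] = set()
    for strand in ("+", "-"):
        scan = s.seq if strand == "+" else revcomp(s.seq)
        if s.is_circular:
            scan = scan + scan
        for frame in range(3):
            for pos, n_codons in _frame_orfs(scan, frame, min_codons, start_codons):
                if s.is_circular and pos >= L:
                    continue  # image of an ORF already reported
                iv_len = 3 * (n_codons + 1)
                if iv_len > L:
                    continue
                if strand == "+":
                    start = pos % L
                else:
                    start = (len(s.seq) - ((pos % L) + iv_len)) % L if s.is_circular else (
                        L - pos - iv_len
                    )
                key = (start, strand, n_codons)
                if key in seen:
                    continue
                seen.add(key)
                out.append(
                    Orf(
                        iv=Interval(start % L, iv_len, strand),
                        strand=strand,
                        length_codons=n_codons,
                    )
                )
    out.sort(key=lambda o: (o.iv.start, o.strand))
    return out


def _frame_orfs(
    scan: str, frame: int, min_codons: int, start_codons: tuple[str, ...]
) -> list[tuple[int, int]]:
    """(start position, codon count) for closed ORFs in one frame of a
    linear scan string."""
    out = []
    open_start = None
    for i in range(frame, len(scan) - 2, 3):
        codon = scan[i : i + 3]
        if codon in _STOPS:
            if open_start is not None:
                n = (i - open_start) // 3
                if n > min_codons:
                    out.append((open_start, n))
                open_start = None
        elif open_start is None and codon in start_codons:
            open_start = i
    return out


def check_internal_stops(seq: str, frame: int = 0) -> tuple[bool, list[int]]:
    """True (with positions) iff a stop codon occurs before the final codon
    of the in-frame sequence."""
    coding = seq[frame:].upper()
    if len(coding) % 3 != 0:
        raise ValueError(f"in-frame sequence length {len(coding)} not divisible by 3")
    positions = [
        i
        for i in range(0, len(coding) - 3, 3)
        if coding[i : i + 3] in _STOPS
    ]
    return bool(positions), positions


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------


def summarize(annotations: list[GeneAnnotation], genome_id: str = "") -> InventoryReport:
    """Per-category counts; pseudogenes count under 'pseudo' only."""
    counts = {c: 0 for c in CATEGORIES}
    for a in annotations:
        cat = "pseudo" if a.pseudo else a.category
        counts[cat] += 1
    return InventoryReport(counts=counts, genome_id=genome_id)


def presence_absence(inventories: dict[str, list[str]]) -> pd.DataFrame:
    """Boolean gene/ORF-by-genome matrix from per-genome id lists."""
    if len(inventories) == 0:
        raise ValueError("at least one genome is required")
    genomes = list(inventories)
    if len(set(genomes)) != len(genomes):
        raise ValueError("duplicate genome ids")
    all_ids = sorted(set().union(*[set(v) for v in inventories.values()]))
    data = {g: [i in set(ids) for i in all_ids] for g, ids in inventories.items()}
    return pd.DataFrame(data, index=all_ids)


def group_specific(
    matrix: pd.DataFrame, groups: dict[str, list[str]]
) -> dict[str, list[str]]:
    """Ids restricted to a proper subset of the declared groups.

    A gene qualifies when it is present in *every* genome of the groups
    where it occurs and absent from all others (partial presence within a
    group disqualifies it).  Keys of the result are '+'-joined group names,
    so an id found in two groups only (e.g. a CMS-candidate ORF shared by
    one clade and one outlier clone) is reported under their joint label.
    """
    out: dict[str, list[str]] = {}
    for gene in matrix.index:
        present: list[str] = []
        partial = False
        for gname, members in groups.items():
            inside = matrix.loc[gene, members]
            if inside.all():
                present.append(gname)
            elif inside.any():
                partial = True
        if partial or not present or len(present) == len(groups):
            continue
        label = "+".join(sorted(present))
        out.setdefault(label, []).append(gene)
    return out
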