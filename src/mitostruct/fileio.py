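"""Readers and writers for the external formats the pipeline touches.

FASTA goes through Biopython.  Circular topology is self-described by a
``circular=true`` token in the FASTA header (absent token means linear).
GFF3 (1-based, inclusive) is converted to the internal 0-based half-open
convention on read and back on write.  PAF rows are exposed as generic
alignment records for junction validation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .sequence import ALPHABET, CircularSequence, Interval

__all__ = [
    "FormatError",
    "GffFeature",
    "PafRecord",
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "write_gff3",
    "read_paf",
    "write_tsv_report",
    "write_json_report",
]


class FormatError(ValueError):
    """Malformed input file; the message names the offending record/line."""


def _parse_header_topology(description: str) -> str:
    for token in description.split():
        if token.lower() == "circular=true":
            return "circular"
        if token.lower() == "circular=false":
            return "linear"
    return "linear"


def read_fasta(path: str | Path) -> list[CircularSequence]:
    """Read FASTA into :class:`CircularSequence` records.

    Topology is parsed from a ``circular=true|false`` header token (default
    linear); sequences are uppercased; ``N`` is allowed.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: empty or invalid FASTA")
    out: list[CircularSequence] = []
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        bad = set(seq) - ALPHABET
        if bad:
            raise FormatError(
                f"{path}: record {rec.id!r} has illegal characters {sorted(bad)!r}"
            )
        try:
            cs = CircularSequence(
                id=rec.id,
                seq=seq,
                topology=_parse_header_topology(rec.description),
                molecule_name=_parse_molecule_name(rec.description),
            )
        except ValueError as exc:
            raise FormatError(f"{path}: record {rec.id!r}: {exc}") from exc
        out.append(cs)
    return out


def _parse_molecule_name(description: str) -> str | None:
    for token in description.split():
        if token.startswith("molecule="):
            return token.split("=", 1)[1].replace("_", " ")
    return None


def write_fasta(path: str | Path, seqs: Iterable[CircularSequence], width: int = 70) -> None:
    records = []
    for s in seqs:
        desc = f"circular={'true' if s.is_circular else 'false'}"
        if s.molecule_name:
            desc += f" molecule={s.molecule_name.replace(' ', '_')}"
        records.append(SeqRecord(Seq(s.seq), id=s.id, description=desc))
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


@dataclass(frozen=True)
class GffFeature:
    """One GFF3 feature with its interval in internal 0-based convention."""

    seqid: str
    source: str
    ftype: str
    iv: Interval
    score: str
    attributes: dict[str, str]

    @property
    def id(self) -> str | None:
        return self.attributes.get("ID")


def read_gff3(path: str | Path) -> list[GffFeature]:
    """Parse GFF3; 1-based inclusive coordinates become 0-based half-open."""
    feats: list[GffFeature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 columns, got {len(cols)}")
            seqid, source, ftype, start, end, score, strand, _phase, attrs = cols
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start_i < 1 or end_i < start_i:
                raise FormatError(f"{path}:{lineno}: bad coordinate range {start}-{end}")
            if strand not in ("+", "-", "."):
                raise FormatError(f"{path}:{lineno}: bad strand {strand!r}")
            attributes = {}
            for pair in attrs.split(";"):
                if pair and "=" in pair:
                    k, v = pair.split("=", 1)
                    attributes[k.strip()] = v.strip()
            feats.append(
                GffFeature(
                    seqid=seqid,
                    source=source,
                    ftype=ftype,
                    iv=Interval(
                        start=start_i - 1,
                        length=end_i - start_i + 1,
                        strand=strand if strand in ("+", "-") else "+",
                    ),
                    score=score,
                    attributes=attributes,
                )
            )
    return feats


def write_gff3(path: str | Path, feats: Sequence[GffFeature]) -> None:
    """Write features back to GFF3 (internal 0-based half-open -> 1-based)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in feats:
            attrs = ";".join(f"{k}={v}" for k, v in f.attributes.items())
            fh.write(
                "\t".join(
                    [
                        f.seqid,
                        f.source,
                        f.ftype,
                        str(f.iv.start + 1),
                        str(f.iv.start + f.iv.length),
                        f.score,
                        f.iv.strand,
                        ".",
                        attrs or ".",
                    ]
                )
                + "\n"
            )


@dataclass(frozen=True)
class PafRecord:
    """One PAF alignment row (12 mandatory columns)."""

    query_name: str
    query_length: int
    query_start: int
    query_end: int
    strand: str
    target_name: str
    target_length: int
    target_start: int
    target_end: int
    n_matches: int
    alignment_length: int
    mapping_quality: int

    @property
    def identity(self) -> float:
        return self.n_matches / self.alignment_length if self.alignment_length else 0.0


def read_paf(path: str | Path) -> list[PafRecord]:
    records: list[PafRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) < 12:
                raise FormatError(
                    f"{path}:{lineno}: PAF needs >= 12 columns, got {len(cols)}"
                )
            try:
                rec = PafRecord(
                    query_name=cols[0],
                    query_length=int(cols[1]),
                    query_start=int(cols[2]),
                    query_end=int(cols[3]),
                    strand=cols[4],
                    target_name=cols[5],
                    target_length=int(cols[6]),
                    target_start=int(cols[7]),
                    target_end=int(cols[8]),
                    n_matches=int(cols[9]),
                    alignment_length=int(cols[10]),
                    mapping_quality=int(cols[11]),
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: bad PAF field: {exc}") from exc
            if rec.strand not in ("+", "-"):
                raise FormatError(f"{path}:{lineno}: bad PAF strand {rec.strand!r}")
            records.append(rec)
    return records


def write_tsv_report(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False)


def write_json_report(path: str | Path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
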