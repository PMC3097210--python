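"""Readers, writers and packaged fixtures for the formats the pipeline touches.

Coordinates are 1-based inclusive everywhere (genomic loci and GFF3 agree on
this convention); residue positions in proteins follow the same convention.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import IO, Iterable, Sequence

import pandas as pd
from Bio.SeqIO.FastaIO import SimpleFastaParser

__all__ = [
    "ProteinRecord",
    "GenomicInterval",
    "GeneModel",
    "CatalogueEntry",
    "read_fasta",
    "write_fasta",
    "parse_locus_string",
    "format_locus_string",
    "read_gene_models",
    "load_catalogue",
]

GROUP_LABELS = ("I", "II", "III", "IV", "V", "VI", "VII", "VIII")


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence: accession or gene name plus residue string.

    Residues are uppercase; the 20 standard amino acids plus ``X`` for
    unknown are accepted.
    """

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein id must be non-empty")
        if not self.sequence:
            raise ValueError(f"protein {self.id!r}: sequence must be non-empty")
        if self.sequence != self.sequence.upper():
            object.__setattr__(self, "sequence", self.sequence.upper())

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """1-based inclusive genomic interval on a chromosome arm (2R, 2L, 3R, 3L, X)."""

    chromosome: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"interval start {self.start} > end {self.end} on {self.chromosome}"
            )
        if self.start < 1:
            raise ValueError("coordinates are 1-based; start must be >= 1")

    @property
    def span(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class GeneModel:
    """A gene span plus its ordered, non-overlapping exons.

    Introns are the gaps between consecutive exons, so a gene with ``n``
    exons has ``n - 1`` introns. Strand may be unknown: the structural
    analyses downstream are strand-agnostic.
    """

    gene_id: str
    interval: GenomicInterval
    exons: tuple[GenomicInterval, ...]
    strand: str = "?"

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"gene {self.gene_id}: at least one exon required")
        exons = tuple(sorted(self.exons, key=lambda e: e.start))
        object.__setattr__(self, "exons", exons)
        for prev, nxt in zip(exons, exons[1:]):
            if nxt.start <= prev.end:
                raise ValueError(
                    f"gene {self.gene_id}: overlapping exons "
                    f"{prev.start}-{prev.end} and {nxt.start}-{nxt.end}"
                )
        for e in exons:
            if e.start < self.interval.start or e.end > self.interval.end:
                raise ValueError(
                    f"gene {self.gene_id}: exon {e.start}-{e.end} outside "
                    f"gene span {self.interval.start}-{self.interval.end}"
                )
            if e.chromosome != self.interval.chromosome:
                raise ValueError(
                    f"gene {self.gene_id}: exon chromosome {e.chromosome} "
                    f"differs from gene chromosome {self.interval.chromosome}"
                )

    @property
    def introns(self) -> tuple[GenomicInterval, ...]:
        out = []
        for prev, nxt in zip(self.exons, self.exons[1:]):
            out.append(
                GenomicInterval(self.interval.chromosome, prev.end + 1, nxt.start - 1)
            )
        return tuple(out)


@dataclass(frozen=True)
class CatalogueEntry:
    """One row of the published family catalogue (nomenclature + locus tables)."""

    species: str
    new_name: str | None  # None for genes dropped in the revised nomenclature
    old_name: str | None = None
    group: str | None = None
    accession: str | None = None
    aa_length: int | None = None
    has_cbd: bool | None = None
    has_est: bool | None = None
    interval: GenomicInterval | None = None

    def __post_init__(self) -> None:
        if self.group is not None and self.group not in GROUP_LABELS:
            raise ValueError(f"{self.new_name}: unknown group label {self.group!r}")


def _as_handle(source: str | IO[str]) -> IO[str]:
    if isinstance(source, str):
        return io.StringIO(source)
    return source


def read_fasta(source: str | IO[str]) -> list[ProteinRecord]:
    """Parse multi-record FASTA from a text stream, path-free.

    Residues are uppercased; record order is preserved. Duplicate ids and
    text before the first header are errors.
    """
    handle = _as_handle(source)
    text = handle.read()
    stripped = text.lstrip()
    if stripped and not stripped.startswith(">"):
        raise ValueError("FASTA parse error: sequence data before first header")
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for title, seq in SimpleFastaParser(io.StringIO(text)):
        parts = title.split(None, 1)
        rec_id = parts[0] if parts else ""
        desc = parts[1] if len(parts) > 1 else ""
        if rec_id in seen:
            raise ValueError(f"duplicate FASTA id {rec_id!r}")
        seen.add(rec_id)
        records.append(ProteinRecord(rec_id, seq.upper(), desc))
    return records


def read_fasta_file(path) -> list[ProteinRecord]:
    with open(path) as fh:
        return read_fasta(fh)


def write_fasta(records: Iterable[ProteinRecord], handle: IO[str], width: int = 60) -> None:
    for rec in records:
        header = f">{rec.id}"
        if rec.description:
            header += f" {rec.description}"
        handle.write(header + "\n")
        for i in range(0, len(rec.sequence), width):
            handle.write(rec.sequence[i : i + width] + "\n")


def fasta_string(records: Iterable[ProteinRecord], width: int = 60) -> str:
    buf = io.StringIO()
    write_fasta(records, buf, width=width)
    return buf.getvalue()


# Locus strings as printed in genome-browser coordinates, e.g.
# "chr2R:21,584,333–21,587,318" (en-dash or hyphen, commas optional).
_LOCUS_RE = re.compile(
    r"^chr(?P<arm>[0-9A-Za-z]+):(?P<start>[0-9,]+)\s*[–—-]\s*(?P<end>[0-9,]+)$"
)


def parse_locus_string(text: str) -> GenomicInterval:
    """Parse ``chr2R:21,584,333–21,587,318`` into a 1-based inclusive interval."""
    m = _LOCUS_RE.match(text.strip())
    if m is None:
        raise ValueError(f"malformed locus string: {text!r}")
    start = int(m.group("start").replace(",", ""))
    end = int(m.group("end").replace(",", ""))
    return GenomicInterval(m.group("arm"), start, end)


def format_locus_string(interval: GenomicInterval, commas: bool = True) -> str:
    fmt = "{:,}" if commas else "{}"
    return (
        f"chr{interval.chromosome}:"
        + fmt.format(interval.start)
        + "–"
        + fmt.format(interval.end)
    )


def _parse_gff3_attributes(text: str) -> dict[str, str]:
    out = {}
    for item in text.strip().split(";"):
        if not item:
            continue
        key, _, val = item.partition("=")
        out[key.strip()] = val.strip()
    return out


def read_gene_models(source: str | IO[str]) -> list[GeneModel]:
    """Read gene models from a GFF3 subset (gene/mRNA/exon features).

    Exons are grouped per gene via their ``Parent``/``gene_id`` attributes
    and sorted by start; GFF3 coordinates are 1-based inclusive. Overlapping
    exons within a gene, or exons outside the gene span, are errors.
    """
    handle = _as_handle(source)
    genes: dict[str, dict] = {}
    order: list[str] = []
    mrna_to_gene: dict[str, str] = {}
    exon_rows: list[tuple[str, GenomicInterval]] = []
    for line in handle:
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 9:
            raise ValueError(f"malformed GFF3 line: {line!r}")
        chrom, _, ftype, start, end, _, strand, _, attrs = fields[:9]
        attributes = _parse_gff3_attributes(attrs)
        if ftype == "gene":
            gid = attributes.get("ID") or attributes.get("gene_id")
            if gid is None:
                raise ValueError(f"gene feature without ID: {line!r}")
            genes[gid] = {
                "interval": GenomicInterval(chrom, int(start), int(end)),
                "strand": strand if strand in "+-" else "?",
            }
            order.append(gid)
        elif ftype in ("mRNA", "transcript"):
            tid = attributes.get("ID")
            parent = attributes.get("Parent")
            if tid and parent:
                mrna_to_gene[tid] = parent
        elif ftype == "exon":
            parent = attributes.get("Parent") or attributes.get("gene_id")
            if parent is None:
                raise ValueError(f"exon without Parent/gene_id: {line!r}")
            exon_rows.append((parent, GenomicInterval(chrom, int(start), int(end))))

    exons_by_gene: dict[str, list[GenomicInterval]] = {g: [] for g in order}
    for parent, iv in exon_rows:
        gid = mrna_to_gene.get(parent, parent)
        if gid not in exons_by_gene:
            # exon table without explicit gene features: infer the gene
            exons_by_gene.setdefault(gid, [])
            if gid not in genes:
                order.append(gid)
        exons_by_gene[gid].append(iv)

    models = []
    for gid in order:
        exons = exons_by_gene.get(gid, [])
        if not exons:
            raise ValueError(f"gene {gid}: no exon features")
        if gid in genes:
            interval = genes[gid]["interval"]
            strand = genes[gid]["strand"]
        else:
            interval = GenomicInterval(
                exons[0].chromosome,
                min(e.start for e in exons),
                max(e.end for e in exons),
            )
            strand = "?"
        models.append(GeneModel(gid, interval, tuple(exons), strand))
    return models


def write_gene_models_gff3(models: Iterable[GeneModel], handle: IO[str]) -> None:
    handle.write("##gff-version 3\n")
    for m in models:
        iv = m.interval
        handle.write(
            f"{iv.chromosome}\tchitfam\tgene\t{iv.start}\t{iv.end}\t.\t{m.strand if m.strand in '+-' else '.'}\t.\tID={m.gene_id}\n"
        )
        for e in m.exons:
            handle.write(
                f"{iv.chromosome}\tchitfam\texon\t{e.start}\t{e.end}\t.\t.\t.\tParent={m.gene_id}\n"
            )


def _flag(value) -> bool | None:
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return None
    return str(value).strip() in ("+", "true", "True", "1", "yes")


def load_catalogue(fixture: str = "ag_catalogue.tsv") -> list[CatalogueEntry]:
    """Load a packaged catalogue fixture (``ag_catalogue.tsv`` or
    ``nomenclature_dm_tc_ag.tsv``) as a list of CatalogueEntry.

    The fixtures transcribe the published nomenclature map, accessions and
    chromosomal loci for the Dm/Tc/Ag chitinase families.
    """
    ref = resources.files("chitfam.tables").joinpath(fixture)
    if not ref.is_file():
        raise FileNotFoundError(f"no packaged fixture named {fixture!r}")
    with ref.open() as fh:
        df = pd.read_csv(fh, sep="\t", dtype=str, keep_default_na=False).fillna("")
    if "new_name" not in df.columns or "species" not in df.columns:
        raise ValueError(f"fixture {fixture!r}: missing required columns")
    entries = []
    for _, row in df.iterrows():
        new_name = row.get("new_name", "") or None
        if new_name is None:
            # nomenclature rows for genes dropped in the revision (e.g. merged
            # gene fragments) carry an old name only
            entries.append(
                CatalogueEntry(species=row["species"], new_name=None,
                               old_name=row.get("old_name", "") or None)
            )
            continue
        locus = row.get("locus", "")
        entries.append(
            CatalogueEntry(
                species=row["species"],
                new_name=new_name,
                old_name=row.get("old_name", "") or None,
                group=row.get("group", "") or None,
                accession=row.get("accession", "") or None,
                aa_length=int(row["aa_length"]) if row.get("aa_length", "") else None,
                has_cbd=_flag(row.get("has_cbd", "")),
                has_est=_flag(row.get("est", "")),
                interval=parse_locus_string(locus) if locus else None,
            )
        )
    return entries


def catalogue_dataframe(entries: Sequence[CatalogueEntry]) -> pd.DataFrame:
    rows = []
    for e in entries:
        rows.append(
            {
                "species": e.species,
                "new_name": e.new_name,
                "old_name": e.old_name,
                "group": e.group,
                "accession": e.accession,
                "aa_length": e.aa_length,
                "has_cbd": e.has_cbd,
                "has_est": e.has_est,
                "locus": format_locus_string(e.interval) if e.interval else None,
            }
        )
    return pd.DataFrame(rows)
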