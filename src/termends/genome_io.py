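"""Genomic data model and file formats.

Everything in this package speaks 1-based, inclusive genomic coordinates on a
single circular-agnostic chromosome; the only 0-based surface is bedGraph
serialization (UCSC dialect, 0-based half-open). "Upstream" and "downstream"
are always in transcript sense — 5'→3' of the feature's strand — never in
genome-coordinate sense.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

import numpy as np
import pandas as pd

FORWARD = "+"
REVERSE = "-"
STRANDS = (FORWARD, REVERSE)

#: Coverage assay kinds.
ASSAY_TERM3 = "term3end"
ASSAY_RNASEQ = "rnaseq"


class AnnotationError(ValueError):
    """Raised for structurally invalid annotations."""


class FormatError(ValueError):
    """Raised for malformed bedGraph/GFF3 input."""


@dataclass(frozen=True, order=True)
class Interval:
    """1-based inclusive genomic interval."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise AnnotationError(f"invalid interval [{self.start}, {self.end}]")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def __contains__(self, coordinate: int) -> bool:
        return self.start <= coordinate <= self.end


@dataclass(frozen=True)
class GeneModel:
    """A gene with transcript-sense substructure.

    ``utr5``/``utr3``/``terminator`` are optional; ``cds`` is mandatory for
    mRNA genes. On the + strand features run utr5 < cds < utr3 < terminator in
    genomic coordinates; on the − strand the genomic order is mirrored.
    """

    gene_id: str
    strand: str
    cds: Interval
    utr5: Optional[Interval] = None
    utr3: Optional[Interval] = None
    terminator: Optional[Interval] = None
    biotype: str = "mRNA"  # mRNA | tRNA | rRNA
    operon_class: str = "monocistronic"  # monocistronic | polycistronic

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise AnnotationError(f"{self.gene_id}: bad strand {self.strand!r}")
        if self.biotype == "mRNA" and len(self.cds) < 3:
            raise AnnotationError(f"{self.gene_id}: CDS shorter than one codon")
        for name, inner, outer in self._order_checks():
            if inner is None or outer is None:
                continue
            if self.strand == FORWARD and not inner.end < outer.start:
                raise AnnotationError(f"{self.gene_id}: {name} out of 5'→3' order")
            if self.strand == REVERSE and not outer.end < inner.start:
                raise AnnotationError(f"{self.gene_id}: {name} out of 5'→3' order")

    def _order_checks(self):
        return [
            ("utr5/cds", self.utr5, self.cds),
            ("cds/utr3", self.cds, self.utr3),
            ("utr3/terminator", self.utr3, self.terminator),
        ]

    @property
    def span(self) -> Interval:
        parts = [p for p in (self.utr5, self.cds, self.utr3, self.terminator) if p]
        return Interval(min(p.start for p in parts), max(p.end for p in parts))

    @property
    def tx_start(self) -> int:
        """Transcript-sense 5' boundary of the gene body (excl. terminator)."""
        body = [p for p in (self.utr5, self.cds, self.utr3) if p]
        return min(p.start for p in body) if self.strand == FORWARD else max(p.end for p in body)

    def cds_tx_offset(self, coordinate: int) -> int:
        """Transcript-sense offset of ``coordinate`` from the CDS start (0-based)."""
        if coordinate not in self.cds:
            raise ValueError(f"{coordinate} not in CDS of {self.gene_id}")
        if self.strand == FORWARD:
            return coordinate - self.cds.start
        return self.cds.end - coordinate

    def effective_utr5(self) -> Optional[Interval]:
        """Annotated 5' UTR, or the gene-start..CDS-start gap when unannotated."""
        if self.utr5 is not None:
            return self.utr5
        return None


@dataclass
class GenomeAnnotation:
    """Single-chromosome gene catalog."""

    genome_length: int
    genes: list[GeneModel] = field(default_factory=list)
    chrom: str = "chr"

    def __post_init__(self) -> None:
        for g in self.genes:
            span = g.span
            if span.start < 1 or span.end > self.genome_length:
                raise AnnotationError(f"{g.gene_id} extends past genome bounds")
        self._by_id = {g.gene_id: g for g in self.genes}
        if len(self._by_id) != len(self.genes):
            raise AnnotationError("duplicate gene_id in annotation")

    def __iter__(self) -> Iterator[GeneModel]:
        return iter(self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    def gene(self, gene_id: str) -> GeneModel:
        return self._by_id[gene_id]

    @property
    def monocistronic(self) -> list[GeneModel]:
        return [g for g in self.genes if g.operon_class == "monocistronic"]


@dataclass
class CoverageTrack:
    """Per-base non-negative counts over the whole genome, one strand.

    ``values[i]`` is the count at 1-based coordinate ``i + 1``.
    """

    strand: str
    values: np.ndarray
    assay: str = ASSAY_TERM3
    chrom: str = "chr"

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise FormatError(f"bad strand {self.strand!r}")
        self.values = np.asarray(self.values, dtype=np.int64)
        if (self.values < 0).any():
            raise FormatError("negative coverage value")

    def __len__(self) -> int:
        return len(self.values)

    def at(self, coordinate: int) -> int:
        """Coverage at a 1-based coordinate (0 outside the genome)."""
        if 1 <= coordinate <= len(self.values):
            return int(self.values[coordinate - 1])
        return 0

    def slice(self, start: int, end: int) -> np.ndarray:
        """Per-base values over [start, end] (1-based incl.), clipped to bounds."""
        lo, hi = max(start, 1), min(end, len(self.values))
        if hi < lo:
            return np.empty(0, dtype=np.int64)
        return self.values[lo - 1 : hi]


# ---------------------------------------------------------------------------
# Transcript-sense coordinate helpers
# ---------------------------------------------------------------------------

def upstream_window(coordinate: int, strand: str, window: int) -> tuple[int, int]:
    """Genomic bounds of the ``window`` nt immediately 5' of ``coordinate``.

    Excludes the coordinate itself. May extend past genome bounds; callers
    clip via :meth:`CoverageTrack.slice`.
    """
    if strand == FORWARD:
        return coordinate - window, coordinate - 1
    return coordinate + 1, coordinate + window


def downstream_shift(coordinate: int, strand: str, n: int = 1) -> int:
    """The coordinate ``n`` bases 3' of ``coordinate`` in transcript sense."""
    return coordinate + n if strand == FORWARD else coordinate - n


def three_prime_most(coordinates: Iterable[int], strand: str) -> int:
    """The transcript-sense 3'-most of a set of same-strand coordinates."""
    coords = list(coordinates)
    return max(coords) if strand == FORWARD else min(coords)


# ---------------------------------------------------------------------------
# bedGraph
# ---------------------------------------------------------------------------

def read_bedgraph(path: str | Path, genome_length: int, strand: str,
                  assay: str = ASSAY_TERM3) -> CoverageTrack:
    """Read a 4-column bedGraph (0-based half-open) into a per-base track.

    Absent intervals are 0. Overlapping intervals with conflicting values and
    negative values are format errors.
    """
    values = np.zeros(genome_length, dtype=np.int64)
    seen = np.zeros(genome_length, dtype=bool)
    chrom = "chr"
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise FormatError(f"{path}:{lineno}: expected 4 columns")
            chrom, start, end, value = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
            if value < 0:
                raise FormatError(f"{path}:{lineno}: negative value {value}")
            if start < 0 or end > genome_length or end <= start:
                raise FormatError(f"{path}:{lineno}: interval [{start},{end}) out of bounds")
            ivalue = int(round(value))
            overlap = seen[start:end]
            if overlap.any() and (values[start:end][overlap] != ivalue).any():
                raise FormatError(f"{path}:{lineno}: conflicting overlap")
            values[start:end] = ivalue
            seen[start:end] = True
    return CoverageTrack(strand=strand, values=values, assay=assay, chrom=chrom)


def write_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    """Write a track as run-length-compressed bedGraph, omitting zero runs."""
    v = track.values
    with open(path, "w") as fh:
        if len(v) == 0:
            return
        # boundaries of constant runs
        changes = np.flatnonzero(np.diff(v)) + 1
        starts = np.concatenate(([0], changes))
        ends = np.concatenate((changes, [len(v)]))
        for s, e in zip(starts, ends):
            if v[s] != 0:
                fh.write(f"{track.chrom}\t{s}\t{e}\t{int(v[s])}\n")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

_GFF_FEATURES = {
    "CDS": "cds",
    "five_prime_UTR": "utr5",
    "three_prime_UTR": "utr3",
    "terminator": "terminator",
}


def _parse_attributes(text: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for item in text.strip().split(";"):
        if not item:
            continue
        key, _, val = item.partition("=")
        out[key.strip()] = val.strip()
    return out


def read_gff3(path: str | Path) -> GenomeAnnotation:
    """Read the package's GFF3 dialect (1-based inclusive, no conversion).

    Recognized feature types: gene, CDS, five_prime_UTR, three_prime_UTR,
    terminator. ``biotype`` and ``operon_class`` come from gene attributes.
    """
    genome_length = 0
    chrom = "chr"
    gene_rows: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if line.startswith("##sequence-region"):
                parts = line.split()
                chrom, genome_length = parts[1], int(parts[3])
                continue
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GFF3 columns")
            chrom, _, ftype, start, end, _, strand, _, attrs_text = cols
            attrs = _parse_attributes(attrs_text)
            iv = Interval(int(start), int(end))
            if ftype == "gene":
                gid = attrs.get("ID")
                if not gid:
                    raise FormatError(f"{path}:{lineno}: gene without ID")
                gene_rows[gid] = {
                    "strand": strand,
                    "biotype": attrs.get("biotype", "mRNA"),
                    "operon_class": attrs.get("operon_class", "monocistronic"),
                }
                order.append(gid)
            elif ftype in _GFF_FEATURES:
                gid = attrs.get("Parent") or attrs.get("ID", "").split(".")[0]
                if gid not in gene_rows:
                    raise FormatError(f"{path}:{lineno}: feature before its gene record")
                gene_rows[gid][_GFF_FEATURES[ftype]] = iv
            # unknown feature types are ignored
    genes = []
    for gid in order:
        row = gene_rows[gid]
        if "cds" not in row:
            raise AnnotationError(f"gene {gid}: mRNA gene lacks a CDS feature")
        genes.append(GeneModel(
            gene_id=gid, strand=row["strand"], cds=row["cds"],
            utr5=row.get("utr5"), utr3=row.get("utr3"),
            terminator=row.get("terminator"),
            biotype=row["biotype"], operon_class=row["operon_class"],
        ))
    if genome_length == 0 and genes:
        genome_length = max(g.span.end for g in genes)
    return GenomeAnnotation(genome_length=genome_length, genes=genes, chrom=chrom)


def write_gff3(annotation: GenomeAnnotation, path: str | Path) -> None:
    inv = {v: k for k, v in _GFF_FEATURES.items()}
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {annotation.chrom} 1 {annotation.genome_length}\n")
        for g in annotation.genes:
            span = g.span
            fh.write("\t".join([
                annotation.chrom, "termends", "gene", str(span.start), str(span.end),
                ".", g.strand, ".",
                f"ID={g.gene_id};biotype={g.biotype};operon_class={g.operon_class}",
            ]) + "\n")
            for attr in ("utr5", "cds", "utr3", "terminator"):
                iv = getattr(g, attr)
                if iv is None:
                    continue
                fh.write("\t".join([
                    annotation.chrom, "termends", inv[attr], str(iv.start), str(iv.end),
                    ".", g.strand, ".", f"ID={g.gene_id}.{attr};Parent={g.gene_id}",
                ]) + "\n")


# ---------------------------------------------------------------------------
# Tables & FASTA
# ---------------------------------------------------------------------------

def write_table(frame: pd.DataFrame, path: str | Path) -> None:
    """Write a DataFrame as a TSV with header row."""
    frame.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_fasta(path: str | Path) -> str:
    """Read the single-record genome FASTA, returning the uppercase sequence."""
    from Bio import SeqIO

    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise FormatError(f"{path}: expected exactly one FASTA record, got {len(records)}")
    return str(records[0].seq).upper()


def write_fasta(sequence: str, path: str | Path, name: str = "chr") -> None:
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for i in range(0, len(sequence), 70):
            fh.write(sequence[i : i + 70] + "\n")
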