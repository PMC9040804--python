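"""Normalization of peak heights by local expression and genomic classification.

A raw Cv height confounds 3'-end stability with transcript abundance: a
modest obstacle on a highly expressed mRNA yields a tall peak. The height is
therefore divided by the log10 of the median RNA-seq coverage over the 50 nt
immediately upstream (transcript sense) of the 3' end, and the normalized
value floored at 0.001 so downstream log fold changes stay finite.

Classification assigns each peak to a single genomic category with the
precedence terminator > tRNA_rRNA > utr5 > cds > utr3 > intergenic; the
decay-intermediate analysis keeps only CDS peaks of expressed monocistronic
genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .genome_io import (CoverageTrack, GeneModel, GenomeAnnotation,
                        upstream_window, ASSAY_RNASEQ)
from .peaks import Peak

DEFAULT_UPSTREAM_WINDOW = 50
DEFAULT_FLOOR = 1e-3
DEFAULT_MIN_RPB = 1.0
DEFAULT_MIN_HEIGHT = 10.0

#: denominator clamp: median upstream coverage below this is raised to it so
#: log10 stays >= 1 and low coverage never inflates a raw height
_MEDIAN_CLAMP = 10.0

CATEGORIES = ("terminator", "tRNA_rRNA", "utr5", "cds", "utr3", "intergenic")


@dataclass(frozen=True)
class NormalizedPeak:
    peak: Peak
    gene_id: Optional[str]
    category: str
    norm_height: float

    @property
    def coordinate(self) -> int:
        return self.peak.coordinate

    @property
    def strand(self) -> str:
        return self.peak.strand


def normalize_height(raw: float, coordinate: int, strand: str,
                     rnaseq: CoverageTrack,
                     window: int = DEFAULT_UPSTREAM_WINDOW,
                     floor: float = DEFAULT_FLOOR) -> float:
    """raw Cv ÷ log10(median upstream RNA-seq coverage), floored.

    The window is the ``window`` nt immediately 5' of the coordinate in
    transcript sense, truncated at genome bounds; with no available bases the
    floor is returned. The median is clamped to >= 10 before the log so the
    denominator is always >= 1.
    """
    if rnaseq.assay != ASSAY_RNASEQ:
        raise ValueError("normalization track must be RNA-seq coverage")
    if rnaseq.strand != strand:
        raise ValueError("RNA-seq track strand does not match peak strand")
    lo, hi = upstream_window(coordinate, strand, window)
    values = rnaseq.slice(lo, hi)
    if values.size == 0:
        return floor
    m = float(np.median(values))
    d = np.log10(max(m, _MEDIAN_CLAMP))
    return max(raw / d, floor)


def classify_peak(peak: Peak, annotation: GenomeAnnotation
                  ) -> tuple[str, Optional[str]]:
    """(category, gene_id) for a peak; strand-matched, fixed precedence."""
    best_rank = len(CATEGORIES) - 1  # intergenic
    best: tuple[str, Optional[str]] = ("intergenic", None)
    for gene in annotation:
        if gene.strand != peak.strand:
            continue
        for category, iv in _gene_intervals(gene):
            if iv is not None and peak.coordinate in iv:
                rank = CATEGORIES.index(category)
                if rank < best_rank:
                    best_rank = rank
                    best = (category, gene.gene_id)
    return best


def _gene_intervals(gene: GeneModel):
    if gene.biotype in ("tRNA", "rRNA"):
        yield "tRNA_rRNA", gene.span
        return
    yield "terminator", gene.terminator
    yield "utr5", gene.utr5
    yield "cds", gene.cds
    yield "utr3", gene.utr3


def annotate_peaks(peaks: Sequence[Peak], annotation: GenomeAnnotation,
                   rnaseq: CoverageTrack,
                   window: int = DEFAULT_UPSTREAM_WINDOW,
                   floor: float = DEFAULT_FLOOR) -> list[NormalizedPeak]:
    """Classify and expression-normalize every peak of one strand."""
    out = []
    for p in peaks:
        category, gene_id = classify_peak(p, annotation)
        nh = normalize_height(p.height, p.coordinate, p.strand, rnaseq,
                              window=window, floor=floor)
        out.append(NormalizedPeak(peak=p, gene_id=gene_id, category=category,
                                  norm_height=nh))
    return out


# ---------------------------------------------------------------------------
# Expression filter
# ---------------------------------------------------------------------------

class ExpressionTable:
    """Per-gene, per-strain expression in normalized reads per CDS base."""

    def __init__(self, reads_per_base: pd.DataFrame):
        if (reads_per_base.values < 0).any():
            raise ValueError("reads_per_base must be non-negative")
        self.frame = reads_per_base  # index: gene_id, columns: strain

    @classmethod
    def from_counts(cls, counts: pd.DataFrame, annotation: GenomeAnnotation,
                    size_factors: Optional[Mapping[str, float]] = None
                    ) -> "ExpressionTable":
        """Counts (gene × strain) → normalized reads ÷ CDS length."""
        norm = counts.astype(float).copy()
        if size_factors is not None:
            for strain in norm.columns:
                norm[strain] = norm[strain] / size_factors[strain]
        lengths = pd.Series({g.gene_id: len(g.cds) for g in annotation})
        rpb = norm.div(lengths.reindex(norm.index), axis=0)
        return cls(rpb)

    def expressed_in_all(self, min_rpb: float = DEFAULT_MIN_RPB) -> set[str]:
        f = self.frame
        return set(f.index[(f >= min_rpb).all(axis=1)])


def filter_monocistronic_cds(peaks: Sequence[NormalizedPeak],
                             annotation: GenomeAnnotation,
                             expression: ExpressionTable,
                             min_rpb: float = DEFAULT_MIN_RPB,
                             min_height: float = DEFAULT_MIN_HEIGHT,
                             apply_height_filter: bool = True
                             ) -> list[NormalizedPeak]:
    """The decay-intermediate peak set: CDS peaks of expressed monocistronic genes.

    Retains peaks with category ``cds`` whose gene is monocistronic and has
    at least ``min_rpb`` reads/base in every strain of the expression table,
    and whose raw Cv height is at least ``min_height``. When strains are
    compared jointly the height test is re-applied at the superset stage with
    "any strain" semantics; ``apply_height_filter=False`` defers it.
    """
    expressed = expression.expressed_in_all(min_rpb)
    known = set(expression.frame.index)
    out = []
    for np_ in peaks:
        if np_.category != "cds" or np_.gene_id is None:
            continue
        gene = annotation.gene(np_.gene_id)
        if gene.operon_class != "monocistronic":
            continue
        if np_.gene_id not in known:
            continue  # dropped: gene absent from the expression table
        if np_.gene_id not in expressed:
            continue
        if apply_height_filter and np_.peak.height < min_height:
            continue
        out.append(np_)
    return out


def find_utr3_peaks(peaks: Sequence[NormalizedPeak],
                    annotation: GenomeAnnotation,
                    expression: ExpressionTable,
                    min_rpb: float = DEFAULT_MIN_RPB) -> list[NormalizedPeak]:
    """3' ends between the stop codon and the intrinsic terminator.

    Restricted to the expression-filtered monocistronic gene set; genes
    lacking a terminator annotation are skipped. The bounds are exclusive:
    a peak inside the terminator interval or the CDS is not a 3'-UTR end.
    """
    expressed = expression.expressed_in_all(min_rpb)
    out = []
    for np_ in peaks:
        if np_.strand not in "+-":
            continue
        for gene in annotation.monocistronic:
            if gene.gene_id not in expressed or gene.terminator is None:
                continue
            if gene.strand != np_.strand or gene.biotype != "mRNA":
                continue
            c = np_.coordinate
            if gene.strand == "+":
                inside = gene.cds.end < c < gene.terminator.start
            else:
                inside = gene.terminator.end < c < gene.cds.start
            if inside:
                out.append(NormalizedPeak(peak=np_.peak, gene_id=gene.gene_id,
                                          category="utr3",
                                          norm_height=np_.norm_height))
                break
    return out


def peaks_frame(peaks: Sequence[NormalizedPeak], strain: str) -> pd.DataFrame:
    return pd.DataFrame(
        [(p.gene_id, p.coordinate, p.strand, p.category, p.peak.height,
          p.norm_height, strain) for p in peaks],
        columns=["gene_id", "coordinate", "strand", "category", "raw_cv",
                 "norm_cv", "strain"],
    )
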