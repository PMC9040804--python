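"""Coverage-variation (Cv) computation and 3' end peak calling.

A free RNA 3' end manifests in Term-seq 3'-end coverage as a coverage step
that falls immediately 3' of the terminal nucleotide: reads covering the
molecule all stop there. Cv is therefore defined as the transcript-sense
first-order derivative of coverage, clipped at zero:

    Cv(i) = max(0, c(i) - c(i'))

where i' is the immediately 3'-adjacent coordinate in transcript sense
(i+1 on the + strand, i-1 on -), and c(i') = 0 beyond the genome boundary.
With this sign convention Cv(i) approximates the number of RNA molecules
whose 3' terminus is exactly at i.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genome_io import ASSAY_TERM3, FORWARD, CoverageTrack

DEFAULT_MIN_HEIGHT = 10.0
DEFAULT_WINDOW = 2


@dataclass
class CvTrack:
    """Per-base Cv values, same 1-based indexing as :class:`CoverageTrack`."""

    strand: str
    cv: np.ndarray
    chrom: str = "chr"

    def at(self, coordinate: int) -> float:
        if 1 <= coordinate <= len(self.cv):
            return float(self.cv[coordinate - 1])
        return 0.0

    def window_max(self, coordinate: int, tol: int) -> float:
        """Maximum Cv within ±tol of a coordinate (0 outside the genome)."""
        lo = max(coordinate - tol, 1)
        hi = min(coordinate + tol, len(self.cv))
        if hi < lo:
            return 0.0
        return float(self.cv[lo - 1 : hi].max())


@dataclass(frozen=True, order=True)
class Peak:
    """A called 3' end: a Cv local maximum above the height threshold."""

    coordinate: int
    strand: str
    height: float


def merge_replicates(tracks: Sequence[CoverageTrack]) -> CoverageTrack:
    """Per-base sum of replicate coverage tracks (merged analysis)."""
    if not tracks:
        raise ValueError("no tracks to merge")
    first = tracks[0]
    for t in tracks[1:]:
        if t.strand != first.strand:
            raise ValueError("strand mismatch between replicates")
        if t.assay != first.assay or len(t) != len(first):
            raise ValueError("assay/length mismatch between replicates")
    total = np.sum([t.values for t in tracks], axis=0)
    return CoverageTrack(strand=first.strand, values=total, assay=first.assay,
                         chrom=first.chrom)


def compute_cv(track: CoverageTrack) -> CvTrack:
    """Transcript-sense coverage drop at every coordinate, clipped at 0."""
    if track.assay != ASSAY_TERM3:
        raise ValueError(f"Cv is defined on {ASSAY_TERM3} coverage, got {track.assay!r}")
    c = track.values.astype(np.float64)
    nxt = np.empty_like(c)
    if track.strand == FORWARD:
        nxt[:-1] = c[1:]
        nxt[-1] = 0.0
    else:
        nxt[1:] = c[:-1]
        nxt[0] = 0.0
    return CvTrack(strand=track.strand, cv=np.maximum(c - nxt, 0.0), chrom=track.chrom)


def call_peaks(cv: CvTrack, min_height: float = DEFAULT_MIN_HEIGHT,
               window: int = DEFAULT_WINDOW) -> list[Peak]:
    """Call Cv local maxima of height ``min_height`` or above.

    A coordinate i is a peak iff cv(i) >= cv(j) for every j within ±window
    and cv(i) >= min_height. Among tied maxima within one window only the
    3'-most (transcript-sense) coordinate is reported, so no two reported
    peaks lie within ±window of each other.
    """
    if min_height <= 0:
        raise ValueError("min_height must be positive")
    if window < 1:
        raise ValueError("window must be >= 1")
    v = cv.cv
    n = len(v)
    candidates: list[int] = []  # 0-based indices
    above = np.flatnonzero(v >= min_height)
    for i in above:
        lo = max(i - window, 0)
        hi = min(i + window + 1, n)
        if v[i] >= v[lo:hi].max():
            candidates.append(int(i))
    # resolve tied runs: two candidates within ±window necessarily tie; keep
    # the transcript-sense 3'-most of each group
    kept: list[int] = []
    order = candidates if cv.strand == FORWARD else candidates[::-1]
    # iterate 5'->3' in transcript sense; a later candidate within window
    # supersedes the earlier one
    for i in order:
        if kept and abs(i - kept[-1]) <= window:
            kept[-1] = i
        else:
            kept.append(i)
    peaks = [Peak(coordinate=i + 1, strand=cv.strand, height=float(v[i])) for i in kept]
    peaks.sort(key=lambda p: p.coordinate)
    return peaks


def peaks_to_frame(peaks: Sequence[Peak]) -> pd.DataFrame:
    return pd.DataFrame(
        [(p.coordinate, p.strand, p.height) for p in peaks],
        columns=["coordinate", "strand", "height"],
    )


def write_peaks_bed(peaks: Sequence[Peak], path: str | Path, chrom: str = "chr") -> None:
    """6-column BED: each peak as a 0-based single-base interval, score = raw Cv."""
    with open(path, "w") as fh:
        for p in sorted(peaks):
            fh.write(f"{chrom}\t{p.coordinate - 1}\t{p.coordinate}\t"
                     f"peak_{p.coordinate}{p.strand}\t{p.height:g}\t{p.strand}\n")
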