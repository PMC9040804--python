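"""Synthetic genomes, planted 3'-end catalogs, and coverage simulation.

The generator emulates the statistical structure the analysis assumes in a
bacterial Term-seq experiment: a compact single-chromosome genome of
non-overlapping genes (5' UTR, CDS, 3' UTR, intrinsic terminator) on both
strands; decay-intermediate 3' ends planted inside CDS interiors whose
expected read counts differ between strain profiles (a wild-type-like strain
and exonuclease/helicase-deficient strains with elevated end multipliers);
strong terminator-associated 3' ends; i.i.d. per-base Poisson background
ends; and per-gene uniform RNA-seq coverage with an optional 5'-enriched
distortion that mimics a decay defect.

All randomness flows from one seeded ``numpy.random.default_rng`` generator
per operation. Draw order is part of the stable API and is documented on
each operation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .genome_io import (ASSAY_RNASEQ, ASSAY_TERM3, FORWARD, REVERSE,
                        CoverageTrack, GeneModel, GenomeAnnotation, Interval,
                        write_bedgraph, write_gff3, write_table)

#: fixed simulated read length; only the 3'-terminus position matters to the
#: coverage-drop detector, so this affects coverage shoulders only
READ_LENGTH = 75

DEFAULT_LENGTH_PARAMS = {
    "utr5": (30, 80),
    "cds": (300, 900),       # rounded down to a multiple of 3
    "utr3": (40, 120),
    "terminator_len": 30,
    "gap": (100, 200),
}


@dataclass(frozen=True)
class StrainProfile:
    """How one strain distorts the shared ground truth.

    ``end_multiplier`` scales every planted decay-intermediate end (models
    loss of 3' exonuclease or helicase activity); ``expression_scale`` is a
    global RNA-seq depth factor; ``five_prime_up_genes`` maps gene_id → the
    5'/3' coverage ratio forced onto that gene's RNA-seq signal.
    """

    name: str
    end_multiplier: float = 1.0
    expression_scale: float = 1.0
    five_prime_up_genes: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.end_multiplier <= 0 or self.expression_scale <= 0:
            raise ValueError("multipliers must be positive")
        if any(r < 1 for r in self.five_prime_up_genes.values()):
            raise ValueError("five_prime_up ratios must be >= 1")


@dataclass(frozen=True)
class PlantedEnd:
    gene_id: str
    coordinate: int
    strand: str
    intensity_by_strain: Mapping[str, float]
    upstream_stem_dg: Optional[float] = None


@dataclass(frozen=True)
class TerminatorEnd:
    gene_id: str
    coordinate: int
    strand: str
    intensity: float


@dataclass
class GroundTruth:
    """Planted 3'-end catalog plus per-gene expression levels."""

    planted_ends: list[PlantedEnd]
    terminator_ends: list[TerminatorEnd]
    gene_expression: dict[str, float]

    def validate(self, annotation: GenomeAnnotation) -> None:
        for e in self.planted_ends:
            gene = annotation.gene(e.gene_id)
            in_cds = e.coordinate in gene.cds
            in_utr3 = gene.utr3 is not None and e.coordinate in gene.utr3
            if not (in_cds or in_utr3):
                raise ValueError(f"planted end {e.coordinate} outside "
                                 f"{e.gene_id} CDS/3'UTR")
            if e.strand != gene.strand:
                raise ValueError(f"planted end strand mismatch in {e.gene_id}")
            if any(v < 0 for v in e.intensity_by_strain.values()):
                raise ValueError("negative planted intensity")


# ---------------------------------------------------------------------------
# Genome generation
# ---------------------------------------------------------------------------

def generate_genome(n_genes: int, seed: int, mono_fraction: float = 1.0,
                    length_params: Optional[dict] = None,
                    n_trna_rrna: int = 0,
                    genome_length: Optional[int] = None) -> GenomeAnnotation:
    """Generate a toy single-chromosome annotation.

    Genes are laid out left to right with random gaps, random strands, and
    the substructure gap/utr5/CDS/utr3/terminator (genomic order mirrored on
    the − strand). ``round(n_genes * mono_fraction)`` genes are flagged
    monocistronic and the rest polycistronic; ``n_trna_rrna`` genes are
    flagged tRNA/rRNA (alternating). Deterministic for a fixed seed.

    Draw order: per gene (strand, utr5 len, cds len, utr3 len, gap), then one
    permutation for the mono/poly assignment, then one for tRNA/rRNA flags.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if not 0.0 <= mono_fraction <= 1.0:
        raise ValueError("mono_fraction must be in [0, 1]")
    if n_trna_rrna > n_genes:
        raise ValueError("n_trna_rrna exceeds n_genes")
    params = dict(DEFAULT_LENGTH_PARAMS)
    if length_params:
        params.update(length_params)
    rng = np.random.default_rng(seed)

    cursor = 1
    layouts = []
    for _ in range(n_genes):
        strand = FORWARD if rng.random() < 0.5 else REVERSE
        l5 = int(rng.integers(*params["utr5"], endpoint=True))
        lc = int(rng.integers(*params["cds"], endpoint=True)) // 3 * 3
        l3 = int(rng.integers(*params["utr3"], endpoint=True))
        lt = int(params["terminator_len"])
        gap = int(rng.integers(*params["gap"], endpoint=True))
        cursor += gap
        start = cursor
        segs = [l5, lc, l3, lt] if strand == FORWARD else [lt, l3, lc, l5]
        bounds = np.cumsum([start] + segs)
        ivs = [Interval(int(bounds[k]), int(bounds[k + 1]) - 1) for k in range(4)]
        if strand == FORWARD:
            utr5, cds, utr3, term = ivs
        else:
            term, utr3, cds, utr5 = ivs
        layouts.append((strand, utr5, cds, utr3, term))
        cursor = int(bounds[-1])
    total = cursor + 100
    if genome_length is not None:
        if total > genome_length:
            raise ValueError(f"requested genes need {total} bases but genome "
                             f"length is {genome_length}")
        total = genome_length

    n_mono = int(round(n_genes * mono_fraction))
    mono_idx = set(rng.permutation(n_genes)[:n_mono].tolist())
    struct_idx = list(rng.permutation(n_genes)[:n_trna_rrna])

    genes = []
    for i, (strand, utr5, cds, utr3, term) in enumerate(layouts):
        biotype = "mRNA"
        if i in struct_idx:
            biotype = "tRNA" if struct_idx.index(i) % 2 == 0 else "rRNA"
        genes.append(GeneModel(
            gene_id=f"gene{i + 1:04d}", strand=strand, cds=cds, utr5=utr5,
            utr3=utr3, terminator=term, biotype=biotype,
            operon_class="monocistronic" if i in mono_idx else "polycistronic",
        ))
    return GenomeAnnotation(genome_length=total, genes=genes)


def generate_sequence(genome_length: int, seed: int, gc: float = 0.44) -> str:
    """Random DNA genome sequence with the given GC content."""
    rng = np.random.default_rng(seed)
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=genome_length, p=p))


# ---------------------------------------------------------------------------
# Planting ends
# ---------------------------------------------------------------------------

#: planted coordinates stay this many bases clear of the CDS bounds
_CDS_MARGIN = 10


def plant_ends(annotation: GenomeAnnotation, n_per_gene: int, seed: int,
               strain_profiles: Sequence[StrainProfile],
               dg_model: Optional[dict] = None,
               base_intensity: tuple[float, float] = (50.0, 200.0),
               terminator_intensity: float = 300.0,
               expression_range: tuple[float, float] = (20.0, 100.0)
               ) -> GroundTruth:
    """Plant decay-intermediate 3' ends in CDS interiors.

    Coordinates are uniform within the CDS interior (>= 10 nt from both
    bounds); per-end expected counts are a random base intensity times each
    profile's ``end_multiplier``. Genes whose CDS is too short to host the
    requested ends are skipped with a warning.

    With ``dg_model`` (keys ``wt_strain``, optional ``dg_range``, default
    (−25, −2) kcal/mol) each planted end also receives an upstream stem ΔG,
    and the wild-type-like profile's intensity is made a deterministic
    decreasing function of ΔG (more stable stem → more accumulation), while
    the other profiles keep ΔG-independent random intensities, so the
    structure association is recoverable for the wild type and attenuated in
    the mutants.

    Draw order: per mRNA gene (expression level, coordinates, then per end:
    base intensity, [dg], per-non-WT-strain intensity draw when dg_model).
    """
    if not strain_profiles:
        raise ValueError("strain_profiles must be non-empty")
    names = [p.name for p in strain_profiles]
    if len(set(names)) != len(names):
        raise ValueError("duplicate strain profile names")
    wt_name = None
    dg_lo, dg_hi = -25.0, -2.0
    if dg_model is not None:
        wt_name = dg_model["wt_strain"]
        if wt_name not in names:
            raise ValueError(f"dg_model wt_strain {wt_name!r} not a profile")
        dg_lo, dg_hi = dg_model.get("dg_range", (dg_lo, dg_hi))
    rng = np.random.default_rng(seed)
    lo_i, hi_i = base_intensity

    planted: list[PlantedEnd] = []
    terminator_ends: list[TerminatorEnd] = []
    expression: dict[str, float] = {}
    for gene in annotation:
        if gene.biotype != "mRNA":
            continue
        expression[gene.gene_id] = float(rng.uniform(*expression_range))
        interior_lo = gene.cds.start + _CDS_MARGIN
        interior_hi = gene.cds.end - _CDS_MARGIN
        n_avail = interior_hi - interior_lo + 1
        if n_avail < n_per_gene:
            warnings.warn(f"{gene.gene_id}: CDS too short to plant "
                          f"{n_per_gene} end(s); skipped")
            continue
        coords = rng.choice(np.arange(interior_lo, interior_hi + 1),
                            size=n_per_gene, replace=False)
        for c in sorted(int(x) for x in coords):
            base = float(rng.uniform(lo_i, hi_i))
            dg = None
            if dg_model is not None:
                dg = float(rng.uniform(dg_lo, dg_hi))
            intensities: dict[str, float] = {}
            for prof in strain_profiles:
                if dg_model is not None and prof.name == wt_name:
                    # deterministic decreasing link: most stable stem
                    # (dg_lo) → hi_i, least stable (dg_hi) → lo_i
                    u = (dg_hi - dg) / (dg_hi - dg_lo)
                    intensities[prof.name] = (lo_i + u * (hi_i - lo_i)) * prof.end_multiplier
                elif dg_model is not None:
                    intensities[prof.name] = float(rng.uniform(lo_i, hi_i)) * prof.end_multiplier
                else:
                    intensities[prof.name] = base * prof.end_multiplier
            planted.append(PlantedEnd(gene_id=gene.gene_id, coordinate=c,
                                      strand=gene.strand,
                                      intensity_by_strain=intensities,
                                      upstream_stem_dg=dg))
        if gene.terminator is not None:
            tc = gene.terminator.end if gene.strand == FORWARD else gene.terminator.start
            terminator_ends.append(TerminatorEnd(
                gene_id=gene.gene_id, coordinate=tc, strand=gene.strand,
                intensity=terminator_intensity))
    truth = GroundTruth(planted_ends=planted, terminator_ends=terminator_ends,
                        gene_expression=expression)
    truth.validate(annotation)
    return truth


# ---------------------------------------------------------------------------
# Track simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulatedTracks:
    strain: str
    term_seq: dict[str, CoverageTrack]   # strand -> 3'-end coverage
    rna_seq: dict[str, CoverageTrack]    # strand -> RNA-seq coverage
    counts: pd.Series                    # per-gene raw counts


def _ends_to_coverage(end_counts: np.ndarray, strand: str,
                      read_length: int = READ_LENGTH) -> np.ndarray:
    """Coverage from per-base 3'-end counts: each end is a read of fixed
    length terminating exactly at its base, so coverage at i sums the ends
    within read_length downstream (transcript sense) of i."""
    csum = np.concatenate(([0], np.cumsum(end_counts)))
    n = len(end_counts)
    cov = np.empty(n, dtype=np.int64)
    if strand == FORWARD:
        # reads ending at j cover [j-L+1, j]: cov[i] = sum ends[i .. i+L-1]
        hi = np.minimum(np.arange(n) + read_length, n)
        cov = csum[hi] - csum[np.arange(n)]
    else:
        lo = np.maximum(np.arange(n) - read_length + 1, 0)
        cov = csum[np.arange(n) + 1] - csum[lo]
    return cov


def simulate_tracks(annotation: GenomeAnnotation, truth: GroundTruth,
                    profile: StrainProfile, noise_rate: float, seed: int,
                    read_length: int = READ_LENGTH) -> SimulatedTracks:
    """Simulate one strain's Term-seq and RNA-seq coverage.

    Term-seq: every planted end contributes Poisson(intensity) reads ending
    exactly at its coordinate (a coverage step dropping by that count
    immediately 3' of it); terminator ends likewise; background ends are
    i.i.d. Poisson(noise_rate) per base per strand. RNA-seq: deterministic
    uniform per-base depth ``round(expression × expression_scale)`` over the
    transcript (5' UTR through 3' UTR), with the CDS 5' third scaled by the
    configured ratio for ``five_prime_up_genes``. The counts table is the
    per-gene sum of RNA-seq coverage over the CDS.

    Draw order: planted ends in catalog order, terminator ends in catalog
    order, background + strand, background − strand.
    """
    if noise_rate < 0:
        raise ValueError("noise_rate must be >= 0")
    rng = np.random.default_rng(seed)
    n = annotation.genome_length
    ends = {FORWARD: np.zeros(n, dtype=np.int64),
            REVERSE: np.zeros(n, dtype=np.int64)}
    for e in truth.planted_ends:
        count = rng.poisson(e.intensity_by_strain[profile.name])
        ends[e.strand][e.coordinate - 1] += count
    for t in truth.terminator_ends:
        ends[t.strand][t.coordinate - 1] += rng.poisson(t.intensity)
    for strand in (FORWARD, REVERSE):
        ends[strand] += rng.poisson(noise_rate, size=n)

    term_seq = {
        s: CoverageTrack(strand=s, values=_ends_to_coverage(ends[s], s, read_length),
                         assay=ASSAY_TERM3)
        for s in (FORWARD, REVERSE)
    }

    rna = {FORWARD: np.zeros(n, dtype=np.int64),
           REVERSE: np.zeros(n, dtype=np.int64)}
    counts: dict[str, int] = {}
    for gene in annotation:
        if gene.biotype != "mRNA":
            continue
        depth = int(round(truth.gene_expression[gene.gene_id]
                          * profile.expression_scale))
        body = [iv for iv in (gene.utr5, gene.cds, gene.utr3) if iv]
        for iv in body:
            rna[gene.strand][iv.start - 1 : iv.end] = depth
        ratio = profile.five_prime_up_genes.get(gene.gene_id)
        if ratio is not None:
            l5, _, _ = _split_lengths(len(gene.cds))
            if gene.strand == FORWARD:
                lo, hi = gene.cds.start, gene.cds.start + l5 - 1
            else:
                lo, hi = gene.cds.end - l5 + 1, gene.cds.end
            rna[gene.strand][lo - 1 : hi] = int(round(depth * ratio))
        counts[gene.gene_id] = int(
            rna[gene.strand][gene.cds.start - 1 : gene.cds.end].sum())

    rna_seq = {
        s: CoverageTrack(strand=s, values=rna[s], assay=ASSAY_RNASEQ)
        for s in (FORWARD, REVERSE)
    }
    return SimulatedTracks(strain=profile.name, term_seq=term_seq,
                           rna_seq=rna_seq, counts=pd.Series(counts))


def _split_lengths(length: int) -> tuple[int, int, int]:
    base, rem = divmod(length, 3)
    return base + (1 if rem >= 1 else 0), base + (1 if rem >= 2 else 0), base


# ---------------------------------------------------------------------------
# Recovery report and serialization
# ---------------------------------------------------------------------------

def recovery_report(called_coordinates: Mapping[str, Sequence[int]],
                    truth: GroundTruth, strain: str,
                    min_intensity: float = 0.0, tol: int = 0) -> dict:
    """Compare called peak coordinates (by strand) against planted ends.

    Returns recovered / total counts for planted ends whose intensity in
    ``strain`` is at least ``min_intensity``, plus the worst coordinate
    offset among calls that match a planted end within ±2 nt slack bands.
    """
    recovered = total = 0
    offsets = []
    for e in truth.planted_ends:
        if e.intensity_by_strain[strain] < min_intensity:
            continue
        total += 1
        calls = np.asarray(called_coordinates.get(e.strand, ()), dtype=int)
        if calls.size == 0:
            continue
        nearest = int(np.abs(calls - e.coordinate).min())
        offsets.append(nearest)
        if nearest <= tol:
            recovered += 1
    return {
        "total_planted": total,
        "recovered": recovered,
        "recovery_rate": recovered / total if total else float("nan"),
        "offsets": offsets,
    }


def truth_frame(truth: GroundTruth) -> pd.DataFrame:
    strains = sorted({s for e in truth.planted_ends
                      for s in e.intensity_by_strain})
    rows = []
    for e in truth.planted_ends:
        row = {"gene_id": e.gene_id, "coordinate": e.coordinate,
               "strand": e.strand, "upstream_stem_dg": e.upstream_stem_dg}
        for s in strains:
            row[f"intensity_{s}"] = e.intensity_by_strain[s]
        rows.append(row)
    return pd.DataFrame(rows)


def write_dataset(outdir: str | Path, annotation: GenomeAnnotation,
                  truth: GroundTruth,
                  tracks_by_strain: Mapping[str, SimulatedTracks]) -> dict:
    """Write the full synthetic dataset: GFF3 annotation, per-strain
    per-strand bedGraphs for both assays, ground-truth TSV, counts TSV.
    Returns a manifest of written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    gff = outdir / "annotation.gff3"
    write_gff3(annotation, gff)
    paths["annotation"] = str(gff)
    tag = {FORWARD: "plus", REVERSE: "minus"}
    for strain, sim in tracks_by_strain.items():
        for s in (FORWARD, REVERSE):
            p = outdir / f"{strain}.term3end.{tag[s]}.bedgraph"
            write_bedgraph(sim.term_seq[s], p)
            paths[f"{strain}.term3end.{tag[s]}"] = str(p)
            p = outdir / f"{strain}.rnaseq.{tag[s]}.bedgraph"
            write_bedgraph(sim.rna_seq[s], p)
            paths[f"{strain}.rnaseq.{tag[s]}"] = str(p)
    counts = pd.DataFrame({s: sim.counts for s, sim in tracks_by_strain.items()})
    counts.index.name = "gene_id"
    cpath = outdir / "counts.tsv"
    counts.to_csv(cpath, sep="\t")
    paths["counts"] = str(cpath)
    tpath = outdir / "ground_truth.tsv"
    write_table(truth_frame(truth), tpath)
    paths["ground_truth"] = str(tpath)
    return paths
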