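"""Cross-strain 3' end comparison.

The strains under comparison (e.g. wild type, an exonuclease deletion, a
catalytically dead point mutant, a helicase deletion) each yield a filtered
peak list. Peaks from all strains are merged into a superset of distinct 3'
end sites: same-strand coordinates are single-linkage clustered with a ±5 nt
link distance, i.e. coordinates more than ±5 nt apart are different 3' ends.
Every cluster is then quantified in every strain — whether or not a peak was
called there — by taking the maximum Cv within ±5 nt of the representative
coordinate and normalizing it by local upstream expression, flooring at
0.001. All comparative statistics (sharing Venns, log2 fold changes,
64-fold buildup subpopulations, rank-sum tests, positional densities) read
this matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome_io import CoverageTrack, GenomeAnnotation, three_prime_most
from .peaks import CvTrack
from .annotate import (NormalizedPeak, normalize_height,
                       DEFAULT_UPSTREAM_WINDOW, DEFAULT_FLOOR)

DEFAULT_CLUSTER_TOL = 5
DEFAULT_MIN_NORM = 0.53
DEFAULT_FC_THRESHOLD = 64.0

#: Monte-Carlo permutations for tied rank-sum tests, and its fixed seed
_MC_PERMUTATIONS = 100_000
_MC_SEED = 20220400


@dataclass
class PeakCluster:
    """One distinct 3' end site in the cross-strain superset."""

    representative: int
    strand: str
    gene_id: Optional[str]
    members: dict[str, NormalizedPeak] = field(default_factory=dict)

    @property
    def cluster_id(self) -> str:
        return f"{self.gene_id or 'NA'}:{self.representative}{self.strand}"

    @property
    def span(self) -> int:
        coords = [p.coordinate for p in self.members.values()]
        return max(coords) - min(coords) if coords else 0

    @property
    def max_raw_height(self) -> float:
        return max((p.peak.height for p in self.members.values()), default=0.0)


def build_superset(peaks_by_strain: Mapping[str, Sequence[NormalizedPeak]],
                   tol: int = DEFAULT_CLUSTER_TOL) -> list[PeakCluster]:
    """Single-linkage cluster same-site peaks across strains.

    Clustering runs within (strand, gene) groups; two peaks link when their
    coordinates differ by at most ``tol``. The representative is the
    coordinate of the maximum raw Cv over all members (ties broken toward
    the transcript-sense 3'-most coordinate).
    """
    groups: dict[tuple, list[tuple[str, NormalizedPeak]]] = {}
    for strain, peaks in peaks_by_strain.items():
        for p in peaks:
            groups.setdefault((p.strand, p.gene_id), []).append((strain, p))
    clusters: list[PeakCluster] = []
    for (strand, gene_id), items in groups.items():
        items.sort(key=lambda sp: sp[1].coordinate)
        run: list[tuple[str, NormalizedPeak]] = []
        for strain, p in items:
            if run and p.coordinate - run[-1][1].coordinate > tol:
                clusters.append(_finish_cluster(run, strand, gene_id))
                run = []
            run.append((strain, p))
        if run:
            clusters.append(_finish_cluster(run, strand, gene_id))
    clusters.sort(key=lambda c: (c.strand, c.representative))
    return clusters


def _finish_cluster(items: list[tuple[str, NormalizedPeak]], strand: str,
                    gene_id: Optional[str]) -> PeakCluster:
    best = max(p.peak.height for _, p in items)
    tied = [p.coordinate for _, p in items if p.peak.height == best]
    rep = three_prime_most(tied, strand)
    members: dict[str, NormalizedPeak] = {}
    for strain, p in items:
        cur = members.get(strain)
        if cur is None or p.peak.height > cur.peak.height:
            members[strain] = p
    return PeakCluster(representative=rep, strand=strand, gene_id=gene_id,
                       members=members)


@dataclass
class PeakMatrix:
    """Clustered 3' end superset × strain table of normalized heights."""

    clusters: list[PeakCluster]
    values: pd.DataFrame  # index: cluster_id, columns: strains, floored

    def __post_init__(self) -> None:
        if (self.values.values < DEFAULT_FLOOR - 1e-12).any():
            raise ValueError("matrix entries below floor")

    @property
    def strains(self) -> list[str]:
        return list(self.values.columns)

    def cluster(self, cluster_id: str) -> PeakCluster:
        for c in self.clusters:
            if c.cluster_id == cluster_id:
                return c
        raise KeyError(cluster_id)


def fill_matrix(clusters: Sequence[PeakCluster],
                cv_by_strain: Mapping[str, Mapping[str, CvTrack]],
                rnaseq_by_strain: Mapping[str, Mapping[str, CoverageTrack]],
                tol: int = DEFAULT_CLUSTER_TOL,
                window: int = DEFAULT_UPSTREAM_WINDOW,
                floor: float = DEFAULT_FLOOR) -> PeakMatrix:
    """Quantify every cluster in every strain.

    ``cv_by_strain`` / ``rnaseq_by_strain`` map strain → strand → track. The
    entry is the normalized window-max Cv within ±tol of the representative,
    computed from that strain's tracks even when the strain called no peak
    there, floored at 0.001.
    """
    strains = list(cv_by_strain)
    rows = {}
    for c in clusters:
        row = {}
        for strain in strains:
            cv = cv_by_strain[strain][c.strand]
            raw = cv.window_max(c.representative, tol)
            row[strain] = normalize_height(
                raw, c.representative, c.strand,
                rnaseq_by_strain[strain][c.strand], window=window, floor=floor)
        rows[c.cluster_id] = row
    values = pd.DataFrame.from_dict(rows, orient="index", columns=strains)
    values = values.reindex([c.cluster_id for c in clusters])
    return PeakMatrix(clusters=list(clusters), values=values)


# ---------------------------------------------------------------------------
# Sharing and fold-change set statistics
# ---------------------------------------------------------------------------

def shared_sets(matrix: PeakMatrix, min_norm: float = DEFAULT_MIN_NORM
                ) -> dict[frozenset[str], int]:
    """Venn region counts: clusters qualifying (entry >= min_norm) in exactly
    each strain subset. Clusters qualifying nowhere are not counted."""
    counts: dict[frozenset[str], int] = {}
    qualifying = matrix.values >= min_norm
    for _, row in qualifying.iterrows():
        subset = frozenset(row.index[row])
        if subset:
            counts[subset] = counts.get(subset, 0) + 1
    return counts


def strain_totals(region_counts: Mapping[frozenset[str], int]) -> dict[str, int]:
    """Per-strain totals (the per-oval numbers of a Venn diagram)."""
    totals: dict[str, int] = {}
    for subset, n in region_counts.items():
        for s in subset:
            totals[s] = totals.get(s, 0) + n
    return totals


def fold_change_sets(matrix: PeakMatrix, reference: str,
                     fc_threshold: float = DEFAULT_FC_THRESHOLD
                     ) -> tuple[dict[str, set[str]], dict[frozenset[str], int]]:
    """Clusters with >= fc_threshold buildup in each mutant vs the reference.

    Returns (per-mutant cluster-id sets, Venn region counts over mutants).
    """
    if reference not in matrix.values.columns:
        raise ValueError(f"reference strain {reference!r} not in matrix")
    mutants = [s for s in matrix.values.columns if s != reference]
    sets: dict[str, set[str]] = {m: set() for m in mutants}
    for cid, row in matrix.values.iterrows():
        for m in mutants:
            if row[m] / row[reference] >= fc_threshold:
                sets[m].add(cid)
    regions: dict[frozenset[str], int] = {}
    universe = set().union(*sets.values()) if sets else set()
    for cid in universe:
        subset = frozenset(m for m in mutants if cid in sets[m])
        regions[subset] = regions.get(subset, 0) + 1
    return sets, regions


def log2_fold_changes(matrix: PeakMatrix, strain_a: str, strain_b: str
                      ) -> pd.Series:
    """Per-cluster log2(norm_a / norm_b); finite thanks to the floor."""
    return np.log2(matrix.values[strain_a] / matrix.values[strain_b])


# ---------------------------------------------------------------------------
# Rank-sum distribution test
# ---------------------------------------------------------------------------

def distribution_test(values_a: Sequence[float], values_b: Sequence[float],
                      alternative: str = "greater") -> float:
    """One-tailed Wilcoxon rank-sum p-value for values_a vs values_b.

    Tie-free samples with n_a*n_b <= 10,000 get the exact rank-sum tail
    probability; larger tie-free samples the normal approximation with
    continuity correction; samples with ties a seeded Monte-Carlo permutation
    p (mid-rank statistic, 10^5 permutations).
    """
    if alternative not in ("greater", "less"):
        raise ValueError("alternative must be 'greater' or 'less'")
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        warnings.warn("all values identical in both samples; p = 1")
        return 1.0
    has_ties = len(np.unique(pooled)) < pooled.size
    if has_ties:
        return _permutation_ranksum_p(a, b, alternative)
    method = "exact" if a.size * b.size <= 10_000 else "asymptotic"
    return float(stats.mannwhitneyu(a, b, alternative=alternative,
                                    method=method).pvalue)


def _permutation_ranksum_p(a: np.ndarray, b: np.ndarray, alternative: str,
                           n_perm: int = _MC_PERMUTATIONS) -> float:
    """Monte-Carlo permutation p for the mid-rank rank-sum statistic."""
    rng = np.random.default_rng(_MC_SEED)
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    n_a = a.size
    observed = ranks[:n_a].sum()
    perm_stats = np.empty(n_perm)
    for i in range(n_perm):
        perm_stats[i] = rng.permutation(ranks)[:n_a].sum()
    if alternative == "greater":
        extreme = np.count_nonzero(perm_stats >= observed - 1e-9)
    else:
        extreme = np.count_nonzero(perm_stats <= observed + 1e-9)
    return float((extreme + 1) / (n_perm + 1))


# ---------------------------------------------------------------------------
# Positional density across CDSs
# ---------------------------------------------------------------------------

def relative_positions(peaks: Sequence[NormalizedPeak],
                       annotation: GenomeAnnotation) -> np.ndarray:
    """Transcript-sense relative CDS position in [0, 1] for CDS peaks."""
    out = []
    for p in peaks:
        if p.category != "cds" or p.gene_id is None:
            raise ValueError("relative_positions expects CDS-category peaks")
        gene = annotation.gene(p.gene_id)
        length = len(gene.cds)
        if length < 2:
            raise ValueError(f"{gene.gene_id}: CDS too short for a relative position")
        out.append(gene.cds_tx_offset(p.coordinate) / (length - 1))
    return np.asarray(out)


def position_density(positions: Sequence[float], bandwidth: Optional[float] = None,
                     n_grid: int = 201) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian KDE on [0, 1] with boundary reflection at 0 and 1.

    Bandwidth defaults to Silverman's rule on the sample. Reflection makes
    the returned density integrate to 1 on [0, 1] up to far-tail leakage.
    """
    x = np.asarray(positions, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two positions for a density")
    if np.any((x < 0) | (x > 1)):
        raise ValueError("positions must lie in [0, 1]")
    bw = bandwidth if bandwidth is not None else "silverman"
    kde = stats.gaussian_kde(x, bw_method=bw)
    grid = np.linspace(0.0, 1.0, n_grid)
    density = kde(grid) + kde(-grid) + kde(2.0 - grid)
    return grid, density


# ---------------------------------------------------------------------------
# Output tables
# ---------------------------------------------------------------------------

def matrix_frame(matrix: PeakMatrix) -> pd.DataFrame:
    meta = pd.DataFrame(
        [(c.cluster_id, c.gene_id, c.representative, c.strand, c.span)
         for c in matrix.clusters],
        columns=["cluster_id", "gene_id", "coordinate", "strand", "chain_span"],
    ).set_index("cluster_id")
    return meta.join(matrix.values)


def venn_frame(region_counts: Mapping[frozenset[str], int]) -> pd.DataFrame:
    rows = [("&".join(sorted(subset)), n) for subset, n in region_counts.items()]
    rows.sort()
    return pd.DataFrame(rows, columns=["region", "count"])
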