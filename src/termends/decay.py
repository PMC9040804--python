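"""RNA-seq 5'/3' read-ratio decay profiling and the ratio of ratios (RR).

If mRNA decay initiates with an internal endonucleolytic cut, the upstream
(5') fragment depends on a 3' exoribonuclease for its removal; losing that
enzyme makes 5'-proximal sequence accumulate relative to 3'-proximal
sequence. Each CDS is split transcript-sense into three near-equal thirds
and the mean reads/base of the 5' third is compared with the 3' third:
genes are 5'-up (>= 1.5-fold more reads in the 5' third), 3'-up (the
converse) or 5'=3'. The RR of a gene is its mutant 5'/3' ratio divided by
its wild-type 5'/3' ratio; genes with RR > 1.5 depend on the missing
exonuclease for decay of the endonucleolytic upstream fragment. Raw counts
are brought onto a common scale with median-of-ratios size factors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome_io import FORWARD, CoverageTrack, GeneModel

DEFAULT_THIRDS_THRESHOLD = 1.5


# ---------------------------------------------------------------------------
# Size factors
# ---------------------------------------------------------------------------

def median_of_ratios(counts: pd.DataFrame
                     ) -> tuple[pd.Series, pd.DataFrame]:
    """Median-of-ratios size factors and normalized counts.

    The reference is the per-gene geometric mean across strains; genes with
    a zero count in any strain are excluded from factor estimation. The size
    factor of a strain is the median over genes of count/reference, and
    normalized counts are raw counts divided by the factor.
    """
    if counts.shape[1] < 2:
        raise ValueError("need at least two strains")
    c = counts.astype(float)
    nonzero = (c > 0).all(axis=1)
    if not nonzero.any():
        raise ValueError("no gene with nonzero counts in all strains")
    sub = c.loc[nonzero]
    ref = np.exp(np.log(sub).mean(axis=1))  # per-gene geometric mean
    factors = sub.div(ref, axis=0).median(axis=0)
    factors.name = "size_factor"
    normalized = c.div(factors, axis=1)
    return factors, normalized


# ---------------------------------------------------------------------------
# Thirds profiles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ThirdsProfile:
    gene_id: str
    strain: str
    reads_5: float  # mean reads/base, 5' one-third of the CDS
    reads_m: float
    reads_3: float


def _third_lengths(length: int) -> tuple[int, int, int]:
    """Partition a CDS length into thirds differing by <= 1 base, the 5'
    segment taking the first extra base."""
    base, rem = divmod(length, 3)
    return base + (1 if rem >= 1 else 0), base + (1 if rem >= 2 else 0), base


def thirds_profile(rnaseq: CoverageTrack, gene: GeneModel,
                   strain: str = "", scale: float = 1.0) -> ThirdsProfile:
    """Mean reads/base over the transcript-sense thirds of the CDS.

    ``scale`` divides the coverage (use a median-of-ratios size factor to
    put strains on a common scale).
    """
    if len(gene.cds) < 3:
        raise ValueError(f"{gene.gene_id}: CDS too short to split into thirds")
    values = rnaseq.slice(gene.cds.start, gene.cds.end).astype(float) / scale
    if gene.strand != FORWARD:
        values = values[::-1]  # now transcript sense, 5'->3'
    l5, lm, l3 = _third_lengths(len(values))
    return ThirdsProfile(
        gene_id=gene.gene_id, strain=strain,
        reads_5=float(values[:l5].mean()),
        reads_m=float(values[l5 : l5 + lm].mean()),
        reads_3=float(values[l5 + lm :].mean()),
    )


def categorize(profile: ThirdsProfile,
               threshold: float = DEFAULT_THIRDS_THRESHOLD) -> Optional[str]:
    """'five_up' | 'three_up' | 'equal'; None (uncategorizable) if both the
    5' and 3' thirds have zero coverage. The threshold is boundary-inclusive:
    a ratio of exactly 1.5 is 5'-up (or 3'-up)."""
    r5, r3 = profile.reads_5, profile.reads_3
    if r5 == 0 and r3 == 0:
        return None
    if r3 == 0 or (r3 > 0 and r5 / r3 >= threshold):
        return "five_up"
    if r5 == 0 or r3 / r5 >= threshold:
        return "three_up"
    return "equal"


def category_summary(profiles: Sequence[ThirdsProfile],
                     threshold: float = DEFAULT_THIRDS_THRESHOLD
                     ) -> pd.Series:
    """Category percentages over categorizable genes (pie-chart-ready)."""
    cats = [categorize(p, threshold) for p in profiles]
    cats = [c for c in cats if c is not None]
    if not cats:
        return pd.Series(dtype=float)
    counts = pd.Series(cats).value_counts()
    return (counts / counts.sum() * 100.0).reindex(
        ["five_up", "equal", "three_up"], fill_value=0.0)


# ---------------------------------------------------------------------------
# Ratio of ratios
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RRRecord:
    gene_id: str
    mutant: str
    ratio_wt: float
    ratio_mut: float
    rr: float


def ratio_of_ratios(profiles_mut: Mapping[str, ThirdsProfile],
                    profiles_wt: Mapping[str, ThirdsProfile]
                    ) -> list[RRRecord]:
    """Per-gene (mutant 5'/3' ratio) / (wild-type 5'/3' ratio).

    Genes with zero mean coverage in the 5' or 3' third of either strain are
    excluded rather than pseudocounted; the number skipped is reported in a
    warning.
    """
    shared = sorted(set(profiles_mut) & set(profiles_wt))
    if not shared:
        raise ValueError("no shared genes between strains")
    out: list[RRRecord] = []
    skipped = 0
    for gid in shared:
        pm, pw = profiles_mut[gid], profiles_wt[gid]
        if min(pm.reads_5, pm.reads_3, pw.reads_5, pw.reads_3) <= 0:
            skipped += 1
            continue
        ratio_mut = pm.reads_5 / pm.reads_3
        ratio_wt = pw.reads_5 / pw.reads_3
        out.append(RRRecord(gene_id=gid, mutant=pm.strain,
                            ratio_wt=ratio_wt, ratio_mut=ratio_mut,
                            rr=ratio_mut / ratio_wt))
    if skipped:
        warnings.warn(f"{skipped} gene(s) excluded from RR: zero-coverage third")
    return out


def rr_correlation(rr_a: Sequence[RRRecord], rr_b: Sequence[RRRecord]
                   ) -> Optional[float]:
    """Pearson r of RR values over genes defined in both mutants; None when
    fewer than 3 shared genes or zero variance."""
    a = {r.gene_id: r.rr for r in rr_a}
    b = {r.gene_id: r.rr for r in rr_b}
    shared = sorted(set(a) & set(b))
    if len(shared) < 3:
        warnings.warn("fewer than 3 shared genes; correlation undefined")
        return None
    x = np.array([a[g] for g in shared])
    y = np.array([b[g] for g in shared])
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        warnings.warn("zero variance in RR values; correlation undefined")
        return None
    return float(stats.pearsonr(x, y).statistic)


def rr_frame(records: Sequence[RRRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.gene_id, r.mutant, r.ratio_wt, r.ratio_mut, r.rr) for r in records],
        columns=["gene_id", "mutant", "ratio_wt", "ratio_mut", "rr"],
    )
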