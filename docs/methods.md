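# Methods

This note documents the models, conventions and numerical choices behind
`termends`, and what the synthetic data does and does not establish.

## Coordinate and strand model

All APIs use 1-based inclusive genomic coordinates on a single chromosome;
the only 0-based surface is bedGraph serialization (UCSC dialect, 0-based
half-open). "Upstream" and "downstream" are always transcript-sense (5′→3′
of the feature's strand): the 50-nt normalization window and the 40-nt
folding window of a − strand 3′ end lie at higher genomic coordinates.
Multi-chromosome genomes are out of scope.

## Coverage variation and peak calling

A free 3′ end produces a coverage step that falls immediately 3′ of the
terminal base. Cv is defined as that transcript-sense drop, clipped at
zero:

    Cv(i) = max(0, c(i) − c(i′)),   i′ = the base immediately 3′ of i,

with c(i′) = 0 beyond the genome boundary. "First-order derivative" admits
two sign conventions; the drop direction is the normative choice here
because it makes Cv(i) equal, in expectation, the number of RNA molecules
terminating exactly at i.

Peaks are Cv local maxima within a ±2 nt window (configurable) with height
≥ 10. The window is a deliberate smoother: 3′-end pile-ups form "mounds"
whose shoulders would otherwise be called as separate ends. Among tied
maxima inside one window only the transcript-sense 3′-most base is
reported — the terminal nucleotide is the biologically meaningful 3′ end —
so no two reported peaks lie within the window of each other. Replicates
are summed before Cv (`merge_replicates`); per-replicate calling is
available for QC by simply not merging.

## Normalization

norm_height = max(raw_Cv / log10(max(m, 10)), 0.001), where m is the
median RNA-seq coverage over the 50 nt immediately upstream of the peak.
The clamp of m at 10 is a guard this package adds: below 10 the log10
denominator would fall under 1 (or become zero/negative) and inflate raw
heights exactly where expression evidence is weakest. The ≥ 1 read/base
expression filter makes the clamp rarely bind in practice. The 0.001 floor
keeps log fold changes finite. The window truncates at the genome boundary;
with no upstream bases at all, the floor is returned.

## Classification and filtering

Category precedence on overlap is terminator > tRNA/rRNA > 5′ UTR > CDS >
3′ UTR > intergenic, strand-matched. Terminator 3′ ends are transcription
products, not decay intermediates; tRNA/rRNA ends are processing products;
5′ UTR ends are mostly riboswitch/attenuator products — all are excluded
from the decay-intermediate set, which keeps CDS peaks of monocistronic
genes (operon decay is confounded) expressed at ≥ 1 read/base in every
strain. The ≥ 10 raw-height requirement uses "any strain" semantics at the
cross-strain superset stage; single-strain analyses apply it per strain.
Genes without an annotated 5′ UTR treat the gene-start..CDS-start gap as 5′
UTR. 3′-UTR ends are those strictly between the stop codon and the
annotated intrinsic terminator; genes lacking a terminator are skipped.

## Cross-strain superset and matrix

Same-strand, same-gene peak coordinates are single-linkage clustered with a
±5 nt link distance; coordinates farther apart are distinct 3′ ends. Single
linkage can chain beyond 5 nt total span; this is accepted because the rule
is pairwise, and each cluster's chain span is reported for QC. The
representative coordinate is the maximum raw Cv across members (tie →
3′-most).

Every (site, strain) matrix entry is computed from that strain's tracks
whether or not the strain called a peak there: the maximum Cv within ±5 nt
of the representative, normalized and floored. The sharing test (entry ≥
0.53 in all compared strains) therefore measures 3′-end *density*, not
peak-call agreement — a called peak one strain and sub-threshold but
substantial signal in another still count as shared. The 0.53 default is a
data-derived constant in the original setting (the minimum normalized
abundance among wild-type monocistronic ends) and is exposed as a
parameter. Whether sharing should be evaluated at the exact representative
coordinate or over the ±5 window is not fully determined by the source
material; the window-max is this package's choice, consistent with how the
matrix is filled.

Buildup subpopulations are clusters whose mutant/reference normalized ratio
is ≥ 64 (boundary inclusive); the strict threshold selects ends with
essentially no wild-type abundance.

## Rank-sum tests

`distribution_test` is a one-tailed Wilcoxon rank-sum. Tie-free samples
with n_a·n_b ≤ 10,000 use the exact rank-sum distribution
(scipy's exact method); larger tie-free samples the normal approximation
with continuity correction; tied samples a Monte-Carlo permutation p on the
mid-rank statistic (10⁵ permutations, fixed internal seed, add-one
estimator) — with ties, "exact" enumeration is ambiguous, and the floored
matrix columns are heavily tied at 0.001. Identical constant samples return
p = 1 with a degenerate-data warning.

## Positional density

A peak's relative CDS position is (transcript-sense offset)/(L−1) ∈ [0,1].
The density is a Gaussian KDE (Silverman bandwidth by default) with
reflection at 0 and 1, so the curve integrates to 1 on [0,1] up to far-tail
leakage; tests verify quadrature to 10⁻³.

## Upstream structure

The folding window is the 40 nt immediately 5′ of — and excluding — the
3′-end base (the inclusion question is underdetermined; exclusion is this
package's convention), reverse-complemented on the − strand, T→U, truncated
with a flag at the genome boundary.

The built-in folding engine is an intentionally reduced nearest-neighbor
model: canonical + wobble pairs, published stacking free energies for the
36 stack types, one flat +4 kcal/mol hairpin-closing penalty, minimum loop
of 3, no bulge/internal-loop/multiloop terms, nested structures only, MFE
clamped at ≤ 0. The dynamic program tracks the minimum over *non-empty*
structures without clamping intermediate values at zero: a positive-energy
substructure (e.g. a lone short helix) can still be the best interior of an
enclosing pair because the alternative — an empty interior — costs the
hairpin penalty. Tests verify the DP against exhaustive enumeration of all
nested structures for sequences up to length 14. Absolute ΔG values differ
from full nearest-neighbor implementations; every statistic in this package
depends only on ΔG ordering or sign, which the reduced model preserves (a
cross-check against RNAfold ordering runs when the tool is installed). The
`external` engine shells out to a configurable command and parses the
trailing `( MFE )` field, falling back to the builtin with a warning if the
tool is missing.

Association is Spearman rank correlation of log₁₀ normalized abundance with
ΔG plus an OLS slope t-test, over sites with normalized abundance ≥ 0.53.

## Decay ratios

CDS thirds are transcript-sense segments whose lengths differ by ≤ 1 base,
the 5′ segment taking the first extra base; means (reads/base) rather than
sums make thirds comparable when L mod 3 ≠ 0. Categories at threshold 1.5
are boundary-inclusive. Genes with zero mean coverage in both the 5′ and 3′
third are uncategorizable; genes with a zero third in either strain are
excluded from RR rather than pseudocounted (no fabricated ratios; the count
of exclusions is warned). RR is computed from size-factor-normalized
coverage; the factors cancel inside RR itself but keep the category
thresholds comparable across strains. Size factors use the median-of-ratios
formula: per-gene geometric-mean reference over all-nonzero genes,
per-strain median of count/reference.

## Synthetic data: what it emulates and what it does not

The generator lays out non-overlapping genes (5′ UTR, CDS divisible by 3,
3′ UTR, 30-nt terminator) with random strands and gaps; defaults are 50
genes, all monocistronic, CDS 300–900 nt. Planted decay-intermediate ends
sit uniformly in CDS interiors ≥ 10 nt from the bounds, one per gene by
default, with base intensities uniform on [50, 200] expected reads scaled
by each strain's end multiplier (wild type 1×, PNPase-deficient strains 5×,
helicase-deficient 3× — chosen to mirror the several-fold global buildup
such mutants show). Terminator ends are planted at intensity 300.
Background 3′ ends are i.i.d. Poisson(0.1)/base — the simplest model that
exercises the ≥ 10 threshold; the true noise floor of real Term-seq tracks
is not characterized here, and the rate is a free parameter, not an
estimate of any dataset. Reads are 75 nt; only the terminus position
matters to the Cv detector, so read length affects coverage shoulders only.

RNA-seq coverage is deterministic and uniform per transcript at
round(expression × scale) reads/base, expression uniform on [20, 100]
reads/base so every gene passes the 1 read/base filter; genes in a
profile's `five_prime_up_genes` get their CDS 5′ third multiplied by the
configured ratio. The counts table is the per-gene CDS coverage sum. With
a `dg_model`, each planted end receives a stem ΔG uniform on [−25, −2]
kcal/mol and the wild-type intensity becomes a deterministic decreasing
function of ΔG while mutant intensities are ΔG-independent draws — so the
pipeline should recover a negative wild-type Spearman correlation and
attenuated mutant correlations, which is exactly what the direction-recovery
tests assert.

What passing tests therefore show: the detector, filters, set statistics
and ratio metrics are correct against their definitions and recover planted
effects under Poisson noise. What they do not show: robustness to mapping
artifacts, autocorrelated coverage noise, operon read-through, rRNA
contamination, or library-specific end biases, none of which the generator
models. Each operation draws from a single seeded generator; the draw order
is documented per operation and is part of the stable API.

## Pipeline and problem sizes

`run_pipeline` composes callpeaks → annotate → compare → structure
(optional, FASTA-gated) → decay, validates the config before any stage
runs, logs per-stage record counts, and writes a manifest (tool version,
config hash, input checksums, seed) with no timestamps so reruns are
byte-identical. Test and acceptance runs use 50–80 gene genomes
(~50–90 kb), one planted end per gene and the default depths above — large
enough for ~50-site supersets and stable rank statistics while keeping the
full suite in seconds.

## Known limitations

- Single chromosome; no BAM/FASTQ handling (tracks are the input contract).
- The reduced folding model's absolute ΔG values are not comparable to
  RNAStructure/ViennaRNA outputs; only ordering/sign are.
- Terminator catalogs are taken from the annotation as given, never
  re-derived.
- The sharing and fold-change thresholds (0.53, 64) are exposed defaults
  whose original values are data-derived; on other datasets they should be
  re-derived, not reused blindly.
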