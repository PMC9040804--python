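"""Shared fixtures: a hand-built micro-annotation for precision tests and a
seeded four-strain synthetic dataset for integration-level checks."""

from __future__ import annotations

import numpy as np
import pytest

import termends as te


@pytest.fixture
def micro_annotation() -> te.GenomeAnnotation:
    """Two mRNA genes (one per strand), a tRNA, and a polycistronic gene."""
    genes = [
        te.GeneModel("geneA", "+", cds=te.Interval(101, 400),
                     utr5=te.Interval(61, 100), utr3=te.Interval(401, 480),
                     terminator=te.Interval(481, 510)),
        te.GeneModel("geneB", "-", cds=te.Interval(641, 940),
                     utr5=te.Interval(941, 980), utr3=te.Interval(561, 640),
                     terminator=te.Interval(531, 560)),
        te.GeneModel("trnaC", "+", cds=te.Interval(1001, 1075),
                     biotype="tRNA"),
        te.GeneModel("geneD", "+", cds=te.Interval(1101, 1400),
                     utr5=te.Interval(1081, 1100), utr3=te.Interval(1401, 1450),
                     terminator=te.Interval(1451, 1480),
                     operon_class="polycistronic"),
    ]
    return te.GenomeAnnotation(genome_length=1600, genes=genes)


STRAIN_PROFILES = [
    te.StrainProfile("WT", end_multiplier=1.0),
    te.StrainProfile("dpnpA", end_multiplier=5.0),
    te.StrainProfile("pnpA_pm", end_multiplier=5.0),
    te.StrainProfile("dcshA", end_multiplier=3.0),
]


@pytest.fixture(scope="session")
def four_strain_dataset():
    """The default study conditions: 50 monocistronic genes, one planted end
    per gene, Poisson background 0.1/base, WT vs three elevated-multiplier
    mutants; seed 42 throughout."""
    annotation = te.generate_genome(50, seed=42, mono_fraction=1.0)
    truth = te.plant_ends(annotation, n_per_gene=1, seed=43,
                          strain_profiles=STRAIN_PROFILES)
    tracks = {
        p.name: te.simulate_tracks(annotation, truth, p, noise_rate=0.1,
                                   seed=44 + i)
        for i, p in enumerate(STRAIN_PROFILES)
    }
    return annotation, truth, tracks


def analyse_strains(annotation, tracks, min_height=10.0, window=2,
                    min_rpb=1.0):
    """Call, annotate and filter peaks for every strain; return the filtered
    peak dict plus the per-strain Cv and RNA-seq track maps (test helper
    mirroring the pipeline's first stages)."""
    import pandas as pd

    counts = pd.DataFrame({name: sim.counts for name, sim in tracks.items()})
    from termends.decay import median_of_ratios

    size_factors, _ = median_of_ratios(counts)
    expression = te.ExpressionTable.from_counts(counts, annotation, size_factors)
    cv_by_strain, rna_by_strain, filtered = {}, {}, {}
    for name, sim in tracks.items():
        cv_by_strain[name] = {s: te.compute_cv(sim.term_seq[s]) for s in "+-"}
        rna_by_strain[name] = sim.rna_seq
        peaks = []
        for s in "+-":
            called = te.call_peaks(cv_by_strain[name][s], min_height=min_height,
                                   window=window)
            peaks.extend(te.annotate_peaks(called, annotation, sim.rna_seq[s]))
        filtered[name] = te.filter_monocistronic_cds(
            peaks, annotation, expression, min_rpb=min_rpb,
            min_height=min_height)
    return filtered, cv_by_strain, rna_by_strain
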