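"""Generator invariants: determinism, construction guarantees, calibration."""

import warnings

import numpy as np
import pytest

import termends as te
from termends.synthetic import READ_LENGTH, truth_frame


PROFILES = [te.StrainProfile("WT"), te.StrainProfile("mut", end_multiplier=5.0)]


class TestGenerateGenome:
    def test_mono_fraction_forces_class(self):
        anno = te.generate_genome(10, seed=1, mono_fraction=1.0)
        assert len(anno) == 10
        assert all(g.operon_class == "monocistronic" for g in anno)

    def test_zero_genes_rejected(self):
        with pytest.raises(ValueError):
            te.generate_genome(0, seed=1)

    def test_mono_poly_split_and_determinism(self):
        a = te.generate_genome(50, seed=7, mono_fraction=0.6)
        b = te.generate_genome(50, seed=7, mono_fraction=0.6)
        n_mono = sum(g.operon_class == "monocistronic" for g in a)
        assert (n_mono, len(a) - n_mono) == (30, 20)
        assert a.genes == b.genes and a.genome_length == b.genome_length

    def test_genes_do_not_overlap_and_fit_genome(self):
        anno = te.generate_genome(30, seed=3, mono_fraction=0.5)
        spans = sorted((g.span.start, g.span.end) for g in anno)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 < s2
        assert spans[-1][1] <= anno.genome_length

    def test_cds_length_divisible_by_three(self):
        anno = te.generate_genome(20, seed=9)
        assert all(len(g.cds) % 3 == 0 for g in anno)

    def test_sizing_error_when_genome_too_small(self):
        with pytest.raises(ValueError):
            te.generate_genome(50, seed=1, genome_length=1000)

    def test_trna_rrna_flags(self):
        anno = te.generate_genome(20, seed=5, n_trna_rrna=4)
        flagged = [g for g in anno if g.biotype in ("tRNA", "rRNA")]
        assert len(flagged) == 4


class TestPlantEnds:
    def test_counts_and_per_strain_intensities(self):
        anno = te.generate_genome(10, seed=1)
        truth = te.plant_ends(anno, n_per_gene=1, seed=2,
                              strain_profiles=PROFILES)
        assert len(truth.planted_ends) == 10
        for e in truth.planted_ends:
            assert set(e.intensity_by_strain) == {"WT", "mut"}
            assert e.intensity_by_strain["mut"] == \
                pytest.approx(5 * e.intensity_by_strain["WT"])

    def test_coordinates_inside_cds_interior(self):
        anno = te.generate_genome(20, seed=4)
        truth = te.plant_ends(anno, n_per_gene=2, seed=5,
                              strain_profiles=PROFILES)
        for e in truth.planted_ends:
            cds = anno.gene(e.gene_id).cds
            assert cds.start + 10 <= e.coordinate <= cds.end - 10
            assert e.strand == anno.gene(e.gene_id).strand

    def test_deterministic_for_fixed_seed(self):
        anno = te.generate_genome(10, seed=1)
        t1 = te.plant_ends(anno, 1, seed=9, strain_profiles=PROFILES)
        t2 = te.plant_ends(anno, 1, seed=9, strain_profiles=PROFILES)
        assert truth_frame(t1).equals(truth_frame(t2))

    def test_short_cds_skipped_with_warning(self):
        genes = [te.GeneModel("tiny", "+", cds=te.Interval(101, 121))]
        anno = te.GenomeAnnotation(genome_length=300, genes=genes)
        with pytest.warns(UserWarning):
            truth = te.plant_ends(anno, n_per_gene=5, seed=1,
                                  strain_profiles=PROFILES)
        assert truth.planted_ends == []

    def test_empty_profiles_rejected(self):
        anno = te.generate_genome(5, seed=1)
        with pytest.raises(ValueError):
            te.plant_ends(anno, 1, seed=1, strain_profiles=[])

    def test_dg_model_monotone_link_in_wt(self):
        anno = te.generate_genome(30, seed=6)
        truth = te.plant_ends(anno, 1, seed=7, strain_profiles=PROFILES,
                              dg_model={"wt_strain": "WT"})
        dgs = np.array([e.upstream_stem_dg for e in truth.planted_ends])
        wt = np.array([e.intensity_by_strain["WT"] for e in truth.planted_ends])
        # perfectly monotone decreasing by construction
        order = np.argsort(dgs)
        assert np.all(np.diff(wt[order]) <= 0)


class TestSimulateTracks:
    def test_tracks_nonnegative_integer_everywhere(self):
        anno = te.generate_genome(10, seed=1)
        truth = te.plant_ends(anno, 1, seed=2, strain_profiles=PROFILES)
        sim = te.simulate_tracks(anno, truth, PROFILES[0], noise_rate=0.2,
                                 seed=3)
        for track in list(sim.term_seq.values()) + list(sim.rna_seq.values()):
            assert track.values.dtype.kind == "i"
            assert (track.values >= 0).all()

    def test_noise_free_cv_equals_poisson_draw_at_planted_coordinate(self):
        anno = te.generate_genome(5, seed=1)
        truth = te.plant_ends(anno, 1, seed=2, strain_profiles=PROFILES)
        sim = te.simulate_tracks(anno, truth, PROFILES[0], noise_rate=0.0,
                                 seed=3)
        for e in truth.planted_ends:
            cv = te.compute_cv(sim.term_seq[e.strand])
            # the only signal near the coordinate is the planted end itself
            assert cv.at(e.coordinate) >= 0
            lam = e.intensity_by_strain["WT"]
            assert abs(cv.at(e.coordinate) - lam) < 6 * np.sqrt(lam)

    def test_coverage_step_shape(self):
        genes = [te.GeneModel("g", "+", cds=te.Interval(201, 500))]
        anno = te.GenomeAnnotation(genome_length=800, genes=genes)
        truth = te.GroundTruth(
            planted_ends=[te.PlantedEnd("g", 300, "+", {"WT": 100.0})],
            terminator_ends=[], gene_expression={"g": 50.0})
        sim = te.simulate_tracks(anno, truth, te.StrainProfile("WT"),
                                 noise_rate=0.0, seed=4)
        v = sim.term_seq["+"].values
        count = v[299]
        assert v[300] == 0                         # drop immediately 3'
        assert v[299 - READ_LENGTH] == 0           # base 5' of the read start
        assert (v[300 - READ_LENGTH : 300] == count).all()

    def test_law_of_large_numbers_at_100_replicates(self):
        genes = [te.GeneModel("g", "+", cds=te.Interval(201, 500))]
        anno = te.GenomeAnnotation(genome_length=800, genes=genes)
        truth = te.GroundTruth(
            planted_ends=[te.PlantedEnd("g", 300, "+", {"WT": 80.0})],
            terminator_ends=[], gene_expression={"g": 50.0})
        total = 0.0
        for rep in range(100):
            sim = te.simulate_tracks(anno, truth, te.StrainProfile("WT"),
                                     noise_rate=0.0, seed=1000 + rep)
            total += te.compute_cv(sim.term_seq["+"]).at(300)
        assert total / (100 * 80.0) == pytest.approx(1.0, abs=0.05)

    def test_five_prime_up_ratio_forced_exactly(self, micro_annotation):
        profile = te.StrainProfile("mut", five_prime_up_genes={"geneA": 3.0})
        truth = te.plant_ends(micro_annotation, 1, seed=5,
                              strain_profiles=[profile],
                              expression_range=(50.0, 50.0))
        sim = te.simulate_tracks(micro_annotation, truth, profile,
                                 noise_rate=0.0, seed=6)
        p = te.thirds_profile(sim.rna_seq["+"], micro_annotation.gene("geneA"))
        assert p.reads_5 / p.reads_3 == pytest.approx(3.0)

    def test_counts_consistent_with_coverage_sums(self):
        anno = te.generate_genome(8, seed=2)
        truth = te.plant_ends(anno, 1, seed=3, strain_profiles=PROFILES)
        sim = te.simulate_tracks(anno, truth, PROFILES[1], noise_rate=0.1,
                                 seed=4)
        for gene in anno:
            cds_sum = sim.rna_seq[gene.strand].slice(gene.cds.start,
                                                     gene.cds.end).sum()
            assert sim.counts[gene.gene_id] == cds_sum

    def test_deterministic_tracks_for_fixed_seed(self):
        anno = te.generate_genome(6, seed=1)
        truth = te.plant_ends(anno, 1, seed=2, strain_profiles=PROFILES)
        s1 = te.simulate_tracks(anno, truth, PROFILES[0], 0.1, seed=5)
        s2 = te.simulate_tracks(anno, truth, PROFILES[0], 0.1, seed=5)
        for strand in "+-":
            np.testing.assert_array_equal(s1.term_seq[strand].values,
                                          s2.term_seq[strand].values)


class TestDownstreamDirection:
    def test_mutant_multiplier_gives_positive_median_log2fc(
            self, four_strain_dataset):
        from conftest import analyse_strains

        annotation, truth, tracks = four_strain_dataset
        filtered, cv, rna = analyse_strains(annotation, tracks)
        clusters = te.build_superset(filtered)
        matrix = te.fill_matrix(clusters, cv, rna)
        lfc = te.log2_fold_changes(matrix, "dpnpA", "WT")
        assert float(np.median(lfc)) > 0


class TestWriteDataset:
    def test_round_trip_through_files(self, tmp_path):
        anno = te.generate_genome(5, seed=1)
        truth = te.plant_ends(anno, 1, seed=2, strain_profiles=PROFILES)
        tracks = {p.name: te.simulate_tracks(anno, truth, p, 0.1, seed=3 + i)
                  for i, p in enumerate(PROFILES)}
        paths = te.write_dataset(tmp_path, anno, truth, tracks)
        back = te.read_gff3(paths["annotation"])
        assert back.genes == anno.genes
        track = te.read_bedgraph(paths["WT.term3end.plus"],
                                 anno.genome_length, "+")
        np.testing.assert_array_equal(track.values,
                                      tracks["WT"].term_seq["+"].values)
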