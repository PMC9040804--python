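"""End-to-end pipeline: configuration, stage composition, and run manifests.

``run_pipeline`` executes callpeaks → annotate → compare → structure
(optional) → decay over a declarative :class:`RunConfig`, writing every
stage output as a TSV plus a JSON manifest with the config hash, input
checksums and seed. Identical config and inputs produce byte-identical
outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .genome_io import (ASSAY_RNASEQ, ASSAY_TERM3, FORWARD, REVERSE,
                        read_bedgraph, read_fasta, read_gff3, write_table)
from .peaks import call_peaks, compute_cv
from .annotate import (ExpressionTable, annotate_peaks,
                       filter_monocistronic_cds, find_utr3_peaks, peaks_frame)
from .compare import (build_superset, fill_matrix, fold_change_sets,
                      log2_fold_changes, matrix_frame, position_density,
                      relative_positions, shared_sets, strain_totals,
                      distribution_test, venn_frame)
from .structure import associate, fold_mfe, upstream_sequence
from .decay import (category_summary, median_of_ratios, ratio_of_ratios,
                    rr_correlation, rr_frame, thirds_profile)

log = logging.getLogger("termends")

_STRANDS = {"plus": FORWARD, "minus": REVERSE}


@dataclass
class StrainInputs:
    name: str
    term_bedgraph: dict[str, str]    # {"plus": path, "minus": path}
    rnaseq_bedgraph: dict[str, str]


@dataclass
class RunConfig:
    """Declarative run description; mirrors the YAML config file 1:1."""

    strains: list[StrainInputs]
    annotation: str
    counts: str
    reference: str
    outdir: str = "termends_out"
    fasta: Optional[str] = None
    seed: int = 0
    min_height: float = 10.0
    window: int = 2
    tol: int = 5
    min_norm: float = 0.53
    fc: float = 64.0
    rpb: float = 1.0
    floor: float = 1e-3
    upstream_window: int = 50
    dg_window: int = 40
    thirds_threshold: float = 1.5

    def validate(self) -> None:
        names = [s.name for s in self.strains]
        if len(set(names)) != len(names):
            raise ValueError("duplicate strain names")
        if self.reference not in names:
            raise ValueError(f"reference strain {self.reference!r} not in "
                             f"strain list {names}")
        for thr in ("min_height", "window", "tol", "min_norm", "fc", "rpb",
                    "floor", "upstream_window", "dg_window", "thirds_threshold"):
            if getattr(self, thr) <= 0:
                raise ValueError(f"{thr} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw.update({k: v for k, v in overrides.items() if v is not None})
        strains = [StrainInputs(**s) for s in raw.pop("strains")]
        return cls(strains=strains, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


def _checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


@dataclass
class PipelineResult:
    matrix: "pd.DataFrame"
    region_counts: dict
    fc_regions: dict
    outputs: dict[str, str]
    manifest: dict


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute all stages; see the module docstring for the stage order."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}

    annotation = read_gff3(config.annotation)
    n = annotation.genome_length
    counts = pd.read_csv(config.counts, sep="\t", index_col=0)
    strain_names = [s.name for s in config.strains]
    log.info("stage callpeaks: %d strains, genome %d bp", len(strain_names), n)

    cv_tracks: dict[str, dict] = {}
    rnaseq_tracks: dict[str, dict] = {}
    peaks_by_strain: dict[str, list] = {}
    raw_peak_counts: dict[str, int] = {}
    for strain in config.strains:
        cv_tracks[strain.name] = {}
        rnaseq_tracks[strain.name] = {}
        all_norm = []
        for tag, s in _STRANDS.items():
            term = read_bedgraph(strain.term_bedgraph[tag], n, s, ASSAY_TERM3)
            rna = read_bedgraph(strain.rnaseq_bedgraph[tag], n, s, ASSAY_RNASEQ)
            cv = compute_cv(term)
            cv_tracks[strain.name][s] = cv
            rnaseq_tracks[strain.name][s] = rna
            called = call_peaks(cv, min_height=config.min_height,
                                window=config.window)
            all_norm.extend(annotate_peaks(called, annotation, rna,
                                           window=config.upstream_window,
                                           floor=config.floor))
        peaks_by_strain[strain.name] = all_norm
        raw_peak_counts[strain.name] = len(all_norm)
        log.info("  %s: %d peaks called", strain.name, len(all_norm))

    # expression filter from size-factor-normalized counts
    size_factors, _ = median_of_ratios(counts[strain_names])
    expression = ExpressionTable.from_counts(counts[strain_names], annotation,
                                             size_factors)
    filtered = {
        name: filter_monocistronic_cds(peaks, annotation, expression,
                                       min_rpb=config.rpb,
                                       min_height=config.min_height)
        for name, peaks in peaks_by_strain.items()
    }
    for name, peaks in filtered.items():
        log.info("stage annotate: %s %d monocistronic CDS peaks", name, len(peaks))
        frame = peaks_frame(peaks, name)
        path = outdir / f"peaks.{name}.tsv"
        write_table(frame, path)
        outputs[f"peaks.{name}"] = str(path)

    utr3 = {
        name: find_utr3_peaks(peaks, annotation, expression, min_rpb=config.rpb)
        for name, peaks in peaks_by_strain.items()
    }
    utr3_counts = {name: len(p) for name, p in utr3.items()}

    log.info("stage compare")
    clusters = build_superset(filtered, tol=config.tol)
    matrix = fill_matrix(clusters, cv_tracks, rnaseq_tracks, tol=config.tol,
                         window=config.upstream_window, floor=config.floor)
    mpath = outdir / "matrix.tsv"
    write_table(matrix_frame(matrix).reset_index(), mpath)
    outputs["matrix"] = str(mpath)

    region_counts = shared_sets(matrix, min_norm=config.min_norm)
    vpath = outdir / "venn_shared.tsv"
    write_table(venn_frame(region_counts), vpath)
    outputs["venn_shared"] = str(vpath)
    log.info("  %d clusters; shared-region totals %s", len(clusters),
             strain_totals(region_counts))

    fc_sets, fc_regions = fold_change_sets(matrix, config.reference,
                                           fc_threshold=config.fc)
    fpath = outdir / "venn_fold_change.tsv"
    write_table(venn_frame(fc_regions), fpath)
    outputs["venn_fold_change"] = str(fpath)

    fc_frames = []
    stats_rows = []
    mutants = [s for s in strain_names if s != config.reference]
    for m in mutants:
        lfc = log2_fold_changes(matrix, m, config.reference)
        fc_frames.append(pd.DataFrame({"cluster_id": lfc.index,
                                       "strain_pair": f"{m}/{config.reference}",
                                       "log2fc": lfc.values}))
        ref_heights = matrix.values[config.reference]
        p = distribution_test(matrix.values[m], ref_heights, "greater")
        stats_rows.append((m, config.reference, float(np.median(lfc)), p))
    fcpath = outdir / "fold_changes.tsv"
    write_table(pd.concat(fc_frames, ignore_index=True) if fc_frames
                else pd.DataFrame(columns=["cluster_id", "strain_pair", "log2fc"]),
                fcpath)
    outputs["fold_changes"] = str(fcpath)
    spath = outdir / "distribution_tests.tsv"
    write_table(pd.DataFrame(stats_rows, columns=["strain", "reference",
                                                  "median_log2fc", "p_value"]),
                spath)
    outputs["distribution_tests"] = str(spath)

    # positional density of the reference strain's peaks across CDSs
    ref_peaks = filtered[config.reference]
    density_path = outdir / "position_density.tsv"
    if len(ref_peaks) >= 2:
        pos = relative_positions(ref_peaks, annotation)
        grid, dens = position_density(pos)
        write_table(pd.DataFrame({"position": grid, "density": dens}),
                    density_path)
        outputs["position_density"] = str(density_path)

    # structure stage (optional)
    if config.fasta:
        log.info("stage structure")
        genome_seq = read_fasta(config.fasta)
        rows = []
        for c in matrix.clusters:
            seq, truncated = upstream_sequence(c.representative, c.strand,
                                               genome_seq,
                                               window=config.dg_window)
            dg = fold_mfe(seq, engine="builtin")
            rows.append((c.cluster_id, seq, dg, truncated, "builtin"))
        struct = pd.DataFrame(rows, columns=["cluster_id", "upstream_seq",
                                             "delta_g", "truncated", "engine"])
        stpath = outdir / "structure.tsv"
        write_table(struct, stpath)
        outputs["structure"] = str(stpath)
        assoc_rows = []
        dg_map = struct.set_index("cluster_id")["delta_g"]
        for name in strain_names:
            qual = matrix.values[name] >= config.min_norm
            if qual.sum() >= 3:
                res = associate(matrix.values.loc[qual, name],
                                dg_map[matrix.values.index[qual]])
                assoc_rows.append((name, res.spearman_r, res.spearman_p,
                                   res.regression_slope, res.regression_p,
                                   res.n))
        apath = outdir / "structure_association.tsv"
        write_table(pd.DataFrame(assoc_rows,
                                 columns=["strain", "spearman_r", "spearman_p",
                                          "slope", "regression_p", "n"]),
                    apath)
        outputs["structure_association"] = str(apath)

    # decay stage
    log.info("stage decay")
    profiles = {}
    expressed = expression.expressed_in_all(config.rpb)
    for strain in config.strains:
        sf = float(size_factors[strain.name])
        profs = {}
        for gene in annotation:
            if gene.biotype != "mRNA" or gene.gene_id not in expressed:
                continue
            rna = rnaseq_tracks[strain.name][gene.strand]
            profs[gene.gene_id] = thirds_profile(rna, gene, strain=strain.name,
                                                 scale=sf)
        profiles[strain.name] = profs
    cat_rows = {}
    for name, profs in profiles.items():
        cat_rows[name] = category_summary(list(profs.values()),
                                          config.thirds_threshold)
    cpath = outdir / "decay_categories.tsv"
    cat_table = pd.DataFrame(cat_rows).T
    cat_table.index.name = "strain"
    cat_table.to_csv(cpath, sep="\t")
    outputs["decay_categories"] = str(cpath)

    rr_by_mutant = {}
    for m in mutants:
        rr_by_mutant[m] = ratio_of_ratios(profiles[m],
                                          profiles[config.reference])
    if rr_by_mutant:
        rpath = outdir / "ratio_of_ratios.tsv"
        write_table(pd.concat([rr_frame(v) for v in rr_by_mutant.values()],
                              ignore_index=True), rpath)
        outputs["ratio_of_ratios"] = str(rpath)
        corr_rows = []
        for i, a in enumerate(mutants):
            for b in mutants[i + 1:]:
                r = rr_correlation(rr_by_mutant[a], rr_by_mutant[b])
                corr_rows.append((a, b, r))
        rcpath = outdir / "rr_correlations.tsv"
        write_table(pd.DataFrame(corr_rows, columns=["mutant_a", "mutant_b",
                                                     "pearson_r"]), rcpath)
        outputs["rr_correlations"] = str(rcpath)

    input_paths = [config.annotation, config.counts] + (
        [config.fasta] if config.fasta else [])
    for strain in config.strains:
        input_paths.extend(strain.term_bedgraph.values())
        input_paths.extend(strain.rnaseq_bedgraph.values())
    manifest = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "inputs": {p: _checksum(p) for p in sorted(input_paths)},
        "record_counts": {
            "peaks_called": raw_peak_counts,
            "peaks_filtered": {k: len(v) for k, v in filtered.items()},
            "utr3_peaks": utr3_counts,
            "clusters": len(clusters),
            "venn_shared_totals": {k: v for k, v in
                                   sorted(strain_totals(region_counts).items())},
            "fc_set_sizes": {k: len(v) for k, v in fc_sets.items()},
        },
        "outputs": outputs,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    outputs["manifest"] = str(outdir / "manifest.json")
    return PipelineResult(matrix=matrix.values, region_counts=region_counts,
                          fc_regions=fc_regions, outputs=outputs,
                          manifest=manifest)
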