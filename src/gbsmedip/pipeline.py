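"""End-to-end orchestration: simulate → QC → dual-route DMR calling →
confound filter → genomic context → cross-population overlap → report.

``run_pipeline`` is a pure function of (config, seed): identical inputs
produce byte-identical tabular outputs.  Each population is analysed
independently (its own normalization, dispersion, BH universe and
thresholds); cross-population overlap and motif stages run afterwards on
the most relaxed threshold's DMR sets, where stricter thresholds leave
nothing to compare.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._version import __version__
from .context import (
    fold_enrichment,
    inter_dmr_distances,
    random_window_expectancy,
    tss_distances,
)
from .digest import chrom_expectancy_ttest, coverage_summary, cpg_enrichment
from .dmr import (
    DEFAULT_THRESHOLDS,
    DMRRecord,
    call_adjw_dmrs,
    dmrs_to_frame,
    input_cnv_filter,
    test_rois,
)
from .io import write_bed, write_counts_table, write_fasta, write_gff3, write_sample_sheet
from .motifs import motif_selection, read_pwms
from .overlap import permutation_overlap_test
from .peaks import binned_coverage, call_peaks, rois_to_regions
from .simulate import SimulationConfig, simulate_dataset
from .windows import assign_counts, filter_min_row_sum, tile_windows
from .context import annotate_feature

logger = logging.getLogger(__name__)


def scale_min_row_sum(base: int = 10, coverage_ratio: float = 1.0) -> int:
    """Coverage-scaled minimum row sum: ``round(base × coverage_ratio)``.

    A population sequenced over a k× larger region is filtered at a k×
    higher minimum count sum so that a comparable number of windows is
    tested in each population.
    """
    if coverage_ratio <= 0:
        raise ValueError("coverage ratio must be > 0")
    return int(np.floor(base * coverage_ratio + 0.5))


@dataclass
class PopulationSpec:
    name: str
    sim: SimulationConfig
    min_row_sum_base: int = 10
    coverage_ratio: float = 1.0


@dataclass
class PipelineConfig:
    populations: list[PopulationSpec]
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    window_size: int = 100
    roi_q_max: float = 0.1
    peak_bin: int = 10
    n_random: int = 100_000
    flank: int = 5_000
    overlap_n: int = 100
    overlap_max_gap: int = 1_000
    pwm_file: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if list(self.thresholds) != sorted(self.thresholds, reverse=True):
            raise ValueError("thresholds must be in descending order")


@dataclass
class RunManifest:
    version: str
    seed: int
    config_hash: str
    populations: dict[str, dict] = field(default_factory=dict)
    cross_population: dict = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)  # path -> sha256
    notes: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "version": self.version,
                "seed": self.seed,
                "config_hash": self.config_hash,
                "populations": self.populations,
                "cross_population": self.cross_population,
                "outputs": self.outputs,
                "notes": self.notes,
            },
            indent=2,
            sort_keys=True,
        )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def run_pipeline(config: PipelineConfig, outdir) -> RunManifest:
    """Run the full analysis and write all stage outputs under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_text = repr(config)
    manifest = RunManifest(
        version=__version__,
        seed=config.seed,
        config_hash=hashlib.sha256(cfg_text.encode()).hexdigest(),
    )
    written: list[Path] = []

    adjw_sets: dict[str, list[DMRRecord]] = {}
    roi_sets: dict[str, list[DMRRecord]] = {}
    roi_seq_sets: dict[str, dict[str, str]] = {}
    genomes = {}

    for pop_idx, pop in enumerate(config.populations):
        pdir = outdir / pop.name
        pdir.mkdir(exist_ok=True)
        sim_cfg = pop.sim
        # derive the population seed from the pipeline seed so one pipeline
        # seed reproduces everything
        sim_cfg = type(sim_cfg)(**{**sim_cfg.__dict__, "seed": sim_cfg.seed + config.seed})
        logger.info("population %s: simulating", pop.name)
        genome, genes, data = simulate_dataset(sim_cfg)
        genomes[pop.name] = genome
        frags = data.fragments

        write_fasta(genome, pdir / "genome.fa")
        write_gff3(genes, pdir / "genes.gff3")
        write_bed(frags.fragments, pdir / "fragments.bed")
        write_counts_table(data.medip.to_frame(), pdir / "medip_counts.tsv")
        sheet = pd.DataFrame(
            {
                "sample_id": data.medip.sample_ids,
                "population": pop.name,
                "group": [s.group for s in data.medip.samples],
                "channel": [s.channel for s in data.medip.samples],
            }
        )
        if data.input is not None:
            write_counts_table(data.input.to_frame(), pdir / "input_counts.tsv")
            sheet = pd.concat(
                [
                    sheet,
                    pd.DataFrame(
                        {
                            "sample_id": data.input.sample_ids,
                            "population": pop.name,
                            "group": [s.group for s in data.input.samples],
                            "channel": [s.channel for s in data.input.samples],
                        }
                    ),
                ],
                ignore_index=True,
            )
        write_sample_sheet(sheet, pdir / "samples.tsv")
        truth_df = pd.DataFrame(
            {
                "location": [iv.region_string() for iv, _ in data.truth.dmrs],
                "log2fc": [e for _, e in data.truth.dmrs],
            }
        )
        _write_tsv(truth_df, pdir / "truth_dmrs.tsv")
        written += [
            pdir / "genome.fa",
            pdir / "genes.gff3",
            pdir / "fragments.bed",
            pdir / "medip_counts.tsv",
            pdir / "samples.tsv",
            pdir / "truth_dmrs.tsv",
        ]

        # ---------------- QC ------------------------------------------
        enr = cpg_enrichment(frags.fragments, genome)
        cov = coverage_summary(
            data.medip.to_frame(), frags, genome, sample_ids=data.medip.sample_ids
        )
        frag_per_chrom: dict[str, float] = {}
        for f in frags.fragments:
            frag_per_chrom[f.chrom] = frag_per_chrom.get(f.chrom, 0) + 1
        expect = chrom_expectancy_ttest(frag_per_chrom, genome)
        qc = pd.DataFrame(
            [
                {
                    "sample_id": c.sample_id,
                    "depth": c.depth,
                    "bp_sequenced": c.bp_sequenced,
                    "breadth": c.breadth,
                    "pct_genome_covered": c.pct_genome_covered,
                }
                for c in cov
            ]
        )
        _write_tsv(qc, pdir / "qc_coverage.tsv")
        written.append(pdir / "qc_coverage.tsv")
        manifest.populations[pop.name] = {
            "n_fragments": len(frags),
            "enrichment_relH_ratio": enr.relh_ratio,
            "enrichment_GoGe_ratio": enr.goge_ratio,
            "fragment_expectancy_p": expect.p_value,
            "truth_warnings": list(data.truth.warnings),
        }

        # ---------------- ADJW route ----------------------------------
        windows = tile_windows(genome, config.window_size)
        matrix = assign_counts(frags, data.medip.counts, windows, data.medip.samples)
        min_row_sum = scale_min_row_sum(pop.min_row_sum_base, pop.coverage_ratio)
        filtered = filter_min_row_sum(matrix, min_row_sum)
        adjw, window_table = call_adjw_dmrs(filtered, config.thresholds)
        _write_tsv(window_table, pdir / "adjw_windows.tsv")
        written.append(pdir / "adjw_windows.tsv")
        for t, recs in adjw.items():
            path = pdir / f"dmrs_adjw_p{t:g}.tsv"
            _write_tsv(dmrs_to_frame(recs), path)
            written.append(path)
        manifest.populations[pop.name]["adjw"] = {
            "windows_total": len(windows),
            "windows_tested": filtered.n_windows,
            "min_row_sum": min_row_sum,
            "dmrs": {f"{t:g}": len(v) for t, v in adjw.items()},
        }

        # ---------------- ROI route ------------------------------------
        pooled = {
            g: data.medip.counts[:, data.medip.group_indices(g)].sum(axis=1)
            for g in ("S", "C")
        }
        cov_bins = binned_coverage(frags, pooled, genome, bin_size=config.peak_bin)
        peaks = call_peaks(cov_bins, q_max=config.roi_q_max)
        regions = rois_to_regions(peaks)
        write_bed(
            [p.interval for p in peaks],
            pdir / "rois.bed",
            names=[p.direction for p in peaks],
        )
        written.append(pdir / "rois.bed")
        roi_dmrs_by_t: dict[float, list[DMRRecord]] = {t: [] for t in config.thresholds}
        roi_table = None
        if regions:
            region_matrix = assign_counts(
                frags, data.medip.counts, regions, data.medip.samples
            )
            roi_dmrs, roi_table = test_rois(region_matrix, threshold=max(config.thresholds))
            for t in config.thresholds:
                roi_dmrs_by_t[t] = [d for d in roi_dmrs if d.p_value <= t]
            _write_tsv(roi_table, pdir / "roi_regions.tsv")
            written.append(pdir / "roi_regions.tsv")
            for t, recs in roi_dmrs_by_t.items():
                path = pdir / f"dmrs_roi_p{t:g}.tsv"
                _write_tsv(dmrs_to_frame(recs), path)
                written.append(path)
        manifest.populations[pop.name]["roi"] = {
            "peaks": len(peaks),
            "regions_tested": len(regions),
            "dmrs": {f"{t:g}": len(v) for t, v in roi_dmrs_by_t.items()},
        }

        # ---------------- input / CNV filter ---------------------------
        loose = max(config.thresholds)
        adjw_loose = adjw[loose]
        roi_loose = roi_dmrs_by_t[loose]
        if data.input is not None:
            input_windows = assign_counts(
                frags, data.input.counts, windows, data.input.samples
            )
            input_filtered = filter_min_row_sum(input_windows, min_row_sum)
            adjw_loose, removed_a, _ = input_cnv_filter(adjw_loose, input_filtered)
            roi_loose, removed_r, _ = input_cnv_filter(roi_loose, input_filtered)
            manifest.populations[pop.name]["cnv_filter"] = {
                "adjw_removed": len(removed_a),
                "roi_removed": len(removed_r),
            }
        else:
            manifest.populations[pop.name]["cnv_filter"] = "skipped: no input channel"
        adjw_sets[pop.name] = adjw_loose
        roi_sets[pop.name] = roi_loose
        roi_seq_sets[pop.name] = {
            d.interval.region_string(): genome.fetch(d.interval) for d in roi_loose
        }

        # ---------------- genomic context ------------------------------
        ctx_dmrs = [d.interval for d in roi_loose] or [d.interval for d in adjw_loose]
        ctx: dict = {}
        if ctx_dmrs:
            widths = np.array([iv.width for iv in ctx_dmrs], dtype=float)
            expectancy = random_window_expectancy(
                genome,
                n=config.n_random,
                length_mean=float(widths.mean()),
                length_sd=float(widths.std()) if len(widths) > 1 else 0.0,
                seed=config.seed + 1000 + pop_idx,
            )
            profile = fold_enrichment(ctx_dmrs, expectancy)
            _write_tsv(profile.table, pdir / "chrom_expectancy.tsv")
            written.append(pdir / "chrom_expectancy.tsv")
            ctx["fold_enrichment_by_class"] = (
                profile.table.groupby("chrom_class")["fold_enrichment"].mean().to_dict()
            )
            if len(ctx_dmrs) >= 2:
                try:
                    inter = inter_dmr_distances(ctx_dmrs)
                    _write_tsv(
                        pd.DataFrame(
                            {
                                "bin": [str(b) for b in inter.bin_labels],
                                "count": inter.bin_counts,
                            }
                        ),
                        pdir / "inter_dmr_distances.tsv",
                    )
                    written.append(pdir / "inter_dmr_distances.tsv")
                except ValueError:
                    ctx["inter_dmr"] = "not computable"
            tssp = tss_distances(ctx_dmrs, genes)
            _write_tsv(
                pd.DataFrame(
                    {
                        "bin_center": tssp.bin_centers,
                        "count": tssp.bin_counts,
                    }
                ),
                pdir / "tss_distances.tsv",
            )
            written.append(pdir / "tss_distances.tsv")
            annotations = [annotate_feature(iv, genes, flank=config.flank) for iv in ctx_dmrs]
            _write_tsv(
                pd.DataFrame(
                    {
                        "dmr": [a.dmr_id for a in annotations],
                        "category": [a.category for a in annotations],
                        "label": [a.label for a in annotations],
                        "genes": [",".join(a.gene_ids) for a in annotations],
                    }
                ),
                pdir / "annotations.tsv",
            )
            written.append(pdir / "annotations.tsv")
            cats = pd.Series([a.category for a in annotations]).value_counts()
            ctx["annotation_categories"] = cats.to_dict()
        manifest.populations[pop.name]["context"] = ctx

    # -------------------- cross-population ----------------------------
    pops = [p.name for p in config.populations]
    if len(pops) >= 2:
        a, b = pops[0], pops[1]
        # overlaps are evaluated on the first population's genome: the
        # simulated populations share the chromosome plan
        genome = genomes[a]
        cross = {}
        for route, sets in (("ADJW", adjw_sets), ("ROI", roi_sets)):
            set_a = [d.interval for d in sets[a]]
            set_b = [d.interval for d in sets[b]]
            if set_a and set_b:
                res = permutation_overlap_test(
                    set_a,
                    set_b,
                    genome,
                    n=config.overlap_n,
                    max_gap=config.overlap_max_gap,
                    seed=config.seed + 77,
                )
                cross[route] = {
                    "n_a": res.observed.n_a,
                    "n_b": res.observed.n_b,
                    "overlapping": res.observed.merged_overlaps,
                    "p_value": res.p_value,
                }
            else:
                cross[route] = "empty DMR set"
        manifest.cross_population = cross

    # -------------------- motifs --------------------------------------
    if config.pwm_file:
        pwms = read_pwms(config.pwm_file)
        all_seqs: dict[str, str] = {}
        for seqs in roi_seq_sets.values():
            all_seqs.update(seqs)
        if all_seqs:
            report = motif_selection(all_seqs, pwms)
            _write_tsv(report.table, outdir / "motif_selection.tsv")
            written.append(outdir / "motif_selection.tsv")
            manifest.cross_population["motifs_selected"] = int(
                report.table["selected"].sum()
            )

    for path in written:
        manifest.outputs[str(path.relative_to(outdir))] = _sha256(path)
    (outdir / "manifest.json").write_text(manifest.to_json())
    return manifest
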