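"""In-silico PstI digestion and immunoprecipitation quality control.

Digests the toy genome at CTGCA^G, size-selects library-compatible
fragments, and computes the standard MeDIP QC statistics: CpG enrichment
of the captured fraction vs the genome (relH and GoGe), per-chromosome
fragment expectancy, and per-sample coverage summaries.
"""

from gbsmedip import SimulationConfig, chrom_expectancy_ttest, coverage_summary, cpg_enrichment, digest, size_select
from gbsmedip.simulate import generate_genome

genome = generate_genome(SimulationConfig(seed=2))
fragments = digest(genome)  # cut at every CTGCAG, fragments tile the genome
print(f"digestion: {len(fragments):,} fragments, total {fragments.total_bp():,} bp "
      f"(= genome length {genome.total_length:,})")

selected = size_select(fragments, 200, 600)
print(f"size selection [200, 600] bp: {len(selected):,} fragments retained "
      f"({selected.total_bp() / genome.total_length:.1%} of the genome)")

scores = cpg_enrichment(selected.fragments, genome)
print(f"CpG enrichment of the reduced fraction: relH ratio {scores.relh_ratio:.2f}, "
      f"GoGe ratio {scores.goge_ratio:.2f}  (1.0 = genome-average; >1 expected for CpG-rich libraries)")

per_chrom = {}
for f in selected.fragments:
    per_chrom[f.chrom] = per_chrom.get(f.chrom, 0) + 1
report = chrom_expectancy_ttest(per_chrom, genome)
print(f"fragments-per-chromosome vs length proportions: chi2 = {report.chi2_statistic:.2f}, "
      f"P = {report.p_value:.3f} (no significant deviation expected)")
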