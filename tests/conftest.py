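import numpy as np
import pytest

from gbsmedip.intervals import GenomeModel, GenomicInterval
from gbsmedip.simulate import ChromSpec, SimulationConfig, simulate_dataset
from gbsmedip.windows import SampleInfo, WindowCountMatrix


@pytest.fixture(scope="session")
def toy_genome() -> GenomeModel:
    """Small two-chromosome genome with deterministic sequence."""
    rng = np.random.default_rng(123)
    seqs = {
        "chr1": "".join(rng.choice(list("ACGT"), size=20_000)),
        "chr2": "".join(rng.choice(list("ACGT"), size=10_000)),
    }
    return GenomeModel(
        [("chr1", 20_000, "macro"), ("chr2", 10_000, "micro")], sequences=seqs
    )


@pytest.fixture(scope="session")
def small_dataset():
    """One small simulated population with planted DMRs (session-cached)."""
    cfg = SimulationConfig(
        seed=17,
        chromosomes=[
            ChromSpec("chr1", 600_000, "macro"),
            ChromSpec("chr2", 400_000, "macro"),
            ChromSpec("chr11", 200_000, "micro"),
            ChromSpec("chrZ", 200_000, "sexZ"),
        ],
        n_genes=30,
        n_s=8,
        n_c=8,
        depth=30.0,
        n_true_dmrs=10,
    )
    genome, genes, data = simulate_dataset(cfg)
    return cfg, genome, genes, data


def make_matrix(counts, n_s, n_c, chrom="chr1", size=100, cpg=None):
    """Window matrix helper: consecutive windows on one chromosome."""
    counts = np.asarray(counts)
    windows = [
        GenomicInterval(chrom, i * size + 1, (i + 1) * size) for i in range(counts.shape[0])
    ]
    samples = [SampleInfo(f"S{i + 1}", "S") for i in range(n_s)] + [
        SampleInfo(f"C{i + 1}", "C") for i in range(n_c)
    ]
    return WindowCountMatrix(windows, counts, samples, cpg_counts=cpg)
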