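import numpy as np
import pytest

from ribote.de import SizeFactorSet, estimate_size_factors
from ribote.io_formats import CountMatrix, SampleInfo
from ribote.simulate import SimConfig, simulate_annotation, simulate_counts


def make_samples(n_replicates=2):
    samples = []
    for cond in ("heterotrophic", "autotrophic"):
        for assay in ("mRNA", "RPF"):
            for rep in range(1, n_replicates + 1):
                samples.append(SampleInfo(f"{cond[:4]}_{assay}_r{rep}",
                                          cond, assay, rep))
    return samples


def matrix_from_group_means(gene_ids, means, n_replicates=2):
    """Exact-count matrix: means[(cond, assay)] is a per-gene vector,
    replicated identically (useful for arithmetic-identity tests)."""
    samples = make_samples(n_replicates)
    cols = []
    for s in samples:
        cols.append(np.asarray(means[(s.condition, s.assay)], dtype=np.int64))
    return CountMatrix(list(gene_ids), samples, np.column_stack(cols))


def unit_size_factors(cm):
    """All-ones size factors, for tests that fix normalization by hand."""
    return SizeFactorSet(np.ones(len(cm.samples)), cm.sample_ids,
                         np.zeros(len(cm.gene_ids)))


@pytest.fixture(scope="session")
def sim_small():
    """One modest synthetic dataset shared by read-only tests."""
    cfg = SimConfig(n_genes=300, n_operons=20, seed=11)
    annotation = simulate_annotation(cfg)
    counts, truth = simulate_counts(cfg, annotation)
    sf = estimate_size_factors(counts)
    return {"config": cfg, "annotation": annotation, "counts": counts,
            "truth": truth, "sf": sf}
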