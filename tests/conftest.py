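import numpy as np
import pytest

from tssmeth.genome import AnnotationSet, GeneModel, GenomicInterval
from tssmeth.scoring import window_scores
from tssmeth.simulate import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def planted_cohort():
    """Default planted cohort: coupling at -1000 bp (normal) / TSS (tumor)."""
    return generate_cohort(CohortConfig(seed=11))


@pytest.fixture(scope="session")
def planted_wsm(planted_cohort):
    return window_scores(planted_cohort.segments, planted_cohort.annotation)


@pytest.fixture(scope="session")
def small_cohort():
    """Cheap cohort for smoke-level checks (60 genes, 10+10 samples)."""
    return generate_cohort(
        CohortConfig(n_genes=60, n_tumor=10, n_normal=10, seed=3)
    )


def make_gene(gene_id="geneA", chrom="chr1", tss=100_000, strand="+"):
    return GeneModel.from_tss(gene_id, chrom, tss, strand)


def make_annotation(genes, cgis=(), sizes=None):
    return AnnotationSet(
        genes=list(genes),
        cgi_intervals=[GenomicInterval(*c) if isinstance(c, tuple) else c for c in cgis],
        chrom_sizes=dict(sizes or {}),
    )
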