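import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from rtkit.annotation import GeneModel


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_gene(gene_id="g1", chrom="chr1", strand="+", exons=((0, 100),),
              start=None, end=None, biotype="protein_coding", isoforms=None):
    isoforms = isoforms if isoforms is not None else (tuple(exons),)
    all_ex = [e for iso in isoforms for e in iso]
    start = min(s for s, _ in all_ex) if start is None else start
    end = max(e for _, e in all_ex) if end is None else end
    return GeneModel(
        gene_id=gene_id, gene_name=gene_id, chrom=chrom, strand=strand,
        start=start, end=end, biotype=biotype, isoforms=isoforms,
    )


@pytest.fixture
def gene_factory():
    return make_gene


def random_annotation(rng, n_genes=8, chrom_len=50_000, chrom="chr1"):
    """Random, possibly overlapping multi-isoform annotation for oracle tests."""
    genes = []
    for i in range(n_genes):
        start = int(rng.integers(0, chrom_len - 5000))
        n_iso = int(rng.integers(1, 4))
        isoforms = []
        for _ in range(n_iso):
            pos = start + int(rng.integers(0, 200))
            exons = []
            for _ in range(int(rng.integers(1, 5))):
                length = int(rng.integers(50, 400))
                exons.append((pos, pos + length))
                pos += length + int(rng.integers(100, 800))
            isoforms.append(tuple(exons))
        span_start = min(s for iso in isoforms for s, _ in iso)
        span_end = max(e for iso in isoforms for _, e in iso)
        genes.append(
            GeneModel(
                gene_id=f"g{i}", gene_name=f"g{i}", chrom=chrom,
                strand="+" if rng.random() < 0.5 else "-",
                start=span_start, end=span_end, biotype="protein_coding",
                isoforms=tuple(isoforms),
            )
        )
    return genes
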