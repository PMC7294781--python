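import numpy as np
import pandas as pd
import pytest

from chromdiff.regions import AnnotationIndex, GeneModel, GenomicInterval


def make_gene(
    gene_id: str,
    chrom: str,
    start: int,
    end: int,
    strand: str = "+",
    with_structure: bool = True,
) -> GeneModel:
    """Gene with a simple 2-exon structure: UTR|CDS ... CDS|UTR."""
    iv = GenomicInterval(chrom, start, end, strand)
    if not with_structure:
        return GeneModel(gene_id, iv, exons=[iv], cds=[iv])
    length = end - start
    e = max(100, length // 5)
    exons = [
        GenomicInterval(chrom, start, start + e, strand),
        GenomicInterval(chrom, end - e, end, strand),
    ]
    utr_len = e // 2
    utr = [
        GenomicInterval(chrom, start, start + utr_len, strand),
        GenomicInterval(chrom, end - utr_len, end, strand),
    ]
    cds = [
        GenomicInterval(chrom, start + utr_len, start + e, strand),
        GenomicInterval(chrom, end - e, end - utr_len, strand),
    ]
    return GeneModel(gene_id, iv, exons=exons, cds=cds, utr=utr)


@pytest.fixture
def toy_index() -> AnnotationIndex:
    """Two genes on a 100 kb chromosome, opposite strands, well separated."""
    genes = [
        make_gene("gA", "chr1", 10000, 20000, "+"),
        make_gene("gB", "chr1", 50000, 70000, "-"),
    ]
    return AnnotationIndex(genes, {"chr1": 100000})


@pytest.fixture
def sample_sheet_6v6() -> pd.DataFrame:
    samples = [f"normal_{i}" for i in range(1, 7)] + [f"AD_{i}" for i in range(1, 7)]
    return pd.DataFrame(
        {"sample_id": samples, "group": ["normal"] * 6 + ["AD"] * 6}
    )


def nb_matrix(
    rng: np.random.Generator,
    n_rows: int,
    mean: float,
    phi: float,
    n_a: int = 6,
    n_b: int = 6,
    log2fc: np.ndarray | None = None,
) -> pd.DataFrame:
    """Direct NB sampler used as a test input (independent of the package)."""
    n = n_a + n_b
    mu = np.full((n_rows, n), float(mean))
    if log2fc is not None:
        half = np.concatenate([np.full(n_a, -0.5), np.full(n_b, 0.5)])
        mu = mu * 2.0 ** (np.asarray(log2fc)[:, None] * half[None, :])
    if phi <= 0:
        x = rng.poisson(mu)
    else:
        r = 1.0 / phi
        x = rng.poisson(rng.gamma(r, mu / r))
    cols = [f"a{i}" for i in range(n_a)] + [f"b{i}" for i in range(n_b)]
    return pd.DataFrame(x, columns=cols)


def groups_for(df: pd.DataFrame) -> pd.Series:
    return pd.Series(
        ["A" if c.startswith("a") else "B" for c in df.columns], index=df.columns
    )
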