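"""Synthetic two-group ChIP/RNA datasets with planted ground truth.

The generator emulates the study design the pipeline targets: two groups of
six samples each, negative-binomial tag counts over promoters, gene bodies
and transcripts, a configurable fraction of genes carrying a planted
histone-mark effect and/or expression effect, and a configurable fraction of
affected genes in which the two effects have opposite signs (the
inverse-coupled genes the integration stage is meant to recover).  Planted
effects are split as +/-delta/2 between the two groups so overall abundance
stays comparable.  Optional per-base tags are placed uniformly within each
region, consistent with the region counts, plus a uniform genomic
background.

One seeded :class:`numpy.random.Generator` drives every draw; per-stage
sub-generators are derived deterministically, so a fixed seed reproduces the
dataset bit for bit.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .regions import AnnotationIndex, GeneModel, GenomicInterval, promoter_region

__all__ = [
    "SimulationConfig",
    "generate_annotation",
    "generate_counts",
    "generate_tags",
    "simulate_dataset",
    "chip_region_table",
    "write_annotation_gtf",
]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults reproduce a 6-vs-6 design with moderate biological dispersion
    (phi = 0.1), 30% of genes carrying a mark effect and 30% an expression
    effect, and half of the smaller affected set inversely coupled.
    ``level_rho`` is the Gaussian-copula correlation between a gene's
    baseline mark intensity and its baseline expression; the negative
    default emulates a repressive mark (highly expressed genes carry less
    of it).
    """

    n_genes: int = 400
    n_per_group: int = 6
    chrom_sizes: dict[str, int] | None = None
    library_size_mean: float | None = None
    library_size_cv: float = 0.1
    dispersion: float = 0.1
    baseline_logmean_range: tuple[float, float] = (5.0, 8.0)
    frac_chip_effect: float = 0.3
    frac_rna_effect: float = 0.3
    frac_inverse_coupled: float = 0.5
    effect_log2fc: float = 2.0
    level_rho: float = -0.5
    gene_length_range: tuple[int, int] = (2000, 50000)
    intergenic_gap: int = 12000
    background_per_bp: float = 0.0005
    group_labels: tuple[str, str] = ("normal", "AD")
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_chip_effect", "frac_rna_effect", "frac_inverse_coupled"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")

    def rng(self, stage: str) -> np.random.Generator:
        """Deterministic per-stage generator derived from the master seed."""
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return np.random.default_rng(int.from_bytes(h[:8], "little"))

    @property
    def sample_ids(self) -> list[str]:
        a, b = self.group_labels
        return [f"{a}_{i + 1}" for i in range(self.n_per_group)] + [
            f"{b}_{i + 1}" for i in range(self.n_per_group)
        ]

    def sample_sheet(self) -> pd.DataFrame:
        a, b = self.group_labels
        return pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "group": [a] * self.n_per_group + [b] * self.n_per_group,
            }
        )


# ---------------------------------------------------------------------------
# annotation


def _gene_structure(
    gene_id: str, chrom: str, start: int, length: int, strand: str,
    rng: np.random.Generator,
) -> GeneModel:
    """Three-exon gene: terminal exons carry UTRs flanking a central CDS."""
    end = start + length
    # exon fractions of the span; introns take the rest
    e1 = max(200, int(length * 0.10))
    e3 = max(200, int(length * 0.10))
    e2 = max(200, int(length * 0.15))
    i1 = (length - e1 - e2 - e3) // 2
    i2 = length - e1 - e2 - e3 - i1
    if i1 < 0 or i2 < 0:  # very short gene: single exon, all CDS
        exons = [GenomicInterval(chrom, start, end, strand)]
        return GeneModel(
            gene_id,
            GenomicInterval(chrom, start, end, strand),
            exons=exons,
            cds=list(exons),
            utr=[],
        )
    b1, b2 = start + e1, start + e1 + i1
    b3, b4 = b2 + e2, b2 + e2 + i2
    exons = [
        GenomicInterval(chrom, start, b1, strand),
        GenomicInterval(chrom, b2, b3, strand),
        GenomicInterval(chrom, b4, end, strand),
    ]
    utr5 = max(50, e1 // 2)
    utr3 = max(50, e3 // 2)
    utr = [
        GenomicInterval(chrom, start, start + utr5, strand),
        GenomicInterval(chrom, end - utr3, end, strand),
    ]
    cds = [
        GenomicInterval(chrom, start + utr5, b1, strand),
        GenomicInterval(chrom, b2, b3, strand),
        GenomicInterval(chrom, b4, end - utr3, strand),
    ]
    return GeneModel(
        gene_id, GenomicInterval(chrom, start, end, strand),
        exons=exons, cds=cds, utr=utr,
    )


def generate_annotation(config: SimulationConfig) -> AnnotationIndex:
    """Place ``n_genes`` non-overlapping genes with promoter/flank clearance.

    Gene lengths are uniform over ``gene_length_range`` (default 2-50 kb, so
    both sub-5 kb genes, excluded from profile gene sets, and longer genes
    exist); strands alternate-randomly; each gene has a three-exon structure
    with UTR/CDS partition.
    """
    rng = config.rng("annotation")
    lo, hi = config.gene_length_range
    lengths = rng.integers(lo, hi + 1, size=config.n_genes)
    strands = rng.choice(["+", "-"], size=config.n_genes)
    gap = config.intergenic_gap
    margin = 8000  # room for 3 kb promoters and 5 kb flanks at chrom edges

    if config.chrom_sizes is None:
        total = int(lengths.sum()) + gap * (config.n_genes + 1) + 2 * margin
        chrom_sizes = {"chr1": total}
    else:
        chrom_sizes = dict(config.chrom_sizes)

    genes: list[GeneModel] = []
    chroms = sorted(chrom_sizes)
    ci = 0
    pos = margin
    width = len(str(config.n_genes))
    for i in range(config.n_genes):
        length = int(lengths[i])
        while ci < len(chroms) and pos + length + margin > chrom_sizes[chroms[ci]]:
            ci += 1
            pos = margin
        if ci >= len(chroms):
            raise ValueError(
                "chromosomes too small for requested number of genes"
            )
        gene_id = f"G{i + 1:0{width}d}"
        genes.append(
            _gene_structure(gene_id, chroms[ci], pos, length, str(strands[i]), rng)
        )
        pos += length + gap
    return AnnotationIndex(genes, chrom_sizes)


def chip_region_table(index: AnnotationIndex, promoter_bp: int = 3000) -> pd.DataFrame:
    """Promoter + gene-body regions per gene, the ChIP counting universe."""
    rows = []
    for g in index:
        p = promoter_region(g, promoter_bp, index.chrom_sizes)
        if p is not None:
            rows.append((f"{g.gene_id}:promoter", g.gene_id, p.chrom, p.start, p.end))
        iv = g.interval
        rows.append((f"{g.gene_id}:body", g.gene_id, iv.chrom, iv.start, iv.end))
    return pd.DataFrame(
        rows, columns=["region_id", "gene_id", "chrom", "start", "end"]
    ).set_index("region_id")


def _plant_effects(config: SimulationConfig, gene_ids: list[str]) -> pd.DataFrame:
    """Assign planted chip/rna log2 fold-changes and truth flags per gene."""
    rng = config.rng("effects")
    n = len(gene_ids)
    n_chip = int(round(config.frac_chip_effect * n))
    n_rna = int(round(config.frac_rna_effect * n))
    n_inv = int(round(config.frac_inverse_coupled * min(n_chip, n_rna)))
    order = rng.permutation(n)
    inv_idx = order[:n_inv]
    chip_only = order[n_inv: n_inv + (n_chip - n_inv)]
    rna_only = order[n_inv + (n_chip - n_inv): n_inv + (n_chip - n_inv) + (n_rna - n_inv)]

    chip_fc = np.zeros(n)
    rna_fc = np.zeros(n)
    d = config.effect_log2fc
    inv_signs = rng.choice([-1.0, 1.0], size=n_inv)
    chip_fc[inv_idx] = inv_signs * d
    rna_fc[inv_idx] = -inv_signs * d
    chip_fc[chip_only] = rng.choice([-1.0, 1.0], size=len(chip_only)) * d
    rna_fc[rna_only] = rng.choice([-1.0, 1.0], size=len(rna_only)) * d

    truth = pd.DataFrame(
        {
            "chip_log2fc": chip_fc,
            "rna_log2fc": rna_fc,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    truth["is_dmg_truth"] = truth["chip_log2fc"] != 0
    truth["is_deg_truth"] = truth["rna_log2fc"] != 0
    truth["is_inverse_truth"] = (
        truth["is_dmg_truth"]
        & truth["is_deg_truth"]
        & (np.sign(truth["chip_log2fc"]) == -np.sign(truth["rna_log2fc"]))
    )
    return truth


def _baseline_quantiles(
    config: SimulationConfig, gene_ids: list[str], layer: str
) -> pd.Series:
    """Per-gene baseline intensity quantiles in [0, 1], shared across layers
    through a Gaussian copula with correlation ``level_rho`` so that mark
    and expression levels can be made inversely tied."""
    from scipy.stats import norm

    rng = config.rng("baseline")
    n = len(gene_ids)
    z_chip = rng.standard_normal(n)
    z_ind = rng.standard_normal(n)
    rho = config.level_rho
    z_rna = rho * z_chip + np.sqrt(max(0.0, 1.0 - rho**2)) * z_ind
    z = z_chip if layer == "chip" else z_rna
    return pd.Series(norm.cdf(z), index=pd.Index(gene_ids, name="gene_id"))


def generate_counts(
    config: SimulationConfig,
    regions: pd.DataFrame,
    layer: str,
    truth: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """NB counts for one layer ('chip' or 'rna') over a region table.

    Per region g and sample k the count is
    ``NB(mean = s_k * mu_g * 2**(+/- delta_g / 2), dispersion phi)`` where
    ``s_k`` is the sample's library-size factor (log-normal, CV
    ``library_size_cv``, mean 1), ``mu_g = 2**U(baseline_logmean_range)``
    and ``delta_g`` the planted log2FC of the region's gene for this layer,
    applied +delta/2 to the case group and -delta/2 to the reference group.

    ``regions`` must carry a ``gene_id`` column (or be indexed by gene id,
    as for the RNA layer).  Returns ``(counts, truth)``; pass an existing
    ``truth`` to keep chip and rna layers consistent.
    """
    if layer not in ("chip", "rna"):
        raise ValueError(f"unknown layer {layer!r}")
    gene_ids = (
        regions["gene_id"].tolist() if "gene_id" in regions else list(regions.index)
    )
    unique_genes = sorted(set(gene_ids))
    if truth is None:
        truth = _plant_effects(config, unique_genes)
    delta = truth[f"{layer}_log2fc"].reindex(gene_ids).values

    rng = config.rng(f"counts:{layer}")
    n_regions = len(regions)
    n_samples = 2 * config.n_per_group
    lo, hi = config.baseline_logmean_range
    mu = 2.0 ** (lo + (hi - lo) * _baseline_quantiles(config, unique_genes, layer)
                 .reindex(gene_ids).values)
    if config.library_size_mean is not None:
        mu *= config.library_size_mean / mu.sum()
    cv = config.library_size_cv
    sigma = np.sqrt(np.log1p(cv**2))
    s = rng.lognormal(mean=-(sigma**2) / 2, sigma=sigma, size=n_samples)

    half = np.concatenate(
        [np.full(config.n_per_group, -0.5), np.full(config.n_per_group, +0.5)]
    )
    mean = mu[:, None] * s[None, :] * 2.0 ** (delta[:, None] * half[None, :])
    phi = config.dispersion
    if phi <= 0:
        counts = rng.poisson(mean)
    else:
        r = 1.0 / phi
        counts = rng.poisson(rng.gamma(shape=r, scale=mean / r))
    cdf = pd.DataFrame(
        counts.astype(np.int64), index=regions.index, columns=config.sample_ids
    )
    return cdf, truth


def generate_tags(
    counts: pd.DataFrame,
    regions: pd.DataFrame,
    config: SimulationConfig,
    chrom_sizes: dict[str, int] | None = None,
) -> dict[str, pd.DataFrame]:
    """Per-sample single-base tags consistent with the region counts.

    For each region x sample, exactly the counted number of tags is placed
    uniformly at random within the region; ``background_per_bp`` adds
    Poisson background tags uniform over each chromosome.  Returns
    ``{sample_id: BED6-like DataFrame}`` sorted by (chrom, start).
    """
    rng = config.rng("tags")
    chrom_arr = regions["chrom"].values
    start_arr = regions["start"].values.astype(np.int64)
    end_arr = regions["end"].values.astype(np.int64)
    out: dict[str, pd.DataFrame] = {}
    for sample in counts.columns:
        c = counts[sample].values.astype(np.int64)
        reps = np.repeat(np.arange(len(regions)), c)
        u = rng.random(reps.size)
        pos = start_arr[reps] + np.floor(
            u * (end_arr[reps] - start_arr[reps])
        ).astype(np.int64)
        chroms = chrom_arr[reps]
        if config.background_per_bp > 0 and chrom_sizes:
            bg_chrom, bg_pos = [], []
            for chrom in sorted(chrom_sizes):
                size = chrom_sizes[chrom]
                n_bg = rng.poisson(config.background_per_bp * size)
                bg_pos.append(rng.integers(0, size, size=n_bg))
                bg_chrom.extend([chrom] * n_bg)
            if bg_chrom:
                chroms = np.concatenate([chroms, np.array(bg_chrom)])
                pos = np.concatenate([pos, np.concatenate(bg_pos)])
        df = pd.DataFrame({"chrom": chroms, "start": pos})
        df["end"] = df["start"] + 1
        df["name"] = sample
        df["score"] = 0
        df["strand"] = "+"
        df = df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
        out[sample] = df
    return out


# ---------------------------------------------------------------------------
# writers


def write_annotation_gtf(index: AnnotationIndex, path: str | Path) -> None:
    """Write the gene models as an Ensembl-dialect GTF (1-based closed)."""
    with open(path, "w") as fh:
        for g in index:
            attrs = f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}.t1";'
            rows = [("gene", g.interval), ("transcript", g.interval)]
            rows += [("exon", iv) for iv in g.exons]
            rows += [("CDS", iv) for iv in g.cds]
            rows += [("UTR", iv) for iv in g.utr]
            for feature, iv in rows:
                fh.write(
                    f"{iv.chrom}\tchromdiff_sim\t{feature}\t{iv.start + 1}\t"
                    f"{iv.end}\t.\t{g.strand}\t.\t{attrs}\n"
                )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def simulate_dataset(config: SimulationConfig, outdir: str | Path) -> dict:
    """Generate and write a complete synthetic dataset.

    Writes annotation (GTF), chrom sizes (TSV), per-sample ChIP tag BEDs,
    ChIP region counts, RNA transcript counts, truth table, sample sheet,
    the realized config (JSON) and a checksum manifest.  Returns the
    manifest dict.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    index = generate_annotation(config)
    regions = chip_region_table(index)
    truth = _plant_effects(config, sorted(g.gene_id for g in index))
    chip_counts, truth = generate_counts(config, regions, "chip", truth)
    rna_regions = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in index],
            "chrom": [g.chrom for g in index],
            "start": [g.interval.start for g in index],
            "end": [g.interval.end for g in index],
        },
        index=pd.Index([g.gene_id for g in index], name="gene_id"),
    )
    rna_counts, truth = generate_counts(config, rna_regions, "rna", truth)
    tags = generate_tags(chip_counts, regions, config, index.chrom_sizes)

    files: dict[str, Path] = {}
    files["annotation"] = outdir / "annotation.gtf"
    write_annotation_gtf(index, files["annotation"])
    files["chrom_sizes"] = outdir / "chrom_sizes.tsv"
    with open(files["chrom_sizes"], "w") as fh:
        for chrom in sorted(index.chrom_sizes):
            fh.write(f"{chrom}\t{index.chrom_sizes[chrom]}\n")
    tag_dir = outdir / "tags"
    tag_dir.mkdir(exist_ok=True)
    for sample, df in tags.items():
        p = tag_dir / f"{sample}.bed"
        df.to_csv(p, sep="\t", header=False, index=False)
        files[f"tags/{sample}"] = p
    files["chip_counts"] = outdir / "chip_counts.tsv"
    chip_counts.to_csv(files["chip_counts"], sep="\t", index_label="region_id")
    files["rna_counts"] = outdir / "rna_counts.tsv"
    rna_counts.to_csv(files["rna_counts"], sep="\t", index_label="gene_id")
    files["truth"] = outdir / "truth.tsv"
    truth.to_csv(files["truth"], sep="\t", float_format="%.6g")
    files["sample_sheet"] = outdir / "sample_sheet.tsv"
    config.sample_sheet().to_csv(files["sample_sheet"], sep="\t", index=False)
    files["config"] = outdir / "config.json"
    cfg = asdict(config)
    cfg["chrom_sizes"] = index.chrom_sizes
    with open(files["config"], "w") as fh:
        json.dump(cfg, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")

    manifest = {
        "files": {
            key: {"path": str(p.relative_to(outdir)), "sha256": _sha256(p)}
            for key, p in sorted(files.items())
        }
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
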