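"""Tag filtering, region counting, occupancy proportions and metagene profiles.

A *tag* is a read reduced to a single genomic base: the 5' end for stranded
alignment records, the interval midpoint for plain BED records (both
configurable).  Duplicate tags at the same (chrom, pos, strand) are
collapsed, and alignment records below a MAPQ threshold are discarded before
reduction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .regions import AnnotationIndex, GeneModel, metagene_bins

__all__ = [
    "TagSet",
    "OccupancyProfile",
    "load_tags",
    "count_tags_in_regions",
    "occupancy_proportions",
    "metagene_profile",
]


@dataclass
class TagSet:
    """Deduplicated, filtered single-position tags for one sample.

    ``positions`` maps chromosome -> sorted int64 array of tag positions
    (strand folded in only for dedup; counting is strand-blind).
    """

    sample_id: str
    positions: dict[str, np.ndarray] = field(default_factory=dict)
    n_raw: int = 0
    n_kept: int = 0

    @property
    def n_tags(self) -> int:
        return sum(len(v) for v in self.positions.values())

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, sample_id: str = "sample", dedup: bool = True
    ) -> "TagSet":
        """Build from a BED-like frame with chrom/start(/end/strand) columns;
        single-base rows are used as-is, wider intervals reduced to midpoints."""
        n_raw = len(df)
        chrom = df["chrom"].astype(str).values
        start = df["start"].values.astype(np.int64)
        if "end" in df:
            end = df["end"].values.astype(np.int64)
            pos = (start + end) // 2
        else:
            pos = start
        strand = (
            df["strand"].astype(str).values if "strand" in df
            else np.full(n_raw, ".")
        )
        return cls._assemble(sample_id, chrom, pos, strand, n_raw, dedup)

    @classmethod
    def _assemble(cls, sample_id, chrom, pos, strand, n_raw, dedup) -> "TagSet":
        if len(pos) == 0:
            return cls(sample_id=sample_id, positions={}, n_raw=n_raw, n_kept=0)
        df = pd.DataFrame({"chrom": chrom, "pos": pos, "strand": strand})
        if dedup:
            df = df.drop_duplicates()
        n_kept = len(df)
        positions = {
            c: np.sort(sub["pos"].values.astype(np.int64))
            for c, sub in df.groupby("chrom", sort=True)
        }
        return cls(
            sample_id=sample_id, positions=positions, n_raw=n_raw, n_kept=n_kept
        )

    def dedup(self) -> "TagSet":
        """Collapse duplicate positions (idempotent; strand already folded)."""
        positions = {c: np.unique(v) for c, v in self.positions.items()}
        return TagSet(
            sample_id=self.sample_id,
            positions=positions,
            n_raw=self.n_raw,
            n_kept=sum(len(v) for v in positions.values()),
        )


class TagFileError(ValueError):
    pass


def load_tags(
    path: str,
    sample_id: str | None = None,
    mapq_min: int = 5,
    dedup: bool = True,
    reduce: str | None = None,
) -> TagSet:
    """Load tags from BED (intervals) or SAM/BAM (alignments).

    Alignment records with MAPQ below ``mapq_min`` are discarded (BED input
    carries no MAPQ, so no filter applies).  ``reduce`` chooses the tag
    position: '5prime' (default for alignments, strand-aware) or 'midpoint'
    (default for BED).  Duplicates at identical (chrom, pos, strand) are
    collapsed when ``dedup``.
    """
    low = path.lower()
    if sample_id is None:
        sample_id = path.rsplit("/", 1)[-1].split(".")[0]
    if low.endswith((".sam", ".bam")):
        return _load_alignments(path, sample_id, mapq_min, dedup,
                                reduce or "5prime")
    return _load_bed(path, sample_id, dedup, reduce or "midpoint")


def _load_bed(path: str, sample_id: str, dedup: bool, reduce: str) -> TagSet:
    chroms: list[str] = []
    pos: list[int] = []
    strands: list[str] = []
    n_raw = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise TagFileError(f"{path}:{lineno}: expected >=3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise TagFileError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            strand = fields[5] if len(fields) >= 6 else "."
            n_raw += 1
            if reduce == "5prime" and strand in ("+", "-"):
                p = start if strand == "+" else end - 1
            else:
                p = (start + end) // 2
            chroms.append(fields[0])
            pos.append(p)
            strands.append(strand)
    return TagSet._assemble(
        sample_id, np.array(chroms), np.array(pos, dtype=np.int64),
        np.array(strands), n_raw, dedup,
    )


def _load_alignments(
    path: str, sample_id: str, mapq_min: int, dedup: bool, reduce: str
) -> TagSet:
    import pysam

    chroms: list[str] = []
    pos: list[int] = []
    strands: list[str] = []
    n_raw = 0
    with pysam.AlignmentFile(path, check_sq=False) as af:
        for rec in af.fetch(until_eof=True):
            if rec.is_unmapped:
                continue
            n_raw += 1
            if rec.mapping_quality < mapq_min:
                continue
            if reduce == "midpoint":
                p = (rec.reference_start + rec.reference_end) // 2
            else:
                p = rec.reference_end - 1 if rec.is_reverse else rec.reference_start
            chroms.append(rec.reference_name)
            pos.append(p)
            strands.append("-" if rec.is_reverse else "+")
    return TagSet._assemble(
        sample_id, np.array(chroms), np.array(pos, dtype=np.int64),
        np.array(strands), n_raw, dedup,
    )


def count_tags_in_regions(tags: TagSet, regions: pd.DataFrame) -> np.ndarray:
    """Count tags whose position falls in each half-open region.

    ``regions`` needs chrom/start/end columns.  Overlapping regions each
    receive the tag.  Binary search on the per-chromosome sorted positions.
    """
    counts = np.zeros(len(regions), dtype=np.int64)
    for chrom, sub in regions.groupby("chrom", sort=False):
        p = tags.positions.get(str(chrom))
        if p is None or len(p) == 0:
            continue
        lo = np.searchsorted(p, sub["start"].values, side="left")
        hi = np.searchsorted(p, sub["end"].values, side="left")
        counts[regions.index.get_indexer(sub.index)] = hi - lo
    return counts


def _region_count(tags: TagSet, chrom: str, start: int, end: int) -> int:
    p = tags.positions.get(chrom)
    if p is None:
        return 0
    return int(np.searchsorted(p, end) - np.searchsorted(p, start))


def occupancy_proportions(
    tags: TagSet,
    index: AnnotationIndex,
    promoter_bp: int = 3000,
) -> dict:
    """Fractions of tags in promoter / gene body / intergenic space, with the
    gene-body fraction subdivided into CDS / UTR / intron.

    Every tag is assigned one category by :func:`~chromdiff.regions.classify_position`
    (precedence CDS > UTR > intron > promoter > intergenic); top-level
    fractions sum to 1 and sub-fractions to the gene-body fraction.
    """
    if tags.n_tags == 0:
        raise ValueError("cannot compute occupancy proportions of an empty TagSet")
    from .regions import classify_positions

    counts = {"CDS": 0, "UTR": 0, "intron": 0, "promoter": 0, "intergenic": 0}
    for chrom, pos in tags.positions.items():
        cats = classify_positions(index, chrom, pos, promoter_bp)
        for cat, n in zip(*np.unique(cats, return_counts=True)):
            counts[str(cat)] += int(n)
    total = sum(counts.values())
    body = counts["CDS"] + counts["UTR"] + counts["intron"]
    out = {
        "promoter": counts["promoter"] / total,
        "gene_body": body / total,
        "intergenic": counts["intergenic"] / total,
        "gene_body_sub": {
            "CDS": counts["CDS"] / body if body else 0.0,
            "UTR": counts["UTR"] / body if body else 0.0,
            "intron": counts["intron"] / body if body else 0.0,
        },
        "n_tags": total,
    }
    return out


@dataclass
class OccupancyProfile:
    """Mean per-bin tag counts over a gene set, oriented 5'->3'."""

    bin_means: np.ndarray
    gene_set_label: str
    n_genes: int
    normalize: str = "raw"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin": np.arange(1, len(self.bin_means) + 1),
                "mean_count": self.bin_means,
            }
        )


def metagene_profile(
    tags: TagSet,
    genes: list[GeneModel],
    flank_bp: int = 5000,
    n_bins: int = 100,
    normalize: str = "raw",
    chrom_sizes: dict[str, int] | None = None,
    label: str = "custom",
) -> OccupancyProfile:
    """Mean tag count per metagene bin over a gene set.

    Each gene's span (5' flank -> body -> 3' flank) is tiled with ``n_bins``
    bins oriented in transcription direction; ``bin_means[i]`` is the mean
    over genes of the tag count in bin i, divided by bin width when
    ``normalize='per-bp'``.
    """
    if not genes:
        raise ValueError("empty gene list")
    if normalize not in ("raw", "per-bp"):
        raise ValueError(f"unknown normalize mode {normalize!r}")
    acc = np.zeros(n_bins, dtype=float)
    for g in genes:
        bins = metagene_bins(g, flank_bp, n_bins, chrom_sizes)
        for i, b in enumerate(bins):
            c = _region_count(tags, b.chrom, b.start, b.end)
            acc[i] += c / len(b) if normalize == "per-bp" else c
    return OccupancyProfile(
        bin_means=acc / len(genes),
        gene_set_label=label,
        n_genes=len(genes),
        normalize=normalize,
    )
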