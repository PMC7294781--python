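"""Gene-model ingestion and strand-aware derivation of analysis regions.

All coordinates are 0-based half-open (BED convention) internally; GTF input
(1-based closed) is converted on read.  A gene's promoter is the fixed window
immediately upstream of its transcription start site (TSS), the gene body the
span from TSS to transcription end site (TES), and metagene bins tile the
gene body plus flanks with a fixed number of equal-width intervals ordered in
the direction of transcription.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from intervaltree import IntervalTree

__all__ = [
    "GenomicInterval",
    "GeneModel",
    "AnnotationIndex",
    "AnnotationError",
    "load_annotation",
    "promoter_region",
    "gene_body_region",
    "metagene_bins",
    "classify_position",
    "category_segments",
    "classify_positions",
]

#: classification labels, in default precedence order (highest first)
DEFAULT_PRECEDENCE = ("CDS", "UTR", "intron", "promoter", "intergenic")


class AnnotationError(ValueError):
    """Raised for malformed or empty annotation input."""


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass
class GeneModel:
    """One gene: outermost span plus exon/CDS/UTR structure.

    ``tss``/``tes`` are strand-aware: on '+' the TSS is ``interval.start``;
    on '-' it is ``interval.end`` (the exclusive genomic end, i.e. the 5'
    end in transcription direction).
    """

    gene_id: str
    interval: GenomicInterval
    exons: list[GenomicInterval] = field(default_factory=list)
    cds: list[GenomicInterval] = field(default_factory=list)
    utr: list[GenomicInterval] = field(default_factory=list)

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def tss(self) -> int:
        return self.interval.start if self.strand != "-" else self.interval.end

    @property
    def tes(self) -> int:
        return self.interval.end if self.strand != "-" else self.interval.start

    @property
    def length(self) -> int:
        return len(self.interval)


def _merge_intervals(
    ivs: list[GenomicInterval],
) -> list[GenomicInterval]:
    """Merge overlapping/adjacent intervals (same chrom/strand assumed)."""
    if not ivs:
        return []
    ivs = sorted(ivs, key=lambda iv: (iv.start, iv.end))
    merged = [ivs[0]]
    for iv in ivs[1:]:
        last = merged[-1]
        if iv.start <= last.end:
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end, last.strand)
        else:
            merged.append(iv)
    return merged


class AnnotationIndex:
    """Collection of gene models with per-chromosome overlap indices."""

    def __init__(self, genes: list[GeneModel], chrom_sizes: dict[str, int]):
        for g in genes:
            size = chrom_sizes.get(g.chrom)
            if size is None:
                raise AnnotationError(
                    f"gene {g.gene_id} on unknown chromosome {g.chrom}"
                )
            if g.interval.end > size:
                raise AnnotationError(
                    f"gene {g.gene_id} extends past end of {g.chrom} ({size})"
                )
        self.genes = list(genes)
        self.chrom_sizes = dict(chrom_sizes)
        self._by_id = {g.gene_id: g for g in self.genes}
        self._trees: dict[str, IntervalTree] = {}
        for g in self.genes:
            self._trees.setdefault(g.chrom, IntervalTree()).addi(
                g.interval.start, g.interval.end, g
            )
        # promoters indexed separately so classification never scans all genes
        self._promoter_trees: dict[str, IntervalTree] = {}
        self._promoter_bp: int | None = None

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def get(self, gene_id: str) -> GeneModel:
        return self._by_id[gene_id]

    def overlapping(self, chrom: str, start: int, end: int) -> list[GeneModel]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return [hit.data for hit in tree.overlap(start, end)]

    def _promoters(self, promoter_bp: int) -> dict[str, IntervalTree]:
        if self._promoter_bp != promoter_bp:
            trees: dict[str, IntervalTree] = {}
            for g in self.genes:
                p = promoter_region(g, promoter_bp, self.chrom_sizes)
                if p is not None:
                    trees.setdefault(g.chrom, IntervalTree()).addi(
                        p.start, p.end, g
                    )
            self._promoter_trees = trees
            self._promoter_bp = promoter_bp
        return self._promoter_trees


# ---------------------------------------------------------------------------
# annotation readers

_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_gtf_attributes(attr: str) -> dict[str, str]:
    return dict(_GTF_ATTR.findall(attr))


def _load_gtf(path: str) -> dict[str, dict]:
    """Collect per-transcript features from an Ensembl-dialect GTF."""
    per_gene: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise AnnotationError(f"{path}:{lineno}: expected 9 GTF columns")
            chrom, _src, feature, start_s, end_s, _score, strand, _frame, attrs = (
                fields[:9]
            )
            try:
                start = int(start_s) - 1  # GTF is 1-based closed
                end = int(end_s)
            except ValueError as exc:
                raise AnnotationError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            if feature not in ("exon", "CDS", "UTR", "five_prime_utr",
                               "three_prime_utr", "transcript", "gene"):
                continue
            attrd = _parse_gtf_attributes(attrs)
            gene_id = attrd.get("gene_id")
            if gene_id is None:
                raise AnnotationError(f"{path}:{lineno}: missing gene_id attribute")
            rec = per_gene.setdefault(
                gene_id,
                {"chrom": chrom, "strand": strand, "spans": [], "exons": [],
                 "cds": [], "utr": []},
            )
            if rec["chrom"] != chrom:
                raise AnnotationError(
                    f"{path}:{lineno}: gene {gene_id} spans multiple chromosomes"
                )
            iv = GenomicInterval(chrom, start, end, strand)
            if feature in ("gene", "transcript"):
                rec["spans"].append(iv)
            elif feature == "exon":
                rec["exons"].append(iv)
            elif feature == "CDS":
                rec["cds"].append(iv)
            else:
                rec["utr"].append(iv)
    return per_gene


def _load_bed12(path: str) -> dict[str, dict]:
    """Read BED12 gene models; blocks become exons, thick region the CDS."""
    per_gene: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 12:
                raise AnnotationError(
                    f"{path}:{lineno}: expected 12 BED columns, got {len(fields)}"
                )
            chrom, start_s, end_s, name = fields[0], fields[1], fields[2], fields[3]
            strand = fields[5]
            thick_start, thick_end = int(fields[6]), int(fields[7])
            n_blocks = int(fields[9])
            try:
                sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
                starts = [int(x) for x in fields[11].rstrip(",").split(",")]
            except ValueError as exc:
                raise AnnotationError(f"{path}:{lineno}: malformed block lists") from exc
            if len(sizes) != n_blocks or len(starts) != n_blocks:
                raise AnnotationError(
                    f"{path}:{lineno}: blockCount disagrees with block lists"
                )
            start, end = int(start_s), int(end_s)
            rec = per_gene.setdefault(
                name,
                {"chrom": chrom, "strand": strand, "spans": [], "exons": [],
                 "cds": [], "utr": []},
            )
            rec["spans"].append(GenomicInterval(chrom, start, end, strand))
            for bs, sz in zip(starts, sizes):
                ex_s, ex_e = start + bs, start + bs + sz
                rec["exons"].append(GenomicInterval(chrom, ex_s, ex_e, strand))
                cds_s, cds_e = max(ex_s, thick_start), min(ex_e, thick_end)
                if cds_s < cds_e:
                    rec["cds"].append(GenomicInterval(chrom, cds_s, cds_e, strand))
                if ex_s < min(ex_e, thick_start):
                    rec["utr"].append(
                        GenomicInterval(chrom, ex_s, min(ex_e, thick_start), strand)
                    )
                if max(ex_s, thick_end) < ex_e:
                    rec["utr"].append(
                        GenomicInterval(chrom, max(ex_s, thick_end), ex_e, strand)
                    )
    return per_gene


def load_annotation(
    path: str,
    chrom_sizes: dict[str, int] | None = None,
    fmt: str | None = None,
    collapse: str = "outermost",
) -> AnnotationIndex:
    """Load gene models from GTF or BED12 into an :class:`AnnotationIndex`.

    Multiple transcripts of one gene are collapsed to the outermost TSS/TES
    and the union of their exons/CDS (``collapse='outermost'``, the only
    implemented policy).

    Parameters
    ----------
    path
        GTF (Ensembl dialect) or BED12 file; format sniffed from the
        extension unless ``fmt`` in {'gtf', 'bed12'} is given.
    chrom_sizes
        chromosome -> length.  When omitted, sizes are taken as the maximal
        annotated end per chromosome.
    """
    if collapse != "outermost":
        raise ValueError(f"unknown collapse policy {collapse!r}")
    if fmt is None:
        low = path.lower()
        fmt = "bed12" if low.endswith((".bed", ".bed12")) else "gtf"
    per_gene = _load_bed12(path) if fmt == "bed12" else _load_gtf(path)
    if not per_gene:
        raise AnnotationError(f"{path}: no gene records found")

    genes: list[GeneModel] = []
    for gene_id in sorted(per_gene):
        rec = per_gene[gene_id]
        pieces = rec["spans"] + rec["exons"] + rec["cds"] + rec["utr"]
        start = min(iv.start for iv in pieces)
        end = max(iv.end for iv in pieces)
        span = GenomicInterval(rec["chrom"], start, end, rec["strand"])
        genes.append(
            GeneModel(
                gene_id=gene_id,
                interval=span,
                exons=_merge_intervals(rec["exons"]),
                cds=_merge_intervals(rec["cds"]),
                utr=_merge_intervals(rec["utr"]),
            )
        )
    if chrom_sizes is None:
        chrom_sizes = {}
        for g in genes:
            chrom_sizes[g.chrom] = max(chrom_sizes.get(g.chrom, 0), g.interval.end)
    return AnnotationIndex(genes, chrom_sizes)


# ---------------------------------------------------------------------------
# derived regions


def promoter_region(
    gene: GeneModel,
    upstream_bp: int = 3000,
    chrom_sizes: dict[str, int] | None = None,
) -> GenomicInterval | None:
    """Window from the TSS to ``upstream_bp`` upstream, clipped at
    chromosome bounds.  Returns ``None`` when clipping leaves nothing
    (gene starting at position 0 on '+')."""
    if upstream_bp <= 0:
        raise ValueError("upstream_bp must be positive")
    if gene.strand == "-":
        start, end = gene.tss, gene.tss + upstream_bp
    else:
        start, end = gene.tss - upstream_bp, gene.tss
    start = max(0, start)
    if chrom_sizes is not None and gene.chrom in chrom_sizes:
        end = min(end, chrom_sizes[gene.chrom])
    if start >= end:
        return None
    return GenomicInterval(gene.chrom, start, end, gene.strand)


def gene_body_region(gene: GeneModel) -> GenomicInterval:
    """Span from TSS to TES — the gene's outermost interval."""
    return gene.interval


def metagene_bins(
    gene: GeneModel,
    flank_bp: int = 5000,
    n_bins: int = 100,
    chrom_sizes: dict[str, int] | None = None,
) -> list[GenomicInterval]:
    """Tile ``[span5' - flank, span3' + flank]`` with ``n_bins`` contiguous
    equal-width bins ordered 5'->3' in transcription direction.

    Any bp remainder is spread one bp at a time over the leading bins.  If
    the flanked span exceeds the chromosome it is clipped first (the bins
    then tile the clipped span).
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    start = gene.interval.start - flank_bp
    end = gene.interval.end + flank_bp
    start = max(0, start)
    if chrom_sizes is not None and gene.chrom in chrom_sizes:
        end = min(end, chrom_sizes[gene.chrom])
    total = end - start
    if total < n_bins:
        raise ValueError(
            f"span of {gene.gene_id} too short ({total} bp) for {n_bins} bins"
        )
    width, rem = divmod(total, n_bins)
    bins: list[GenomicInterval] = []
    pos = start
    # remainder assigned to leading bins in transcription direction
    extras = [1] * rem + [0] * (n_bins - rem)
    if gene.strand == "-":
        extras = extras[::-1]
    for i in range(n_bins):
        w = width + extras[i]
        bins.append(GenomicInterval(gene.chrom, pos, pos + w, gene.strand))
        pos += w
    if gene.strand == "-":
        bins.reverse()
    return bins


def classify_position(
    index: AnnotationIndex,
    chrom: str,
    pos: int,
    promoter_bp: int = 3000,
    precedence: tuple[str, ...] = DEFAULT_PRECEDENCE,
) -> str:
    """Assign a single category to a genomic position.

    Default precedence CDS > UTR > intron > promoter > intergenic: a gene
    body sub-category wins over an overlapping neighbour's promoter.
    """
    if chrom not in index.chrom_sizes:
        raise KeyError(f"unknown chromosome {chrom!r}")
    if not (0 <= pos < index.chrom_sizes[chrom]):
        raise ValueError(f"position {pos} outside {chrom}")
    hit_cats: set[str] = set()
    for g in index.overlapping(chrom, pos, pos + 1):
        sub = "intron"
        for iv in g.cds:
            if iv.contains(pos):
                sub = "CDS"
                break
        else:
            for iv in g.utr:
                if iv.contains(pos):
                    sub = "UTR"
                    break
        hit_cats.add(sub)
    ptree = index._promoters(promoter_bp).get(chrom)
    if ptree is not None and ptree.overlap(pos, pos + 1):
        hit_cats.add("promoter")
    for cat in precedence:
        if cat in hit_cats:
            return cat
    return "intergenic"


def category_segments(
    index: AnnotationIndex,
    chrom: str,
    promoter_bp: int = 3000,
    precedence: tuple[str, ...] = DEFAULT_PRECEDENCE,
):
    """Piecewise-constant category decomposition of one chromosome.

    Returns ``(breaks, cats)``: ``breaks`` is a sorted int64 array of segment
    boundaries starting at 0 and ending at the chromosome length, and
    ``cats[i]`` is the category of ``[breaks[i], breaks[i+1])``.  Equivalent
    to :func:`classify_position` at every base, but computed by a sweep.
    """
    if chrom not in index.chrom_sizes:
        raise KeyError(f"unknown chromosome {chrom!r}")
    size = index.chrom_sizes[chrom]
    per_cat: dict[str, list[tuple[int, int]]] = {
        "CDS": [], "UTR": [], "intron": [], "promoter": []
    }
    for g in index.genes:
        if g.chrom != chrom:
            continue
        per_cat["intron"].append((g.interval.start, g.interval.end))
        per_cat["CDS"].extend((iv.start, iv.end) for iv in g.cds)
        per_cat["UTR"].extend((iv.start, iv.end) for iv in g.utr)
        p = promoter_region(g, promoter_bp, index.chrom_sizes)
        if p is not None:
            per_cat["promoter"].append((p.start, p.end))
    pts = {0, size}
    for ivs in per_cat.values():
        for s, e in ivs:
            pts.add(min(s, size))
            pts.add(min(e, size))
    breaks = np.array(sorted(pts), dtype=np.int64)
    n_seg = len(breaks) - 1
    covered: dict[str, "np.ndarray"] = {}
    for cat, ivs in per_cat.items():
        diff = np.zeros(n_seg + 1, dtype=np.int64)
        for s, e in ivs:
            i = np.searchsorted(breaks, min(s, size))
            j = np.searchsorted(breaks, min(e, size))
            diff[i] += 1
            diff[j] -= 1
        covered[cat] = np.cumsum(diff[:-1]) > 0
    cats = np.full(n_seg, "intergenic", dtype=object)
    for cat in reversed([c for c in precedence if c != "intergenic"]):
        if cat in covered:
            cats[covered[cat]] = cat
    return breaks, cats


def classify_positions(
    index: AnnotationIndex,
    chrom: str,
    positions,
    promoter_bp: int = 3000,
    precedence: tuple[str, ...] = DEFAULT_PRECEDENCE,
):
    """Vectorized :func:`classify_position` for an array of positions."""
    breaks, cats = category_segments(index, chrom, promoter_bp, precedence)
    pos = np.asarray(positions, dtype=np.int64)
    if pos.size and (pos.min() < 0 or pos.max() >= index.chrom_sizes[chrom]):
        raise ValueError(f"positions outside {chrom}")
    seg = np.searchsorted(breaks, pos, side="right") - 1
    return cats[seg]
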