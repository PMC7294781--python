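"""Broad-domain calling and cross-sample consensus regions.

The domain caller is deliberately simple: the genome is tiled with fixed
windows, a window is significant when its tag count exceeds the upper tail
of a global Poisson background (genome-wide tags per window), and nearby
significant windows are merged.  It stands in for a full peak caller where
broad repressive domains are the signal of interest; externally produced
peak BED files are accepted interchangeably.

Consensus regions are, by default, the maximal runs of bases covered by
peaks from at least ``min_support`` distinct samples (per-base support
semantics).  An "any-overlap union" mode merges peaks across samples and
keeps merged regions touched by enough samples, for comparability with
overlap-voting tools.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import poisson

from .tags import TagSet

__all__ = [
    "PeakSet",
    "ConsensusRegions",
    "call_domains",
    "consensus_regions",
    "read_peaks_bed",
    "write_peaks_bed",
]


@dataclass
class PeakSet:
    """Sorted, non-overlapping peaks for one sample.

    ``peaks`` columns: chrom, start, end, count, p_value.
    """

    sample_id: str
    peaks: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["chrom", "start", "end", "count", "p_value"]
        )
    )

    def __len__(self) -> int:
        return len(self.peaks)


@dataclass
class ConsensusRegions:
    """Non-overlapping regions supported by >= min_support samples.

    ``regions`` columns: chrom, start, end, support (max per-base sample
    count within the region).
    """

    regions: pd.DataFrame
    min_support: int

    def __len__(self) -> int:
        return len(self.regions)

    def region_ids(self) -> pd.Index:
        return pd.Index(
            [
                f"{r.chrom}:{r.start}-{r.end}"
                for r in self.regions.itertuples(index=False)
            ],
            name="region_id",
        )

    def to_frame(self) -> pd.DataFrame:
        df = self.regions.copy()
        df.index = self.region_ids()
        return df


def call_domains(
    tags: TagSet,
    chrom_sizes: dict[str, int],
    window_bp: int = 1000,
    p_threshold: float = 1e-3,
    merge_gap_bp: int = 1000,
) -> PeakSet:
    """Call enriched domains against a global Poisson background.

    The genome is tiled with non-overlapping ``window_bp`` windows; the
    background rate is the genome-wide tag count per window.  A window is
    kept when ``P(X >= count) < p_threshold`` for X ~ Poisson(lambda);
    kept windows closer than ``merge_gap_bp`` are merged, recording the
    merged tag count and its Poisson p-value.
    """
    total_bp = sum(chrom_sizes.values())
    n_tags = tags.n_tags
    if n_tags == 0:
        return PeakSet(sample_id=tags.sample_id)
    lam = n_tags * window_bp / total_bp
    rows = []
    for chrom in sorted(chrom_sizes):
        size = chrom_sizes[chrom]
        pos = tags.positions.get(chrom)
        if pos is None or len(pos) == 0:
            continue
        edges = np.arange(0, size + window_bp, window_bp)
        edges[-1] = min(edges[-1], size)
        if edges[-1] <= edges[-2]:
            edges = edges[:-1]
        counts = np.diff(np.searchsorted(pos, edges))
        # P(X >= c) = sf(c - 1); strict threshold
        pvals = poisson.sf(counts - 1, lam)
        sig = np.flatnonzero(pvals < p_threshold)
        for i in sig:
            rows.append((chrom, int(edges[i]), int(edges[i + 1])))
    if not rows:
        return PeakSet(sample_id=tags.sample_id)
    # merge windows within merge_gap_bp
    merged = []
    for chrom, start, end in rows:
        if (
            merged
            and merged[-1][0] == chrom
            and start - merged[-1][2] <= merge_gap_bp
        ):
            merged[-1][2] = end
        else:
            merged.append([chrom, start, end])
    out = []
    for chrom, start, end in merged:
        pos = tags.positions[chrom]
        count = int(np.searchsorted(pos, end) - np.searchsorted(pos, start))
        lam_region = n_tags * (end - start) / total_bp
        out.append(
            (chrom, start, end, count, float(poisson.sf(count - 1, lam_region)))
        )
    return PeakSet(
        sample_id=tags.sample_id,
        peaks=pd.DataFrame(out, columns=["chrom", "start", "end", "count", "p_value"]),
    )


def consensus_regions(
    peaksets: list[PeakSet],
    min_support: int = 2,
    mode: str = "per-base",
) -> ConsensusRegions:
    """Regions supported by peaks from >= ``min_support`` distinct samples.

    ``mode='per-base'`` (default): keep maximal runs of bases covered by
    enough samples; a region's support is the maximum per-base sample count
    inside it.  ``mode='union'``: merge all peaks across samples and keep
    merged regions overlapped by >= min_support distinct samples.
    """
    if len(peaksets) < min_support:
        raise ValueError(
            f"need at least min_support={min_support} peak sets, got {len(peaksets)}"
        )
    events: dict[str, list[tuple[int, int]]] = {}
    for ps in peaksets:
        for r in ps.peaks.itertuples(index=False):
            events.setdefault(r.chrom, []).append((int(r.start), int(r.end)))
    rows = []
    if mode == "per-base":
        for chrom in sorted(events):
            ivs = events[chrom]
            pts = np.array(sorted({p for iv in ivs for p in iv}), dtype=np.int64)
            diff = np.zeros(len(pts), dtype=np.int64)
            for s, e in ivs:
                diff[np.searchsorted(pts, s)] += 1
                diff[np.searchsorted(pts, e)] -= 1
            cover = np.cumsum(diff)[:-1]  # coverage on [pts[i], pts[i+1])
            ok = cover >= min_support
            i = 0
            while i < len(ok):
                if ok[i]:
                    j = i
                    while j + 1 < len(ok) and ok[j + 1]:
                        j += 1
                    rows.append(
                        (
                            chrom,
                            int(pts[i]),
                            int(pts[j + 1]),
                            int(cover[i: j + 1].max()),
                        )
                    )
                    i = j + 1
                else:
                    i += 1
    elif mode == "union":
        for chrom in sorted(events):
            ivs = sorted(events[chrom])
            merged: list[list[int]] = []
            for s, e in ivs:
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            for s, e in merged:
                support = sum(
                    1
                    for ps in peaksets
                    if (
                        (ps.peaks["chrom"] == chrom)
                        & (ps.peaks["start"] < e)
                        & (ps.peaks["end"] > s)
                    ).any()
                )
                if support >= min_support:
                    rows.append((chrom, s, e, support))
    else:
        raise ValueError(f"unknown consensus mode {mode!r}")
    return ConsensusRegions(
        regions=pd.DataFrame(rows, columns=["chrom", "start", "end", "support"]),
        min_support=min_support,
    )


def read_peaks_bed(path: str, sample_id: str | None = None) -> PeakSet:
    """Read a peak BED (>=3 columns; score column taken as -log10 p)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 BED columns")
            p = 10 ** (-float(f[4])) if len(f) >= 5 and f[4] not in (".", "") else np.nan
            rows.append((f[0], int(f[1]), int(f[2]), 0, p))
    if sample_id is None:
        sample_id = path.rsplit("/", 1)[-1].split(".")[0]
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "count", "p_value"])
    df = df.sort_values(["chrom", "start"]).reset_index(drop=True)
    return PeakSet(sample_id=sample_id, peaks=df)


def write_peaks_bed(peaks: PeakSet, path: str) -> None:
    """Write peaks as BED6 with score = -log10 p (capped at 9999)."""
    with open(path, "w") as fh:
        for i, r in enumerate(peaks.peaks.itertuples(index=False)):
            score = min(9999.0, -np.log10(max(r.p_value, 1e-300)))
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{peaks.sample_id}_peak{i + 1}\t"
                f"{score:.2f}\t.\n"
            )
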