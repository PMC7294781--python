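"""Integration of histone-mark and expression calls.

Produces the headline integrative outputs: the divergent ("inverse") gene
sets in which the mark and the transcript move in opposite directions, the
common epigenome set (genes called by both sides), expression-stratified
metagene occupancy profiles, the rank correlation between mark occupancy
and expression, hierarchical clustering of the per-gene change vectors, and
a marker-list-based cell-type partition of the common set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage, to_tree
from scipy.stats import spearmanr

from .regions import AnnotationIndex
from .tags import OccupancyProfile, TagSet, metagene_profile

__all__ = [
    "IntegrationResult",
    "StratifiedProfiles",
    "inverse_overlap",
    "expression_stratified_profiles",
    "k9_expression_correlation",
    "cluster_changes",
    "celltype_partition",
]


@dataclass
class IntegrationResult:
    """Divergent gene sets and the common epigenome.

    ``up_mrna_down_k9``: expression up, mark down; ``down_mrna_up_k9`` the
    mirror; ``common_epigenomes``: genes called on both sides regardless of
    direction.  ``evidence`` holds the per-gene supporting rows.
    """

    up_mrna_down_k9: set[str]
    down_mrna_up_k9: set[str]
    common_epigenomes: set[str]
    evidence: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def inverse_total(self) -> set[str]:
        return self.up_mrna_down_k9 | self.down_mrna_up_k9

    def summary(self) -> str:
        return (
            f"common epigenomes (DMG ∩ DEG): {len(self.common_epigenomes)}\n"
            f"inverse genes total:           {len(self.inverse_total)}\n"
            f"  mRNA up,   mark down:        {len(self.up_mrna_down_k9)}\n"
            f"  mRNA down, mark up:          {len(self.down_mrna_up_k9)}"
        )


def inverse_overlap(calls: pd.DataFrame) -> IntegrationResult:
    """Divergent-change gene sets from a per-gene call table.

    ``calls`` needs boolean ``dmg``/``deg`` and integer ``dmg_direction``/
    ``deg_direction`` columns.  Set (a) collects genes with expression up
    and mark down, set (b) the mirror; concordant genes stay only in the
    common-epigenome set.
    """
    both = calls["dmg"] & calls["deg"]
    up_a = both & (calls["deg_direction"] == 1) & (calls["dmg_direction"] == -1)
    dn_b = both & (calls["deg_direction"] == -1) & (calls["dmg_direction"] == 1)
    evidence = calls.loc[both, [c for c in calls.columns if c.startswith(("dmg", "deg"))]]
    return IntegrationResult(
        up_mrna_down_k9=set(calls.index[up_a]),
        down_mrna_up_k9=set(calls.index[dn_b]),
        common_epigenomes=set(calls.index[both]),
        evidence=evidence,
    )


@dataclass
class StratifiedProfiles:
    """Occupancy profiles of the highest- and lowest-expressed gene sets."""

    high_profile: OccupancyProfile
    low_profile: OccupancyProfile
    high_genes: list[str]
    low_genes: list[str]


def expression_stratified_profiles(
    tagsets: dict[str, TagSet] | TagSet,
    rna_norm: pd.DataFrame,
    index: AnnotationIndex,
    n_select: int = 1000,
    min_length: int = 5000,
    flank_bp: int = 5000,
    n_bins: int = 100,
    normalize: str = "raw",
) -> StratifiedProfiles:
    """Metagene occupancy of the top and bottom expression strata.

    Genes are ranked by mean normalized expression across samples (stable
    tie-break by gene id); genes shorter than ``min_length`` are excluded
    before the top/bottom ``n_select`` are taken (``n_select`` shrinks with
    a warning when fewer qualify).  Tags from multiple samples are pooled.
    """
    import warnings

    mean_expr = rna_norm.mean(axis=1)
    qualifying = [
        g.gene_id
        for g in index
        if g.length >= min_length and g.gene_id in mean_expr.index
    ]
    if not qualifying:
        raise ValueError(f"no genes of length >= {min_length} with expression")
    n_eff = min(n_select, len(qualifying) // 2)
    if n_eff < n_select:
        warnings.warn(
            f"only {len(qualifying)} qualifying genes; using n_select={n_eff}"
        )
    # stable rank by (mean expression, gene_id)
    ranked = mean_expr.loc[qualifying].sort_index().sort_values(kind="mergesort")
    low_genes = list(ranked.index[:n_eff])
    high_genes = list(ranked.index[-n_eff:])

    if isinstance(tagsets, TagSet):
        pooled = tagsets
    else:
        pooled = _pool_tagsets(tagsets)
    high = metagene_profile(
        pooled, [index.get(g) for g in high_genes], flank_bp, n_bins,
        normalize, index.chrom_sizes, label="high",
    )
    low = metagene_profile(
        pooled, [index.get(g) for g in low_genes], flank_bp, n_bins,
        normalize, index.chrom_sizes, label="low",
    )
    return StratifiedProfiles(
        high_profile=high, low_profile=low,
        high_genes=high_genes, low_genes=low_genes,
    )


def _pool_tagsets(tagsets: dict[str, TagSet]) -> TagSet:
    """Concatenate tags across samples (duplicates kept: counts sum)."""
    positions: dict[str, list[np.ndarray]] = {}
    n_raw = n_kept = 0
    for ts in tagsets.values():
        n_raw += ts.n_raw
        n_kept += ts.n_kept
        for chrom, pos in ts.positions.items():
            positions.setdefault(chrom, []).append(pos)
    return TagSet(
        sample_id="pooled",
        positions={c: np.sort(np.concatenate(v)) for c, v in positions.items()},
        n_raw=n_raw,
        n_kept=n_kept,
    )


def k9_expression_correlation(
    k9_norm: pd.DataFrame,
    rna_norm: pd.DataFrame,
    method: str = "spearman",
) -> tuple[float, float]:
    """Rank correlation between per-gene mean mark occupancy and expression.

    Both inputs are normalized per-gene count matrices indexed by gene id
    (the mark matrix over the chosen region type, promoter or body);
    restricted to the common gene universe.
    """
    common = k9_norm.index.intersection(rna_norm.index)
    if len(common) < 10:
        raise ValueError("need >= 10 shared genes for a correlation")
    x = k9_norm.loc[common].mean(axis=1)
    y = rna_norm.loc[common].mean(axis=1)
    if x.nunique() <= 1 or y.nunique() <= 1:
        raise ValueError("correlation undefined for constant input")
    if method != "spearman":
        raise ValueError(f"unsupported correlation method {method!r}")
    rho, p = spearmanr(x, y)
    return float(rho), float(p)


def cluster_changes(
    delta_k9: pd.Series,
    delta_rna: pd.Series,
) -> tuple[np.ndarray, list[str], str]:
    """Hierarchical clustering of per-gene (mark change, expression change).

    Ward linkage on Euclidean distances; returns the scipy linkage matrix,
    the leaf order (gene ids, deterministic under fixed input order) and a
    Newick serialization with merge heights as branch lengths.
    """
    df = pd.concat({"delta_k9": delta_k9, "delta_rna": delta_rna}, axis=1)
    if df.isna().any().any():
        raise ValueError("NaN in change vectors")
    if len(df) < 2:
        raise ValueError("need >= 2 genes to cluster")
    z = linkage(df.values, method="ward", metric="euclidean")
    order = [df.index[i] for i in leaves_list(z)]
    newick = _to_newick(to_tree(z), list(df.index))
    return z, order, newick


def _to_newick(node, labels: list[str]) -> str:
    def rec(n, parent_dist: float) -> str:
        length = max(0.0, parent_dist - n.dist)
        if n.is_leaf():
            return f"{labels[n.id]}:{length:.6g}"
        return (
            f"({rec(n.left, n.dist)},{rec(n.right, n.dist)}):{length:.6g}"
        )

    return rec(node, node.dist) + ";"


def celltype_partition(
    common: set[str],
    marker_lists: dict[str, set[str]],
    deg_directions: pd.Series,
) -> dict[str, dict[str, set[str]]]:
    """Split the common-epigenome set by cell-type marker membership.

    For each cell type, the intersection of ``common`` with its marker list,
    split into up- and down-regulated sets by ``deg_directions`` (+1/-1 per
    gene).  A gene on several marker lists appears under each.
    """
    if not marker_lists:
        raise ValueError("empty marker map")
    out: dict[str, dict[str, set[str]]] = {}
    for celltype, markers in marker_lists.items():
        hit = common & set(markers)
        out[celltype] = {
            "up": {g for g in hit if deg_directions.get(g, 0) == 1},
            "down": {g for g in hit if deg_directions.get(g, 0) == -1},
        }
    return out
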