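"""Differentially marked / expressed gene calling.

Two routes identify differentially marked genes (DMGs):

* method 1 — call differential consensus peak regions (DMRs) and map every
  passing region to the genes whose body it overlaps;
* method 2 — compare promoter and gene-body tag count matrices directly,
  each through the full statistical chain (TMM -> dispersion -> exact test
  -> permutation fold-change cutoff).

The union of the two routes is the DMG set.  Differentially expressed genes
(DEGs) run the identical chain on the transcript count matrix.  Per-gene
directions come from the most significant supporting call (smallest p;
ties broken by larger |log2FC|, then lexicographic region id), with a
conflict flag when supporting calls disagree in sign.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diffstats import (
    CountMatrix,
    DifferentialResults,
    TwoGroupCountModel,
)
from .regions import AnnotationIndex, promoter_region
from .tags import TagSet, count_tags_in_regions

__all__ = [
    "StatsConfig",
    "run_differential",
    "dmrs_to_genes",
    "build_region_counts",
    "promoter_genebody_dmgs",
    "combine_dmgs",
    "call_degs",
    "build_gene_call_table",
]


@dataclass
class StatsConfig:
    """Parameters of the differential chain, shared by ChIP and RNA sides."""

    alpha: float = 0.05
    n_permutations: int = 1000
    percentile: float = 0.10
    cutoff_mode: str = "literal"
    prior_count: float = 0.5
    dispersion_method: str = "moments"
    bh_correction: bool = False
    seed: int = 0


def run_differential(matrix: CountMatrix, config: StatsConfig) -> DifferentialResults:
    """TMM -> common dispersion -> exact test -> permutation cutoff -> calls."""
    model = TwoGroupCountModel(matrix)
    return model.fit(
        alpha=config.alpha,
        n_permutations=config.n_permutations,
        percentile=config.percentile,
        cutoff_mode=config.cutoff_mode,
        prior_count=config.prior_count,
        dispersion_method=config.dispersion_method,
        bh_correction=config.bh_correction,
        seed=config.seed,
    )


def _best_support(rows: pd.DataFrame) -> pd.Series:
    """Most significant row: smallest p, then largest |log2fc|, then id."""
    ranked = rows.assign(_abs=rows["log2fc"].abs())
    ranked = ranked.sort_values(
        by=["p_value", "_abs", "_id"], ascending=[True, False, True]
    )
    return ranked.iloc[0]


def dmrs_to_genes(
    dmr_result: pd.DataFrame,
    dmr_regions: pd.DataFrame,
    index: AnnotationIndex,
    include_promoters: bool = False,
    promoter_bp: int = 3000,
) -> pd.DataFrame:
    """Map passing DMRs to genes by gene-body overlap (>= 1 bp).

    ``dmr_result`` is a called differential table indexed by region id with
    ``passes``/``p_value``/``log2fc``; ``dmr_regions`` holds the region
    coordinates (chrom/start/end, same index).  With ``include_promoters``,
    overlap with the 3 kb promoter also links a DMR to the gene.

    Returns one row per gene: direction, supporting p/log2fc/region id.
    """
    passing = dmr_result[dmr_result["passes"]]
    hits: list[tuple] = []
    for rid, row in passing.iterrows():
        reg = dmr_regions.loc[rid]
        genes = index.overlapping(reg["chrom"], int(reg["start"]), int(reg["end"]))
        if include_promoters:
            extra = []
            for g in index.genes:
                if g.chrom != reg["chrom"]:
                    continue
                p = promoter_region(g, promoter_bp, index.chrom_sizes)
                if p is not None and p.start < reg["end"] and p.end > reg["start"]:
                    extra.append(g)
            genes = list({g.gene_id: g for g in genes + extra}.values())
        for g in genes:
            hits.append((g.gene_id, str(rid), row["p_value"], row["log2fc"]))
    if not hits:
        return pd.DataFrame(
            columns=["p_value", "log2fc", "direction", "region_id"],
            index=pd.Index([], name="gene_id"),
        )
    hdf = pd.DataFrame(hits, columns=["gene_id", "_id", "p_value", "log2fc"])
    out = []
    for gene_id, rows in hdf.groupby("gene_id", sort=True):
        best = _best_support(rows)
        out.append(
            (
                gene_id,
                best["p_value"],
                best["log2fc"],
                int(np.sign(best["log2fc"])),
                best["_id"],
            )
        )
    return pd.DataFrame(
        out, columns=["gene_id", "p_value", "log2fc", "direction", "region_id"]
    ).set_index("gene_id")


def build_region_counts(
    tagsets: dict[str, TagSet],
    regions: pd.DataFrame,
    group: pd.Series,
    group_order: tuple[str, str] | None = None,
) -> CountMatrix:
    """Count every sample's tags in a region table -> CountMatrix."""
    data = {
        sample: count_tags_in_regions(ts, regions)
        for sample, ts in tagsets.items()
    }
    counts = pd.DataFrame(data, index=regions.index)
    return CountMatrix(counts=counts, group=group, group_order=group_order)


def promoter_genebody_dmgs(
    tagsets: dict[str, TagSet],
    index: AnnotationIndex,
    group: pd.Series,
    config: StatsConfig,
    promoter_bp: int = 3000,
    group_order: tuple[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Method 2: promoter and gene-body count comparison.

    Builds the two per-gene count matrices from the tag sets and runs each
    through the differential chain independently.  Returns (promoter calls,
    gene-body calls, metadata); call tables are indexed by gene id with
    ``passes``/``direction``/``p_value``/``log2fc``.
    """
    prom_rows, body_rows = [], []
    for g in index:
        p = promoter_region(g, promoter_bp, index.chrom_sizes)
        if p is not None:
            prom_rows.append((g.gene_id, p.chrom, p.start, p.end))
        body_rows.append((g.gene_id, g.chrom, g.interval.start, g.interval.end))
    prom_df = pd.DataFrame(
        prom_rows, columns=["gene_id", "chrom", "start", "end"]
    ).set_index("gene_id")
    body_df = pd.DataFrame(
        body_rows, columns=["gene_id", "chrom", "start", "end"]
    ).set_index("gene_id")

    prom_matrix = build_region_counts(tagsets, prom_df, group, group_order)
    body_matrix = build_region_counts(tagsets, body_df, group, group_order)
    prom_res = run_differential(prom_matrix, config)
    body_res = run_differential(body_matrix, config)
    meta = {
        "promoter": prom_res.run_metadata(),
        "gene_body": body_res.run_metadata(),
    }
    return prom_res.table, body_res.table, meta


def combine_dmgs(
    method1: pd.DataFrame,
    method2_promoter: pd.DataFrame,
    method2_body: pd.DataFrame,
) -> pd.DataFrame:
    """Union of the DMG routes with per-gene direction attribution.

    Inputs: method 1 as the gene table from :func:`dmrs_to_genes`;
    method 2 as called differential tables indexed by gene id.  The output
    GeneCallTable fragment has per-gene booleans for each route, the union
    flag, the winning direction (smallest supporting p), and a conflict
    flag when supporting routes disagree in sign.
    """
    support: list[tuple] = []
    for gene_id, row in method1.iterrows():
        support.append((gene_id, "dmr", row["p_value"], row["log2fc"]))
    for name, table in (("promoter", method2_promoter), ("gene_body", method2_body)):
        if "passes" in table:
            passing = table[table["passes"]]
        else:
            passing = table
        for gene_id, row in passing.iterrows():
            support.append((gene_id, name, row["p_value"], row["log2fc"]))
    genes = sorted({s[0] for s in support})
    sdf = pd.DataFrame(support, columns=["gene_id", "_id", "p_value", "log2fc"])
    rows = []
    for gene_id in genes:
        sub = sdf[sdf["gene_id"] == gene_id]
        best = _best_support(sub)
        directions = set(np.sign(sub["log2fc"]).astype(int))
        rows.append(
            {
                "gene_id": gene_id,
                "dmg_method1": bool((sub["_id"] == "dmr").any()),
                "dmg_method2_promoter": bool((sub["_id"] == "promoter").any()),
                "dmg_method2_body": bool((sub["_id"] == "gene_body").any()),
                "dmg": True,
                "dmg_direction": int(np.sign(best["log2fc"])),
                "dmg_p_value": best["p_value"],
                "dmg_log2fc": best["log2fc"],
                "dmg_conflict": len(directions) > 1,
            }
        )
    cols = [
        "dmg_method1", "dmg_method2_promoter", "dmg_method2_body", "dmg",
        "dmg_direction", "dmg_p_value", "dmg_log2fc", "dmg_conflict",
    ]
    if not rows:
        return pd.DataFrame(columns=cols, index=pd.Index([], name="gene_id"))
    return pd.DataFrame(rows).set_index("gene_id")[cols]


def call_degs(
    rna_matrix: CountMatrix, config: StatsConfig
) -> tuple[pd.DataFrame, dict]:
    """DEG calling: the same statistical chain on expression counts.

    Returns the called table (indexed by gene id, with ``passes`` and
    ``direction``; up = higher in the case group) and run metadata.
    """
    res = run_differential(rna_matrix, config)
    return res.table, res.run_metadata()


def build_gene_call_table(
    dmg_table: pd.DataFrame,
    deg_table: pd.DataFrame,
    gene_universe: list[str],
) -> pd.DataFrame:
    """Assemble the full per-gene call table over a gene universe.

    Combines the DMG fragment from :func:`combine_dmgs` with DEG calls into
    one table with ``dmg``/``deg`` booleans, directions (0 when not called)
    and supporting statistics.
    """
    out = pd.DataFrame(index=pd.Index(sorted(gene_universe), name="gene_id"))
    frag = dmg_table.reindex(out.index)
    for col in ("dmg_method1", "dmg_method2_promoter", "dmg_method2_body", "dmg",
                "dmg_conflict"):
        out[col] = frag[col].astype("boolean").fillna(False).astype(bool)
    out["dmg_direction"] = frag["dmg_direction"].astype("Int64").fillna(0).astype(int)
    out["dmg_p_value"] = frag["dmg_p_value"]
    out["dmg_log2fc"] = frag["dmg_log2fc"]
    deg = deg_table.reindex(out.index)
    out["deg"] = deg["passes"].astype("boolean").fillna(False).astype(bool)
    out["deg_direction"] = deg["direction"].astype("Int64").fillna(0).astype(int)
    out["deg_p_value"] = deg["p_value"]
    out["deg_log2fc"] = deg["log2fc"]
    return out
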