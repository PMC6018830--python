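"""Association of DMRs with genes, TEs and 24-nt smRNA loci, and the
cross-tabulations against differential expression.

Geometry: a gene's extended region is its body plus strand-aware 2-kb
promoter (upstream of the transcription start) and downstream flanks. Any
>= 1 bp overlap associates; a DMR straddling a region boundary yields one
association per region touched. "Flanking" aggregates promoter and
downstream wherever panels are split body-vs-flank.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .core import CONTEXTS
from .intervals import gene_region_bounds, overlap_length

logger = logging.getLogger(__name__)

__all__ = [
    "associate_dmrs_with_genes",
    "associate_dmrs_with_tes",
    "associate_smrnas",
    "crosstab_expression",
    "gene_sets_body_vs_flank",
    "te_gene_upregulation",
]

LOCATIONS = ("promoter", "gene_body", "downstream")

ASSOCIATION_COLUMNS = [
    "dmr_id",
    "gene_id",
    "location",
    "overlap_bp",
    "context",
    "status",
    "chrom",
    "dmr_start",
    "dmr_end",
]


def associate_dmrs_with_genes(
    dmrs: pd.DataFrame, genes: pd.DataFrame, config: PipelineConfig
) -> pd.DataFrame:
    """One row per (DMR, gene, overlapped region) with the overlap width."""
    rows = []
    dmr_by_chrom = {c: sub for c, sub in dmrs.groupby("chrom", sort=False)}
    for g in genes.itertuples(index=False):
        sub = dmr_by_chrom.get(g.chrom)
        if sub is None:
            continue
        regions = gene_region_bounds(int(g.start), int(g.end), str(g.strand), config.flank_size)
        reach_lo = min(lo for lo, hi in regions.values() if lo <= hi)
        reach_hi = max(hi for lo, hi in regions.values() if lo <= hi)
        near = sub[(sub["start"] <= reach_hi) & (sub["end"] >= reach_lo)]
        for d in near.itertuples(index=False):
            for location in LOCATIONS:
                lo, hi = regions[location]
                if lo > hi:
                    continue
                ov = overlap_length(int(d.start), int(d.end), lo, hi)
                if ov >= 1:
                    rows.append(
                        (
                            d.dmr_id,
                            g.gene_id,
                            location,
                            ov,
                            d.context,
                            d.status,
                            d.chrom,
                            int(d.start),
                            int(d.end),
                        )
                    )
    out = pd.DataFrame(rows, columns=ASSOCIATION_COLUMNS)
    logger.info(
        "gene association: %d DMR-gene-region links, %d distinct genes",
        len(out),
        out["gene_id"].nunique() if len(out) else 0,
    )
    return out


def associate_dmrs_with_tes(dmrs: pd.DataFrame, tes: pd.DataFrame) -> pd.DataFrame:
    """Per (TE, context): counted once, with aggregated hyper/hypo/mixed status."""
    rows = []
    dmr_by_chrom = {c: sub for c, sub in dmrs.groupby("chrom", sort=False)}
    for t in tes.itertuples(index=False):
        sub = dmr_by_chrom.get(t.chrom)
        if sub is None:
            continue
        hit = sub[(sub["start"] <= int(t.end)) & (sub["end"] >= int(t.start))]
        for context in CONTEXTS:
            statuses = set(hit.loc[hit["context"] == context, "status"])
            if not statuses:
                continue
            status = statuses.pop() if len(statuses) == 1 else "mixed"
            rows.append((t.te_id, t.chrom, int(t.start), int(t.end), context, status))
    return pd.DataFrame(rows, columns=["te_id", "chrom", "start", "end", "context", "status"])


def associate_smrnas(
    smrnas: pd.DataFrame,
    dmrs: pd.DataFrame,
    associations: pd.DataFrame,
    config: PipelineConfig,
    genes: pd.DataFrame | None = None,
) -> dict:
    """smRNA/DMR association fractions and the smRNA region distribution.

    An smRNA associates with a DMR on >= 1 bp overlap. Each (smRNA, context)
    pair counts once; context fractions are shares of all such pairs and sum
    to 1 when any association exists. The region distribution covers
    DMR-associated genes only, with the usual strand-aware geometry (needs
    ``genes`` to locate their bounds).
    """
    pair_counts: dict[tuple[str, str], int] = {}
    dmr_by_chrom = {c: sub for c, sub in dmrs.groupby("chrom", sort=False)}
    for s in smrnas.itertuples(index=False):
        sub = dmr_by_chrom.get(s.chrom)
        if sub is None:
            continue
        hit = sub[(sub["start"] <= int(s.end)) & (sub["end"] >= int(s.start))]
        for context in hit["context"].unique():
            statuses = set(hit.loc[hit["context"] == context, "status"])
            status = statuses.pop() if len(statuses) == 1 else "mixed"
            pair_counts[(context, status)] = pair_counts.get((context, status), 0) + 1
    total_pairs = sum(pair_counts.values())
    fractions = {
        context: {
            "fraction": (
                sum(v for (c, _), v in pair_counts.items() if c == context) / total_pairs
                if total_pairs
                else 0.0
            ),
            "by_status": {
                status: v / total_pairs if total_pairs else 0.0
                for (c, status), v in pair_counts.items()
                if c == context
            },
        }
        for context in CONTEXTS
    }

    region_counts = {loc: 0 for loc in LOCATIONS}
    if genes is not None and len(associations):
        assoc_gene_ids = set(associations["gene_id"])
        assoc_genes = genes[genes["gene_id"].isin(assoc_gene_ids)]
        smrna_by_chrom = {c: sub for c, sub in smrnas.groupby("chrom", sort=False)}
        for g in assoc_genes.itertuples(index=False):
            sub = smrna_by_chrom.get(g.chrom)
            if sub is None:
                continue
            regions = gene_region_bounds(
                int(g.start), int(g.end), str(g.strand), config.flank_size
            )
            for s in sub.itertuples(index=False):
                for loc in LOCATIONS:
                    lo, hi = regions[loc]
                    if lo <= hi and overlap_length(int(s.start), int(s.end), lo, hi) >= 1:
                        region_counts[loc] += 1
    region_total = sum(region_counts.values())
    return {
        "n_smrnas": int(len(smrnas)),
        "n_associated_pairs": total_pairs,
        "fractions_by_context": fractions,
        "region_counts": region_counts,
        "region_fractions": {
            loc: (v / region_total if region_total else 0.0) for loc, v in region_counts.items()
        },
    }


def crosstab_expression(
    associations: pd.DataFrame, expression: pd.DataFrame, config: PipelineConfig
) -> dict:
    """Cross-tabulate DMR-associated genes against expression status.

    Returns, per comparison: the count of DMR-associated genes that are
    differentially expressed, counts of genes associated with hyper- vs
    hypomethylated DMRs, and — for each context in {CG, CHH} x location in
    {gene_body, flanking} x DMR status — the up/down fractions among
    differentially expressed genes of that class (flanking = promoter +
    downstream). Classes are non-exclusive: a gene contributes to every
    panel it belongs to.
    """
    out: dict[str, dict] = {}
    assoc_genes = associations["gene_id"].unique() if len(associations) else np.array([], dtype=object)
    for comparison, expr in expression.groupby("comparison", sort=False):
        status_map = dict(zip(expr["gene_id"], expr["status"]))
        missing = [g for g in assoc_genes if g not in status_map]
        if missing:
            logger.warning(
                "comparison %s: %d DMR-associated genes absent from expression table; counted ns",
                comparison,
                len(missing),
            )

        def status_of(gene_id: str) -> str:
            return status_map.get(gene_id, "ns")

        de_genes = {g for g in assoc_genes if status_of(g) != "ns"}

        by_dmr_status = {}
        for dmr_status in ("hyper", "hypo"):
            sub = associations[associations["status"] == dmr_status]
            by_dmr_status[dmr_status] = int(sub["gene_id"].nunique())

        panels = {}
        for context in ("CG", "CHH"):
            for location_label, locations in (
                ("gene_body", ("gene_body",)),
                ("flanking", ("promoter", "downstream")),
            ):
                for dmr_status in ("hyper", "hypo"):
                    sub = associations[
                        (associations["context"] == context)
                        & (associations["location"].isin(locations))
                        & (associations["status"] == dmr_status)
                    ]
                    gene_ids = sub["gene_id"].unique()
                    n_up = sum(1 for g in gene_ids if status_of(g) == "up")
                    n_down = sum(1 for g in gene_ids if status_of(g) == "down")
                    denom = n_up + n_down
                    panels[f"{context}_{location_label}_{dmr_status}"] = {
                        "n_genes": int(len(gene_ids)),
                        "n_up": n_up,
                        "n_down": n_down,
                        "frac_up": n_up / denom if denom else float("nan"),
                        "frac_down": n_down / denom if denom else float("nan"),
                    }
        out[str(comparison)] = {
            "n_dmr_associated_genes": int(len(assoc_genes)),
            "n_de_dmr_associated_genes": len(de_genes),
            "genes_by_dmr_status": by_dmr_status,
            "panels": panels,
        }
    return out


def gene_sets_body_vs_flank(associations: pd.DataFrame, config: PipelineConfig | None = None) -> dict:
    """Disjoint gene sets: CG-body only, CHH-flank only, and both."""
    if len(associations) == 0:
        return {"CG_body_only": set(), "CHH_flank_only": set(), "both": set()}
    cg_body = set(
        associations.loc[
            (associations["context"] == "CG") & (associations["location"] == "gene_body"),
            "gene_id",
        ]
    )
    chh_flank = set(
        associations.loc[
            (associations["context"] == "CHH")
            & (associations["location"].isin(["promoter", "downstream"])),
            "gene_id",
        ]
    )
    return {
        "CG_body_only": cg_body - chh_flank,
        "CHH_flank_only": chh_flank - cg_body,
        "both": cg_body & chh_flank,
    }


def te_gene_upregulation(
    te_associations: pd.DataFrame,
    genes: pd.DataFrame,
    expression: pd.DataFrame,
    config: PipelineConfig,
) -> dict:
    """Counts of up-regulated genes near hyper- vs hypomethylated TEs.

    Proximity uses the gene body plus both 2-kb flanks. A TE's status is the
    aggregated per-context status from :func:`associate_dmrs_with_tes`; TEs
    of any context count, 'mixed' TEs count under neither pile.
    """
    out: dict[str, dict] = {}
    te_by_chrom = {c: sub for c, sub in te_associations.groupby("chrom", sort=False)}
    for comparison, expr in expression.groupby("comparison", sort=False):
        up_genes = expr.loc[expr["status"] == "up", "gene_id"]
        up_set = set(up_genes)
        counts = {"hyper": 0, "hypo": 0}
        for g in genes.itertuples(index=False):
            if g.gene_id not in up_set:
                continue
            regions = gene_region_bounds(
                int(g.start), int(g.end), str(g.strand), config.flank_size
            )
            lo = min(l for l, h in regions.values() if l <= h)
            hi = max(h for l, h in regions.values() if l <= h)
            sub = te_by_chrom.get(g.chrom)
            if sub is None:
                continue
            near = sub[(sub["start"] <= hi) & (sub["end"] >= lo)]
            statuses = set(near["status"])
            for status in ("hyper", "hypo"):
                if status in statuses:
                    counts[status] += 1
        out[str(comparison)] = counts
    return out
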