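"""Metagene methylation-density profiles over gene bodies and fixed flanks.

For every gene the body is rescaled into ``n_bins`` equal-length bins and
each flank (``flank_size`` bp up- and downstream of the gene, strand-aware)
into ``n_bins`` fixed-length bins. Coordinates are flipped for minus-strand
genes so that bin 1 of the upstream segment is always farthest from the
TSS. Counts are pooled over genes *before* division: the per-bin density is
(methylated calls) / (covered cytosines of the same context) across all
genes, not the mean of per-gene ratios.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .core import CONTEXTS

logger = logging.getLogger(__name__)

__all__ = ["compute_metaprofile", "SEGMENTS"]

SEGMENTS = ("upstream", "body", "downstream")


def _bin_index(offset: np.ndarray, segment_length: int, n_bins: int) -> np.ndarray:
    # ties at segment boundaries resolve to the downstream bin; the final
    # position of a segment would index n_bins and is clamped into the last
    idx = (offset * n_bins) // segment_length
    return np.minimum(idx, n_bins - 1)


def compute_metaprofile(
    calls: pd.DataFrame,
    genes: pd.DataFrame,
    config: PipelineConfig,
) -> pd.DataFrame:
    """Pooled per-bin methylation densities, one row per context/segment/bin.

    Genes shorter than ``n_bins`` bp are skipped with a warning. Bins with
    no covered cytosine get NaN density.
    """
    n_bins = config.n_bins
    flank = config.flank_size
    ctx_codes = {c: i for i, c in enumerate(CONTEXTS)}

    n_mc = np.zeros((len(CONTEXTS), len(SEGMENTS), n_bins), dtype=np.int64)
    n_cov = np.zeros_like(n_mc)

    calls_sorted = calls.sort_values(["chrom", "pos"], kind="mergesort")
    by_chrom = {
        chrom: (
            sub["pos"].to_numpy(),
            sub["context"].map(ctx_codes).to_numpy(),
            sub["is_methylated"].to_numpy(),
        )
        for chrom, sub in calls_sorted.groupby("chrom", sort=False)
    }

    n_skipped = 0
    for g in genes.itertuples(index=False):
        start, end, minus = int(g.start), int(g.end), g.strand == "-"
        gene_len = end - start + 1
        if gene_len < n_bins:
            n_skipped += 1
            continue
        if g.chrom not in by_chrom:
            continue
        pos, ctx, meth = by_chrom[g.chrom]

        # (segment index, region lo, region hi, region length)
        if minus:
            spans = [(0, end + 1, end + flank), (1, start, end), (2, start - flank, start - 1)]
        else:
            spans = [(0, start - flank, start - 1), (1, start, end), (2, end + 1, end + flank)]
        for seg, lo, hi in spans:
            seg_len = hi - lo + 1
            if seg_len <= 0:
                continue
            i = np.searchsorted(pos, max(lo, 1), side="left")
            j = np.searchsorted(pos, hi, side="right")
            if i == j:
                continue
            p = pos[i:j]
            offset = (hi - p) if minus else (p - lo)
            bins = _bin_index(offset, seg_len, n_bins)
            np.add.at(n_cov, (ctx[i:j], seg, bins), 1)
            np.add.at(n_mc, (ctx[i:j], seg, bins), meth[i:j].astype(np.int64))

    if n_skipped:
        logger.warning("metaprofile: skipped %d genes shorter than %d bp", n_skipped, n_bins)

    rows = []
    for ci, context in enumerate(CONTEXTS):
        for si, segment in enumerate(SEGMENTS):
            for b in range(n_bins):
                cov = int(n_cov[ci, si, b])
                mc = int(n_mc[ci, si, b])
                density = mc / cov if cov > 0 else float("nan")
                rows.append((context, segment, b + 1, density, mc, cov))
    return pd.DataFrame(
        rows, columns=["context", "segment", "bin_index", "density", "n_mC", "n_covered_C"]
    )
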