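"""Interval geometry helpers (1-based, closed intervals throughout)."""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["overlap_length", "gene_region_bounds", "find_overlaps"]


def overlap_length(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Number of bases shared by two closed intervals (0 if disjoint)."""
    return max(0, min(a_end, b_end) - max(a_start, b_start) + 1)


def gene_region_bounds(start: int, end: int, strand: str, flank: int) -> dict[str, tuple[int, int]]:
    """Strand-aware promoter / gene_body / downstream bounds for one gene.

    Promoter is the ``flank`` bp upstream of the transcription start (the
    higher-coordinate side for minus-strand genes); downstream is symmetric.
    Bounds are clipped at position 1.
    """
    if strand == "-":
        promoter = (end + 1, end + flank)
        downstream = (max(1, start - flank), start - 1)
    else:
        promoter = (max(1, start - flank), start - 1)
        downstream = (end + 1, end + flank)
    return {"promoter": promoter, "gene_body": (start, end), "downstream": downstream}


def find_overlaps(
    left: pd.DataFrame,
    right: pd.DataFrame,
    suffixes: tuple[str, str] = ("_a", "_b"),
) -> pd.DataFrame:
    """All-pairs ≥1 bp overlap join between two interval frames.

    Both frames need ``chrom``/``start``/``end`` columns. Returns one row per
    overlapping pair, carrying every column of both inputs (suffixed on
    collision) plus ``overlap_bp``. Scans chromosome by chromosome with a
    sorted sweep, which is plenty at annotation scale.
    """
    out_rows = []
    if len(left) == 0 or len(right) == 0:
        cols = (
            [c + suffixes[0] if c in right.columns else c for c in left.columns]
            + [c + suffixes[1] if c in left.columns else c for c in right.columns]
            + ["overlap_bp"]
        )
        return pd.DataFrame(columns=cols)
    for chrom, lsub in left.groupby("chrom", sort=False):
        rsub = right[right["chrom"] == chrom]
        if len(rsub) == 0:
            continue
        r_start = rsub["start"].to_numpy()
        r_end = rsub["end"].to_numpy()
        order = np.argsort(r_start, kind="mergesort")
        r_start_sorted = r_start[order]
        # running maximum of end among intervals sorted by start lets us
        # prune candidates whose ends all precede the query start
        r_end_sorted = r_end[order]
        for li, l in zip(lsub.index, lsub.itertuples(index=False)):
            hi = np.searchsorted(r_start_sorted, l.end, side="right")
            if hi == 0:
                continue
            cand = order[:hi]
            mask = r_end_sorted[:hi] >= l.start
            for ri in cand[mask]:
                out_rows.append((li, rsub.index[ri]))
    if not out_rows:
        cols = list(left.columns) + list(right.columns) + ["overlap_bp"]
        cols = list(dict.fromkeys(cols)) + []
        return pd.DataFrame(columns=_joined_columns(left, right, suffixes))
    li, ri = zip(*out_rows)
    lpart = left.loc[list(li)].reset_index(drop=True)
    rpart = right.loc[list(ri)].reset_index(drop=True)
    shared = set(lpart.columns) & set(rpart.columns)
    lpart = lpart.rename(columns={c: c + suffixes[0] for c in shared})
    rpart = rpart.rename(columns={c: c + suffixes[1] for c in shared})
    joined = pd.concat([lpart, rpart], axis=1)
    joined["overlap_bp"] = (
        np.minimum(joined["end" + suffixes[0]], joined["end" + suffixes[1]])
        - np.maximum(joined["start" + suffixes[0]], joined["start" + suffixes[1]])
        + 1
    ).astype(np.int64)
    return joined


def _joined_columns(left, right, suffixes):
    shared = set(left.columns) & set(right.columns)
    cols = [c + suffixes[0] if c in shared else c for c in left.columns]
    cols += [c + suffixes[1] if c in shared else c for c in right.columns]
    return cols + ["overlap_bp"]
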