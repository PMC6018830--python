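"""Sliding-window DMR detection between a test sample and a reference.

Per context, the genome is tiled with fixed-size windows on a step grid
(defaults 100/50). Within each window, read counts are pooled over the
cytosines of that context that reach the coverage floor in *both* samples
(so both percentages are computed on identical position sets), the pooled
2x2 table is scored with an exact two-sided Fisher test, q-values come
from the sliding-linear-model correction over all eligible windows of the
context, and a window is reported as a DMR when it simultaneously has at
least ``min_cytosines_per_window`` qualifying cytosines, an absolute
pooled percentage difference of at least ``min_meth_diff`` points, and a
q-value at or below ``max_qvalue``. Significant windows are reported
individually — no merging — and classified hyper (test above reference)
or hypo by the sign of the difference.
"""

from __future__ import annotations

import logging
from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .core import CONTEXTS, DMR_COLUMNS
from .slim import slim_qvalues

logger = logging.getLogger(__name__)

__all__ = [
    "make_windows",
    "aggregate_window_counts",
    "fisher_exact_2x2",
    "call_dmrs",
    "intersect_dmrs",
]


def make_windows(chrom_lengths: dict[str, int], config: PipelineConfig) -> pd.DataFrame:
    """Tiling window grid: starts 1, 1+step, ...; only full windows kept."""
    rows = []
    for chrom, length in chrom_lengths.items():
        if length < 1:
            raise ValueError(f"chromosome {chrom} has non-positive length {length}")
        starts = np.arange(1, length - config.window_size + 2, config.window_step, dtype=np.int64)
        for s in starts:
            rows.append((chrom, int(s), int(s) + config.window_size - 1))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def fisher_exact_2x2(m1: int, u1: int, m2: int, u2: int) -> float:
    """Exact two-sided Fisher p for the table [[m1, u1], [m2, u2]].

    Two-sided by minimum-likelihood summation: the hypergeometric
    probabilities of all tables with the observed margins that are no more
    likely than the observed table are summed. Table weights are exact
    integers (products of binomial coefficients), so tie comparison is
    exact; the final ratio is converted to float once. An all-zero table
    returns 1 by convention.
    """
    for v in (m1, u1, m2, u2):
        if v < 0 or int(v) != v:
            raise ValueError("Fisher table entries must be non-negative integers")
    m1, u1, m2, u2 = int(m1), int(u1), int(m2), int(u2)
    r1 = m1 + u1
    r2 = m2 + u2
    c1 = m1 + m2
    n = r1 + r2
    if n == 0:
        return 1.0
    k_lo = max(0, c1 - r2)
    k_hi = min(r1, c1)
    w_obs = comb(r1, m1) * comb(r2, m2)
    num = 0
    for k in range(k_lo, k_hi + 1):
        w = comb(r1, k) * comb(r2, c1 - k)
        if w <= w_obs:
            num += w
    return float(Fraction(num, comb(n, c1)))


def aggregate_window_counts(
    calls_test: pd.DataFrame,
    calls_ref: pd.DataFrame,
    windows: pd.DataFrame,
    context: str,
    config: PipelineConfig,
) -> pd.DataFrame:
    """Pool per-window 2x2 counts over jointly covered cytosines of a context.

    A position contributes only if it reaches ``min_coverage`` in both
    samples (the call frames are already coverage-filtered, so the joint
    requirement reduces to presence in both). Returns one row per grid
    window with n_cytosines, pooled m/u counts per sample, and pooled
    percentages; windows with no qualifying cytosines keep zero counts.
    """
    t = calls_test[calls_test["context"] == context]
    r = calls_ref[calls_ref["context"] == context]
    t = t[t["coverage"] >= config.min_coverage]
    r = r[r["coverage"] >= config.min_coverage]
    joint = t.merge(
        r,
        on=["chrom", "pos", "strand"],
        suffixes=("_test", "_ref"),
        how="inner",
    )

    size, step = config.window_size, config.window_step
    n_spans = -(-size // step)  # windows covering any given position

    win = windows.copy().reset_index(drop=True)

    parts = []
    if len(joint):
        pos = joint["pos"].to_numpy()
        k_max = (pos - 1) // step
        for j in range(n_spans):
            k = k_max - j
            starts = 1 + k * step
            valid = (k >= 0) & (pos <= starts + size - 1)
            part = pd.DataFrame(
                {
                    "chrom": joint["chrom"].to_numpy()[valid],
                    "start": starts[valid],
                    "n_cytosines": 1,
                    "m_test": joint["count_meth_test"].to_numpy()[valid],
                    "u_test": joint["count_unmeth_test"].to_numpy()[valid],
                    "m_ref": joint["count_meth_ref"].to_numpy()[valid],
                    "u_ref": joint["count_unmeth_ref"].to_numpy()[valid],
                }
            )
            parts.append(part)

    out = win.copy()
    if parts:
        pooled = (
            pd.concat(parts, ignore_index=True)
            .groupby(["chrom", "start"], sort=False, as_index=False)
            .sum()
        )
        # windows beyond the chromosome end are absent from the grid and
        # silently dropped by the left merge onto it
        out = out.merge(pooled, on=["chrom", "start"], how="left")
    for col in ("n_cytosines", "m_test", "u_test", "m_ref", "u_ref"):
        if col not in out.columns:
            out[col] = 0
        out[col] = out[col].fillna(0).astype(np.int64)
    out["context"] = context
    tot_test = out["m_test"] + out["u_test"]
    tot_ref = out["m_ref"] + out["u_ref"]
    with np.errstate(invalid="ignore", divide="ignore"):
        out["meth_test"] = 100.0 * out["m_test"] / tot_test
        out["meth_ref"] = 100.0 * out["m_ref"] / tot_ref
    out["diff"] = out["meth_test"] - out["meth_ref"]
    return out


def call_dmrs(
    calls_test: pd.DataFrame,
    calls_ref: pd.DataFrame,
    chrom_lengths: dict[str, int],
    config: PipelineConfig,
    contexts: tuple[str, ...] = CONTEXTS,
) -> pd.DataFrame:
    """Full DMR stage; returns the combined per-context DMR frame."""
    windows = make_windows(chrom_lengths, config)
    results = []
    for context in contexts:
        table = aggregate_window_counts(calls_test, calls_ref, windows, context, config)
        eligible = table[table["n_cytosines"] >= config.min_cytosines_per_window].copy()
        if len(eligible) == 0:
            logger.info("context %s: no eligible windows", context)
            continue
        eligible["p_value"] = [
            fisher_exact_2x2(m1, u1, m2, u2)
            for m1, u1, m2, u2 in zip(
                eligible["m_test"], eligible["u_test"], eligible["m_ref"], eligible["u_ref"]
            )
        ]
        qvals, pi0 = slim_qvalues(eligible["p_value"].to_numpy())
        eligible["q_value"] = qvals
        keep = (
            (eligible["diff"].abs() >= config.min_meth_diff)
            & (eligible["q_value"] <= config.max_qvalue)
            & (eligible["n_cytosines"] >= config.min_cytosines_per_window)
        )
        dmrs = eligible[keep].copy()
        dmrs["status"] = np.where(dmrs["diff"] > 0, "hyper", "hypo")
        logger.info(
            "context %s: %d eligible windows, pi0=%.3f, %d DMRs (%d hyper / %d hypo)",
            context,
            len(eligible),
            pi0,
            len(dmrs),
            int((dmrs["status"] == "hyper").sum()),
            int((dmrs["status"] == "hypo").sum()),
        )
        results.append(dmrs)
    if not results:
        return pd.DataFrame(columns=DMR_COLUMNS)
    out = pd.concat(results, ignore_index=True)
    out["dmr_id"] = (
        out["chrom"].astype(str)
        + "_"
        + out["start"].astype(str)
        + "_"
        + out["end"].astype(str)
    )
    out = out.sort_values(["chrom", "start", "context"]).reset_index(drop=True)
    return out[DMR_COLUMNS]


def summarize_dmrs(dmrs: pd.DataFrame) -> dict:
    """Per-context DMR counts and hypo/hyper fractions."""
    out: dict[str, dict] = {}
    for context in CONTEXTS:
        sub = dmrs[dmrs["context"] == context]
        n = len(sub)
        n_hyper = int((sub["status"] == "hyper").sum())
        out[context] = {
            "n_dmrs": n,
            "n_hyper": n_hyper,
            "n_hypo": n - n_hyper,
            "frac_hyper": n_hyper / n if n else float("nan"),
            "frac_hypo": (n - n_hyper) / n if n else float("nan"),
        }
    return out


def intersect_dmrs(comparison_results: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Windows that are DMRs in every comparison (coordinate+context match).

    Output rows carry per-comparison diff columns (``diff_<name>``) and a
    ``variable_status`` flag marking windows whose hypo/hyper status is not
    the same in all comparisons.
    """
    if not comparison_results:
        return pd.DataFrame(columns=["dmr_id", "chrom", "start", "end", "context"])
    names = list(comparison_results)
    key = ["chrom", "start", "end", "context"]
    merged: pd.DataFrame | None = None
    for name in names:
        sub = comparison_results[name][key + ["diff", "status"]].rename(
            columns={"diff": f"diff_{name}", "status": f"status_{name}"}
        )
        merged = sub if merged is None else merged.merge(sub, on=key, how="inner")
    assert merged is not None
    status_cols = [f"status_{n}" for n in names]
    merged["variable_status"] = merged[status_cols].nunique(axis=1) > 1
    merged["dmr_id"] = (
        merged["chrom"].astype(str)
        + "_"
        + merged["start"].astype(str)
        + "_"
        + merged["end"].astype(str)
    )
    cols = ["dmr_id"] + key + [f"diff_{n}" for n in names] + status_cols + ["variable_status"]
    return merged[cols].sort_values(["chrom", "start", "context"]).reset_index(drop=True)
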