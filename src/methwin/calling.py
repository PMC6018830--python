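"""Methylcytosine calling from per-cytosine count data.

A cytosine is retained when its coverage (methylated + unmethylated reads)
reaches ``min_coverage``; it is called methylated when the one-sided
binomial tail probability of observing at least its methylated count under
the measured bisulfite non-conversion rate falls at or below ``mc_alpha``.
Retained-but-unmethylated sites stay in the output: they are the
denominators for window statistics and metagene profiles.

Strands are treated as independent sites; no CpG strand merging is done.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .config import PipelineConfig
from .core import CALL_COLUMNS, CONTEXTS

logger = logging.getLogger(__name__)

__all__ = [
    "estimate_conversion_efficiency",
    "binomial_tail_pvalue",
    "call_methylcytosines",
    "summarize_context_fractions",
]


def estimate_conversion_efficiency(control_sites: pd.DataFrame) -> float:
    """Bisulfite conversion efficiency, in percent, from an unmethylated control.

    Every methylated read on the control contig is a conversion failure, so
    efficiency = 100 * sum(unmethylated) / sum(all reads).
    """
    meth = int(control_sites["count_meth"].sum())
    unmeth = int(control_sites["count_unmeth"].sum())
    total = meth + unmeth
    if total == 0:
        raise ValueError("cannot estimate conversion efficiency: zero total coverage on control")
    return 100.0 * unmeth / total


def binomial_tail_pvalue(count_meth: np.ndarray, coverage: np.ndarray, rate: float) -> np.ndarray:
    """One-sided upper binomial tail P(X >= count_meth | n=coverage, p=rate)."""
    count_meth = np.asarray(count_meth)
    coverage = np.asarray(coverage)
    # sf(k-1) = P(X >= k)
    return stats.binom.sf(count_meth - 1, coverage, rate)


def call_methylcytosines(
    sites: pd.DataFrame,
    config: PipelineConfig,
    nonconversion_rate: float | None = None,
) -> pd.DataFrame:
    """Call mCs on a sites frame, returning the calls frame.

    Sites with coverage < ``config.min_coverage`` are dropped entirely. The
    non-conversion rate defaults to ``config.nonconversion_rate`` and must
    lie strictly inside (0, 1) so the binomial test is well defined.
    """
    rate = config.nonconversion_rate if nonconversion_rate is None else nonconversion_rate
    if not (0.0 < rate < 1.0):
        raise ValueError(f"nonconversion_rate must lie in (0, 1), got {rate!r}")

    coverage = sites["count_meth"].to_numpy() + sites["count_unmeth"].to_numpy()
    keep = coverage >= config.min_coverage
    n_dropped = int((~keep).sum())
    kept = sites.loc[keep].reset_index(drop=True)
    coverage = coverage[keep]

    p_value = binomial_tail_pvalue(kept["count_meth"].to_numpy(), coverage, rate)
    calls = pd.DataFrame(
        {
            "chrom": kept["chrom"],
            "pos": kept["pos"],
            "strand": kept["strand"],
            "context": kept["context"],
            "count_meth": kept["count_meth"],
            "count_unmeth": kept["count_unmeth"],
            "coverage": coverage,
            "level": kept["count_meth"].to_numpy() / coverage,
            "p_value": p_value,
            "is_methylated": p_value <= config.mc_alpha,
        }
    )
    logger.info(
        "mC calling: %d sites in, %d below coverage %d, %d retained, %d methylated",
        len(sites),
        n_dropped,
        config.min_coverage,
        len(calls),
        int(calls["is_methylated"].sum()),
    )
    return calls[CALL_COLUMNS]


def summarize_context_fractions(calls: pd.DataFrame) -> dict:
    """Per-context mC fractions, mean levels and level quantiles.

    ``fraction_of_mCs`` is each context's share of all methylated calls and
    sums to 1 over CG/CHG/CHH. ``mean_level`` and the quantiles are computed
    over methylated calls only (box-plot style summaries).
    """
    mc = calls[calls["is_methylated"]]
    if len(mc) == 0:
        raise ValueError("no methylated calls; context fractions are undefined")
    total = len(mc)
    out: dict[str, dict] = {}
    for context in CONTEXTS:
        sub = mc[mc["context"] == context]
        levels = sub["level"].to_numpy()
        if len(levels):
            quantiles = {
                f"q{int(q * 100)}": float(np.quantile(levels, q))
                for q in (0.0, 0.25, 0.5, 0.75, 1.0)
            }
            mean_level = float(levels.mean())
        else:
            quantiles = {}
            mean_level = float("nan")
        out[context] = {
            "n_mC": int(len(sub)),
            "fraction_of_mCs": len(sub) / total,
            "mean_level": mean_level,
            "level_quantiles": quantiles,
        }
    return out
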