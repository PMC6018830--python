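"""q-values via a sliding-linear-model estimate of the null proportion.

The proportion of true nulls, pi0, is read off the empirical p-value CDF:
for a uniform/alternative mixture the CDF slope approaches pi0 as the
cut-point approaches 1, because alternative p-values concentrate near 0.
Ordinary least-squares lines are fit on sliding windows of lambda
cut-points; the estimate averages the slopes of the contiguous right-most
run of windows whose slopes agree with the final window (the stabilized,
null-dominated region). An atom of p-values at exactly 1 — common with
discrete exact tests — steepens the final window and pushes pi0 to 1,
which is the conservative and correct limit there.

q-values are the standard step-up quantities scaled by pi0:
q_(i) = pi0 * min_{j >= i} (m * p_(j) / j), clipped to [0, 1]; they are
non-decreasing in p by construction.

With fewer tests than ``min_tests`` the slope fit is too noisy and the
routine falls back to Benjamini-Hochberg (pi0 = 1), with a log notice.
"""

from __future__ import annotations

import logging

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["estimate_pi0_slim", "slim_qvalues"]


def estimate_pi0_slim(
    p_values: np.ndarray,
    n_lambda: int = 100,
    window_points: int | None = None,
    slope_tolerance: float = 0.1,
) -> float:
    """Estimate the proportion of true null hypotheses from p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("cannot estimate pi0 from an empty p-value collection")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if window_points is None:
        window_points = max(n_lambda // 10, 2)

    lam = np.linspace(0.0, 1.0, n_lambda + 1)
    cdf = np.searchsorted(np.sort(p), lam, side="right") / p.size

    n_windows = n_lambda + 1 - window_points
    slopes = np.empty(n_windows)
    for j in range(n_windows):
        x = lam[j : j + window_points + 1]
        y = cdf[j : j + window_points + 1]
        xc = x - x.mean()
        slopes[j] = float(xc @ (y - y.mean()) / (xc @ xc))
    clipped = np.clip(slopes, 0.0, 1.0)

    # contiguous right-most run of windows agreeing with the final slope
    final = clipped[-1]
    k = n_windows
    while k > 0 and abs(clipped[k - 1] - final) <= slope_tolerance:
        k -= 1
    pi0 = float(np.clip(clipped[k:].mean(), 0.0, 1.0))
    return pi0


def _bh_step_up(p: np.ndarray, pi0: float) -> np.ndarray:
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1] * pi0
    q = np.empty(m)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q


def slim_qvalues(p_values: np.ndarray, min_tests: int = 100) -> tuple[np.ndarray, float]:
    """q-values (same order as input) and the pi0 estimate used."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("cannot compute q-values for an empty p-value collection")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size < min_tests:
        logger.info(
            "only %d tests (< %d): falling back to Benjamini-Hochberg with pi0 = 1",
            p.size,
            min_tests,
        )
        pi0 = 1.0
    else:
        pi0 = estimate_pi0_slim(p)
    return _bh_step_up(p, pi0), pi0
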