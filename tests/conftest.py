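"""Shared fixtures: small toy frames plus two session-scoped synthetic runs.

``default_run`` is the standard 2-Mb simulation at mean coverage 30 used by
the level-recovery, conversion-efficiency and metaprofile checks.
``dmr_run`` is a larger paired run with 500 planted differential windows
among >50,000 null windows, used by the DMR filter and recovery checks.
Both are deterministic.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from methwin.calling import call_methylcytosines
from methwin.config import PipelineConfig
from methwin.dmr import call_dmrs
from methwin.simulate import (
    plant_dmrs,
    simulate_counts,
    simulate_genome,
    simulate_methylome,
)


@pytest.fixture(scope="session")
def cfg() -> PipelineConfig:
    return PipelineConfig(seed=11)


@pytest.fixture(scope="session")
def default_run(cfg):
    """2-Mb genome + control: truth, ref counts, ref calls."""
    annotation, positions = simulate_genome(
        cfg, n_chroms=2, chrom_length=1_000_000, seed=11
    )
    truth = simulate_methylome(annotation, positions, cfg, seed=12)
    ref = simulate_counts(truth, cfg, coverage_mean=30.0, sample="ref")
    control = ref[ref["chrom"] == truth.control_contig]
    calls = call_methylcytosines(ref[ref["chrom"] != truth.control_contig], cfg)
    return {
        "annotation": annotation,
        "truth": truth,
        "ref_counts": ref,
        "control_counts": control,
        "calls": calls,
    }


@pytest.fixture(scope="session")
def dmr_run(cfg):
    """Paired 3-Mb run with 500 planted windows; full DMR stage output."""
    annotation, positions = simulate_genome(
        cfg, n_chroms=3, chrom_length=1_000_000, seed=21
    )
    truth = simulate_methylome(annotation, positions, cfg, seed=22)
    truth = plant_dmrs(
        truth,
        cfg,
        n_dmrs=500,
        diff_range=(40.0, 60.0),
        seed=23,
        min_sites_per_window=8,
        annotation=annotation,
    )
    ref = simulate_counts(truth, cfg, coverage_mean=30.0, sample="ref")
    test = simulate_counts(truth, cfg, coverage_mean=30.0, sample="test")
    calls_ref = call_methylcytosines(ref[ref["chrom"] != truth.control_contig], cfg)
    calls_test = call_methylcytosines(test[test["chrom"] != truth.control_contig], cfg)
    lengths = {k: v for k, v in truth.chrom_lengths.items() if k != truth.control_contig}
    dmrs = call_dmrs(calls_test, calls_ref, lengths, cfg)
    return {
        "annotation": annotation,
        "truth": truth,
        "calls_ref": calls_ref,
        "calls_test": calls_test,
        "chrom_lengths": lengths,
        "dmrs": dmrs,
    }


def make_calls_frame(rows) -> pd.DataFrame:
    """Helper: build a calls frame from (chrom, pos, strand, context, m, u) rows."""
    df = pd.DataFrame(
        rows, columns=["chrom", "pos", "strand", "context", "count_meth", "count_unmeth"]
    )
    df["coverage"] = df["count_meth"] + df["count_unmeth"]
    df["level"] = np.where(df["coverage"] > 0, df["count_meth"] / df["coverage"], 0.0)
    df["p_value"] = 0.0
    df["is_methylated"] = df["level"] > 0.5
    return df
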