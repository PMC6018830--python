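"""Domain record types shared across the pipeline.

Tabular stages operate on :class:`pandas.DataFrame` objects whose columns
mirror these records; the dataclasses define the canonical field names,
value domains and per-record invariants, and provide conversion helpers for
record-level work and tests.

Coordinate convention: 1-based, closed intervals everywhere. BED input is
converted on ingestion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

__all__ = [
    "CONTEXTS",
    "CytosineSite",
    "MethylationCall",
    "DMRWindow",
    "ExpressionRecord",
    "GenomeAnnotation",
    "sites_to_frame",
    "frame_to_sites",
    "SITE_COLUMNS",
    "CALL_COLUMNS",
    "DMR_COLUMNS",
]

CONTEXTS = ("CG", "CHG", "CHH")

SITE_COLUMNS = ["chrom", "pos", "strand", "count_meth", "count_unmeth", "context", "trinucleotide"]

CALL_COLUMNS = [
    "chrom",
    "pos",
    "strand",
    "context",
    "count_meth",
    "count_unmeth",
    "coverage",
    "level",
    "p_value",
    "is_methylated",
]

DMR_COLUMNS = [
    "dmr_id",
    "chrom",
    "start",
    "end",
    "context",
    "n_cytosines",
    "meth_test",
    "meth_ref",
    "diff",
    "p_value",
    "q_value",
    "status",
]


@dataclass(frozen=True)
class CytosineSite:
    """One cytosine with its strand, context and read counts."""

    chrom: str
    pos: int
    strand: str
    count_meth: int
    count_unmeth: int
    context: str
    trinucleotide: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.count_meth < 0 or self.count_unmeth < 0:
            raise ValueError("read counts must be non-negative")
        if self.context not in CONTEXTS:
            raise ValueError(f"unknown context {self.context!r}; expected one of {CONTEXTS}")

    @property
    def coverage(self) -> int:
        return self.count_meth + self.count_unmeth


@dataclass(frozen=True)
class MethylationCall:
    """A coverage-qualified cytosine with its methylation test result."""

    site: CytosineSite
    coverage: int
    level: float
    p_value: float
    is_methylated: bool


@dataclass(frozen=True)
class DMRWindow:
    """A fixed-width window with pooled two-sample counts and test results."""

    chrom: str
    start: int
    end: int
    context: str
    n_cytosines: int
    meth_test: float
    meth_ref: float
    diff: float
    p_value: float
    q_value: float
    status: str

    @property
    def dmr_id(self) -> str:
        return f"{self.chrom}_{self.start}_{self.end}"

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class ExpressionRecord:
    gene_id: str
    comparison: str
    fold_change: float
    p_value: float
    status: str  # {"up", "down", "ns"}


@dataclass
class GenomeAnnotation:
    """Interval sets for genes, TEs and small-RNA loci (1-based, closed).

    ``genes``:  columns gene_id, chrom, start, end, strand
    ``tes``:    columns te_id, chrom, start, end, te_class
    ``smrnas``: columns chrom, start, end
    """

    genes: pd.DataFrame = field(default_factory=lambda: _empty_genes())
    tes: pd.DataFrame = field(default_factory=lambda: _empty_tes())
    smrnas: pd.DataFrame = field(default_factory=lambda: _empty_smrnas())
    chrom_lengths: dict[str, int] = field(default_factory=dict)


def _empty_genes() -> pd.DataFrame:
    return pd.DataFrame(columns=["gene_id", "chrom", "start", "end", "strand"])


def _empty_tes() -> pd.DataFrame:
    return pd.DataFrame(columns=["te_id", "chrom", "start", "end", "te_class"])


def _empty_smrnas() -> pd.DataFrame:
    return pd.DataFrame(columns=["chrom", "start", "end"])


def sites_to_frame(sites: Iterable[CytosineSite]) -> pd.DataFrame:
    """Pack CytosineSite records into the canonical sites frame."""
    rows = [
        (s.chrom, s.pos, s.strand, s.count_meth, s.count_unmeth, s.context, s.trinucleotide)
        for s in sites
    ]
    return pd.DataFrame(rows, columns=SITE_COLUMNS)


def frame_to_sites(frame: pd.DataFrame) -> list[CytosineSite]:
    """Unpack a sites frame into CytosineSite records (validates each row)."""
    return [
        CytosineSite(
            chrom=str(r.chrom),
            pos=int(r.pos),
            strand=str(r.strand),
            count_meth=int(r.count_meth),
            count_unmeth=int(r.count_unmeth),
            context=str(r.context),
            trinucleotide=str(r.trinucleotide),
        )
        for r in frame.itertuples(index=False)
    ]
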