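"""Readers and writers for the external text formats.

Formats handled:

* cytosine report — 7-column TSV: chrom, pos (1-based), strand, methylated
  count, unmethylated count, context, trinucleotide
* gene/TE/smRNA annotations — GFF3 (1-based closed) or BED (0-based
  half-open), auto-detected by file extension; everything is normalized to
  the internal 1-based closed convention
* methylation-call TSV, DMR TSV, metaprofile TSV, expression TSV

All readers return pandas DataFrames with the canonical column names from
:mod:`methwin.core`; reader∘writer is the identity on every record type.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .core import CALL_COLUMNS, CONTEXTS, DMR_COLUMNS, SITE_COLUMNS, GenomeAnnotation

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "read_cx_report",
    "write_cx_report",
    "read_features",
    "read_calls",
    "write_calls",
    "read_dmrs",
    "write_dmrs",
    "read_expression",
    "write_expression",
    "write_metaprofile",
    "read_metaprofile",
    "derive_expression_status",
]


class FormatError(ValueError):
    """Raised on a malformed input line; the message names the line number."""


# ---------------------------------------------------------------------------
# cytosine reports
# ---------------------------------------------------------------------------


def read_cx_report(path: str | Path, config: PipelineConfig | None = None) -> pd.DataFrame:
    """Read a per-cytosine report into the canonical sites frame.

    Line order is preserved. Malformed lines raise :class:`FormatError`
    naming the offending 1-based line number.
    """
    path = Path(path)
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=SITE_COLUMNS,
            dtype={"chrom": str, "strand": str, "context": str, "trinucleotide": str},
            comment="#",
        )
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=SITE_COLUMNS)
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: malformed cytosine report: {exc}") from exc

    for col in ("pos", "count_meth", "count_unmeth"):
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() | (numeric % 1 != 0)
        if bad.any():
            line = int(df.index[bad][0]) + 1
            raise FormatError(f"{path}:{line}: non-integer value in column '{col}'")
        df[col] = numeric.astype(np.int64)

    bad_ctx = ~df["context"].isin(CONTEXTS)
    if bad_ctx.any():
        line = int(df.index[bad_ctx][0]) + 1
        token = df.loc[df.index[bad_ctx][0], "context"]
        raise FormatError(f"{path}:{line}: unknown context token {token!r}")
    bad_strand = ~df["strand"].isin(["+", "-"])
    if bad_strand.any():
        line = int(df.index[bad_strand][0]) + 1
        raise FormatError(f"{path}:{line}: strand must be '+' or '-'")
    if (df["pos"] < 1).any():
        line = int(df.index[df["pos"] < 1][0]) + 1
        raise FormatError(f"{path}:{line}: position must be >= 1")
    if (df[["count_meth", "count_unmeth"]] < 0).any().any():
        raise FormatError(f"{path}: negative read count")
    logger.info("read %d cytosine sites from %s", len(df), path)
    return df


def write_cx_report(path: str | Path, sites: pd.DataFrame) -> None:
    sites[SITE_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

_BED_EXT = {".bed"}
_GFF_EXT = {".gff", ".gff3"}


def _parse_gff_attributes(attr: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for chunk in attr.strip().split(";"):
        if "=" in chunk:
            k, v = chunk.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_features(
    path: str | Path, kind: str, config: PipelineConfig | None = None
) -> pd.DataFrame:
    """Read gene/TE/smRNA intervals, normalized to 1-based closed coordinates.

    ``kind`` is one of ``gene``, ``te``, ``smrna``. GFF3 vs BED is decided
    by extension. smRNA intervals whose length differs from
    ``config.smrna_length`` are excluded with a warning.
    """
    if kind not in ("gene", "te", "smrna"):
        raise ValueError(f"kind must be gene/te/smrna, got {kind!r}")
    path = Path(path)
    config = config or PipelineConfig()
    ext = path.suffix.lower()
    if ext in _BED_EXT:
        df = _read_bed(path)
    elif ext in _GFF_EXT:
        df = _read_gff3(path, kind)
    else:
        raise FormatError(f"{path}: cannot autodetect format from extension {ext!r}")

    bad = df["start"] > df["end"]
    if bad.any():
        row = df[bad].iloc[0]
        raise FormatError(
            f"{path}: interval start > end after normalization "
            f"({row['chrom']}:{row['start']}-{row['end']})"
        )

    if kind == "smrna":
        length = df["end"] - df["start"] + 1
        off = length != config.smrna_length
        if off.any():
            logger.warning(
                "%s: excluding %d smRNA intervals with length != %d nt",
                path,
                int(off.sum()),
                config.smrna_length,
            )
            df = df[~off].reset_index(drop=True)
        return df[["chrom", "start", "end"]].copy()
    if kind == "gene":
        out = df.rename(columns={"name": "gene_id"})
        out["strand"] = out["strand"].replace(".", "+")
        return out[["gene_id", "chrom", "start", "end", "strand"]].copy()
    out = df.rename(columns={"name": "te_id"})
    out["te_class"] = out.get("te_class", pd.Series(["TE"] * len(out)))
    return out[["te_id", "chrom", "start", "end", "te_class"]].copy()


def _read_bed(path: Path) -> pd.DataFrame:
    try:
        raw = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=["chrom", "start", "end", "name", "strand"])
    ncol = raw.shape[1]
    raw = raw.rename(columns={0: "chrom", 1: "start", 2: "end"})
    # BED is 0-based half-open; internal convention is 1-based closed.
    raw["start"] = raw["start"].astype(np.int64) + 1
    raw["end"] = raw["end"].astype(np.int64)
    raw["name"] = (
        raw[3].astype(str)
        if ncol > 3
        else [f"feat_{i + 1}" for i in range(len(raw))]
    )
    raw["strand"] = raw[5].astype(str) if ncol > 5 else "."
    return raw[["chrom", "start", "end", "name", "strand"]]


def _read_gff3(path: Path, kind: str) -> pd.DataFrame:
    cols = ["chrom", "source", "type", "start", "end", "score", "strand", "phase", "attributes"]
    try:
        raw = pd.read_csv(path, sep="\t", header=None, names=cols, comment="#", dtype={0: str})
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=["chrom", "start", "end", "name", "strand"])
    if kind == "gene":
        raw = raw[raw["type"].str.lower() == "gene"]
    raw = raw.reset_index(drop=True)
    names = []
    for i, attr in enumerate(raw["attributes"].astype(str)):
        parsed = _parse_gff_attributes(attr)
        names.append(parsed.get("ID", parsed.get("Name", f"feat_{i + 1}")))
    out = pd.DataFrame(
        {
            "chrom": raw["chrom"].astype(str),
            "start": raw["start"].astype(np.int64),
            "end": raw["end"].astype(np.int64),
            "name": names,
            "strand": raw["strand"].astype(str),
        }
    )
    return out


def write_features_bed(path: str | Path, df: pd.DataFrame, kind: str) -> None:
    """Write intervals as BED6 (internal 1-based closed -> BED half-open)."""
    name_col = {"gene": "gene_id", "te": "te_id"}.get(kind)
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "start": df["start"].astype(np.int64) - 1,
            "end": df["end"].astype(np.int64),
            "name": df[name_col] if name_col and name_col in df else ".",
            "score": ".",
            "strand": df["strand"] if "strand" in df else ".",
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def write_features_gff3(path: str | Path, genes: pd.DataFrame) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for r in genes.itertuples(index=False):
            fh.write(
                f"{r.chrom}\tmethwin\tgene\t{r.start}\t{r.end}\t.\t{r.strand}\t.\t"
                f"ID={r.gene_id}\n"
            )


# ---------------------------------------------------------------------------
# methylation calls
# ---------------------------------------------------------------------------


def write_calls(path: str | Path, calls: pd.DataFrame) -> None:
    calls[CALL_COLUMNS].to_csv(path, sep="\t", index=False)


def read_calls(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    df["is_methylated"] = df["is_methylated"].astype(bool)
    return df[CALL_COLUMNS]


# ---------------------------------------------------------------------------
# DMRs
# ---------------------------------------------------------------------------

_DMR_FILE_COLUMNS = [
    "dmr_id",
    "chrom",
    "start",
    "end",
    "context",
    "n_cytosines",
    "meth_test",
    "meth_ref",
    "diff",
    "p",
    "q",
    "status",
]


def write_dmrs(path: str | Path, dmrs: pd.DataFrame) -> None:
    """Write the DMR table, sorted by (chrom, start).

    The ``dmr_id`` column is (re)built as ``chrom_start_end``.
    """
    out = dmrs.copy()
    out = out.sort_values(["chrom", "start", "context"], kind="mergesort").reset_index(drop=True)
    out["dmr_id"] = (
        out["chrom"].astype(str)
        + "_"
        + out["start"].astype(np.int64).astype(str)
        + "_"
        + out["end"].astype(np.int64).astype(str)
    )
    out = out.rename(columns={"p_value": "p", "q_value": "q"})
    for col in _DMR_FILE_COLUMNS:
        if col not in out.columns:
            out[col] = pd.Series(dtype=float)
    out[_DMR_FILE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_dmrs(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    df = df.rename(columns={"p": "p_value", "q": "q_value"})
    return df[DMR_COLUMNS]


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------


def derive_expression_status(df: pd.DataFrame, config: PipelineConfig) -> pd.DataFrame:
    """Attach the up/down/ns status column from fold change and p-value.

    Fold change is a signed linear ratio: positive means higher in the test
    sample; ``up`` requires fold_change >= de_min_fold_change and
    p_value <= de_max_pvalue, ``down`` is symmetric, everything else is ns.
    """
    out = df.copy()
    fc = out["fold_change"].astype(float)
    p = out["p_value"].astype(float)
    status = np.where(
        (fc >= config.de_min_fold_change) & (p <= config.de_max_pvalue),
        "up",
        np.where((fc <= -config.de_min_fold_change) & (p <= config.de_max_pvalue), "down", "ns"),
    )
    out["status"] = status
    return out


def read_expression(path: str | Path, config: PipelineConfig | None = None) -> pd.DataFrame:
    config = config or PipelineConfig()
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "comparison": str})
    required = {"gene_id", "comparison", "fold_change", "p_value"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: expression table missing columns {sorted(missing)}")
    return derive_expression_status(df, config)


def write_expression(path: str | Path, df: pd.DataFrame) -> None:
    df[["gene_id", "comparison", "fold_change", "p_value"]].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# metaprofile
# ---------------------------------------------------------------------------

_PROFILE_COLUMNS = ["context", "segment", "bin_index", "density", "n_mC", "n_covered_C"]


def write_metaprofile(path: str | Path, profile: pd.DataFrame) -> None:
    profile[_PROFILE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_metaprofile(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")[_PROFILE_COLUMNS]
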