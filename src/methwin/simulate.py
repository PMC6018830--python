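"""Synthetic WGBS data with planted ground truth.

The generator builds, deterministically from a seed:

* a toy genome: chromosomes with non-overlapping genes and TEs placed
  uniformly, cytosine positions with a configurable context mix, and one
  control contig carrying cytosines but no features and no methylation
  (the unmethylated-control analogue used to measure conversion
  efficiency);
* a per-cytosine "true level" surface from a two-component beta mixture per
  context (a near-zero unmethylated component plus a methylated component
  whose default means are 0.93/0.89/0.38 for CG/CHG/CHH), modulated by
  feature effects: CG enrichment in gene bodies, CHH enrichment in 2-kb
  flanks, TE-body hypermethylation, and a depleted window around the TSS;
* a second-sample surface with planted differential windows on the
  window grid, recorded in a truth table with their realized (post-clip)
  differences;
* read counts per site (negative-binomial coverage, binomial methylated
  counts including bisulfite non-conversion);
* 24-nt smRNA loci enriched in planted hyper-CHH windows and gene flanks;
* an expression table whose up/down statuses are coupled to planted DMR
  classes by configurable probabilities.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .core import CONTEXTS, GenomeAnnotation
from .intervals import gene_region_bounds

logger = logging.getLogger(__name__)

__all__ = [
    "MethylomeParams",
    "SimulationTruth",
    "simulate_genome",
    "simulate_methylome",
    "plant_dmrs",
    "simulate_counts",
    "simulate_smrnas",
    "simulate_expression",
    "classify_genes_by_planted",
    "DEFAULT_EXPRESSION_RULES",
]

_H_BASES = np.array(list("ACT"))
_BASES = np.array(list("ACGT"))

POSITION_COLUMNS = ["chrom", "pos", "strand", "context", "trinucleotide"]

PLANTED_COLUMNS = [
    "chrom",
    "start",
    "end",
    "context",
    "direction",
    "target_diff",
    "realized_diff",
    "n_sites",
]


@dataclass
class MethylomeParams:
    """Beta-mixture and feature-effect parameters of the methylation surface.

    ``meth_mean``: mean of the methylated beta component per context.
    ``meth_weight``: baseline probability that a site belongs to the
    methylated component. Feature-specific weights replace the baseline
    inside gene bodies (CG), 2-kb flanks (CHH) and TE bodies (all contexts).
    The TSS window multiplies both the component weight and the drawn level
    by ``tss_depletion`` within ``tss_halfwidth`` bp of the gene start.
    """

    meth_mean: dict[str, float] = field(
        default_factory=lambda: {"CG": 0.93, "CHG": 0.89, "CHH": 0.38}
    )
    meth_concentration: dict[str, float] = field(
        default_factory=lambda: {"CG": 60.0, "CHG": 60.0, "CHH": 60.0}
    )
    meth_weight: dict[str, float] = field(
        default_factory=lambda: {"CG": 0.11, "CHG": 0.155, "CHH": 0.09}
    )
    unmeth_mean: float = 0.0025
    unmeth_concentration: float = 200.0
    gene_body_cg_weight: float = 0.6
    flank_chh_weight: float = 0.25
    te_weight: float = 0.7
    tss_depletion: float = 0.2
    tss_halfwidth: int = 150

    def validate(self) -> None:
        for name, mapping in (
            ("meth_mean", self.meth_mean),
            ("meth_weight", self.meth_weight),
        ):
            for ctx in CONTEXTS:
                v = mapping[ctx]
                if not (0.0 <= v <= 1.0):
                    raise ValueError(f"{name}[{ctx}] must lie in [0, 1], got {v!r}")
        for v, name in (
            (self.gene_body_cg_weight, "gene_body_cg_weight"),
            (self.flank_chh_weight, "flank_chh_weight"),
            (self.te_weight, "te_weight"),
            (self.tss_depletion, "tss_depletion"),
        ):
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v!r}")


@dataclass
class SimulationTruth:
    """Planted methylation surfaces plus the generating metadata."""

    seed: int
    positions: pd.DataFrame
    level_ref: np.ndarray
    control_contig: str
    chrom_lengths: dict[str, int]
    level_test: np.ndarray | None = None
    planted: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=PLANTED_COLUMNS))

    def __post_init__(self) -> None:
        if len(self.level_ref) != len(self.positions):
            raise ValueError("level_ref length must match positions")
        if np.any((self.level_ref < 0) | (self.level_ref > 1)):
            raise ValueError("true levels must lie in [0, 1]")
        ctrl = self.positions["chrom"].to_numpy() == self.control_contig
        if np.any(self.level_ref[ctrl] != 0.0):
            raise ValueError("control contig must be fully unmethylated")

    def save_json(self, path: str | Path) -> None:
        """Persist the truth table and metadata (not the per-site surfaces)."""
        payload = {
            "seed": self.seed,
            "control_contig": self.control_contig,
            "chrom_lengths": self.chrom_lengths,
            "n_sites": int(len(self.positions)),
            "planted_dmrs": self.planted.to_dict(orient="records"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------


def _place_nonoverlapping(
    rng: np.random.Generator,
    n: int,
    chrom_length: int,
    length_range: tuple[int, int],
    occupied: list[tuple[int, int]],
) -> list[tuple[int, int]]:
    """Greedily draw n non-overlapping intervals; raises if space runs out."""
    placed: list[tuple[int, int]] = []
    taken = sorted(occupied)
    attempts = 0
    max_attempts = 300 * max(n, 1)
    while len(placed) < n:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                f"could not place {n} non-overlapping features of length "
                f"{length_range} on a {chrom_length}-bp chromosome "
                f"({len(placed)} placed); lower the density"
            )
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        if length > chrom_length:
            continue
        start = int(rng.integers(1, chrom_length - length + 2))
        end = start + length - 1
        if any(s <= end and e >= start for s, e in taken):
            continue
        placed.append((start, end))
        taken.append((start, end))
    return placed


def _trinucleotides(rng: np.random.Generator, contexts: np.ndarray) -> np.ndarray:
    tri = np.empty(len(contexts), dtype=object)
    for ctx, mask in (
        ("CG", contexts == "CG"),
        ("CHG", contexts == "CHG"),
        ("CHH", contexts == "CHH"),
    ):
        n = int(mask.sum())
        if n == 0:
            continue
        if ctx == "CG":
            tri[mask] = np.char.add("CG", rng.choice(_BASES, n))
        elif ctx == "CHG":
            tri[mask] = np.char.add(np.char.add("C", rng.choice(_H_BASES, n)), "G")
        else:
            tri[mask] = np.char.add(
                np.char.add("C", rng.choice(_H_BASES, n)), rng.choice(_H_BASES, n)
            )
    return tri


def simulate_genome(
    config: PipelineConfig,
    n_chroms: int = 2,
    chrom_length: int = 1_000_000,
    gene_density: float = 100.0,
    te_density: float = 50.0,
    seed: int | None = None,
    cytosine_density: float = 0.2,
    context_mix: Sequence[float] = (0.25, 0.25, 0.50),
    gene_length_range: tuple[int, int] = (1500, 4500),
    te_length_range: tuple[int, int] = (500, 3000),
    control_length: int | None = None,
    control_contig: str = "ChrC",
) -> tuple[GenomeAnnotation, pd.DataFrame]:
    """Build the toy genome: annotations plus cytosine positions.

    ``gene_density``/``te_density`` are features per Mb; ``context_mix`` is
    the (CG, CHG, CHH) probability vector for cytosine contexts. The control
    contig gets cytosines but no features. Fully deterministic for a seed.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    mix = np.asarray(context_mix, dtype=float)
    if mix.shape != (3,) or not np.isclose(mix.sum(), 1.0) or np.any(mix < 0):
        raise ValueError("context_mix must be 3 non-negative probabilities summing to 1")

    chrom_lengths = {f"Chr{i + 1}": int(chrom_length) for i in range(n_chroms)}
    genes_rows, tes_rows = [], []
    gene_counter = te_counter = 0
    for chrom in list(chrom_lengths):
        n_genes = int(round(gene_density * chrom_length / 1e6))
        n_tes = int(round(te_density * chrom_length / 1e6))
        gene_iv = _place_nonoverlapping(rng, n_genes, chrom_length, gene_length_range, [])
        te_iv = _place_nonoverlapping(rng, n_tes, chrom_length, te_length_range, gene_iv)
        for start, end in sorted(gene_iv):
            gene_counter += 1
            strand = "+" if rng.random() < 0.5 else "-"
            genes_rows.append((f"g{gene_counter:05d}", chrom, start, end, strand))
        for start, end in sorted(te_iv):
            te_counter += 1
            tes_rows.append((f"te{te_counter:05d}", chrom, start, end, "TE"))

    if control_length is None:
        control_length = max(10_000, chrom_length // 10)
    chrom_lengths[control_contig] = int(control_length)

    pos_frames = []
    for chrom, length in chrom_lengths.items():
        n_sites = int(round(cytosine_density * length))
        n_sites = min(n_sites, length)
        positions = np.sort(rng.choice(length, size=n_sites, replace=False)) + 1
        contexts = rng.choice(np.array(CONTEXTS), size=n_sites, p=mix)
        strands = rng.choice(np.array(["+", "-"]), size=n_sites)
        pos_frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": positions.astype(np.int64),
                    "strand": strands,
                    "context": contexts,
                    "trinucleotide": _trinucleotides(rng, contexts),
                }
            )
        )
    positions = pd.concat(pos_frames, ignore_index=True)

    annotation = GenomeAnnotation(
        genes=pd.DataFrame(genes_rows, columns=["gene_id", "chrom", "start", "end", "strand"]),
        tes=pd.DataFrame(tes_rows, columns=["te_id", "chrom", "start", "end", "te_class"]),
        chrom_lengths=chrom_lengths,
    )
    logger.info(
        "simulated genome: %d chroms + control, %d genes, %d TEs, %d cytosines",
        n_chroms,
        len(annotation.genes),
        len(annotation.tes),
        len(positions),
    )
    return annotation, positions


# ---------------------------------------------------------------------------
# methylome surface
# ---------------------------------------------------------------------------


def _mark_ranges(
    positions: pd.DataFrame, features: pd.DataFrame, lo_col: str = "start", hi_col: str = "end"
) -> np.ndarray:
    """Boolean mask over positions lying inside any feature interval."""
    mask = np.zeros(len(positions), dtype=bool)
    pos = positions["pos"].to_numpy()
    chroms = positions["chrom"].to_numpy()
    for chrom, sub in features.groupby("chrom", sort=False):
        sel = np.flatnonzero(chroms == chrom)
        if len(sel) == 0:
            continue
        p = pos[sel]
        for lo, hi in zip(sub[lo_col].to_numpy(), sub[hi_col].to_numpy()):
            i = np.searchsorted(p, lo, side="left")
            j = np.searchsorted(p, hi, side="right")
            mask[sel[i:j]] = True
    return mask


def _flank_frames(genes: pd.DataFrame, flank: int) -> pd.DataFrame:
    rows = []
    for g in genes.itertuples(index=False):
        regions = gene_region_bounds(int(g.start), int(g.end), str(g.strand), flank)
        for loc in ("promoter", "downstream"):
            lo, hi = regions[loc]
            if lo <= hi:
                rows.append((g.chrom, lo, hi))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def _tss_frames(genes: pd.DataFrame, halfwidth: int) -> pd.DataFrame:
    rows = []
    for g in genes.itertuples(index=False):
        tss = int(g.end) if g.strand == "-" else int(g.start)
        rows.append((g.chrom, max(1, tss - halfwidth), tss + halfwidth))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def simulate_methylome(
    annotation: GenomeAnnotation,
    positions: pd.DataFrame,
    config: PipelineConfig,
    params: MethylomeParams | None = None,
    seed: int | None = None,
    control_contig: str = "ChrC",
) -> SimulationTruth:
    """Assign a true methylation level to every cytosine position."""
    params = params or MethylomeParams()
    params.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)

    contexts = positions["context"].to_numpy()
    n = len(positions)
    weight = np.empty(n, dtype=float)
    mean = np.empty(n, dtype=float)
    conc = np.empty(n, dtype=float)
    for ctx in CONTEXTS:
        m = contexts == ctx
        weight[m] = params.meth_weight[ctx]
        mean[m] = params.meth_mean[ctx]
        conc[m] = params.meth_concentration[ctx]

    in_body = _mark_ranges(positions, annotation.genes)
    in_flank = _mark_ranges(positions, _flank_frames(annotation.genes, config.flank_size))
    in_te = _mark_ranges(positions, annotation.tes)
    in_tss = _mark_ranges(positions, _tss_frames(annotation.genes, params.tss_halfwidth))

    weight = np.where(in_body & (contexts == "CG"), params.gene_body_cg_weight, weight)
    weight = np.where(in_flank & ~in_body & (contexts == "CHH"), params.flank_chh_weight, weight)
    weight = np.where(in_te, np.maximum(weight, params.te_weight), weight)
    weight = np.where(in_tss, weight * params.tss_depletion, weight)

    methylated = rng.random(n) < weight
    a_meth = mean * conc
    b_meth = (1.0 - mean) * conc
    a_un = params.unmeth_mean * params.unmeth_concentration
    b_un = (1.0 - params.unmeth_mean) * params.unmeth_concentration
    level = np.where(
        methylated,
        rng.beta(np.maximum(a_meth, 1e-6), np.maximum(b_meth, 1e-6)),
        rng.beta(max(a_un, 1e-6), max(b_un, 1e-6)),
    )
    level = np.where(in_tss, level * params.tss_depletion, level)

    ctrl = positions["chrom"].to_numpy() == control_contig
    level[ctrl] = 0.0
    level = np.clip(level, 0.0, 1.0)

    return SimulationTruth(
        seed=int(config.seed if seed is None else seed),
        positions=positions.reset_index(drop=True),
        level_ref=level,
        control_contig=control_contig,
        chrom_lengths=dict(annotation.chrom_lengths),
    )


# ---------------------------------------------------------------------------
# planted DMRs
# ---------------------------------------------------------------------------


def _window_grid(length: int, size: int, step: int) -> np.ndarray:
    if length < size:
        return np.empty(0, dtype=np.int64)
    return np.arange(1, length - size + 2, step, dtype=np.int64)


def _shift_for_target(old: np.ndarray, target: float, sign: int) -> np.ndarray:
    """Per-site shift magnitude whose clipped mean shift equals ``target``.

    Monotone bisection on s in [0, 1]: realized(s) = |mean(clip(old ± s)) -
    mean(old)| increases from 0 to the feasibility bound.
    """
    lo_s, hi_s = 0.0, 1.0
    for _ in range(40):
        mid = 0.5 * (lo_s + hi_s)
        realized = abs(np.mean(np.clip(old + sign * mid, 0.0, 1.0)) - np.mean(old))
        if realized < target:
            lo_s = mid
        else:
            hi_s = mid
    return np.clip(old + sign * hi_s, 0.0, 1.0)


def plant_dmrs(
    truth: SimulationTruth,
    config: PipelineConfig,
    n_dmrs: int,
    diff_range: tuple[float, float] = (40.0, 60.0),
    context_mix: Sequence[float] = (0.3, 0.2, 0.5),
    seed: int | None = None,
    min_sites_per_window: int | None = None,
    hyper_fraction: float = 0.5,
    annotation: GenomeAnnotation | None = None,
    prefer_features: bool = True,
) -> SimulationTruth:
    """Plant differential windows into a copy of the reference surface.

    Windows sit on the calling grid (start ≡ 1 mod window_step), never
    overlap each other, contain at least ``min_sites_per_window`` cytosines
    of the planted context, and are shifted so the realized mean difference
    over the window's context sites matches the drawn target (in percent
    points, |target| within ``diff_range``). When ``prefer_features`` is
    set and an annotation is supplied, CHH windows are drawn preferentially
    from 2-kb gene flanks (planted hyper) and CG windows from gene bodies
    (planted hypo), emulating the regulatory classes whose expression
    coupling is simulated downstream.
    """
    if min_sites_per_window is None:
        min_sites_per_window = config.min_cytosines_per_window
    rng = np.random.default_rng(truth.seed + 1 if seed is None else seed)
    mix = np.asarray(context_mix, dtype=float)
    if not np.isclose(mix.sum(), 1.0):
        raise ValueError("context_mix must sum to 1")
    lo_d, hi_d = diff_range
    if not (0 < lo_d <= hi_d <= 100):
        raise ValueError("diff_range must satisfy 0 < lo <= hi <= 100")
    if lo_d < config.min_meth_diff:
        raise ValueError(
            f"planted |diff| ({lo_d}) must be >= min_meth_diff ({config.min_meth_diff})"
        )

    level_test = truth.level_ref.copy()
    positions = truth.positions
    pos_arr = positions["pos"].to_numpy()
    chrom_arr = positions["chrom"].to_numpy()
    ctx_arr = positions["context"].to_numpy()

    # candidate windows per (chrom, context): counts and site-index slices
    candidates: dict[str, list[tuple[str, int, np.ndarray]]] = {c: [] for c in CONTEXTS}
    for chrom, length in truth.chrom_lengths.items():
        if chrom == truth.control_contig:
            continue
        starts = _window_grid(length, config.window_size, config.window_step)
        if len(starts) == 0:
            continue
        csel = chrom_arr == chrom
        for ctx in CONTEXTS:
            idx = np.flatnonzero(csel & (ctx_arr == ctx))
            p = pos_arr[idx]
            lo = np.searchsorted(p, starts, side="left")
            hi = np.searchsorted(p, starts + config.window_size - 1, side="right")
            ok = (hi - lo) >= min_sites_per_window
            for s, i, j in zip(starts[ok], lo[ok], hi[ok]):
                candidates[ctx].append((chrom, int(s), idx[i:j]))

    in_flank = in_body = None
    if prefer_features and annotation is not None and len(annotation.genes):
        flanks = _flank_frames(annotation.genes, config.flank_size)
        body = annotation.genes[["chrom", "start", "end"]]
        in_flank = {
            ctx: _candidate_feature_mask(candidates[ctx], flanks, config.window_size)
            for ctx in CONTEXTS
        }
        in_body = {
            ctx: _candidate_feature_mask(candidates[ctx], body, config.window_size)
            for ctx in CONTEXTS
        }

    taken: dict[str, list[tuple[int, int]]] = {}
    planted_rows = []
    n_ctx = rng.multinomial(n_dmrs, mix)
    for ctx, count in zip(CONTEXTS, n_ctx):
        cand = candidates[ctx]
        order = rng.permutation(len(cand))
        if in_flank is not None:
            # feature-preferred candidates first, shuffled within each block
            pref = in_flank[ctx] if ctx == "CHH" else (in_body[ctx] if ctx == "CG" else None)
            if pref is not None:
                order = np.concatenate([order[pref[order]], order[~pref[order]]])
        cursor = 0
        placed = 0
        while placed < count:
            if cursor >= len(order):
                raise ValueError(
                    f"insufficient eligible windows for context {ctx}: "
                    f"needed {count}, placed {placed}"
                )
            chrom, start, idx = cand[order[cursor]]
            cursor += 1
            end = start + config.window_size - 1
            if any(s <= end and e >= start for s, e in taken.get(chrom, [])):
                continue
            old = level_test[idx]
            mu = float(np.mean(old))
            want_hyper = rng.random() < hyper_fraction
            target = float(rng.uniform(lo_d, hi_d)) / 100.0
            feasible_hyper = (1.0 - mu) >= target + 0.02
            feasible_hypo = mu >= target + 0.02
            if want_hyper and not feasible_hyper:
                want_hyper = False
            if not want_hyper and not feasible_hypo:
                if feasible_hyper:
                    want_hyper = True
                else:
                    continue
            sign = 1 if want_hyper else -1
            new = _shift_for_target(old, target, sign)
            level_test[idx] = new
            realized = 100.0 * float(np.mean(new) - np.mean(old))
            taken.setdefault(chrom, []).append((start, end))
            planted_rows.append(
                (
                    chrom,
                    start,
                    end,
                    ctx,
                    "hyper" if want_hyper else "hypo",
                    sign * target * 100.0,
                    realized,
                    len(idx),
                )
            )
            placed += 1

    planted = pd.DataFrame(planted_rows, columns=PLANTED_COLUMNS)
    planted = planted.sort_values(["chrom", "start"]).reset_index(drop=True)
    out = SimulationTruth(
        seed=truth.seed,
        positions=positions,
        level_ref=truth.level_ref,
        control_contig=truth.control_contig,
        chrom_lengths=truth.chrom_lengths,
        level_test=level_test,
        planted=planted,
    )
    logger.info("planted %d DMR windows (%s)", len(planted), dict(zip(CONTEXTS, n_ctx)))
    return out


def _candidate_feature_mask(
    cand: list[tuple[str, int, np.ndarray]], features: pd.DataFrame, window_size: int
) -> np.ndarray:
    """True where a candidate window overlaps any feature interval."""
    mask = np.zeros(len(cand), dtype=bool)
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, sub in features.groupby("chrom", sort=False):
        starts = sub["start"].to_numpy()
        order = np.argsort(starts)
        by_chrom[chrom] = (starts[order], sub["end"].to_numpy()[order])
    for i, (chrom, start, _) in enumerate(cand):
        if chrom not in by_chrom:
            continue
        fs, fe = by_chrom[chrom]
        hi = np.searchsorted(fs, start + window_size - 1, side="right")
        mask[i] = bool(np.any(fe[:hi] >= start))
    return mask


# ---------------------------------------------------------------------------
# read counts
# ---------------------------------------------------------------------------


def simulate_counts(
    truth: SimulationTruth,
    config: PipelineConfig,
    coverage_mean: float = 30.0,
    dispersion: float | None = 20.0,
    seed: int | None = None,
    sample: str = "ref",
) -> pd.DataFrame:
    """Draw per-site read counts for one sample, returning a sites frame.

    Coverage is negative-binomial with the given mean and size parameter
    ``dispersion`` (variance = mean + mean²/dispersion); ``dispersion=None``
    gives Poisson coverage. The methylated count is binomial with success
    probability level + (1 − level) · nonconversion_rate, so the control
    contig's apparent methylation equals the non-conversion rate in
    expectation.
    """
    if coverage_mean <= 0:
        raise ValueError(f"coverage_mean must be positive, got {coverage_mean!r}")
    if sample not in ("ref", "test"):
        raise ValueError("sample must be 'ref' or 'test'")
    level = truth.level_ref if sample == "ref" else truth.level_test
    if level is None:
        raise ValueError("truth has no test surface; run plant_dmrs first")
    base_seed = truth.seed if seed is None else seed
    rng = np.random.default_rng([base_seed, 0 if sample == "ref" else 1, 7])

    n = len(truth.positions)
    if dispersion is None:
        coverage = rng.poisson(coverage_mean, size=n)
    else:
        if dispersion <= 0:
            raise ValueError("dispersion must be positive (or None for Poisson)")
        p_nb = dispersion / (dispersion + coverage_mean)
        coverage = rng.negative_binomial(dispersion, p_nb, size=n)
    success = level + (1.0 - level) * config.nonconversion_rate
    count_meth = rng.binomial(coverage, success)
    out = truth.positions.copy()
    out["count_meth"] = count_meth.astype(np.int64)
    out["count_unmeth"] = (coverage - count_meth).astype(np.int64)
    return out[["chrom", "pos", "strand", "count_meth", "count_unmeth", "context", "trinucleotide"]]


# ---------------------------------------------------------------------------
# smRNA loci
# ---------------------------------------------------------------------------


def simulate_smrnas(
    truth: SimulationTruth,
    annotation: GenomeAnnotation,
    config: PipelineConfig,
    n_smrnas: int = 500,
    seed: int | None = None,
    frac_planted_chh: float = 0.4,
    frac_flank: float = 0.3,
) -> pd.DataFrame:
    """24-nt loci enriched in planted hyper-CHH windows and gene flanks."""
    rng = np.random.default_rng((truth.seed + 3) if seed is None else seed)
    length = config.smrna_length
    hyper_chh = truth.planted[
        (truth.planted["context"] == "CHH") & (truth.planted["direction"] == "hyper")
    ]
    rows: list[tuple[str, int, int]] = []
    chroms = [c for c in truth.chrom_lengths if c != truth.control_contig]
    for _ in range(n_smrnas):
        u = rng.random()
        if u < frac_planted_chh and len(hyper_chh):
            w = hyper_chh.iloc[int(rng.integers(len(hyper_chh)))]
            start = int(rng.integers(w["start"], w["end"] - length + 2))
            rows.append((str(w["chrom"]), start, start + length - 1))
        elif u < frac_planted_chh + frac_flank and len(annotation.genes):
            g = annotation.genes.iloc[int(rng.integers(len(annotation.genes)))]
            side = "promoter" if rng.random() < 0.5 else "downstream"
            lo, hi = gene_region_bounds(int(g["start"]), int(g["end"]), str(g["strand"]), config.flank_size)[side]
            hi = min(hi, truth.chrom_lengths[str(g["chrom"])])
            if hi - lo + 1 < length:
                continue
            start = int(rng.integers(lo, hi - length + 2))
            rows.append((str(g["chrom"]), start, start + length - 1))
        else:
            chrom = chroms[int(rng.integers(len(chroms)))]
            start = int(rng.integers(1, truth.chrom_lengths[chrom] - length + 2))
            rows.append((chrom, start, start + length - 1))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


# ---------------------------------------------------------------------------
# expression coupling
# ---------------------------------------------------------------------------

# (context, location, direction) -> (P(up), P(down)); first match wins,
# in insertion order, when a gene carries several planted DMR classes.
DEFAULT_EXPRESSION_RULES: dict[tuple[str, str, str], tuple[float, float]] = {
    ("CHH", "promoter", "hyper"): (0.75, 0.25),
    ("CHH", "downstream", "hyper"): (0.75, 0.25),
    ("CG", "gene_body", "hypo"): (0.75, 0.25),
}


def classify_genes_by_planted(
    truth: SimulationTruth,
    annotation: GenomeAnnotation,
    config: PipelineConfig,
    rules: Mapping[tuple[str, str, str], tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Per-gene planted-DMR class: the first rule key whose window overlaps.

    Returns columns gene_id, rule_context, rule_location, rule_direction,
    has_planted (any planted window touching the gene's extended region).
    Genes matching no rule get empty rule fields.
    """
    rules = DEFAULT_EXPRESSION_RULES if rules is None else rules
    planted = truth.planted
    rows = []
    for g in annotation.genes.itertuples(index=False):
        regions = gene_region_bounds(int(g.start), int(g.end), str(g.strand), config.flank_size)
        sub = planted[planted["chrom"] == g.chrom]
        matched: tuple[str, str, str] | None = None
        has_planted = False
        overlaps_by_key = set()
        for w in sub.itertuples(index=False):
            for loc, (lo, hi) in regions.items():
                if lo <= hi and w.start <= hi and w.end >= lo:
                    has_planted = True
                    overlaps_by_key.add((w.context, loc, w.direction))
        for key in rules:
            if key in overlaps_by_key:
                matched = key
                break
        rows.append(
            (
                g.gene_id,
                matched[0] if matched else "",
                matched[1] if matched else "",
                matched[2] if matched else "",
                has_planted,
            )
        )
    return pd.DataFrame(
        rows, columns=["gene_id", "rule_context", "rule_location", "rule_direction", "has_planted"]
    )


def simulate_expression(
    truth: SimulationTruth,
    annotation: GenomeAnnotation,
    config: PipelineConfig,
    seed: int | None = None,
    rules: Mapping[tuple[str, str, str], tuple[float, float]] | None = None,
    comparison: str = "test_vs_ref",
    baseline_up: float = 0.15,
    baseline_down: float = 0.15,
) -> pd.DataFrame:
    """Expression table whose statuses are coupled to planted DMR classes.

    Genes matching an expression rule are drawn up/down with the rule's
    probabilities; genes touching a planted window but matching no rule use
    the baseline probabilities; genes with no planted window are null.
    Up/down records satisfy the differential-expression thresholds by
    construction; null records never do.
    """
    rules = DEFAULT_EXPRESSION_RULES if rules is None else rules
    for key, (p_up, p_down) in rules.items():
        if not (0.0 <= p_up <= 1.0 and 0.0 <= p_down <= 1.0 and p_up + p_down <= 1.0):
            raise ValueError(f"rule {key}: probabilities must lie in [0,1] with sum <= 1")
    if not (0.0 <= baseline_up <= 1.0 and 0.0 <= baseline_down <= 1.0):
        raise ValueError("baseline probabilities must lie in [0, 1]")

    rng = np.random.default_rng((truth.seed + 5) if seed is None else seed)
    classes = classify_genes_by_planted(truth, annotation, config, rules)
    rows = []
    for rec in classes.itertuples(index=False):
        if rec.rule_context:
            p_up, p_down = rules[(rec.rule_context, rec.rule_location, rec.rule_direction)]
        elif rec.has_planted:
            p_up, p_down = baseline_up, baseline_down
        else:
            p_up, p_down = 0.0, 0.0
        u = rng.random()
        if u < p_up:
            fc = float(rng.uniform(config.de_min_fold_change, 8 * config.de_min_fold_change))
            p = float(rng.uniform(1e-8, config.de_max_pvalue))
        elif u < p_up + p_down:
            fc = -float(rng.uniform(config.de_min_fold_change, 8 * config.de_min_fold_change))
            p = float(rng.uniform(1e-8, config.de_max_pvalue))
        else:
            sign = 1.0 if rng.random() < 0.5 else -1.0
            fc = sign * float(np.exp(rng.normal(0.0, 0.2)))
            fc = float(np.clip(fc, -0.95 * config.de_min_fold_change, 0.95 * config.de_min_fold_change))
            p = float(rng.uniform(0.0, 1.0))
        rows.append((rec.gene_id, comparison, fc, p))
    out = pd.DataFrame(rows, columns=["gene_id", "comparison", "fold_change", "p_value"])
    from .io import derive_expression_status

    return derive_expression_status(out, config)
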