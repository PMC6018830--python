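import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methwin.annotate import (
    associate_dmrs_with_genes,
    associate_dmrs_with_tes,
    associate_smrnas,
    crosstab_expression,
    gene_sets_body_vs_flank,
    te_gene_upregulation,
)
from methwin.config import PipelineConfig
from methwin.intervals import find_overlaps, gene_region_bounds, overlap_length
from methwin.io import derive_expression_status

# the session-scoped `cfg` fixture from conftest supplies default thresholds


def _genes(rows):
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])


def _dmrs(rows):
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "context", "status"])
    df["dmr_id"] = df["chrom"] + "_" + df["start"].astype(str) + "_" + df["end"].astype(str)
    df["n_cytosines"] = 6
    df["meth_test"] = 50.0
    df["meth_ref"] = 20.0
    df["diff"] = np.where(df["status"] == "hyper", 30.0, -30.0)
    df["p_value"] = 1e-9
    df["q_value"] = 1e-6
    return df


def _expr(rows, cfg):
    df = pd.DataFrame(rows, columns=["gene_id", "comparison", "fold_change", "p_value"])
    return derive_expression_status(df, cfg)


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------


def test_plus_strand_promoter(cfg):
    genes = _genes([("g1", "Ca1", 5001, 8000, "+")])
    dmrs = _dmrs([("Ca1", 3500, 3599, "CHH", "hyper")])
    assoc = associate_dmrs_with_genes(dmrs, genes, cfg)
    assert len(assoc) == 1
    assert assoc.iloc[0]["location"] == "promoter"
    assert assoc.iloc[0]["overlap_bp"] == 100


def test_gene_body(cfg):
    genes = _genes([("g1", "Ca1", 5001, 8000, "+")])
    dmrs = _dmrs([("Ca1", 6001, 6100, "CG", "hypo")])
    assoc = associate_dmrs_with_genes(dmrs, genes, cfg)
    assert list(assoc["location"]) == ["gene_body"]


def test_minus_strand_promoter_is_high_side(cfg):
    genes = _genes([("g1", "Ca1", 5001, 8000, "-")])
    dmrs = _dmrs([("Ca1", 9500, 9599, "CHH", "hyper")])
    assoc = associate_dmrs_with_genes(dmrs, genes, cfg)
    assert list(assoc["location"]) == ["promoter"]


def test_boundary_straddle_two_associations(cfg):
    genes = _genes([("g1", "Ca1", 5001, 8000, "+")])
    dmrs = _dmrs([("Ca1", 7951, 8050, "CG", "hyper")])
    assoc = associate_dmrs_with_genes(dmrs, genes, cfg)
    assert sorted(assoc["location"]) == ["downstream", "gene_body"]
    by_loc = assoc.set_index("location")["overlap_bp"]
    assert by_loc["gene_body"] == 50
    assert by_loc["downstream"] == 50


def test_out_of_reach_dmr_not_associated(cfg):
    genes = _genes([("g1", "Ca1", 5001, 8000, "+")])
    dmrs = _dmrs([("Ca1", 100, 199, "CG", "hyper")])  # >2 kb upstream
    assert len(associate_dmrs_with_genes(dmrs, genes, cfg)) == 0


@given(
    a_start=st.integers(1, 300),
    a_len=st.integers(1, 100),
    b_start=st.integers(1, 300),
    b_len=st.integers(1, 100),
)
@settings(max_examples=200, deadline=None)
def test_overlap_matches_per_base_oracle(a_start, a_len, b_start, b_len):
    a_end, b_end = a_start + a_len - 1, b_start + b_len - 1
    oracle = len(set(range(a_start, a_end + 1)) & set(range(b_start, b_end + 1)))
    assert overlap_length(a_start, a_end, b_start, b_end) == oracle


def test_find_overlaps_matches_bruteforce():
    rng = np.random.default_rng(4)
    a = pd.DataFrame(
        {
            "chrom": rng.choice(["c1", "c2"], 40),
            "start": rng.integers(1, 500, 40),
        }
    )
    a["end"] = a["start"] + rng.integers(0, 80, 40)
    b = pd.DataFrame(
        {
            "chrom": rng.choice(["c1", "c2"], 40),
            "start": rng.integers(1, 500, 40),
        }
    )
    b["end"] = b["start"] + rng.integers(0, 80, 40)
    got = find_overlaps(a, b)
    n_expected = sum(
        1
        for x in a.itertuples()
        for y in b.itertuples()
        if x.chrom == y.chrom and x.start <= y.end and x.end >= y.start
    )
    assert len(got) == n_expected
    assert (got["overlap_bp"] >= 1).all()


def test_gene_region_bounds_clip():
    regions = gene_region_bounds(500, 900, "+", 2000)
    assert regions["promoter"] == (1, 499)
    assert regions["gene_body"] == (500, 900)
    assert regions["downstream"] == (901, 2900)


# ---------------------------------------------------------------------------
# TE association
# ---------------------------------------------------------------------------


def _tes(rows):
    return pd.DataFrame(rows, columns=["te_id", "chrom", "start", "end", "te_class"])


def test_te_deduplicated_single_status(cfg):
    tes = _tes([("te1", "Ca1", 1000, 2000, "TE")])
    dmrs = _dmrs(
        [("Ca1", 1001, 1100, "CHH", "hyper"), ("Ca1", 1501, 1600, "CHH", "hyper")]
    )
    assoc = associate_dmrs_with_tes(dmrs, tes)
    assert len(assoc) == 1
    assert assoc.iloc[0]["context"] == "CHH"
    assert assoc.iloc[0]["status"] == "hyper"


def test_te_without_dmr_absent(cfg):
    tes = _tes([("te1", "Ca1", 1000, 2000, "TE")])
    dmrs = _dmrs([("Ca1", 5001, 5100, "CHH", "hyper")])
    assert len(associate_dmrs_with_tes(dmrs, tes)) == 0


def test_te_mixed_status(cfg):
    tes = _tes([("te1", "Ca1", 1000, 2000, "TE")])
    dmrs = _dmrs(
        [("Ca1", 1001, 1100, "CG", "hyper"), ("Ca1", 1501, 1600, "CG", "hypo")]
    )
    assoc = associate_dmrs_with_tes(dmrs, tes)
    assert list(assoc["status"]) == ["mixed"]


def test_te_counted_once_per_context(cfg):
    tes = _tes([("te1", "Ca1", 1000, 2000, "TE")])
    dmrs = _dmrs(
        [("Ca1", 1001, 1100, "CG", "hyper"), ("Ca1", 1501, 1600, "CHH", "hyper")]
    )
    assoc = associate_dmrs_with_tes(dmrs, tes)
    assert sorted(assoc["context"]) == ["CG", "CHH"]


# ---------------------------------------------------------------------------
# smRNA association
# ---------------------------------------------------------------------------


def _smrnas(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def test_smrna_inside_dmr_counted(cfg):
    smrnas = _smrnas([("Ca1", 1010, 1033)])
    dmrs = _dmrs([("Ca1", 1001, 1100, "CHH", "hyper")])
    out = associate_smrnas(smrnas, dmrs, pd.DataFrame(columns=["gene_id"]), cfg)
    assert out["fractions_by_context"]["CHH"]["fraction"] == 1.0
    assert out["fractions_by_context"]["CHH"]["by_status"]["hyper"] == 1.0


def test_smrna_no_overlap_no_division_error(cfg):
    smrnas = _smrnas([("Ca1", 50_000, 50_023)])
    dmrs = _dmrs([("Ca1", 1001, 1100, "CHH", "hyper")])
    out = associate_smrnas(smrnas, dmrs, pd.DataFrame(columns=["gene_id"]), cfg)
    assert out["n_associated_pairs"] == 0
    assert all(v["fraction"] == 0.0 for v in out["fractions_by_context"].values())


def test_smrna_two_contexts_counted_once_each(cfg):
    smrnas = _smrnas([("Ca1", 1090, 1113)])
    dmrs = _dmrs(
        [("Ca1", 1001, 1100, "CHH", "hyper"), ("Ca1", 1101, 1200, "CG", "hypo")]
    )
    out = associate_smrnas(smrnas, dmrs, pd.DataFrame(columns=["gene_id"]), cfg)
    fracs = out["fractions_by_context"]
    assert fracs["CHH"]["fraction"] == pytest.approx(0.5)
    assert fracs["CG"]["fraction"] == pytest.approx(0.5)
    total = sum(v["fraction"] for v in fracs.values())
    assert total == pytest.approx(1.0)


def test_smrna_region_distribution(cfg):
    genes = _genes([("g1", "Ca1", 5001, 8000, "+")])
    dmrs = _dmrs([("Ca1", 6001, 6100, "CG", "hypo")])
    assoc = associate_dmrs_with_genes(dmrs, genes, cfg)
    smrnas = _smrnas([("Ca1", 4000, 4023), ("Ca1", 6000, 6023), ("Ca1", 8500, 8523)])
    out = associate_smrnas(smrnas, dmrs, assoc, cfg, genes=genes)
    assert out["region_counts"] == {"promoter": 1, "gene_body": 1, "downstream": 1}


# ---------------------------------------------------------------------------
# expression crosstab
# ---------------------------------------------------------------------------


def test_crosstab_toy_fraction(cfg):
    """10 up-regulated of 16 up+down genes with body hypo-CG DMRs -> 0.625."""
    genes = _genes([(f"g{i}", "Ca1", 10_000 * i + 5001, 10_000 * i + 7000, "+") for i in range(20)])
    dmr_rows = [
        ("Ca1", 10_000 * i + 5501, 10_000 * i + 5600, "CG", "hypo") for i in range(20)
    ]
    dmrs = _dmrs(dmr_rows)
    assoc = associate_dmrs_with_genes(dmrs, genes, cfg)
    expr_rows = []
    for i in range(20):
        if i < 10:
            expr_rows.append((f"g{i}", "c1", 4.0, 0.01))  # up
        elif i < 16:
            expr_rows.append((f"g{i}", "c1", -4.0, 0.01))  # down
        else:
            expr_rows.append((f"g{i}", "c1", 1.0, 0.9))  # ns
    out = crosstab_expression(assoc, _expr(expr_rows, cfg), cfg)
    panel = out["c1"]["panels"]["CG_gene_body_hypo"]
    assert panel["n_up"] == 10
    assert panel["n_down"] == 6
    assert panel["frac_up"] == pytest.approx(0.625)
    assert panel["frac_down"] == pytest.approx(0.375)
    assert out["c1"]["n_de_dmr_associated_genes"] == 16


def test_crosstab_empty_expression(cfg):
    genes = _genes([("g1", "Ca1", 5001, 8000, "+")])
    dmrs = _dmrs([("Ca1", 6001, 6100, "CG", "hypo")])
    assoc = associate_dmrs_with_genes(dmrs, genes, cfg)
    out = crosstab_expression(assoc, _expr([], cfg), cfg)
    assert out == {}


def test_crosstab_gene_in_two_panels(cfg):
    genes = _genes([("g1", "Ca1", 5001, 8000, "+")])
    dmrs = _dmrs(
        [("Ca1", 6001, 6100, "CG", "hypo"), ("Ca1", 3500, 3599, "CHH", "hyper")]
    )
    assoc = associate_dmrs_with_genes(dmrs, genes, cfg)
    expr = _expr([("g1", "c1", 4.0, 0.01)], cfg)
    out = crosstab_expression(assoc, expr, cfg)
    assert out["c1"]["panels"]["CG_gene_body_hypo"]["n_up"] == 1
    assert out["c1"]["panels"]["CHH_flanking_hyper"]["n_up"] == 1


def test_crosstab_missing_gene_counted_ns(cfg, caplog):
    genes = _genes([("g1", "Ca1", 5001, 8000, "+")])
    dmrs = _dmrs([("Ca1", 6001, 6100, "CG", "hypo")])
    assoc = associate_dmrs_with_genes(dmrs, genes, cfg)
    expr = _expr([("other", "c1", 4.0, 0.01)], cfg)
    with caplog.at_level("WARNING"):
        out = crosstab_expression(assoc, expr, cfg)
    assert out["c1"]["n_de_dmr_associated_genes"] == 0
    assert any("absent from expression" in r.message for r in caplog.records)


def test_crosstab_fraction_complement(dmr_run, cfg):
    """Where both up and down fractions are defined they sum to 1."""
    from methwin.simulate import simulate_expression

    truth = dmr_run["truth"]
    annotation = dmr_run["annotation"]
    expr = simulate_expression(truth, annotation, cfg, seed=77)
    assoc = associate_dmrs_with_genes(dmr_run["dmrs"], annotation.genes, cfg)
    out = crosstab_expression(assoc, expr, cfg)
    for comp in out.values():
        for panel in comp["panels"].values():
            if panel["n_up"] + panel["n_down"] > 0:
                assert panel["frac_up"] + panel["frac_down"] == pytest.approx(1.0)
                assert 0.0 <= panel["frac_up"] <= 1.0


# ---------------------------------------------------------------------------
# gene sets and TE-coupled up-regulation
# ---------------------------------------------------------------------------


def test_gene_sets_cg_body_only(cfg):
    genes = _genes([("g1", "Ca1", 5001, 8000, "+")])
    dmrs = _dmrs([("Ca1", 6001, 6100, "CG", "hypo")])
    assoc = associate_dmrs_with_genes(dmrs, genes, cfg)
    sets = gene_sets_body_vs_flank(assoc)
    assert sets["CG_body_only"] == {"g1"}
    assert sets["CHH_flank_only"] == set()
    assert sets["both"] == set()


def test_gene_sets_both(cfg):
    genes = _genes([("g1", "Ca1", 5001, 8000, "+")])
    dmrs = _dmrs(
        [("Ca1", 6001, 6100, "CG", "hypo"), ("Ca1", 3500, 3599, "CHH", "hyper")]
    )
    assoc = associate_dmrs_with_genes(dmrs, genes, cfg)
    sets = gene_sets_body_vs_flank(assoc)
    assert sets["both"] == {"g1"}
    assert sets["CG_body_only"] == set()
    assert sets["CHH_flank_only"] == set()


def test_gene_sets_empty(cfg):
    sets = gene_sets_body_vs_flank(pd.DataFrame(columns=["gene_id", "context", "location"]))
    assert sets == {"CG_body_only": set(), "CHH_flank_only": set(), "both": set()}


def test_te_upregulation_counts(cfg):
    genes = _genes([("g1", "Ca1", 5001, 8000, "+"), ("g2", "Ca1", 50_001, 53_000, "+")])
    te_assoc = pd.DataFrame(
        [
            ("te1", "Ca1", 8100, 8500, "CHH", "hyper"),  # in g1 downstream flank
            ("te2", "Ca1", 40_000, 40_500, "CHH", "hyper"),  # out of reach of both
        ],
        columns=["te_id", "chrom", "start", "end", "context", "status"],
    )
    expr = _expr([("g1", "c1", 4.0, 0.01), ("g2", "c1", 4.0, 0.01)], cfg)
    out = te_gene_upregulation(te_assoc, genes, expr, cfg)
    assert out["c1"] == {"hyper": 1, "hypo": 0}


def test_te_upregulation_down_gene_excluded(cfg):
    genes = _genes([("g1", "Ca1", 5001, 8000, "+")])
    te_assoc = pd.DataFrame(
        [("te1", "Ca1", 8100, 8500, "CHH", "hyper")],
        columns=["te_id", "chrom", "start", "end", "context", "status"],
    )
    expr = _expr([("g1", "c1", -4.0, 0.01)], cfg)
    out = te_gene_upregulation(te_assoc, genes, expr, cfg)
    assert out["c1"] == {"hyper": 0, "hypo": 0}
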