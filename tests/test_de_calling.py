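import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from tzsig import DEConfig, gate_expression, call_de, heatmap_matrix, ddct_fold_change
from tzsig.io_formats import FormatError
from conftest import make_expression


def tumor_samples(n_s, n_r):
    return ([(f"S{i}", "tumor", "TzS", None) for i in range(n_s)]
            + [(f"R{i}", "tumor", "TzR", None) for i in range(n_r)])


def paired_samples(n_pairs):
    return ([(f"s{i}", "cellline", "TzS", f"p{i}") for i in range(n_pairs)]
            + [(f"r{i}", "cellline", "TzR", f"p{i}") for i in range(n_pairs)])


# -- gate --------------------------------------------------------------------

@pytest.mark.parametrize("biotype,tzs,tzr,expected", [
    # every TzS sample >= 1.0 is enough, even with TzR near zero
    ("mRNA", [1.2, 1.0, 3.0], [0.1, 0.2], True),
    # no group uniformly above threshold
    ("mRNA", [0.9, 5.0], [0.9, 5.0], False),
    # lincRNA boundary is inclusive at 0.25
    ("lincRNA", [0.0, 0.0], [0.25, 0.25], True),
])
def test_gate_group_rule(biotype, tzs, tzr, expected):
    samples = tumor_samples(len(tzs), len(tzr))
    m = make_expression({"g": (biotype, tzs + tzr)}, samples)
    gate = gate_expression(m, DEConfig(), "TzR", "TzS")
    assert bool(gate["g"]) is expected


def test_gate_unknown_condition_rejected():
    m = make_expression({"g": ("mRNA", [1.0, 1.0])}, tumor_samples(1, 1))
    with pytest.raises(FormatError, match="unknown condition"):
        gate_expression(m, DEConfig(), "TzR", "nope")


def test_gate_monotone_in_thresholds(rng):
    values = rng.lognormal(0.0, 1.5, size=(60, 5))
    genes = {f"g{i}": ("mRNA" if i % 3 else "lincRNA", list(values[i]))
             for i in range(60)}
    m = make_expression(genes, tumor_samples(3, 2))
    loose = gate_expression(m, DEConfig(fpkm_min_mrna=0.5, fpkm_min_lincrna=0.1),
                            "TzR", "TzS")
    tight = gate_expression(m, DEConfig(fpkm_min_mrna=2.0, fpkm_min_lincrna=0.5),
                            "TzR", "TzS")
    assert not (tight & ~loose).any()  # raising thresholds never adds a gene


# -- differential calling ----------------------------------------------------

def test_fold_change_boundary_inclusive():
    # means 4.0 vs 2.0 with pseudocount 0 -> FC exactly 2.0 -> up
    m = make_expression({"g": ("mRNA", [2.0, 2.0, 4.0, 4.0])}, tumor_samples(2, 2))
    de = call_de(m, DEConfig(pseudocount=0.0), "TzR", "TzS").set_index("gene_id")
    assert de.loc["g", "fold_change"] == 2.0
    assert bool(de.loc["g", "is_differential"])
    assert de.loc["g", "direction"] == "up"


def test_tumor_mode_has_no_p_value():
    m = make_expression({"g": ("mRNA", [1.0, 1.0, 4.1, 4.1])}, tumor_samples(2, 2))
    de = call_de(m, DEConfig(), "TzR", "TzS").set_index("gene_id")
    assert np.isnan(de.loc["g", "p_value"])
    assert bool(de.loc["g", "is_differential"])  # fold-change-only rule


def test_identical_pairs_give_p_one_not_differential():
    m = make_expression({"g": ("mRNA", [3.0, 5.0, 7.0, 3.0, 5.0, 7.0])},
                        paired_samples(3))
    de = call_de(m, DEConfig(use_paired_test=True), "TzR", "TzS").set_index("gene_id")
    assert de.loc["g", "p_value"] == 1.0
    assert not bool(de.loc["g", "is_differential"])


def test_paired_t_matches_frozen_closed_form():
    # log2 differences exactly [1.0, 1.1, 0.9]:
    # t = 1.0 / (0.1/sqrt(3)), df = 2; two-sided p frozen from the
    # regularized-incomplete-beta form of the t CDF.
    tzs = [1.0, 1.0, 1.0]
    tzr = [2.0 ** 1.0, 2.0 ** 1.1, 2.0 ** 0.9]
    m = make_expression({"g": ("mRNA", tzs + tzr)}, paired_samples(3))
    de = call_de(m, DEConfig(use_paired_test=True, pseudocount=0.0),
                 "TzR", "TzS").set_index("gene_id")
    assert de.loc["g", "p_value"] == pytest.approx(0.003316758722356861, abs=1e-10)


def test_cellline_mode_requires_significance():
    # clear 4x fold change but wildly inconsistent pairs -> p too large
    m = make_expression({"g": ("mRNA", [1.0, 1.0, 1.0, 64.0, 0.9, 1.1])},
                        paired_samples(3))
    cfg = DEConfig(use_paired_test=True)
    de = call_de(m, cfg, "TzR", "TzS").set_index("gene_id")
    assert de.loc["g", "fold_change"] > 2.0
    assert de.loc["g", "p_value"] > cfg.alpha
    assert not bool(de.loc["g", "is_differential"])
    assert de.loc["g", "direction"] == "none"


def test_too_few_pairs_rejected():
    m = make_expression({"g": ("mRNA", [1.0, 2.0])}, paired_samples(1))
    with pytest.raises(FormatError, match="2 pairs"):
        call_de(m, DEConfig(use_paired_test=True), "TzR", "TzS")


def test_swapping_conditions_inverts_fold_change(rng):
    values = rng.lognormal(1.0, 1.0, size=(40, 6))
    genes = {f"g{i}": ("mRNA", list(values[i])) for i in range(40)}
    m = make_expression(genes, paired_samples(3))
    cfg = DEConfig(use_paired_test=True, pseudocount=0.0)
    fwd = call_de(m, cfg, "TzR", "TzS").set_index("gene_id")
    rev = call_de(m, cfg, "TzS", "TzR").set_index("gene_id")
    np.testing.assert_allclose(fwd["fold_change"], 1.0 / rev["fold_change"],
                               rtol=1e-12)
    np.testing.assert_allclose(fwd["p_value"], rev["p_value"], rtol=1e-12)
    up, down = fwd["direction"] == "up", rev["direction"] == "down"
    assert (up == down).all()


def test_de_monotone_in_fold_change_threshold(rng):
    values = rng.lognormal(1.5, 1.0, size=(80, 5))
    genes = {f"g{i}": ("mRNA", list(values[i])) for i in range(80)}
    m = make_expression(genes, tumor_samples(3, 2))
    loose = call_de(m, DEConfig(fc_up=1.5), "TzR", "TzS")["is_differential"]
    tight = call_de(m, DEConfig(fc_up=3.0), "TzR", "TzS")["is_differential"]
    assert not (tight & ~loose).any()


def test_bh_option_never_adds_calls(rng):
    values = rng.lognormal(1.5, 0.8, size=(100, 6))
    genes = {f"g{i}": ("mRNA", list(values[i])) for i in range(100)}
    m = make_expression(genes, paired_samples(3))
    plain = call_de(m, DEConfig(use_paired_test=True), "TzR", "TzS")
    bh = call_de(m, DEConfig(use_paired_test=True, fdr_bh=True), "TzR", "TzS")
    assert set(bh.loc[bh.is_differential, "gene_id"]) <= \
           set(plain.loc[plain.is_differential, "gene_id"])


# -- heatmap -----------------------------------------------------------------

def test_heatmap_row_standardization():
    m = make_expression({"g": ("mRNA", [1.0, 3.0, 7.0])},
                        tumor_samples(2, 1))
    de = pd.DataFrame({"gene_id": ["g"], "is_differential": [True]})
    z = heatmap_matrix(m, de, pseudocount=1.0)
    np.testing.assert_allclose(z.loc["g"].to_numpy(), [-1.0, 0.0, 1.0])


def test_heatmap_constant_row_maps_to_zeros():
    m = make_expression({"g": ("mRNA", [2.0, 2.0, 2.0])}, tumor_samples(2, 1))
    de = pd.DataFrame({"gene_id": ["g"], "is_differential": [True]})
    z = heatmap_matrix(m, de)
    assert (z.loc["g"] == 0.0).all()


def test_heatmap_rows_have_zero_mean_unit_sd(rng):
    values = rng.lognormal(2.0, 1.0, size=(30, 7))
    genes = {f"g{i}": ("mRNA", list(values[i])) for i in range(30)}
    m = make_expression(genes, tumor_samples(4, 3))
    de = pd.DataFrame({"gene_id": list(genes), "is_differential": True})
    z = heatmap_matrix(m, de)
    np.testing.assert_allclose(z.mean(axis=1), 0.0, atol=1e-12)
    np.testing.assert_allclose(z.std(axis=1, ddof=1), 1.0, rtol=1e-12)


# -- qPCR --------------------------------------------------------------------

@pytest.mark.parametrize("cts,expected", [
    ((25, 20, 25, 20), 1.0),
    ((24, 20, 25, 20), 2.0),
    ((26, 20, 25, 20), 0.5),
])
def test_ddct_fold_change(cts, expected):
    assert ddct_fold_change(*cts) == expected


@given(st.floats(-5, 5), st.floats(-5, 5))
def test_ddct_reference_gene_cancels(delta, shift):
    # shifting every Ct by the same amount leaves the ratio unchanged
    base = ddct_fold_change(25 + delta, 20, 25, 20)
    shifted = ddct_fold_change(25 + delta + shift, 20 + shift,
                               25 + shift, 20 + shift)
    assert base == pytest.approx(shifted, rel=1e-9)
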