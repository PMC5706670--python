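"""FPKM, Spearman correlation, and marker-panel classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ctcseq.alignments import AlignedReadRecord
from ctcseq.expression import (
    ExpressionError,
    ExpressionMatrix,
    MarkerPanelConfig,
    classify_cell,
    compute_fpkm,
    correlation_matrix,
    count_fragments,
    pool_bulk_profile,
    spearman,
)


def _rec(read_id, gene, cell="c1", mate=1):
    return AlignedReadRecord(read_id, cell, gene, 0, (("M", 10),), mate, "A" * 10)


def test_mate_pair_counts_once():
    counts = count_fragments([_rec("f1", "G", mate=1), _rec("f1", "G", mate=2)], ["G"])
    assert counts.loc["G", "c1"] == 1


def test_unmated_read_counts_once_and_additivity():
    recs = [_rec(f"a{i}", "G1") for i in range(10)] + [_rec(f"b{i}", "G2") for i in range(5)]
    counts = count_fragments(recs, ["G1", "G2"])
    assert counts["c1"].tolist() == [10, 5]


def test_unknown_gene_is_error():
    with pytest.raises(ExpressionError):
        count_fragments([_rec("f1", "GX")], ["G1"])


def test_zero_records_give_all_zero_matrix():
    counts = count_fragments([], ["G1", "G2"], cell_ids=["c1"])
    assert (counts.values == 0).all()


@pytest.mark.parametrize(
    "count,length,total,expected",
    [(1, 1000, 10**6, 1.0), (10, 500, 10**6, 20.0), (0, 800, 10**6, 0.0)],
)
def test_fpkm_unit_definition(count, length, total, expected):
    counts = pd.DataFrame({"c": [count]}, index=["G"])
    fpkm = compute_fpkm(counts, {"G": length}, {"c": total})
    assert fpkm.loc["G", "c"] == pytest.approx(expected)


def test_fpkm_invariant_to_fragment_duplication():
    counts = pd.DataFrame({"c": [3, 7]}, index=["G1", "G2"])
    lengths = {"G1": 1500, "G2": 700}
    f1 = compute_fpkm(counts, lengths, counts.sum(axis=0))
    f2 = compute_fpkm(2 * counts, lengths, 2 * counts.sum(axis=0))
    assert np.allclose(f1.values, f2.values)


def test_zero_total_names_cell():
    counts = pd.DataFrame({"empty": [0]}, index=["G"])
    with pytest.raises(ExpressionError, match="empty"):
        compute_fpkm(counts, {"G": 100}, {"empty": 0})


# ----------------------------------------------------------------- spearman

def test_spearman_perfect_antitone_and_identity():
    assert spearman([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)
    assert spearman([1.0, 5.0, 9.0], [1.0, 5.0, 9.0]) == pytest.approx(1.0)


def test_spearman_with_ties_matches_rank_then_pearson_oracle():
    # ranks x = (1, 2.5, 2.5, 4), y = (1, 3, 2, 4) -> r = 4.5 / sqrt(4.5 * 5)
    assert spearman([1, 2, 2, 4], [1, 3, 2, 4]) == pytest.approx(0.9486833, abs=1e-6)


def test_spearman_zero_variance_flagged_missing():
    assert np.isnan(spearman([1, 1, 1], [1, 2, 3]))


@given(
    st.lists(st.integers(-50, 50), min_size=4, max_size=12, unique=True),
    st.sampled_from(["exp", "cube", "affine"]),
)
def test_spearman_invariant_under_strictly_monotone_transforms(xs, kind):
    rng = np.random.default_rng(abs(hash(tuple(xs))) % 2**31)
    ys = rng.permutation(len(xs)).astype(float)
    x = np.array(xs)
    fx = {"exp": np.exp(x / 25), "cube": x**3, "affine": 3 * x + 2}[kind]
    r0, r1 = spearman(x, ys), spearman(fx, ys)
    if np.isnan(r0):
        assert np.isnan(r1)
    else:
        assert r0 == pytest.approx(r1, abs=1e-12)


def test_correlation_matrix_matches_pairwise_oracle():
    fpkm = pd.DataFrame(
        {"c1": [1.0, 5.0, 2.0, 9.0], "c2": [2.0, 1.0, 7.0, 4.0], "c3": [1.0, 1.0, 2.0, 2.0]},
        index=["g1", "g2", "g3", "g4"],
    )
    expr = ExpressionMatrix.from_counts(
        (fpkm * 10).astype(int), {g: 1000 for g in fpkm.index}
    )
    corr = correlation_matrix(expr)
    log = expr.log_fpkm()
    for a in fpkm.columns:
        for b in fpkm.columns:
            if a == b:
                assert corr.loc[a, b] == 1.0
            else:
                assert corr.loc[a, b] == pytest.approx(spearman(log[a], log[b]), abs=1e-12)


def test_duplicated_profiles_have_unit_correlation_zero_sd():
    fpkm = pd.DataFrame({"c1": [1.0, 4.0, 2.0], "c2": [1.0, 4.0, 2.0]}, index=list("abc"))
    corr = correlation_matrix(np.log2(fpkm + 1))
    assert corr.loc["c1", "c2"] == pytest.approx(1.0)


def test_bulk_pooling_sums_fragments_before_normalizing():
    counts = pd.DataFrame({"c1": [10, 0], "c2": [0, 10]}, index=["G1", "G2"])
    bulk = pool_bulk_profile(counts, ["c1", "c2"], {"G1": 1000, "G2": 1000}, "b")
    assert bulk.loc["G1", "b"] == bulk.loc["G2", "b"] > 0


# ------------------------------------------------------------ classification

PANEL = MarkerPanelConfig()


@pytest.mark.parametrize(
    "fpkm,expected",
    [
        ({"EPCAM": 50, "KRT7": 30, "KRT8": 100, "CD45": 0}, "epithelial"),
        ({"EPCAM": 0, "KRT7": 0, "KRT8": 0, "CD45": 40}, "leukocyte"),
        ({"EPCAM": 50, "KRT7": 0, "KRT8": 0, "CD45": 40}, "atypical"),
        ({"EPCAM": 50, "KRT7": 30, "KRT8": 0, "CD45": 0.5}, "epithelial"),  # 2-of-3
        ({"EPCAM": 0.2, "KRT7": 0, "KRT8": 0, "CD45": 0.4}, "atypical"),
    ],
)
def test_marker_panel_rule(fpkm, expected):
    assert classify_cell(fpkm, PANEL) == expected


def test_missing_marker_gene_is_configuration_error():
    with pytest.raises(ExpressionError, match="CD45"):
        classify_cell({"EPCAM": 1.0, "KRT7": 1.0, "KRT8": 1.0}, PANEL)


def test_marker_sets_must_be_disjoint_and_nonempty():
    with pytest.raises(ExpressionError):
        MarkerPanelConfig(epithelial_genes=frozenset({"A"}), leukocyte_genes=frozenset({"A"}))
    with pytest.raises(ExpressionError):
        MarkerPanelConfig(epithelial_genes=frozenset(), leukocyte_genes=frozenset({"B"}))
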