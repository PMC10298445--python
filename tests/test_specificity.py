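"""The specificity caller, binning, Z-scores, and clustering order.

The caller is checked against a naive per-gene, per-tissue double loop;
clustering is checked against a from-scratch agglomerative complete-linkage
implementation (cluster-partition sequence, which is orientation-free).
"""

import logging

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist

from tissuespec.specificity import (
    BIN_LABELS,
    CallerConfig,
    bin_by_level,
    bin_share,
    call_tissue_specific,
    cluster_order,
    expression_bin,
    filter_undetected,
    row_zscore,
)
from tissuespec.synthetic_data import gen_expression_matrix

from conftest import make_matrix


def naive_caller(matrix, config):
    """Oracle: explicit double loop over genes × tissues."""
    out = {}
    for g in matrix.gene_ids:
        row = matrix.data.loc[g]
        if row.max() < config.detection_threshold:
            continue
        for t in matrix.tissue_labels:
            others = row.drop(t)
            low_ok = (others < config.low_threshold).all()
            if config.strict_zero:
                low_ok = low_ok and (others > 0).all()
            if row[t] > config.high_threshold and low_ok:
                out[g] = t
    return out


# ---------------------------------------------------------------- caller

def test_single_high_tissue_is_called():
    m = make_matrix([[150, 0, 0]], tissues=["flower", "leaf", "root"])
    (call,) = call_tissue_specific(m)
    assert call.target_tissue == "flower"
    assert call.target_fpkm == 150
    assert call.max_off_target_fpkm == 0
    assert call.bin_label == "100–500"


def test_threshold_boundaries_are_strict():
    # target must exceed 100 strictly
    assert call_tissue_specific(make_matrix([[100.0, 0]])) == []
    # off-target must stay strictly below 10
    assert call_tissue_specific(make_matrix([[150.0, 10.0]])) == []
    assert len(call_tissue_specific(make_matrix([[150.0, 9.99]]))) == 1


def test_two_high_tissues_disqualify():
    assert call_tissue_specific(make_matrix([[150, 200, 0]])) == []


def test_silent_off_target_allowed_unless_strict_zero():
    m = make_matrix([[150, 0, 3]])
    assert len(call_tissue_specific(m)) == 1
    assert call_tissue_specific(m, CallerConfig(strict_zero=True)) == []


def test_detection_filter_boundary_and_partition(toy_matrix):
    detected, undetected = filter_undetected(toy_matrix)
    assert undetected == ["faint"]
    assert detected.gene_ids == ["spec", "flat", "near_miss"]
    # value exactly at the detection threshold counts as detected
    at = make_matrix([[1.0, 0.0], [0.99, 0.5]])
    det, undet = filter_undetected(at)
    assert det.gene_ids == ["g0"] and undet == ["g1"]


def test_output_sorted_by_tissue_then_descending_fpkm():
    m = make_matrix(
        [[150, 0], [900, 0], [0, 400]],
        genes=["a", "b", "c"], tissues=["flower", "seed"],
    )
    calls = call_tissue_specific(m)
    assert [(c.target_tissue, c.gene_id) for c in calls] == [
        ("flower", "b"), ("flower", "a"), ("seed", "c"),
    ]


@given(
    st.integers(0, 2**31 - 1),
    st.integers(1, 50),
    st.integers(2, 9),
)
def test_caller_equivalent_to_double_loop(seed, n_genes, n_tissues):
    rng = np.random.default_rng(seed)
    # mixture spanning all decision regions (0, ~1, ~10, ~100, >100)
    vals = rng.choice(
        [0.0, 0.5, 1.0, 5.0, 9.9, 10.0, 50.0, 100.0, 150.0, 5000.0],
        size=(n_genes, n_tissues),
    ) * rng.uniform(0.9, 1.1, size=(n_genes, n_tissues))
    m = make_matrix(vals)
    config = CallerConfig()
    got = {c.gene_id: c.target_tissue for c in call_tissue_specific(m, config)}
    assert got == naive_caller(m, config)


def test_partition_and_monotonicity():
    m, _ = gen_expression_matrix(500, ["a", "b", "c"], {"a": 7, "b": 5}, 20, seed=3)
    config = CallerConfig()
    detected, undetected = filter_undetected(m, config)
    calls = call_tissue_specific(m, config)
    non_called = detected.shape[0] - len(calls)
    assert len(calls) + non_called + len(undetected) == m.shape[0]

    base = {c.gene_id for c in calls}
    harder_high = {c.gene_id for c in call_tissue_specific(m, CallerConfig(high_threshold=200))}
    harder_low = {c.gene_id for c in call_tissue_specific(m, CallerConfig(low_threshold=5))}
    assert harder_high <= base
    assert harder_low <= base


def test_planted_truth_recovered_exactly():
    m, truth = gen_expression_matrix(
        1000, list("abcdefghi"), {"a": 10, "d": 15, "i": 12}, 100, seed=42
    )
    got = {c.gene_id: c.target_tissue for c in call_tissue_specific(m)}
    assert got == truth.planted_specific  # precision = recall = 1
    _, undetected = filter_undetected(m)
    assert set(undetected) == truth.planted_undetected


# ---------------------------------------------------------------- binning

@pytest.mark.parametrize(
    "fpkm,label",
    [
        (100.5, "100–500"),
        (499.999, "100–500"),
        (500.0, "500–1000"),  # boundary goes to the upper bin
        (1000.0, "1000–5000"),
        (4999.0, "1000–5000"),
        (5000.0, ">5000"),
        (20000.0, ">5000"),
    ],
)
def test_half_open_bin_convention(fpkm, label):
    assert expression_bin(fpkm) == label


def test_bin_rejects_sub_threshold_fpkm():
    with pytest.raises(ValueError):
        expression_bin(99.0)


def test_bin_counts_conserve_calls():
    m, _ = gen_expression_matrix(800, list("abcde"), {"a": 20, "c": 9}, 0, seed=11)
    calls = call_tissue_specific(m)
    table = bin_by_level(calls)
    assert list(table.columns) == list(BIN_LABELS)
    assert table.to_numpy().sum() == len(calls)
    for tissue in table.index:
        assert table.loc[tissue].sum() == sum(
            c.target_tissue == tissue for c in calls
        )


def test_bin_share_arithmetic():
    assert bin_share({"a": 1, "b": 1}, 4) == 50.0
    with pytest.raises(ValueError):
        bin_share({"a": 1}, 0)


# ---------------------------------------------------------------- z-scores

def test_row_zscore_hand_computed():
    z = row_zscore(make_matrix([[1, 2, 3]]))
    assert np.allclose(z.to_numpy(), [[-1, 0, 1]])  # sample sd = 1


def test_constant_row_maps_to_zero_with_warning(caplog):
    with caplog.at_level(logging.WARNING, logger="tissuespec.specificity"):
        z = row_zscore(make_matrix([[5, 5, 5]]))
    assert np.allclose(z.to_numpy(), 0)
    assert any("constant" in r.message for r in caplog.records)


@given(st.lists(st.floats(0, 1e4, allow_nan=False, width=32), min_size=3, max_size=9))
def test_zscore_normalization_identity(row):
    if np.std(row, ddof=1) == 0:
        return
    z = row_zscore(make_matrix([row])).to_numpy().ravel()
    assert abs(z.mean()) < 1e-9
    assert abs(z.std(ddof=1) - 1) < 1e-9


# ---------------------------------------------------------------- clustering

def naive_complete_linkage_partitions(arr):
    """Oracle: agglomerative complete linkage, smallest-index tie-break.

    Returns the sequence of cluster partitions (sets of frozensets) after
    each merge — orientation-free, so comparable with scipy's tree.
    """
    clusters = [frozenset([i]) for i in range(len(arr))]
    d = {(i, j): float(np.linalg.norm(arr[i] - arr[j]))
         for i in range(len(arr)) for j in range(i + 1, len(arr))}

    def cdist(a, b):
        return max(d[tuple(sorted((i, j)))] for i in a for j in b)

    partitions = []
    while len(clusters) > 1:
        best = min(
            ((cdist(a, b), ia, ib)
             for ia, a in enumerate(clusters)
             for ib, b in enumerate(clusters) if ia < ib),
            key=lambda t: (t[0], t[1], t[2]),
        )
        _, ia, ib = best
        merged = clusters[ia] | clusters[ib]
        clusters = [c for k, c in enumerate(clusters) if k not in (ia, ib)]
        clusters.append(merged)
        partitions.append(set(clusters))
    return partitions


def scipy_partitions(arr):
    tree = linkage(pdist(arr), method="complete")
    clusters = {i: frozenset([i]) for i in range(len(arr))}
    partitions = []
    for step, (a, b, _, _) in enumerate(tree):
        merged = clusters.pop(int(a)) | clusters.pop(int(b))
        clusters[len(arr) + step] = merged
        partitions.append(set(clusters.values()))
    return partitions


def test_single_row_order():
    assert cluster_order(np.array([[1.0, 2.0]])) == [0]


def test_near_rows_adjacent_in_leaf_order():
    arr = np.array([[0, 0], [10, 10], [0.1, 0]])
    order = cluster_order(arr)
    assert abs(order.index(0) - order.index(2)) == 1


def test_duplicated_rows_adjacent():
    arr = np.array([[1.0, 1], [5, 5], [1, 1], [9, 0]])
    order = cluster_order(arr)
    assert abs(order.index(0) - order.index(2)) == 1


@given(st.integers(0, 2**31 - 1), st.integers(2, 6))
def test_merge_structure_matches_naive_oracle(seed, n):
    arr = np.random.default_rng(seed).normal(size=(n, 3))
    assert scipy_partitions(arr) == naive_complete_linkage_partitions(arr)
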