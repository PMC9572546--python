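import itertools

import numpy as np
import pandas as pd
import pytest

from jnkscreen.descriptors import DescriptorMatrix
from jnkscreen.feature_selection import (SelectionReport,
                                         ThreeStageDescriptorSelector,
                                         apply_selection_report,
                                         drop_zero_mutual_info,
                                         drop_zero_variance, prune_correlated,
                                         select_features)


def _dm(values, names=None):
    values = np.asarray(values, dtype=float)
    names = names or [f"d{j}" for j in range(values.shape[1])]
    return DescriptorMatrix([f"c{i}" for i in range(values.shape[0])],
                            names, values)


# ---------------------------------------------------------------------------
# stage 1: variance
# ---------------------------------------------------------------------------

def test_variance_stage_drops_constants_only():
    matrix = _dm(np.column_stack([
        np.full(4, 3.5),          # constant -> dropped
        [0, 1, 0, 1],             # varying -> kept
    ]))
    reduced, report = drop_zero_variance(matrix)
    assert reduced.descriptor_names == ["d1"]
    assert report.entries[0]["descriptor"] == "d0"
    assert report.entries[0]["value"] == 0.0


def test_variance_stage_matches_generator_ground_truth(small_qsar):
    reduced, report = drop_zero_variance(small_qsar.matrix)
    assert sorted(report.dropped) == sorted(small_qsar.manifest["constant"])


def test_all_constant_matrix_is_an_error():
    with pytest.raises(ValueError, match="zero variance"):
        drop_zero_variance(_dm(np.ones((4, 3))))


# ---------------------------------------------------------------------------
# stage 2: mutual information
# ---------------------------------------------------------------------------

def test_mi_stage_keeps_label_copy_drops_shuffled_copy():
    rng = np.random.default_rng(0)
    y = np.array([0, 1] * 300)
    label_copy = y.astype(float) + rng.normal(0, 0.3, 600)
    shuffled = rng.permutation(label_copy)  # same marginal, independent of y
    matrix = _dm(np.column_stack([label_copy, shuffled]),
                 ["label_copy", "shuffled"])
    reduced, report = drop_zero_mutual_info(matrix, y, seed=0)
    assert reduced.descriptor_names == ["label_copy"]
    assert "shuffled" in report.dropped


def test_mi_stage_is_deterministic_given_seed():
    rng = np.random.default_rng(1)
    y = np.array([0, 1] * 75)
    matrix_values = rng.normal(size=(150, 8))
    matrix_values[:, :2] += 1.5 * y[:, None]  # two informative columns
    matrix = _dm(matrix_values)
    first, _ = drop_zero_mutual_info(matrix, y, seed=42)
    second, _ = drop_zero_mutual_info(matrix, y, seed=42)
    assert first.descriptor_names == second.descriptor_names
    assert set(first.descriptor_names) >= {"d0", "d1"}


def test_mi_stage_requires_both_classes():
    matrix = _dm(np.random.default_rng(2).normal(size=(20, 3)))
    with pytest.raises(ValueError, match="both classes"):
        drop_zero_mutual_info(matrix, np.ones(20, dtype=int), seed=0)


# ---------------------------------------------------------------------------
# stage 3: correlation
# ---------------------------------------------------------------------------

def test_correlated_pair_reduced_to_one():
    rng = np.random.default_rng(3)
    x = rng.normal(size=400)
    y = 0.9 * x + np.sqrt(1 - 0.81) * rng.normal(size=400)
    matrix = _dm(np.column_stack([x, y]))
    reduced, report = prune_correlated(matrix, threshold=0.8)
    assert len(reduced.descriptor_names) == 1
    assert report.entries[0]["kept_partner"] == "d0"


def test_exactly_threshold_correlation_keeps_both():
    # engineered so the computed r is exactly 0.8: strict > spares the pair
    a = np.array([1.0, 1.0, -1.0, -1.0])
    b = 4 * a + 3 * np.array([1.0, -1.0, 1.0, -1.0])
    reduced, _ = prune_correlated(_dm(np.column_stack([a, b])), threshold=0.8)
    assert len(reduced.descriptor_names) == 2


def test_identical_triplet_keeps_first():
    x = np.random.default_rng(4).normal(size=50)
    reduced, report = prune_correlated(_dm(np.column_stack([x, x, x])))
    assert reduced.descriptor_names == ["d0"]
    assert all(e["kept_partner"] == "d0" for e in report.entries)


def _brute_force_greedy(corr, threshold):
    kept = []
    for j in range(corr.shape[0]):
        if all(abs(corr[j, k]) <= threshold for k in kept):
            kept.append(j)
    return kept


def test_permutations_change_members_not_kept_count():
    """Across all column orders of a 6-column toy the kept count is invariant
    and survivors are pairwise below threshold (brute-force oracle)."""
    rng = np.random.default_rng(5)
    base = rng.normal(size=(300, 3))
    toy = np.column_stack([base[:, 0],
                           base[:, 0] + 0.01 * rng.normal(size=300),  # clique 1
                           base[:, 1],
                           base[:, 1] + 0.01 * rng.normal(size=300),  # clique 2
                           base[:, 2],
                           rng.normal(size=300)])
    counts = set()
    for perm in itertools.permutations(range(6)):
        matrix = _dm(toy[:, perm], [f"p{j}" for j in range(6)])
        reduced, _ = prune_correlated(matrix)
        corr = np.corrcoef(reduced.values, rowvar=False)
        off = np.abs(corr - np.eye(len(reduced.descriptor_names)))
        assert off.max() <= 0.8
        # oracle: greedy on the permuted correlation matrix
        full_corr = np.corrcoef(toy[:, perm], rowvar=False)
        oracle_kept = _brute_force_greedy(full_corr, 0.8)
        assert len(reduced.descriptor_names) == len(oracle_kept)
        counts.add(len(reduced.descriptor_names))
    assert counts == {4}


# ---------------------------------------------------------------------------
# full funnel
# ---------------------------------------------------------------------------

def test_full_funnel_recovers_planted_structure(small_qsar):
    ds = small_qsar
    selected, report = select_features(ds.matrix, ds.labels, seed=11)
    dropped = set(report.dropped)
    kept = set(report.kept)
    assert set(ds.manifest["constant"]) <= dropped
    assert set(ds.manifest["independent"]) <= dropped
    # every duplicate clique collapses to at most one member
    for dup, src in ds.manifest["duplicated"].items():
        assert (dup in kept) + (src in kept) <= 1
    # no surviving pair above the threshold
    corr = np.corrcoef(selected.values, rowvar=False)
    assert np.abs(corr - np.eye(len(kept))).max() <= 0.8
    # report reconstructs the partition
    assert kept | dropped == set(ds.matrix.descriptor_names)
    assert kept & dropped == set()


def test_stage_order_is_variance_then_mi_then_correlation(small_qsar):
    _, report = select_features(small_qsar.matrix, small_qsar.labels, seed=11)
    stages = [e["stage"] for e in report.entries]
    boundary = [stages.index(s) for s in ("variance", "mutual_info", "correlation")]
    assert boundary == sorted(boundary)
    assert stages == sorted(stages, key=("variance", "mutual_info",
                                         "correlation").index)


def test_selector_is_idempotent(small_qsar):
    selected, _ = select_features(small_qsar.matrix, small_qsar.labels, seed=11)
    again, report = select_features(selected, small_qsar.labels, seed=11)
    assert again.descriptor_names == selected.descriptor_names
    assert report.dropped == []


def test_report_csv_round_trip_and_reapplication(tmp_path, small_qsar):
    selected, report = select_features(small_qsar.matrix, small_qsar.labels,
                                       seed=11)
    path = tmp_path / "selection_report.csv"
    report.write_csv(path)
    restored = SelectionReport.read_csv(path)
    assert restored.kept == report.kept
    assert [e["descriptor"] for e in restored.entries] == report.dropped
    reapplied = apply_selection_report(small_qsar.matrix, restored)
    assert reapplied.descriptor_names == selected.descriptor_names


def test_sklearn_transformer_interface(small_qsar):
    frame = small_qsar.matrix.to_frame()
    selector = ThreeStageDescriptorSelector(random_state=11)
    out = selector.fit(frame, small_qsar.labels).transform(frame)
    assert isinstance(out, pd.DataFrame)
    assert list(out.columns) == selector.selected_names_
    assert selector.get_support().sum() == len(selector.selected_names_)
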