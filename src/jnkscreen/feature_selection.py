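"""Three-stage descriptor pruning: variance → mutual information → correlation.

Stage order is fixed. (i) drop descriptors with zero variance; (ii) drop
descriptors carrying no mutual information about the activity label;
(iii) prune pairwise Pearson correlation above a threshold (default 0.8,
strict >) keeping the earlier column of each offending pair. Every drop is
recorded with its reason so the surviving panel can be reconstructed.

The kNN mutual-information estimator returns small positive values even for
label-independent features, so "zero MI" is operationalized as MI at or
below a threshold: either a fixed ``mi_epsilon`` or (default) a seeded
permutation null — 1.25 × the largest MI observed for any feature against
shuffled labels. A moderately large neighbor count (15) keeps the
estimator's sampling noise well below the signal of genuinely informative
descriptors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.feature_selection import mutual_info_classif
from sklearn.utils.validation import check_is_fitted

from .descriptors import DescriptorMatrix

STAGES = ("variance", "mutual_info", "correlation")

REPORT_COLUMNS = ["stage", "descriptor", "reason", "value", "kept_partner"]


@dataclass
class SelectionReport:
    """Per-stage drop records plus the final kept panel."""

    entries: list[dict] = field(default_factory=list)
    kept: list[str] = field(default_factory=list)

    def add(self, stage: str, descriptor: str, reason: str, value: float,
            kept_partner: str | None = None) -> None:
        if stage not in STAGES:
            raise ValueError(f"unknown stage {stage!r}")
        self.entries.append({"stage": stage, "descriptor": descriptor,
                             "reason": reason, "value": value,
                             "kept_partner": kept_partner})

    @property
    def dropped(self) -> list[str]:
        return [e["descriptor"] for e in self.entries]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=REPORT_COLUMNS)

    def write_csv(self, path: str | Path) -> None:
        frame = self.to_frame()
        # kept panel rides along as pseudo-entries so one file restores both
        kept = pd.DataFrame({"stage": "kept", "descriptor": self.kept,
                             "reason": "", "value": np.nan, "kept_partner": None})
        pd.concat([frame, kept], ignore_index=True).to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path) -> "SelectionReport":
        frame = pd.read_csv(path)
        kept = frame[frame["stage"] == "kept"]["descriptor"].tolist()
        entries = frame[frame["stage"] != "kept"].replace({np.nan: None})
        return cls(entries=entries.to_dict("records"), kept=kept)


class ThreeStageDescriptorSelector(BaseEstimator, TransformerMixin):
    """sklearn transformer running the fixed variance → MI → correlation funnel.

    Parameters
    ----------
    variance_epsilon : columns with variance <= this are dropped (default 0).
    mi_epsilon : fixed MI threshold, or "auto" for a seeded permutation null.
    mi_permutations : shuffled-label replicates behind the "auto" null.
    mi_neighbors : kNN count for the MI estimator (larger = less variance).
    correlation_threshold : |Pearson r| strictly above this prunes the later
        column of the pair (default 0.8).
    random_state : seeds the MI estimator and the permutation null.
    """

    def __init__(self, variance_epsilon: float = 0.0,
                 mi_epsilon: float | str = "auto",
                 mi_permutations: int = 5,
                 mi_neighbors: int = 15,
                 correlation_threshold: float = 0.8,
                 random_state: int = 0):
        self.variance_epsilon = variance_epsilon
        self.mi_epsilon = mi_epsilon
        self.mi_permutations = mi_permutations
        self.mi_neighbors = mi_neighbors
        self.correlation_threshold = correlation_threshold
        self.random_state = random_state

    def fit(self, X, y):
        frame = _to_frame(X)
        y = np.asarray(y)
        if len(y) != len(frame):
            raise ValueError("labels not aligned with matrix rows")
        report = SelectionReport()

        frame = _variance_stage(frame, self.variance_epsilon, report)
        frame = _mutual_info_stage(frame, y, report,
                                   mi_epsilon=self.mi_epsilon,
                                   n_permutations=self.mi_permutations,
                                   n_neighbors=self.mi_neighbors,
                                   seed=self.random_state)
        frame = _correlation_stage(frame, self.correlation_threshold, report)

        report.kept = [str(c) for c in frame.columns]
        self.report_ = report
        self.selected_names_ = report.kept
        self.n_features_in_ = _to_frame(X).shape[1]
        self.feature_names_in_ = [str(c) for c in _to_frame(X).columns]
        return self

    def transform(self, X):
        check_is_fitted(self, "selected_names_")
        if isinstance(X, DescriptorMatrix):
            return X.select(self.selected_names_)
        frame = _to_frame(X)
        missing = set(self.selected_names_) - set(map(str, frame.columns))
        if missing:
            raise ValueError(f"matrix lacks selected descriptors {sorted(missing)}")
        return frame[self.selected_names_]

    def get_support(self) -> np.ndarray:
        check_is_fitted(self, "selected_names_")
        kept = set(self.selected_names_)
        return np.array([n in kept for n in self.feature_names_in_])


def _to_frame(X) -> pd.DataFrame:
    if isinstance(X, DescriptorMatrix):
        return X.to_frame()
    if isinstance(X, pd.DataFrame):
        return X
    arr = np.asarray(X, dtype=float)
    return pd.DataFrame(arr, columns=[f"x{j}" for j in range(arr.shape[1])])


def _variance_stage(frame: pd.DataFrame, eps: float, report: SelectionReport) -> pd.DataFrame:
    variances = frame.var(axis=0, ddof=0)
    # a column whose max equals its min is constant even when float rounding
    # leaves its computed variance a hair above zero
    constant = (frame.max(axis=0) == frame.min(axis=0))
    keep = (variances > eps) & ~constant
    for name in frame.columns[~keep]:
        var = 0.0 if constant[name] else float(variances[name])
        report.add("variance", str(name), "zero variance", var)
    if not keep.any():
        raise ValueError("all descriptors have zero variance")
    return frame.loc[:, keep]


_MI_NULL_FACTOR = 1.25  # safety factor over the permutation-null max


def _mi_threshold(values: np.ndarray, y: np.ndarray, n_permutations: int,
                  n_neighbors: int, seed: int) -> float:
    """Permutation null for the MI estimator: max MI against shuffled labels."""
    rng = np.random.default_rng(seed)
    null_max = 0.0
    for p in range(n_permutations):
        perm = rng.permutation(len(y))
        mi = mutual_info_classif(values, y[perm], random_state=seed + 1 + p,
                                 n_neighbors=n_neighbors)
        null_max = max(null_max, float(mi.max()))
    return _MI_NULL_FACTOR * null_max


def _mutual_info_stage(frame: pd.DataFrame, y: np.ndarray, report: SelectionReport,
                       mi_epsilon: float | str, n_permutations: int,
                       seed: int, n_neighbors: int = 15) -> pd.DataFrame:
    if len(np.unique(y)) < 2:
        raise ValueError("mutual-information stage requires both classes present")
    values = frame.to_numpy(dtype=float)
    mi = mutual_info_classif(values, y, random_state=seed, n_neighbors=n_neighbors)
    if mi_epsilon == "auto":
        threshold = _mi_threshold(values, y, n_permutations, n_neighbors, seed)
    else:
        threshold = float(mi_epsilon)
    keep = mi > threshold
    for name, value in zip(frame.columns, mi):
        if value <= threshold:
            report.add("mutual_info", str(name), "zero mutual information", float(value))
    if not keep.any():
        raise ValueError("all descriptors dropped at the mutual-information stage")
    return frame.loc[:, keep]


def _correlation_stage(frame: pd.DataFrame, threshold: float,
                       report: SelectionReport) -> pd.DataFrame:
    corr = np.corrcoef(frame.to_numpy(dtype=float), rowvar=False)
    corr = np.nan_to_num(np.atleast_2d(corr), nan=0.0)
    names = [str(c) for c in frame.columns]
    kept_idx: list[int] = []
    for j in range(len(names)):
        partner = None
        for k in kept_idx:
            if abs(corr[j, k]) > threshold:
                partner = k
                break
        if partner is None:
            kept_idx.append(j)
        else:
            report.add("correlation", names[j],
                       f"|r| > {threshold}", float(abs(corr[j, partner])),
                       kept_partner=names[partner])
    return frame.iloc[:, kept_idx]


# ---------------------------------------------------------------------------
# functional wrappers over DescriptorMatrix
# ---------------------------------------------------------------------------

def drop_zero_variance(matrix: DescriptorMatrix, eps: float = 0.0,
                       ) -> tuple[DescriptorMatrix, SelectionReport]:
    if matrix.shape[0] == 0:
        raise ValueError("empty matrix")
    report = SelectionReport()
    frame = _variance_stage(matrix.to_frame(), eps, report)
    report.kept = [str(c) for c in frame.columns]
    return matrix.select(report.kept), report


def drop_zero_mutual_info(matrix: DescriptorMatrix, labels: Sequence[int],
                          seed: int = 0, mi_epsilon: float | str = "auto",
                          n_permutations: int = 5, mi_neighbors: int = 15,
                          ) -> tuple[DescriptorMatrix, SelectionReport]:
    report = SelectionReport()
    frame = _mutual_info_stage(matrix.to_frame(), np.asarray(labels), report,
                               mi_epsilon=mi_epsilon, n_permutations=n_permutations,
                               seed=seed, n_neighbors=mi_neighbors)
    report.kept = [str(c) for c in frame.columns]
    return matrix.select(report.kept), report


def prune_correlated(matrix: DescriptorMatrix, threshold: float = 0.8,
                     ) -> tuple[DescriptorMatrix, SelectionReport]:
    if matrix.shape[0] < 2:
        raise ValueError("correlation pruning needs at least 2 rows")
    report = SelectionReport()
    frame = _correlation_stage(matrix.to_frame(), threshold, report)
    report.kept = [str(c) for c in frame.columns]
    return matrix.select(report.kept), report


def select_features(matrix: DescriptorMatrix, labels: Sequence[int], seed: int = 0,
                    variance_epsilon: float = 0.0,
                    mi_epsilon: float | str = "auto",
                    correlation_threshold: float = 0.8,
                    ) -> tuple[DescriptorMatrix, SelectionReport]:
    """Run the full three-stage funnel and return matrix + audit report."""
    selector = ThreeStageDescriptorSelector(
        variance_epsilon=variance_epsilon, mi_epsilon=mi_epsilon,
        correlation_threshold=correlation_threshold, random_state=seed,
    ).fit(matrix, labels)
    return selector.transform(matrix), selector.report_


def apply_selection_report(matrix: DescriptorMatrix, report: SelectionReport,
                           ) -> DescriptorMatrix:
    """Apply a previously saved selection to a new matrix."""
    missing = set(report.kept) - set(matrix.descriptor_names)
    if missing:
        raise ValueError(f"matrix lacks selected descriptors {sorted(missing)}")
    return matrix.select(report.kept)
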