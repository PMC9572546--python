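"""Molecular descriptor computation, standardization and chemical-space PCA.

The default provider computes the classic 208-name RDKit physicochemical /
topological descriptor panel. Descriptor values have wildly heterogeneous
units, so chemical-space analysis is done on standardized (z-scored)
features, i.e. correlation PCA. The applicability domain is an axis-aligned
bounding box on the first two principal components of the training set:
a prediction is considered in-domain when it projects inside the box
(optionally widened by a fractional margin).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors as _RDDescriptors
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.utils.validation import check_is_fitted

from .chem_io import CompoundRecord, Reject

# Descriptors added to RDKit after the classic 208-name panel was frozen;
# excluded so the default panel keeps its historical composition.
_POST_PANEL_ADDITIONS = ("AvgIpc", "SPS")


@dataclass
class DescriptorMatrix:
    """Compounds × named numeric descriptors, with pruning provenance."""

    compound_ids: list[str]
    descriptor_names: list[str]
    values: np.ndarray  # shape (n_compounds, n_descriptors)
    provenance: str = "raw"  # raw | standardized | selected

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            self.values = self.values.reshape(len(self.compound_ids), -1)
        if self.values.shape != (len(self.compound_ids), len(self.descriptor_names)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.compound_ids)} ids × {len(self.descriptor_names)} names")
        if len(set(self.descriptor_names)) != len(self.descriptor_names):
            raise ValueError("descriptor names must be unique")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.compound_ids, name="compound_id"),
                            columns=self.descriptor_names)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, provenance: str = "raw") -> "DescriptorMatrix":
        return cls([str(i) for i in frame.index], [str(c) for c in frame.columns],
                   frame.to_numpy(dtype=float), provenance)

    def select(self, names: Sequence[str], provenance: str = "selected") -> "DescriptorMatrix":
        idx = [self.descriptor_names.index(n) for n in names]
        return DescriptorMatrix(list(self.compound_ids), list(names),
                                self.values[:, idx], provenance)

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path)

    @classmethod
    def read_csv(cls, path: str | Path, provenance: str = "raw") -> "DescriptorMatrix":
        return cls.from_frame(pd.read_csv(path, index_col=0), provenance)


class DescriptorProvider(Protocol):
    """A backend advertising a fixed, ordered descriptor name list."""

    @property
    def names(self) -> list[str]: ...

    def compute(self, smiles: str) -> np.ndarray: ...


class RDKitDescriptorProvider:
    """The standard 208-descriptor RDKit panel (MolWt, TPSA, BCUT2D_*, ...)."""

    def __init__(self) -> None:
        self._funcs = [(name, fn) for name, fn in _RDDescriptors._descList
                       if name not in _POST_PANEL_ADDITIONS]
        self._names = [name for name, _ in self._funcs]

    @property
    def names(self) -> list[str]:
        return list(self._names)

    def compute(self, smiles: str) -> np.ndarray:
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise ValueError(f"unparseable SMILES: {smiles!r}")
        out = np.empty(len(self._funcs))
        for j, (name, fn) in enumerate(self._funcs):
            try:
                out[j] = float(fn(mol))
            except Exception:
                out[j] = np.nan
            if not np.isfinite(out[j]):
                raise ValueError(f"descriptor {name} is not finite for {smiles!r}")
        return out


class PrecomputedDescriptorProvider:
    """File-backed provider serving rows of a precomputed descriptor table."""

    def __init__(self, table: pd.DataFrame, smiles_column: str = "smiles") -> None:
        if smiles_column in table.columns:
            table = table.set_index(smiles_column)
        self._table = table.astype(float)
        self._names = [str(c) for c in table.columns]

    @classmethod
    def from_csv(cls, path: str | Path, **kwargs) -> "PrecomputedDescriptorProvider":
        return cls(pd.read_csv(path, index_col=0), **kwargs)

    @property
    def names(self) -> list[str]:
        return list(self._names)

    def compute(self, smiles: str) -> np.ndarray:
        if smiles not in self._table.index:
            raise ValueError(f"no precomputed descriptors for {smiles!r}")
        row = self._table.loc[smiles].to_numpy(dtype=float)
        if not np.all(np.isfinite(row)):
            bad = self._names[int(np.argmin(np.isfinite(row)))]
            raise ValueError(f"descriptor {bad} is not finite for {smiles!r}")
        return row


def compute_descriptors(records: Sequence[CompoundRecord],
                        provider: DescriptorProvider | None = None,
                        ) -> tuple[DescriptorMatrix, list[Reject]]:
    """One descriptor row per parseable record; failures become rejects."""
    provider = provider or RDKitDescriptorProvider()
    names = provider.names
    ids, rows, rejects = [], [], []
    for i, rec in enumerate(records):
        try:
            rows.append(provider.compute(rec.smiles))
            ids.append(rec.compound_id)
        except ValueError as exc:
            rejects.append(Reject(f"record {i + 1}", rec.compound_id, str(exc)))
    values = np.vstack(rows) if rows else np.empty((0, len(names)))
    return DescriptorMatrix(ids, names, values, "raw"), rejects


# ---------------------------------------------------------------------------
# standardization
# ---------------------------------------------------------------------------

class Standardizer(BaseEstimator, TransformerMixin):
    """Per-descriptor z-scoring fitted on training data only.

    Constant columns get scale 1 so they map to exactly 0 instead of
    dividing by zero. Test matrices are transformed with the training
    parameters, never refitted.
    """

    def fit(self, X, y=None):
        frame = X.to_frame() if isinstance(X, DescriptorMatrix) else pd.DataFrame(X)
        self.feature_names_ = [str(c) for c in frame.columns]
        values = frame.to_numpy(dtype=float)
        self.mean_ = values.mean(axis=0)
        scale = values.std(axis=0, ddof=0)
        # constant columns (max == min, exact) map to 0 instead of 0/0
        constant = values.max(axis=0) == values.min(axis=0)
        scale[constant] = 1.0
        if constant.any() and len(values):
            self.mean_[constant] = values[0, constant]
        self.scale_ = scale
        return self

    def transform(self, X):
        check_is_fitted(self, "mean_")
        if isinstance(X, DescriptorMatrix):
            if X.descriptor_names != self.feature_names_:
                unseen = set(X.descriptor_names) - set(self.feature_names_)
                missing = set(self.feature_names_) - set(X.descriptor_names)
                raise ValueError(
                    f"descriptor mismatch: unseen {sorted(unseen)}, missing {sorted(missing)}")
            values = (X.values - self.mean_) / self.scale_
            return DescriptorMatrix(list(X.compound_ids), list(X.descriptor_names),
                                    values, "standardized")
        return (np.asarray(X, dtype=float) - self.mean_) / self.scale_


def fit_standardizer(matrix: DescriptorMatrix) -> Standardizer:
    return Standardizer().fit(matrix)


def apply_standardizer(std: Standardizer, matrix: DescriptorMatrix) -> DescriptorMatrix:
    return std.transform(matrix)


# ---------------------------------------------------------------------------
# chemical space / applicability domain
# ---------------------------------------------------------------------------

class ChemSpacePCA(BaseEstimator, TransformerMixin):
    """PCA projection of standardized descriptors for chemical-space maps.

    Stores per-component training min/max so library compounds can be
    flagged in/out of the training applicability domain.
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X, y=None):
        values, _ = _as_values(X)
        if self.n_components > values.shape[1]:
            raise ValueError(
                f"n_components={self.n_components} exceeds {values.shape[1]} descriptors")
        self.pca_ = PCA(n_components=self.n_components, svd_solver="full").fit(values)
        coords = self.pca_.transform(values)
        self.loadings_ = self.pca_.components_
        self.explained_variance_ratio_ = self.pca_.explained_variance_ratio_
        self.train_min_ = coords.min(axis=0)
        self.train_max_ = coords.max(axis=0)
        return self

    def transform(self, X) -> pd.DataFrame:
        check_is_fitted(self, "pca_")
        values, ids = _as_values(X)
        coords = self.pca_.transform(values)
        cols = [f"pc{i + 1}" for i in range(coords.shape[1])]
        return pd.DataFrame(coords, columns=cols,
                            index=pd.Index(ids, name="compound_id"))

    def applicability_domain(self, X, margin: float = 0.0) -> tuple[pd.Series, float]:
        """In-domain flag per compound plus the overall overlap fraction.

        A compound is in-domain iff its first two component coordinates lie in
        [min − margin·range, max + margin·range] of the training projection.
        """
        check_is_fitted(self, "pca_")
        coords = self.transform(X)
        k = min(2, coords.shape[1])
        lo = self.train_min_[:k]
        hi = self.train_max_[:k]
        span = hi - lo
        lo_m = lo - margin * span
        hi_m = hi + margin * span
        vals = coords.to_numpy()[:, :k]
        inside = np.all((vals >= lo_m) & (vals <= hi_m), axis=1)
        flags = pd.Series(inside, index=coords.index, name="in_domain")
        overlap = float(inside.mean()) if len(inside) else float("nan")
        return flags, overlap


def _as_values(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, DescriptorMatrix):
        return X.values, list(X.compound_ids)
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), [str(i) for i in X.index]
    arr = np.asarray(X, dtype=float)
    return arr, [str(i) for i in range(arr.shape[0])]


def fit_chemspace(matrix: DescriptorMatrix, n_components: int = 2) -> ChemSpacePCA:
    if n_components not in (2, 3):
        raise ValueError("chemical-space PCA uses 2 or 3 components")
    return ChemSpacePCA(n_components=n_components).fit(matrix)


def project(model: ChemSpacePCA, matrix: DescriptorMatrix) -> pd.DataFrame:
    return model.transform(matrix)


def applicability_domain(model: ChemSpacePCA, matrix: DescriptorMatrix,
                         margin: float = 0.0) -> tuple[pd.Series, float]:
    return model.applicability_domain(matrix, margin=margin)
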