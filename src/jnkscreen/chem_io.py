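"""Compound tables: reading/writing, bioactivity curation and train/test splitting.

The curation contract mirrors common kinase-bioactivity practice: duplicate
structures (same canonical SMILES) are collapsed, entries without a measured
IC50 are removed, and a binary activity label is assigned by a strict
threshold on IC50 (default 1 µM: IC50 < 1 µM ⇒ active).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from rdkit import Chem
from rdkit import RDLogger
from sklearn.model_selection import train_test_split

RDLogger.DisableLog("rdApp.*")

ACTIVITY_THRESHOLD_UM = 1.0

CSV_COLUMNS = ["compound_id", "smiles", "name", "cas_number", "ic50_um", "label"]


class CurationError(ValueError):
    """All records were removed during curation."""


@dataclass
class CompoundRecord:
    """One molecule with identifiers, structure and optional measured activity."""

    compound_id: str
    smiles: str
    name: str | None = None
    cas_number: str | None = None
    ic50_um: float | None = None
    label: str = "unknown"

    def __post_init__(self) -> None:
        if self.ic50_um is not None and self.ic50_um <= 0:
            raise ValueError(f"ic50_um must be positive, got {self.ic50_um}")
        if self.label not in ("active", "inactive", "unknown"):
            raise ValueError(f"unknown label {self.label!r}")


@dataclass
class Reject:
    """A record that failed validation, with enough context to audit it."""

    location: str  # e.g. "row 3" / "line 7" / "mol 2"
    compound_id: str | None
    reason: str


@dataclass
class CurationReport:
    n_input: int
    n_kept: int
    removed_no_activity: int
    removed_unparseable: int
    merged_duplicates: int
    n_active: int
    n_inactive: int
    rejects: list[Reject] = field(default_factory=list)


@dataclass
class DatasetSplit:
    """A train/test partition of compound ids at a fixed integer ratio."""

    train_ids: list[str]
    test_ids: list[str]
    ratio: tuple[int, int]
    seed: int


def canonical_smiles(smiles: str) -> str | None:
    """Canonical SMILES via RDKit, or None when the structure does not parse."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    return Chem.MolToSmiles(mol)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("csv", "smi", "sdf"):
        return suffix
    raise ValueError(f"cannot infer format from suffix {path.suffix!r}")


def read_compounds(path: str | Path, format: str | None = None
                   ) -> tuple[list[CompoundRecord], list[Reject]]:
    """Read compound records from CSV, SMILES (.smi) or SDF.

    Returns (records, rejects); structures that fail to parse are reported in
    the rejects list with their row/line position, never silently dropped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    fmt = format or _infer_format(path)
    if fmt == "csv":
        return _read_csv(path)
    if fmt == "smi":
        return _read_smi(path)
    if fmt == "sdf":
        return _read_sdf(path)
    raise ValueError(f"unsupported format {fmt!r}")


def _opt_str(value) -> str | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    s = str(value)
    return s if s else None


def _read_csv(path: Path) -> tuple[list[CompoundRecord], list[Reject]]:
    frame = pd.read_csv(path, dtype={"compound_id": str, "cas_number": str},
                        float_precision="round_trip")
    missing = {"compound_id", "smiles"} - set(frame.columns)
    if missing:
        raise ValueError(f"CSV {path} missing required columns {sorted(missing)}")
    records, rejects = [], []
    for idx, row in frame.iterrows():
        loc = f"row {idx + 2}"  # 1-based with header
        smiles = row["smiles"]
        if not isinstance(smiles, str) or canonical_smiles(smiles) is None:
            rejects.append(Reject(loc, _opt_str(row["compound_id"]), "unparseable SMILES"))
            continue
        ic50 = row.get("ic50_um")
        ic50 = None if ic50 is None or pd.isna(ic50) else float(ic50)
        label = _opt_str(row.get("label")) or "unknown"
        records.append(CompoundRecord(
            compound_id=str(row["compound_id"]),
            smiles=smiles,
            name=_opt_str(row.get("name")),
            cas_number=_opt_str(row.get("cas_number")),
            ic50_um=ic50,
            label=label,
        ))
    return records, rejects


def _read_smi(path: Path) -> tuple[list[CompoundRecord], list[Reject]]:
    records, rejects = [], []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        parts = line.split("\t")
        smiles = parts[0]
        cid = parts[1] if len(parts) > 1 else f"line{lineno}"
        if canonical_smiles(smiles) is None:
            rejects.append(Reject(f"line {lineno}", cid, "unparseable SMILES"))
            continue
        records.append(CompoundRecord(compound_id=cid, smiles=smiles))
    return records, rejects


_SDF_PROPS = ("name", "cas_number", "ic50_um", "label")


def _read_sdf(path: Path) -> tuple[list[CompoundRecord], list[Reject]]:
    records, rejects = [], []
    supplier = Chem.SDMolSupplier(str(path))
    for i, mol in enumerate(supplier):
        loc = f"mol {i + 1}"
        if mol is None:
            rejects.append(Reject(loc, None, "unparseable molecule block"))
            continue
        props = mol.GetPropsAsDict()
        cid = str(props.get("compound_id", mol.GetProp("_Name") if mol.HasProp("_Name") else loc))
        ic50 = props.get("ic50_um")
        records.append(CompoundRecord(
            compound_id=cid,
            smiles=Chem.MolToSmiles(mol),
            name=props.get("name"),
            cas_number=str(props["cas_number"]) if "cas_number" in props else None,
            ic50_um=float(ic50) if ic50 is not None else None,
            label=str(props.get("label", "unknown")),
        ))
    return records, rejects


def write_compounds(records: Sequence[CompoundRecord], path: str | Path,
                    format: str | None = None) -> None:
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "csv":
        to_frame(records).to_csv(path, index=False)
    elif fmt == "smi":
        path.write_text("".join(f"{r.smiles}\t{r.compound_id}\n" for r in records))
    elif fmt == "sdf":
        writer = Chem.SDWriter(str(path))
        for r in records:
            mol = Chem.MolFromSmiles(r.smiles)
            if mol is None:
                raise ValueError(f"cannot write unparseable SMILES for {r.compound_id}")
            mol.SetProp("_Name", r.compound_id)
            mol.SetProp("compound_id", r.compound_id)
            if r.name is not None:
                mol.SetProp("name", r.name)
            if r.cas_number is not None:
                mol.SetProp("cas_number", r.cas_number)
            if r.ic50_um is not None:
                mol.SetProp("ic50_um", repr(r.ic50_um))
            mol.SetProp("label", r.label)
            writer.write(mol)
        writer.close()
    else:
        raise ValueError(f"unsupported format {fmt!r}")


def to_frame(records: Sequence[CompoundRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [{c: getattr(r, c) for c in CSV_COLUMNS} for r in records],
        columns=CSV_COLUMNS,
    )


# ---------------------------------------------------------------------------
# curation
# ---------------------------------------------------------------------------

def curate_dataset(records: Sequence[CompoundRecord],
                   threshold_um: float = ACTIVITY_THRESHOLD_UM,
                   ) -> tuple[list[CompoundRecord], CurationReport]:
    """Deduplicate, drop activity-less entries and assign labels.

    Duplicates share a canonical-SMILES structure key; their IC50 values are
    aggregated by geometric mean (order-independent). Labels follow the strict
    rule IC50 < threshold ⇒ active, otherwise inactive.
    """
    if not records:
        raise ValueError("curate_dataset requires a non-empty record list")
    if threshold_um <= 0:
        raise ValueError("threshold_um must be positive")

    rejects: list[Reject] = []
    removed_no_activity = 0
    groups: dict[str, list[CompoundRecord]] = {}
    order: list[str] = []
    for i, rec in enumerate(records):
        key = canonical_smiles(rec.smiles)
        if key is None:
            rejects.append(Reject(f"record {i + 1}", rec.compound_id, "unparseable SMILES"))
            continue
        if rec.ic50_um is None:
            removed_no_activity += 1
            continue
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(rec)

    merged = 0
    curated: list[CompoundRecord] = []
    for key in order:
        group = groups[key]
        first = group[0]
        if len(group) > 1:
            merged += len(group) - 1
        log_mean = sum(math.log(r.ic50_um) for r in group) / len(group)
        ic50 = math.exp(log_mean)
        label = "active" if ic50 < threshold_um else "inactive"
        curated.append(replace(first, smiles=key, ic50_um=ic50, label=label))

    if not curated:
        reasons = Counter({"no measured activity": removed_no_activity,
                           "unparseable SMILES": len(rejects)})
        dominant = reasons.most_common(1)[0][0]
        raise CurationError(f"all records removed during curation (mostly: {dominant})")

    n_active = sum(r.label == "active" for r in curated)
    report = CurationReport(
        n_input=len(records),
        n_kept=len(curated),
        removed_no_activity=removed_no_activity,
        removed_unparseable=len(rejects),
        merged_duplicates=merged,
        n_active=n_active,
        n_inactive=len(curated) - n_active,
        rejects=rejects,
    )
    return curated, report


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------

def split_dataset(records: Sequence[CompoundRecord],
                  ratio: tuple[int, int] = (4, 1),
                  seed: int = 0,
                  stratify: bool = True) -> DatasetSplit:
    """Deterministic train/test split at an integer ratio (default 4:1).

    Stratifies on the activity label by default so class proportions are
    preserved; a plain random split is available with stratify=False.
    """
    if len(records) < 5:
        raise ValueError("need at least 5 records to split")
    if ratio[0] <= 0 or ratio[1] <= 0:
        raise ValueError("ratio parts must be positive integers")
    ids = [r.compound_id for r in records]
    labels = [r.label for r in records]
    if stratify and len(set(labels)) < 2:
        raise ValueError("stratified split requires both classes present")
    test_size = ratio[1] / (ratio[0] + ratio[1])
    train_ids, test_ids = train_test_split(
        ids,
        test_size=test_size,
        random_state=seed,
        shuffle=True,
        stratify=labels if stratify else None,
    )
    return DatasetSplit(train_ids=list(train_ids), test_ids=list(test_ids),
                        ratio=tuple(ratio), seed=seed)
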