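"""Library screening: dual-confidence activity filter, rule-based
drug-likeness/ADMET filter, fingerprint similarity clustering and the
ML + docking consensus score.

Consensus scoring combines the two ensemble confidences with the docking
binding free energy: S_ml is the mean of the voting and stacking
confidences, S_dock is the ratio of the compound's binding free energy to
the co-crystallized reference ligand's affinity (default −10.6 kcal/mol,
capped at 1 when a compound out-docks the reference), and the total score
is the mean of the two sub-scores. Candidates are ranked by total score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .chem_io import CompoundRecord

REFERENCE_ENERGY_KCAL = -10.6  # co-crystallized ligand affinity
CONFIDENCE_THRESHOLD = 0.8
TOTAL_SCORE_THRESHOLD = 0.8

TOX_ENDPOINTS = ("mutagenicity", "carcinogenicity", "hepatotoxicity",
                 "oral_acute_toxicity")


@dataclass
class AdmetAnnotation:
    """Predicted physicochemical / pharmacokinetic / toxicity annotations."""

    mw: float                 # Da
    logp: float
    hbd: int
    hba: int
    logs: float               # log10 mol/L aqueous solubility
    hia_percent: float        # human intestinal absorption, [0, 100]
    mce18: float              # medicinal-chemistry evolution score
    bbb_permeant: bool
    tox_flags: frozenset = frozenset()

    def __post_init__(self) -> None:
        if not 0.0 <= self.hia_percent <= 100.0:
            raise ValueError("hia_percent must be within [0, 100]")
        if self.hbd < 0 or self.hba < 0:
            raise ValueError("H-bond donor/acceptor counts must be non-negative")
        unknown = set(self.tox_flags) - set(TOX_ENDPOINTS)
        if unknown:
            raise ValueError(f"unknown toxicity flags {sorted(unknown)}")
        self.tox_flags = frozenset(self.tox_flags)


@dataclass
class ConsensusScore:
    s_ml: float
    s_dock: float
    s_total: float


@dataclass
class ScreeningRecord:
    """A library compound moving through the screening funnel."""

    compound: CompoundRecord
    conf_voting: float | None = None
    conf_stacking: float | None = None
    admet: AdmetAnnotation | None = None
    docking_energy_kcal: float | None = None
    consensus: ConsensusScore | None = None

    @property
    def compound_id(self) -> str:
        return self.compound.compound_id


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def activity_filter(records: Sequence[ScreeningRecord],
                    threshold: float = CONFIDENCE_THRESHOLD,
                    ) -> tuple[list[ScreeningRecord], dict]:
    """Keep compounds both integrated models call active: conf ≥ threshold in both."""
    passing = []
    for rec in records:
        if rec.conf_voting is None or rec.conf_stacking is None:
            raise ValueError(f"{rec.compound_id}: missing ensemble confidence")
        if rec.conf_voting >= threshold and rec.conf_stacking >= threshold:
            passing.append(rec)
    counts = {"input": len(records), "passed": len(passing),
              "failed": len(records) - len(passing)}
    return passing, counts


def _lipinski_violations(a: AdmetAnnotation) -> int:
    return sum([a.mw > 500, a.logp > 5, a.hbd > 5, a.hba > 10])


def druglikeness_failures(annotation: AdmetAnnotation,
                          lipinski_violations_allowed: int = 0) -> list[str]:
    """Names of the drug-likeness rules this annotation violates.

    Rules: Lipinski's Rule of Five (at most ``lipinski_violations_allowed``
    violations, default none), LogS in [−4, 0.5], HIA > 30 %, MCE-18 > 45,
    BBB permeant, and no toxicity flags.
    """
    a = annotation
    failures = []
    if _lipinski_violations(a) > lipinski_violations_allowed:
        failures.append("Lipinski")
    if not (-4.0 <= a.logs <= 0.5):
        failures.append("LogS")
    if not a.hia_percent > 30.0:
        failures.append("HIA")
    if not a.mce18 > 45.0:
        failures.append("MCE18")
    if not a.bbb_permeant:
        failures.append("BBB")
    if a.tox_flags:
        failures.append("Toxicity")
    return failures


def druglikeness_filter(records: Sequence[ScreeningRecord],
                        lipinski_violations_allowed: int = 0,
                        ) -> tuple[list[ScreeningRecord], dict]:
    """Apply the full drug-likeness rule set; tally failures per rule.

    A compound passes only when ``druglikeness_failures`` is empty.
    """
    tally = {"Lipinski": 0, "LogS": 0, "HIA": 0, "MCE18": 0, "BBB": 0,
             "Toxicity": 0}
    passing = []
    for rec in records:
        if rec.admet is None:
            raise ValueError(f"{rec.compound_id}: missing ADMET annotation")
        failures = druglikeness_failures(rec.admet, lipinski_violations_allowed)
        if failures:
            for rule in failures:
                tally[rule] += 1
        else:
            passing.append(rec)
    tally["input"] = len(records)
    tally["passed"] = len(passing)
    return passing, tally


# ---------------------------------------------------------------------------
# similarity clustering
# ---------------------------------------------------------------------------

class MorganFingerprintProvider:
    """2048-bit circular (Morgan, radius 2) fingerprints."""

    def __init__(self, radius: int = 2, n_bits: int = 2048):
        self._gen = rdFingerprintGenerator.GetMorganGenerator(
            radius=radius, fpSize=n_bits)

    def fingerprint(self, smiles: str):
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise ValueError(f"unparseable SMILES: {smiles!r}")
        return self._gen.GetFingerprint(mol)


def similarity_cluster(records: Sequence[ScreeningRecord | CompoundRecord],
                       provider: MorganFingerprintProvider | None = None,
                       ) -> tuple[pd.DataFrame, np.ndarray]:
    """Pairwise Tanimoto similarity matrix + average-linkage clustering tree.

    Returns (similarity DataFrame indexed by compound id, scipy linkage
    matrix over 1 − similarity distances).
    """
    provider = provider or MorganFingerprintProvider()
    comps = [r.compound if isinstance(r, ScreeningRecord) else r for r in records]
    if len(comps) < 2:
        raise ValueError("similarity clustering needs at least 2 records")
    from rdkit import DataStructs
    fps, ids = [], []
    for c in comps:
        fps.append(provider.fingerprint(c.smiles))
        ids.append(c.compound_id)
    n = len(fps)
    sim = np.eye(n)
    for i in range(n):
        row = DataStructs.BulkTanimotoSimilarity(fps[i], fps[i + 1:])
        sim[i, i + 1:] = row
        sim[i + 1:, i] = row
    frame = pd.DataFrame(sim, index=ids, columns=ids)
    dist = squareform(1.0 - sim, checks=False)
    tree = linkage(dist, method="average")
    return frame, tree


def cut_clusters(tree: np.ndarray, n_clusters: int) -> np.ndarray:
    """Flat cluster labels from the linkage tree."""
    return fcluster(tree, t=n_clusters, criterion="maxclust")


# ---------------------------------------------------------------------------
# consensus scoring / ranking
# ---------------------------------------------------------------------------

def consensus_score(record: ScreeningRecord,
                    reference_energy_kcal: float = REFERENCE_ENERGY_KCAL,
                    ) -> ConsensusScore:
    """Combine ensemble confidences and docking affinity into one score."""
    if reference_energy_kcal == 0:
        raise ValueError("reference energy must be non-zero")
    if reference_energy_kcal > 0:
        raise ValueError("reference energy must be negative (favorable)")
    if record.conf_voting is None or record.conf_stacking is None:
        raise ValueError(f"{record.compound_id}: missing ensemble confidence")
    if record.docking_energy_kcal is None:
        raise ValueError(f"{record.compound_id}: missing docking energy")

    s_ml = (record.conf_voting + record.conf_stacking) / 2.0
    energy = record.docking_energy_kcal
    if energy > 0:
        warnings.warn(f"{record.compound_id}: positive docking energy, "
                      "docking sub-score set to 0", stacklevel=2)
        s_dock = 0.0
    else:
        s_dock = min(1.0, energy / reference_energy_kcal)
    s_total = (s_ml + s_dock) / 2.0
    score = ConsensusScore(s_ml=s_ml, s_dock=s_dock, s_total=s_total)
    record.consensus = score
    return score


def score_library(records: Sequence[ScreeningRecord],
                  reference_energy_kcal: float = REFERENCE_ENERGY_KCAL,
                  ) -> list[ScreeningRecord]:
    for rec in records:
        consensus_score(rec, reference_energy_kcal)
    return list(records)


def rank_candidates(records: Sequence[ScreeningRecord],
                    select_threshold: float = TOTAL_SCORE_THRESHOLD,
                    ) -> tuple[pd.DataFrame, list[ScreeningRecord]]:
    """Rank scored compounds by total score (desc), tie-break on compound id.

    Selection uses strict > on the total score.
    """
    unscored = [r.compound_id for r in records if r.consensus is None]
    if unscored:
        raise ValueError(f"records not scored yet: {unscored[:5]}")
    rows = []
    for rec in records:
        rows.append({
            "compound_id": rec.compound_id,
            "name": rec.compound.name,
            "conf_voting": rec.conf_voting,
            "conf_stacking": rec.conf_stacking,
            "docking_energy_kcal": rec.docking_energy_kcal,
            "s_ml": rec.consensus.s_ml,
            "s_dock": rec.consensus.s_dock,
            "s_total": rec.consensus.s_total,
        })
    frame = pd.DataFrame(rows)
    frame = frame.sort_values(["s_total", "compound_id"],
                              ascending=[False, True], kind="stable")
    frame["rank"] = range(1, len(frame) + 1)
    frame["selected"] = frame["s_total"] > select_threshold
    frame = frame.reset_index(drop=True)
    by_id = {r.compound_id: r for r in records}
    selected = [by_id[cid] for cid in frame.loc[frame["selected"], "compound_id"]]
    return frame, selected


# ---------------------------------------------------------------------------
# library table I/O
# ---------------------------------------------------------------------------

LIBRARY_COLUMNS = (
    ["compound_id", "smiles", "name", "conf_voting", "conf_stacking",
     "mw", "logp", "hbd", "hba", "logs", "hia_percent", "mce18", "bbb_permeant"]
    + [f"tox_{t}" for t in TOX_ENDPOINTS]
    + ["docking_energy_kcal"]
)


def library_to_frame(records: Sequence[ScreeningRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        a = rec.admet
        row = {
            "compound_id": rec.compound_id,
            "smiles": rec.compound.smiles,
            "name": rec.compound.name,
            "conf_voting": rec.conf_voting,
            "conf_stacking": rec.conf_stacking,
            "docking_energy_kcal": rec.docking_energy_kcal,
        }
        if a is not None:
            row.update({"mw": a.mw, "logp": a.logp, "hbd": a.hbd, "hba": a.hba,
                        "logs": a.logs, "hia_percent": a.hia_percent,
                        "mce18": a.mce18, "bbb_permeant": a.bbb_permeant})
            for t in TOX_ENDPOINTS:
                row[f"tox_{t}"] = t in a.tox_flags
        rows.append(row)
    return pd.DataFrame(rows, columns=LIBRARY_COLUMNS)


def library_from_frame(frame: pd.DataFrame) -> list[ScreeningRecord]:
    records = []
    for _, row in frame.iterrows():
        admet = None
        if "mw" in frame.columns and not pd.isna(row["mw"]):
            flags = frozenset(t for t in TOX_ENDPOINTS if bool(row.get(f"tox_{t}", False)))
            admet = AdmetAnnotation(
                mw=float(row["mw"]), logp=float(row["logp"]),
                hbd=int(row["hbd"]), hba=int(row["hba"]), logs=float(row["logs"]),
                hia_percent=float(row["hia_percent"]), mce18=float(row["mce18"]),
                bbb_permeant=bool(row["bbb_permeant"]), tox_flags=flags)
        energy = row.get("docking_energy_kcal")
        records.append(ScreeningRecord(
            compound=CompoundRecord(compound_id=str(row["compound_id"]),
                                    smiles=str(row["smiles"]),
                                    name=None if pd.isna(row.get("name")) else str(row["name"])),
            conf_voting=None if pd.isna(row.get("conf_voting")) else float(row["conf_voting"]),
            conf_stacking=None if pd.isna(row.get("conf_stacking")) else float(row["conf_stacking"]),
            admet=admet,
            docking_energy_kcal=None if energy is None or pd.isna(energy) else float(energy),
        ))
    return records


def write_library(records: Sequence[ScreeningRecord], path: str | Path) -> None:
    library_to_frame(records).to_csv(path, index=False)


def read_library(path: str | Path) -> list[ScreeningRecord]:
    return library_from_frame(pd.read_csv(path))
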