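"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators mirror the three real inputs the pipeline consumes:

* ``synth_qsar_dataset`` — a labelled descriptor matrix emulating a curated
  kinase bioactivity set (default composition 1138 active / 285 inactive,
  208 descriptors) with planted pathologies: exactly-constant columns,
  exact duplicate columns, and label-independent columns. Informative
  descriptors are class-conditional Gaussians whose means differ by
  ``effect_size`` pooled standard deviations (default 1.0, a clearly
  learnable but non-trivial separation).
* ``synth_screening_library`` — an annotated screening library with planted
  dual-high-confidence compounds, planted ADMET pass/fail labels and
  docking energies, shaped like a natural-product library funnel.
* ``synth_dose_response`` — TR-FRET plate readings back-computed from a
  logistic inhibition curve with known IC50, so the assay math and the
  generator form an exact inverse pair at zero noise.

Every generator is a deterministic function of its seed and returns a
manifest naming the planted structure. Synthetic SMILES come from a small
scaffold × substituent template grid — chemically valid and fast; they
exercise parsers, not chemistry-space realism.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .bioassay import PlateReading, dilution_series
from .chem_io import CompoundRecord
from .descriptors import DescriptorMatrix
from .screening import (TOX_ENDPOINTS, AdmetAnnotation, ScreeningRecord)

# ---------------------------------------------------------------------------
# synthetic SMILES
# ---------------------------------------------------------------------------

_SCAFFOLDS = [
    "c1ccc({})cc1", "c1ccc2ccccc2c1", "c1ccc(-c2ccccc2{})cc1",
    "c1ccncc1", "c1ccc({})nc1", "c1cnc2[nH]ccc2c1",
    "c1ccc2[nH]c({})cc2c1", "c1ccc2occc2c1", "c1ccc2scc({})c2c1",
    "C1CCC({})CC1", "C1CCNC1{}", "C1CCOC1{}",
    "c1ccc(N({})C=O)cc1", "c1ccc(OC{})cc1", "c1cc(O)ccc1{}",
    "O=C(O)c1ccc({})cc1", "O=C(N{})c1ccccc1", "c1cc(F)ccc1{}",
    "c1cc(Cl)ccc1{}", "Cc1cc({})ccc1O", "c1ccc(CC{})cc1",
    "O=C1CCCN1{}", "c1ccc(S{})cc1", "c1coc({})c1", "c1csc({})c1",
]

_SUBSTITUENTS = [
    "C", "CC", "CCC", "CCCC", "O", "OC", "OCC", "N", "NC", "NCC",
    "Cl", "F", "Br", "C(=O)O", "C(=O)OC", "C(=O)N", "C#N", "CO",
    "CN", "C(F)(F)F", "CCO", "S",
]


def synth_smiles(index: int) -> str:
    """Deterministic valid SMILES for any index (template grid, then chained)."""
    singles = list(_SUBSTITUENTS)
    chained = [a + b for a, b in itertools.product(_SUBSTITUENTS, repeat=2)]
    subs = [""] + singles + chained
    scaffold = _SCAFFOLDS[index % len(_SCAFFOLDS)]
    sub = subs[(index // len(_SCAFFOLDS)) % len(subs)]
    if "{}" not in scaffold:
        return scaffold
    if sub == "":
        return scaffold.replace("({})", "").replace("{}", "")
    return scaffold.format(sub)


# ---------------------------------------------------------------------------
# QSAR dataset
# ---------------------------------------------------------------------------

@dataclass
class SynthSpec:
    """Composition of the synthetic QSAR dataset."""

    n_active: int = 1138
    n_inactive: int = 285
    n_features: int = 208
    n_constant: int = 12
    n_duplicated: int = 20
    n_independent: int = 30
    effect_size: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        pathological = self.n_constant + self.n_duplicated + self.n_independent
        if pathological >= self.n_features:
            raise ValueError("pathology counts must sum to less than n_features")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")
        if self.n_active < 1 or self.n_inactive < 1:
            raise ValueError("both classes need at least one compound")


@dataclass
class SynthQSARDataset:
    records: list[CompoundRecord]
    matrix: DescriptorMatrix
    labels: np.ndarray  # 1 = active, aligned with matrix rows
    manifest: dict


def synth_qsar_dataset(spec: SynthSpec | None = None) -> SynthQSARDataset:
    spec = spec or SynthSpec()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_active + spec.n_inactive
    labels = np.zeros(n, dtype=int)
    labels[rng.choice(n, size=spec.n_active, replace=False)] = 1

    names = [f"desc_{j:03d}" for j in range(spec.n_features)]
    roles = rng.permutation(spec.n_features)
    constant_idx = sorted(roles[: spec.n_constant])
    independent_idx = sorted(roles[spec.n_constant: spec.n_constant + spec.n_independent])
    duplicated_idx = sorted(roles[spec.n_constant + spec.n_independent:
                                  spec.n_constant + spec.n_independent + spec.n_duplicated])
    informative_idx = sorted(set(range(spec.n_features))
                             - set(constant_idx) - set(independent_idx)
                             - set(duplicated_idx))

    values = np.empty((n, spec.n_features))
    for j in informative_idx:
        values[:, j] = rng.normal(size=n) + spec.effect_size * labels
    for j in independent_idx:
        values[:, j] = rng.normal(size=n)
    for j in constant_idx:
        values[:, j] = float(np.round(rng.uniform(-5, 5), 3))
    sources = rng.choice(informative_idx, size=spec.n_duplicated, replace=True)
    dup_map = {}
    for j, src in zip(duplicated_idx, sources):
        values[:, j] = values[:, src]
        dup_map[names[j]] = names[src]

    records = []
    for i in range(n):
        if labels[i] == 1:
            ic50 = float(10.0 ** rng.uniform(-2.0, -0.02))  # < 1 µM
        else:
            ic50 = float(10.0 ** rng.uniform(0.02, 2.0))    # > 1 µM
        records.append(CompoundRecord(
            compound_id=f"CMP{i:05d}", smiles=synth_smiles(i),
            ic50_um=ic50, label="active" if labels[i] else "inactive"))

    matrix = DescriptorMatrix([r.compound_id for r in records], names, values, "raw")
    manifest = {
        "seed": spec.seed,
        "n_active": spec.n_active,
        "n_inactive": spec.n_inactive,
        "effect_size": spec.effect_size,
        "constant": [names[j] for j in constant_idx],
        "independent": [names[j] for j in independent_idx],
        "duplicated": dup_map,
        "informative": [names[j] for j in informative_idx],
    }
    return SynthQSARDataset(records=records, matrix=matrix, labels=labels,
                            manifest=manifest)


# ---------------------------------------------------------------------------
# screening library
# ---------------------------------------------------------------------------

def _passing_admet(rng: np.random.Generator) -> AdmetAnnotation:
    return AdmetAnnotation(
        mw=float(rng.uniform(200, 480)), logp=float(rng.uniform(0.0, 4.5)),
        hbd=int(rng.integers(0, 6)), hba=int(rng.integers(0, 11)),
        logs=float(rng.uniform(-3.9, 0.4)), hia_percent=float(rng.uniform(35, 100)),
        mce18=float(rng.uniform(46, 120)), bbb_permeant=True, tox_flags=frozenset())


_VIOLATIONS = ("Lipinski", "LogS", "HIA", "MCE18", "BBB", "Toxicity")


def _violated_admet(rng: np.random.Generator) -> tuple[AdmetAnnotation, list[str]]:
    a = _passing_admet(rng)
    n_rules = int(rng.integers(1, 3))
    rules = sorted(str(r) for r in rng.choice(_VIOLATIONS, size=n_rules,
                                              replace=False))
    kwargs = dict(mw=a.mw, logp=a.logp, hbd=a.hbd, hba=a.hba, logs=a.logs,
                  hia_percent=a.hia_percent, mce18=a.mce18,
                  bbb_permeant=a.bbb_permeant, tox_flags=a.tox_flags)
    for rule in rules:
        if rule == "Lipinski":
            kwargs["mw"] = float(rng.uniform(501, 900))
        elif rule == "LogS":
            kwargs["logs"] = float(rng.choice([rng.uniform(-8, -4.1),
                                               rng.uniform(0.6, 2.0)]))
        elif rule == "HIA":
            kwargs["hia_percent"] = float(rng.uniform(0, 29.9))
        elif rule == "MCE18":
            kwargs["mce18"] = float(rng.uniform(0, 44.9))
        elif rule == "BBB":
            kwargs["bbb_permeant"] = False
        elif rule == "Toxicity":
            kwargs["tox_flags"] = frozenset({str(rng.choice(TOX_ENDPOINTS))})
    return AdmetAnnotation(**kwargs), list(rules)


def synth_screening_library(n: int = 4112,
                            fraction_dual_high: float = 343 / 4112,
                            admet_pass_fraction: float = 22 / 343,
                            energy_range_kcal: tuple[float, float] = (-9.5, -6.0),
                            seed: int = 0,
                            ) -> tuple[list[ScreeningRecord], dict]:
    """Annotated library with planted filter outcomes.

    Exactly round(fraction_dual_high · n) compounds get both ensemble
    confidences ≥ 0.8; within each stratum (dual-high / rest) a
    round(admet_pass_fraction · stratum) subset is planted to satisfy every
    drug-likeness rule. Docking energies are uniform over
    ``energy_range_kcal``. The manifest names every planted set.
    """
    if not (0.0 <= fraction_dual_high <= 1.0 and 0.0 <= admet_pass_fraction <= 1.0):
        raise ValueError("fractions must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_high = round(fraction_dual_high * n)
    high_set = set(rng.choice(n, size=n_high, replace=False).tolist())

    high_ids = [i for i in range(n) if i in high_set]
    low_ids = [i for i in range(n) if i not in high_set]
    n_pass_high = round(admet_pass_fraction * len(high_ids))
    n_pass_low = round(admet_pass_fraction * len(low_ids))
    pass_set = set(rng.choice(high_ids, size=n_pass_high, replace=False).tolist()) \
        if high_ids else set()
    if low_ids:
        pass_set |= set(rng.choice(low_ids, size=n_pass_low, replace=False).tolist())

    lo_e, hi_e = min(energy_range_kcal), max(energy_range_kcal)
    records: list[ScreeningRecord] = []
    violations: dict[str, list[str]] = {}
    for i in range(n):
        cid = f"LIB{i:05d}"
        if i in high_set:
            conf_v = float(rng.uniform(0.8, 1.0))
            conf_s = float(rng.uniform(0.8, 1.0))
        else:
            if rng.uniform() < 0.5:
                conf_v = float(rng.uniform(0.0, 0.795))
                conf_s = float(rng.uniform(0.0, 1.0))
            else:
                conf_v = float(rng.uniform(0.0, 1.0))
                conf_s = float(rng.uniform(0.0, 0.795))
        if i in pass_set:
            admet = _passing_admet(rng)
        else:
            admet, rules = _violated_admet(rng)
            violations[cid] = rules
        records.append(ScreeningRecord(
            compound=CompoundRecord(compound_id=cid, smiles=synth_smiles(i)),
            conf_voting=conf_v, conf_stacking=conf_s, admet=admet,
            docking_energy_kcal=float(rng.uniform(lo_e, hi_e))))

    manifest = {
        "seed": seed, "n": n,
        "dual_high": [f"LIB{i:05d}" for i in sorted(high_set)],
        "admet_pass": [f"LIB{i:05d}" for i in sorted(pass_set)],
        "admet_violations": violations,
    }
    return records, manifest


# ---------------------------------------------------------------------------
# dose–response plates
# ---------------------------------------------------------------------------

def synth_dose_response(ic50_um: float, hill: float = 1.0, top: float = 100.0,
                        bottom: float = 0.0,
                        concentrations_um=None,
                        ratio_noise_sd: float = 0.0, seed: int = 0,
                        r_no_compound: float = 2.0, r_no_kinase: float = 0.5,
                        control_replicates: int = 2) -> list[PlateReading]:
    """Plate readings whose Eq.-(5) inhibition reproduces a 4PL curve exactly
    at zero noise. Multiplicative Gaussian noise (sd = ratio_noise_sd, as a
    fraction of the ratio) is applied to every well when requested.
    """
    if ic50_um <= 0:
        raise ValueError("ic50_um must be positive")
    conc = np.asarray(concentrations_um if concentrations_um is not None
                      else dilution_series(), dtype=float)
    if np.any(conc <= 0):
        raise ValueError("concentrations must be positive")
    rng = np.random.default_rng(seed)

    def noisy(ratio: float) -> float:
        if ratio_noise_sd == 0:
            return ratio
        return max(1e-6, ratio * (1.0 + float(rng.normal(0.0, ratio_noise_sd))))

    window = r_no_compound - r_no_kinase
    readings = []
    for k in range(control_replicates):
        readings.append(PlateReading(f"NC{k}", 0.0, noisy(r_no_compound),
                                     "no_compound_control"))
        readings.append(PlateReading(f"NK{k}", 0.0, noisy(r_no_kinase),
                                     "no_kinase_control"))
    for k, c in enumerate(conc):
        inhibition = bottom + (top - bottom) / (1.0 + (ic50_um / c) ** hill)
        ratio = r_no_compound - inhibition / 100.0 * window
        readings.append(PlateReading(f"S{k}", float(c), noisy(ratio), "sample"))
    return readings
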