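import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from jnkscreen.chem_io import CompoundRecord
from jnkscreen.data import (REFERENCE_LIGAND_ENERGY_KCAL, TOP5_CANDIDATES,
                            TOP5_RANKING)
from jnkscreen.screening import (AdmetAnnotation, ScreeningRecord,
                                 activity_filter, consensus_score,
                                 cut_clusters, druglikeness_failures,
                                 druglikeness_filter, library_from_frame,
                                 library_to_frame, rank_candidates,
                                 similarity_cluster)
from jnkscreen.synthetic_data import synth_screening_library


def _rec(cid="X", conf_v=0.9, conf_s=0.9, energy=-9.0, admet=None, smiles="CCO"):
    return ScreeningRecord(CompoundRecord(cid, smiles), conf_voting=conf_v,
                           conf_stacking=conf_s, admet=admet,
                           docking_energy_kcal=energy)


def _good_admet(**overrides):
    kwargs = dict(mw=350.0, logp=2.0, hbd=2, hba=5, logs=-2.0,
                  hia_percent=80.0, mce18=60.0, bbb_permeant=True,
                  tox_flags=frozenset())
    kwargs.update(overrides)
    return AdmetAnnotation(**kwargs)


# ---------------------------------------------------------------------------
# activity filter
# ---------------------------------------------------------------------------

def test_activity_filter_requires_both_confidences_high():
    passing, counts = activity_filter([_rec(conf_v=0.85, conf_s=0.85),
                                       _rec("Y", conf_v=0.85, conf_s=0.79)])
    assert [r.compound_id for r in passing] == ["X"]
    assert counts == {"input": 2, "passed": 1, "failed": 1}


def test_activity_filter_boundary_is_inclusive():
    passing, _ = activity_filter([_rec(conf_v=0.8, conf_s=0.8)])
    assert len(passing) == 1


def test_activity_filter_missing_confidence_is_an_error():
    record = _rec()
    record.conf_stacking = None
    with pytest.raises(ValueError, match="confidence"):
        activity_filter([record])


def test_planted_dual_high_count_recovered_exactly():
    records, manifest = synth_screening_library(n=400, fraction_dual_high=0.1,
                                                seed=5)
    passing, counts = activity_filter(records)
    assert counts["passed"] == 40
    assert {r.compound_id for r in passing} == set(manifest["dual_high"])


# ---------------------------------------------------------------------------
# drug-likeness filter
# ---------------------------------------------------------------------------

def test_druglikeness_all_rules_satisfied_passes():
    passing, tally = druglikeness_filter([_rec(admet=_good_admet())])
    assert len(passing) == 1
    assert all(tally[r] == 0 for r in
               ("Lipinski", "LogS", "HIA", "MCE18", "BBB", "Toxicity"))


@pytest.mark.parametrize("override, rule", [
    ({"logs": -5.0}, "LogS"),
    ({"mw": 600.0}, "Lipinski"),
    ({"hia_percent": 20.0}, "HIA"),
    ({"mce18": 30.0}, "MCE18"),
    ({"bbb_permeant": False}, "BBB"),
    ({"tox_flags": frozenset({"hepatotoxicity"})}, "Toxicity"),
])
def test_druglikeness_single_rule_failures(override, rule):
    admet = _good_admet(**override)
    assert druglikeness_failures(admet) == [rule]
    passing, tally = druglikeness_filter([_rec(admet=admet)])
    assert passing == [] and tally[rule] == 1


def test_lipinski_violation_allowance_knob():
    admet = _good_admet(mw=600.0)  # one violation
    assert druglikeness_failures(admet, lipinski_violations_allowed=1) == []


def test_missing_annotation_is_an_error():
    with pytest.raises(ValueError, match="ADMET"):
        druglikeness_filter([_rec(admet=None)])


def test_filters_commute_as_set_operations():
    records, _ = synth_screening_library(n=300, fraction_dual_high=0.2,
                                         admet_pass_fraction=0.3, seed=8)
    a_then_d, _ = druglikeness_filter(activity_filter(records)[0])
    d_then_a, _ = activity_filter(druglikeness_filter(records)[0])
    assert {r.compound_id for r in a_then_d} == {r.compound_id for r in d_then_a}


# ---------------------------------------------------------------------------
# similarity clustering
# ---------------------------------------------------------------------------

def test_identical_structures_have_unit_similarity():
    frame, _ = similarity_cluster([_rec("A", smiles="c1ccccc1O"),
                                   _rec("B", smiles="Oc1ccccc1")])
    assert frame.loc["A", "B"] == 1.0
    assert np.allclose(np.diag(frame.to_numpy()), 1.0)


def test_disjoint_fingerprints_have_zero_similarity():
    frame, _ = similarity_cluster([_rec("A", smiles="C"),
                                   _rec("B", smiles="O")])
    assert frame.loc["A", "B"] == 0.0


def test_similarity_matrix_is_symmetric_and_tree_recovers_families():
    benzenes = [f"c1ccccc1{tail}" for tail in ("O", "N", "C", "CO", "CC")]
    alkanes = ["C" * k for k in (8, 9, 10, 11, 12)]
    records = [_rec(f"B{i}", smiles=s) for i, s in enumerate(benzenes)] \
        + [_rec(f"A{i}", smiles=s) for i, s in enumerate(alkanes)]
    frame, tree = similarity_cluster(records)
    values = frame.to_numpy()
    assert np.allclose(values, values.T)
    labels = cut_clusters(tree, 2)
    benzene_labels = set(labels[:5])
    alkane_labels = set(labels[5:])
    assert len(benzene_labels) == 1 and len(alkane_labels) == 1
    assert benzene_labels != alkane_labels


# ---------------------------------------------------------------------------
# consensus scoring
# ---------------------------------------------------------------------------

def test_consensus_worked_example_tricin():
    record = _rec("Tricin", conf_v=0.830, conf_s=0.836, energy=-9.007)
    score = consensus_score(record)
    assert score.s_ml == pytest.approx(0.833, abs=5e-4)
    assert record.consensus is score


def test_docking_subscore_is_capped_ratio():
    at_reference = consensus_score(_rec(energy=REFERENCE_LIGAND_ENERGY_KCAL))
    assert at_reference.s_dock == 1.0
    stronger = consensus_score(_rec(energy=-12.0))
    assert stronger.s_dock == 1.0  # out-docks the reference: capped


def test_positive_energy_warns_and_zeroes_docking_score():
    with pytest.warns(UserWarning, match="positive docking energy"):
        score = consensus_score(_rec(energy=2.0))
    assert score.s_dock == 0.0


def test_reference_energy_validation():
    with pytest.raises(ValueError):
        consensus_score(_rec(), reference_energy_kcal=0.0)
    with pytest.raises(ValueError):
        consensus_score(_rec(), reference_energy_kcal=5.0)


def test_lariciresinol_total_score_within_half_percent():
    row = TOP5_CANDIDATES[0]
    record = _rec(row["name"], row["conf_voting"], row["conf_stacking"],
                  row["docking_energy_kcal"])
    score = consensus_score(record)
    assert score.s_total == pytest.approx(row["reported_s_total"], rel=0.005)


@settings(deadline=None, max_examples=60, derandomize=True)
@given(conf_v=st.floats(0, 1), conf_s=st.floats(0, 1),
       energy=st.floats(-12, -1), bump=st.floats(0.001, 0.2))
def test_total_score_monotone_in_confidence_and_affinity(conf_v, conf_s,
                                                         energy, bump):
    base = consensus_score(_rec(conf_v=conf_v, conf_s=conf_s, energy=energy))
    higher_conf = consensus_score(
        _rec(conf_v=min(1.0, conf_v + bump), conf_s=conf_s, energy=energy))
    stronger_dock = consensus_score(
        _rec(conf_v=conf_v, conf_s=conf_s, energy=energy - bump))
    assert higher_conf.s_total >= base.s_total
    assert stronger_dock.s_total >= base.s_total
    for s in (base.s_ml, base.s_dock, base.s_total):
        assert 0.0 <= s <= 1.0


# ---------------------------------------------------------------------------
# ranking
# ---------------------------------------------------------------------------

def test_ranking_reproduces_reference_candidate_order():
    records = [_rec(row["name"], row["conf_voting"], row["conf_stacking"],
                    row["docking_energy_kcal"]) for row in TOP5_CANDIDATES]
    for record in records:
        consensus_score(record)
    frame, _ = rank_candidates(records)
    assert list(frame["compound_id"]) == TOP5_RANKING


def test_ranking_tie_break_is_stable_by_id():
    records = [_rec(cid, conf_v=0.9, conf_s=0.9, energy=-9.0)
               for cid in ("C", "A", "B")]
    for record in records:
        consensus_score(record)
    frame, _ = rank_candidates(records)
    assert list(frame["compound_id"]) == ["A", "B", "C"]


def test_selection_threshold_is_strict():
    records = []
    for cid, s_ml in (("P", 0.81), ("Q", 0.80), ("R", 0.79)):
        record = _rec(cid, conf_v=s_ml, conf_s=s_ml,
                      energy=REFERENCE_LIGAND_ENERGY_KCAL)
        consensus_score(record)
        record.consensus.s_total = s_ml  # exact boundary values
        records.append(record)
    frame, selected = rank_candidates(records, select_threshold=0.8)
    assert [r.compound_id for r in selected] == ["P"]
    assert frame["selected"].sum() == 1


def test_unscored_records_cannot_be_ranked():
    with pytest.raises(ValueError, match="not scored"):
        rank_candidates([_rec()])


def test_library_frame_round_trip():
    records, _ = synth_screening_library(n=25, fraction_dual_high=0.2, seed=3)
    frame = library_to_frame(records)
    back = library_from_frame(frame)
    assert [r.compound_id for r in back] == [r.compound_id for r in records]
    assert [r.conf_voting for r in back] == pytest.approx(
        [r.conf_voting for r in records])
    assert [r.admet.tox_flags for r in back] == [r.admet.tox_flags for r in records]
    assert [r.docking_energy_kcal for r in back] == pytest.approx(
        [r.docking_energy_kcal for r in records])
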