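"""Knockouts, overexpression, edgetic mutations, and the single-node screen."""

import itertools

import numpy as np
import pytest

import hscnet
from hscnet.attractors import find_attractors_complete
from hscnet.logic import Const
from hscnet.network import UnknownNodeError, parse_network
from hscnet.perturbation import (
    PerturbationError,
    PerturbationSpec,
    apply_perturbation,
    compare_to_wildtype,
    perturbation_screen,
)

QUIESCENT = "External_cycling=0,External_quiescence=1"
BOTH = "External_cycling=1,External_quiescence=1"
CYCLING_ONLY = "External_cycling=1,External_quiescence=0"


def _attractors_by_signature(net):
    atts = find_attractors_complete(net)
    groups = {}
    for a in atts:
        sig = (a.input_signature["External_quiescence"],
               a.input_signature["External_cycling"])
        groups.setdefault(sig, []).append(a)
    return groups


def test_knockout_clamps_node_everywhere(hsc):
    ko = apply_perturbation(hsc, PerturbationSpec.knockout("BMI1"))
    assert ko.functions[ko.index("BMI1")] == Const(0)
    for att in find_attractors_complete(ko):
        assert att.value_of("BMI1") == 0


def test_overexpression_clamps_to_one(hsc):
    oe = apply_perturbation(hsc, PerturbationSpec.overexpression("ROS"))
    for att in find_attractors_complete(oe):
        assert att.value_of("ROS") == 1


def test_original_network_is_untouched(hsc):
    before = hsc.functions[hsc.index("BMI1")]
    apply_perturbation(hsc, PerturbationSpec.knockout("BMI1"))
    assert hsc.functions[hsc.index("BMI1")] is before


def test_ko_and_oe_differ_unless_constant(hsc):
    ko = apply_perturbation(hsc, PerturbationSpec.knockout("TP53"))
    oe = apply_perturbation(hsc, PerturbationSpec.overexpression("TP53"))
    i = hsc.index("TP53")
    assert ko.functions[i] != oe.functions[i]


def test_interaction_removal_substitutes_literal(hsc):
    spec = PerturbationSpec(removed_interactions=[("ATM", "MDM2")])
    edited = apply_perturbation(hsc, spec)
    fn = edited.functions[edited.index("MDM2")]
    # (TP53 | MEF) & !CDKN2D with ATM treated as constantly absent
    expected = parse_network(
        "targets, factors\nTP53, TP53\nMEF, MEF\nCDKN2D, CDKN2D\n"
        "MDM2, (TP53 | MEF) & !CDKN2D\n"
    ).functions[3]
    for bits in itertools.product([0, 1], repeat=4):
        assignment = dict(zip(["TP53", "MEF", "CDKN2D", "ATM"], bits))
        assert fn.evaluate(assignment) == expected.evaluate(assignment)


def test_removing_atm_mdm2_edge_destroys_lt_fixed_point(hsc, wt_labels):
    """Edgetic loss of the ATM brake on MDM2 turns the quiescent fixed
    point into a TP53/MDM2 oscillation."""
    spec = PerturbationSpec(removed_interactions=[("ATM", "MDM2")])
    edited = apply_perturbation(hsc, spec)
    groups = _attractors_by_signature(edited)
    quiescent = groups[(1, 0)]
    assert all(a.length > 1 for a in quiescent)
    assert all(a.value_of("TP53") == "osc" for a in quiescent)


@pytest.mark.parametrize(
    "spec,err",
    [
        (PerturbationSpec(clamps={"NOPE": 0}), UnknownNodeError),
        (PerturbationSpec(clamps={"TP53": 2}), PerturbationError),
        (PerturbationSpec(removed_interactions=[("TP53", "RAS")]),
         PerturbationError),  # no such edge
    ],
)
def test_invalid_specs_raise(hsc, spec, err):
    with pytest.raises(err):
        apply_perturbation(hsc, spec)


def test_screen_counts_and_baseline(hsc):
    table = perturbation_screen(hsc)
    conditions = table[["node", "mode"]].drop_duplicates()
    assert len(conditions) == 2 * (36 - 2) + 1
    wt = table[table["mode"] == "WT"]
    assert len(wt) == 4  # the four wildtype attractors


def test_screen_bmi1_ko_blocks_s_phase(hsc):
    table = perturbation_screen(hsc)
    bmi1 = table[(table["node"] == "BMI1") & (table["mode"] == "KO")]
    assert len(bmi1) > 0
    assert (bmi1["S_phase"] == 0).all()


def test_foxo3a_and_atm_ko_stress_only_under_quiescence(hsc):
    """Loss of either ROS guardian triggers ROS/senescence/apoptosis in the
    dormant condition but leaves stimulated conditions at wildtype."""
    wt = find_attractors_complete(hsc)
    for gene in ("FOXO3A", "ATM"):
        ko = apply_perturbation(hsc, PerturbationSpec.knockout(gene))
        groups = _attractors_by_signature(ko)
        (quiescent,) = groups[(1, 0)]
        for marker in ("ROS", "CDKN2A", "CDKN2D", "Apoptosis", "Senescence"):
            assert quiescent.value_of(marker) == 1, (gene, marker)
        report = compare_to_wildtype(wt, find_attractors_complete(ko))
        assert report[BOTH]["differences"] == {}
        assert report[CYCLING_ONLY]["differences"] == {}


def test_tp53_ko_quiescent_attractor(hsc):
    ko = apply_perturbation(hsc, PerturbationSpec.knockout("TP53"))
    (quiescent,) = _attractors_by_signature(ko)[(1, 0)]
    assert quiescent.value_of("GFI1") == 0
    assert quiescent.value_of("ROS") == 1
    assert quiescent.value_of("Apoptosis") == 0


def test_bmi1_tp53_double_ko_rescues_apoptosis(hsc):
    bmi1 = apply_perturbation(hsc, PerturbationSpec.knockout("BMI1"))
    (bmi1_quiescent,) = _attractors_by_signature(bmi1)[(1, 0)]
    assert bmi1_quiescent.value_of("Apoptosis") == 1
    double = apply_perturbation(hsc, PerturbationSpec.knockout("BMI1", "TP53"))
    for atts in _attractors_by_signature(double).values():
        for att in atts:
            assert att.value_of("Apoptosis") == 0


def test_compare_to_wildtype_identity(wt_attractors):
    report = compare_to_wildtype(wt_attractors, wt_attractors)
    assert all(r["differences"] == {} for r in report.values())


def test_compare_to_wildtype_foxo3a_gains(hsc, wt_attractors):
    ko = apply_perturbation(hsc, PerturbationSpec.knockout("FOXO3A"))
    report = compare_to_wildtype(wt_attractors, find_attractors_complete(ko))
    diffs = report[QUIESCENT]["differences"]
    for marker in ("ROS", "Apoptosis", "Senescence"):
        assert diffs[marker] == {"wildtype": 0, "perturbed": 1}


def test_compare_to_wildtype_reports_lost_signature(hsc, wt_attractors):
    missing = [a for a in wt_attractors
               if a.input_signature["External_cycling"] == 1]
    report = compare_to_wildtype(wt_attractors, missing)
    lost = [sig for sig, r in report.items() if r["status"] == "attractor lost"]
    assert len(lost) == 2


def test_mef_ko_restores_tp53_activity(hsc, wt_attractors):
    """MEF loss removes the MDM2 brake: TP53/GFI1 regain activity in every
    condition (they are constantly off in the wildtype stimulated
    attractors) and S-phase entry is impaired under cycling stimulation."""
    ko = apply_perturbation(hsc, PerturbationSpec.knockout("MEF"))
    groups = _attractors_by_signature(ko)
    for sig, atts in groups.items():
        for att in atts:
            assert att.value_of("TP53") in (1, "osc")
            assert att.value_of("GFI1") in (1, "osc")
    for att in groups[(0, 1)]:
        assert att.value_of("S_phase") != 1
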