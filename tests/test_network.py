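"""Network container, file dialect, the HSC fixture, interaction graph."""

import itertools

import numpy as np
import pytest

import hscnet
from hscnet.logic import Not, Var, parse_expression
from hscnet.network import (
    NetworkFormatError,
    UnknownNodeError,
    interaction_graph,
    interaction_graph_sif,
    parse_network,
    write_network,
)

TOY = "targets, factors\nA, B\nB, A\n"


def truth_tables_equal(net_a, net_b):
    """Semantic equality by exhaustive evaluation of every function."""
    assert net_a.node_names == net_b.node_names
    for name, fa, fb in zip(net_a.node_names, net_a.functions, net_b.functions):
        variables = sorted(fa.variables() | fb.variables())
        assert len(variables) <= 10
        for bits in itertools.product([0, 1], repeat=len(variables)):
            assignment = dict(zip(variables, bits))
            assert fa.evaluate(assignment) == fb.evaluate(assignment), name
    return True


def test_parse_minimal_network():
    net = parse_network(TOY)
    assert net.node_names == ["A", "B"]
    assert net.functions[0] == Var("B")
    assert net.input_nodes == []


@pytest.mark.parametrize(
    "text,match",
    [
        ("targets, factors\nA, C\n", "C"),  # undeclared literal
        ("targets, factors\nA, B\nA, B\nB, A\n", "duplicate"),
        ("A, B\nB, A\n", "header"),
        ("targets, factors\nA, B &\nB, A\n", "line 2"),
    ],
)
def test_parse_errors(text, match):
    with pytest.raises(NetworkFormatError, match=match):
        parse_network(text)


def test_comments_and_whitespace_are_ignored():
    net = parse_network("# c\ntargets , factors\n A ,  B  # trailing\nB,A\n")
    assert net.node_names == ["A", "B"]


def test_roundtrip_toy():
    net = parse_network(TOY)
    assert truth_tables_equal(net, parse_network(write_network(net)))


def test_unrepresentable_name_raises_on_write():
    net = hscnet.BooleanNetwork(["a,b", "x"], [Var("x"), Var("x")])
    with pytest.raises(NetworkFormatError):
        write_network(net)


# --- the HSC fixture ------------------------------------------------------

def test_hsc_fixture_basic_shape(hsc):
    assert hsc.n == 36
    assert hsc.input_nodes == ["External_quiescence", "External_cycling"]
    assert hsc.display("TSC1_2") == "TSC1/2"
    assert hsc.display("S_phase") == "S-phase"


def test_hsc_tp53_is_negation_of_mdm2(hsc):
    fn = hsc.functions[hsc.index("TP53")]
    assert fn == Not(Var("MDM2"))


def test_hsc_fixture_roundtrips(hsc):
    assert truth_tables_equal(hsc, parse_network(write_network(hsc)))


# independent hand-coded rules for five nodes, checked exhaustively
ORACLES = {
    "ROS": (
        ["Mitochondria", "ATM", "FOXO3A", "BMI1", "TP53"],
        lambda m, a, f, b, t: int(m or (not a) or (not f) or (not b) or (not t)),
    ),
    "MDM2": (
        ["TP53", "MEF", "CDKN2D", "ATM"],
        lambda t, m, c, a: int((t or m) and (not c) and (not a)),
    ),
    "CCNE1": (
        ["CDKN1C", "CDKN1A", "CDKN1B", "CCND1", "E2F"],
        lambda c1c, c1a, c1b, ccnd, e2f: int(
            (not c1c) and (((not c1a) and (not c1b)) or ccnd) and e2f
        ),
    ),
    "Senescence": (
        ["CDKN2A", "ROS", "TP53", "CDKN1A"],
        lambda a2, ros, tp, a1: int((a2 and ros) or (tp and ros and a1)),
    ),
    "CDKN1A": (
        ["TP53", "FOXO3A", "External_quiescence", "GFI1", "cMYC"],
        lambda t, f, q, g, m: int((t or f or q or g) and not m),
    ),
}


@pytest.mark.parametrize("node", sorted(ORACLES))
def test_fixture_functions_match_hand_coded_oracle(hsc, node):
    regs, rule = ORACLES[node]
    fn = hsc.functions[hsc.index(node)]
    assert fn.variables() == set(regs)
    for bits in itertools.product([0, 1], repeat=len(regs)):
        assert fn.evaluate(dict(zip(regs, bits))) == rule(*bits), bits


def test_interaction_graph_counts_and_signs(hsc):
    g = interaction_graph(hsc)
    assert g.graph["n_nodes"] == 36
    assert g.graph["n_edges"] == 77  # distinct pairs incl input self-loops
    assert g.graph["n_literal_occurrences"] == 78  # ROS twice in Senescence
    assert g.edges[("TP53", "GFI1")]["sign"] == "+"
    assert g.edges[("ATM", "MDM2")]["sign"] == "-"
    assert g.has_edge("External_quiescence", "External_quiescence")


def test_dual_sign_edge():
    net = parse_network("targets, factors\nA, B | !B\nB, B\n")
    g = interaction_graph(net)
    assert g.edges[("B", "A")]["sign"] == "dual"


def test_sif_export_uses_display_names(hsc):
    sif = interaction_graph_sif(hsc)
    lines = sif.strip().splitlines()
    assert len(lines) == 77
    assert "TP53\t+\tGFI1" in lines
    assert any(line.startswith("TSC1/2\t") for line in lines)


def test_input_nodes_require_positive_self_literal():
    net = parse_network("targets, factors\nA, !A\nB, B\n")
    assert net.input_nodes == ["B"]
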