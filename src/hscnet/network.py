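"""Boolean network container, the text-file dialect, and interaction graphs.

A network is an ordered list of node names plus one update function per
node.  The node order is load-bearing: it fixes bit positions for every
state encoding downstream (node 0 is the least-significant bit).

The file dialect is the ``targets, factors`` format: a header line, then
one ``name, expression`` line per node; ``#`` starts a line comment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .logic import (
    And,
    Const,
    Expr,
    ExpressionError,
    Not,
    Or,
    Var,
    format_expression,
    parse_expression,
)


class NetworkFormatError(ValueError):
    """Syntax or semantic error in a network definition file."""


class UnknownNodeError(NetworkFormatError):
    """An expression references a node that is not declared."""


@dataclass
class CompiledFunction:
    """Truth-table form of one node's update rule.

    ``regulators`` are node indices; ``table`` has ``2**len(regulators)``
    entries indexed by the regulator bits with regulator 0 least significant.
    """

    regulators: np.ndarray  # int64 indices
    table: np.ndarray  # uint8, length 2**k


@dataclass
class BooleanNetwork:
    """An ordered Boolean network under synchronous-update semantics."""

    node_names: list[str]
    functions: list[Expr]
    display_names: dict[str, str] = field(default_factory=dict)
    _compiled: list[CompiledFunction] | None = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self):
        if len(self.node_names) != len(self.functions):
            raise ValueError("one function per node is required")
        if len(set(self.node_names)) != len(self.node_names):
            raise ValueError("node names must be unique")
        index = set(self.node_names)
        for name, fn in zip(self.node_names, self.functions):
            for lit, _ in fn.literals():
                if lit not in index:
                    raise UnknownNodeError(
                        f"function of {name!r} references unknown node {lit!r}"
                    )

    # -- basic introspection -------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.node_names)

    def index(self, name: str) -> int:
        try:
            return self.node_names.index(name)
        except ValueError:
            raise UnknownNodeError(f"unknown node {name!r}") from None

    @property
    def input_nodes(self) -> list[str]:
        """Nodes whose function is exactly their own positive literal."""
        return [
            name
            for name, fn in zip(self.node_names, self.functions)
            if isinstance(fn, Var) and fn.name == name
        ]

    def display(self, name: str) -> str:
        return self.display_names.get(name, name)

    # -- compiled truth tables ----------------------------------------------

    def compiled(self) -> list[CompiledFunction]:
        """Per-node truth tables for vectorized evaluation (cached)."""
        if self._compiled is None:
            compiled = []
            for fn in self.functions:
                regs = sorted(fn.variables(), key=self.index)
                reg_idx = np.array([self.index(r) for r in regs], dtype=np.int64)
                k = len(regs)
                table = np.empty(2**k, dtype=np.uint8)
                for row in range(2**k):
                    assignment = {r: (row >> j) & 1 for j, r in enumerate(regs)}
                    table[row] = fn.evaluate(assignment)
                compiled.append(CompiledFunction(reg_idx, table))
            self._compiled = compiled
        return self._compiled

    @classmethod
    def from_truth_tables(
        cls,
        node_names: Sequence[str],
        regulators: Sequence[Sequence[int]],
        tables: Sequence[np.ndarray],
        display_names: Mapping[str, str] | None = None,
    ) -> "BooleanNetwork":
        """Build a network from explicit truth tables.

        Expressions are synthesized in disjunctive normal form so the
        network serializes through the text dialect like any other.
        """
        names = list(node_names)
        functions: list[Expr] = []
        compiled: list[CompiledFunction] = []
        for regs, table in zip(regulators, tables):
            table = np.asarray(table, dtype=np.uint8)
            k = len(regs)
            if table.shape != (2**k,):
                raise ValueError("truth table size must be 2**len(regulators)")
            functions.append(_dnf_from_table([names[r] for r in regs], table))
            compiled.append(
                CompiledFunction(np.asarray(regs, dtype=np.int64), table)
            )
        net = cls(names, functions, dict(display_names or {}))
        net._compiled = compiled
        return net


def _dnf_from_table(reg_names: list[str], table: np.ndarray) -> Expr:
    ones = np.flatnonzero(table)
    if len(ones) == 0:
        return Const(0)
    if len(ones) == len(table):
        return Const(1)
    minterms = []
    for row in ones:
        lits = [
            Var(name) if (row >> j) & 1 else Not(Var(name))
            for j, name in enumerate(reg_names)
        ]
        minterms.append(lits[0] if len(lits) == 1 else And(tuple(lits)))
    return minterms[0] if len(minterms) == 1 else Or(tuple(minterms))


# ---------------------------------------------------------------------------
# File dialect

def parse_network(
    text: str, display_names: Mapping[str, str] | None = None
) -> BooleanNetwork:
    """Parse a ``targets, factors`` definition into a network.

    Raises :class:`NetworkFormatError` (with the offending line number) on
    syntax errors, duplicate targets, or undeclared literals.
    """
    names: list[str] = []
    exprs: list[Expr] = []
    seen: set[str] = set()
    header_seen = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if not header_seen:
            normalized = [p.strip().lower() for p in line.split(",")]
            if normalized != ["targets", "factors"]:
                raise NetworkFormatError(
                    f"line {lineno}: expected 'targets, factors' header"
                )
            header_seen = True
            continue
        if "," not in line:
            raise NetworkFormatError(
                f"line {lineno}: expected 'name, expression'"
            )
        name, expr_text = (p.strip() for p in line.split(",", 1))
        if not name:
            raise NetworkFormatError(f"line {lineno}: empty target name")
        if name in seen:
            raise NetworkFormatError(
                f"line {lineno}: duplicate definition of node {name!r}"
            )
        seen.add(name)
        try:
            expr = parse_expression(expr_text)
        except ExpressionError as exc:
            raise NetworkFormatError(f"line {lineno}: {exc}") from exc
        names.append(name)
        exprs.append(expr)
    if not header_seen:
        raise NetworkFormatError("missing 'targets, factors' header")
    if not names:
        raise NetworkFormatError("no node definitions found")
    return BooleanNetwork(names, exprs, dict(display_names or {}))


def write_network(net: BooleanNetwork) -> str:
    """Serialize to the ``targets, factors`` dialect.

    Round-trips: ``parse_network(write_network(net))`` has the same nodes
    and the same truth tables as ``net``.
    """
    lines = ["targets, factors"]
    for name, fn in zip(net.node_names, net.functions):
        if "," in name or any(c.isspace() for c in name):
            raise NetworkFormatError(
                f"node name {name!r} is not representable in the file dialect"
            )
        lines.append(f"{name}, {format_expression(fn)}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Interaction graph

def interaction_graph(net: BooleanNetwork) -> nx.DiGraph:
    """Signed regulator→target graph derived from literal polarity.

    One edge per distinct (regulator, target) pair with attribute
    ``sign`` in ``{'+', '-', 'dual'}``.  Graph attributes report both
    counting conventions: ``n_edges`` (distinct pairs, including input
    self-loops) and ``n_literal_occurrences`` (every literal counted,
    so a regulator appearing twice in one rule counts twice).
    """
    g = nx.DiGraph()
    g.add_nodes_from(net.node_names)
    occurrences = 0
    for target, fn in zip(net.node_names, net.functions):
        polarity: dict[str, set[bool]] = {}
        for reg, negated in fn.literals():
            occurrences += 1
            polarity.setdefault(reg, set()).add(negated)
        for reg, negs in polarity.items():
            sign = "dual" if len(negs) == 2 else ("-" if True in negs else "+")
            g.add_edge(reg, target, sign=sign)
    g.graph["n_nodes"] = net.n
    g.graph["n_edges"] = g.number_of_edges()
    g.graph["n_literal_occurrences"] = occurrences
    return g


def interaction_graph_sif(net: BooleanNetwork) -> str:
    """SIF-like TSV export: ``regulator<TAB>sign<TAB>target`` per edge."""
    g = interaction_graph(net)
    rows = [
        f"{net.display(u)}\t{d['sign']}\t{net.display(v)}"
        for u, v, d in g.edges(data=True)
    ]
    return "\n".join(rows) + "\n"
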