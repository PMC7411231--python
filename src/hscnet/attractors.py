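"""Attractor enumeration under synchronous updates.

Complete search decomposes the state space by the input-node assignments
(inputs are fixed points of their own update functions, so each of the
2^#inputs input signatures is a closed subspace), propagates eventually
constant nodes, and exhaustively enumerates the transition system of the
remaining free nodes.  The result is certified complete: either every
attractor of the network is returned — fixed points and limit cycles of
any length — or an explicit :class:`CompletenessError` is raised when a
reduced subspace is too large to enumerate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .dynamics import batch_attractor_keys, cycle_from_state, decode, encode
from .network import BooleanNetwork


class CompletenessError(RuntimeError):
    """Complete search could not be certified within resource bounds."""


@dataclass
class Attractor:
    """A recurrent state cycle.

    ``states`` holds the cycle in canonical rotation (minimal integer
    encoding first); stepping maps each row to the next, cyclically.
    ``input_signature`` gives the constant input-node values shared by
    every cycle state.  ``basin_fraction`` is a sampling estimate when
    produced by the sampled search.
    """

    states: np.ndarray  # (L, n) uint8
    node_names: list[str]
    input_signature: dict[str, int]
    basin_fraction: float | None = None
    basin_samples: int | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def length(self) -> int:
        return self.states.shape[0]

    @property
    def is_fixed_point(self) -> bool:
        return self.length == 1

    @property
    def key(self) -> int:
        """Canonical identity: minimal integer encoding over the cycle."""
        return int(encode(self.states[0], len(self.node_names))[0])

    def value_of(self, name: str):
        """Constant 0/1 of a node across the cycle, or ``'osc'``."""
        col = self.states[:, self.node_names.index(name)]
        if (col == col[0]).all():
            return int(col[0])
        return "osc"

    def __eq__(self, other):
        return (
            isinstance(other, Attractor)
            and self.node_names == other.node_names
            and self.states.shape == other.states.shape
            and bool((self.states == other.states).all())
        )

    def __hash__(self):
        return hash((tuple(self.node_names), self.key, self.length))


def _restrict_table(
    regulators: np.ndarray, table: np.ndarray, assigned: dict[int, int]
) -> tuple[list[int], np.ndarray]:
    """Partially evaluate a truth table given fixed regulator values."""
    free = [int(r) for r in regulators if int(r) not in assigned]
    k_free = len(free)
    reduced = np.empty(2**k_free, dtype=np.uint8)
    for row in range(2**k_free):
        full_idx = 0
        fi = 0
        for j, r in enumerate(regulators):
            r = int(r)
            if r in assigned:
                bit = assigned[r]
            else:
                bit = (row >> fi) & 1
                fi += 1
            full_idx |= bit << j
        reduced[row] = table[full_idx]
    return free, reduced


def _propagate_constants(
    net: BooleanNetwork, assigned: dict[int, int]
) -> dict[int, int]:
    """Least fixpoint of eventually-constant-node propagation.

    A node whose update function becomes constant once already-assigned
    nodes are substituted holds that constant in every attractor of the
    subspace, so it can be assigned too; iterate to closure.
    """
    assigned = dict(assigned)
    compiled = net.compiled()
    changed = True
    while changed:
        changed = False
        for i, fn in enumerate(compiled):
            if i in assigned:
                continue
            _, reduced = _restrict_table(fn.regulators, fn.table, assigned)
            if (reduced == reduced[0]).all():
                # Constant even over the node's own value (if self-regulating),
                # so the node equals this constant from the next step onward.
                assigned[i] = int(reduced[0])
                changed = True
    return assigned


def _enumerate_subspace(
    net: BooleanNetwork, assigned: dict[int, int], limit: int
) -> list[np.ndarray]:
    """All attractor cycles in the subspace fixed by ``assigned``.

    Enumerates the reduced transition system over the free nodes and
    extracts the cycles of its functional graph by pointer doubling.
    Returns full-width cycles in canonical rotation.
    """
    n = net.n
    free = [i for i in range(n) if i not in assigned]
    m = len(free)
    if m > limit:
        raise CompletenessError(
            f"reduced subspace has {m} free nodes (> limit {limit}); "
            "complete search cannot be certified"
        )
    free_pos = {node: j for j, node in enumerate(free)}
    compiled = net.compiled()

    size = 1 << m
    codes = np.arange(size, dtype=np.int64)
    succ = np.zeros(size, dtype=np.int64)
    for node in free:
        fn = compiled[node]
        fr, table = _restrict_table(fn.regulators, fn.table, assigned)
        if fr:
            idx = (codes >> free_pos[fr[0]]) & 1
            for j in range(1, len(fr)):
                idx = idx | (((codes >> free_pos[fr[j]]) & 1) << j)
            vals = table[idx].astype(np.int64)
        else:
            vals = np.full(size, int(table[0]), dtype=np.int64)
        succ |= vals << free_pos[node]

    # After 2**m steps every state sits on a cycle; the image of the
    # 2**m-fold iterate is exactly the set of cycle states.
    far = succ
    for _ in range(max(m, 1)):
        far = far[far]
    cycle_codes = np.unique(far)

    cycles: list[np.ndarray] = []
    visited: set[int] = set()
    for c in cycle_codes.tolist():
        if c in visited:
            continue
        cyc = [c]
        visited.add(c)
        nxt = int(succ[c])
        while nxt != c:
            cyc.append(nxt)
            visited.add(nxt)
            nxt = int(succ[nxt])
        # lift reduced codes to full-width states
        full = np.empty((len(cyc), n), dtype=np.uint8)
        for i, val in assigned.items():
            full[:, i] = val
        arr = np.asarray(cyc, dtype=np.uint64)
        for node, j in free_pos.items():
            full[:, node] = ((arr >> np.uint64(j)) & np.uint64(1)).astype(np.uint8)
        shift = int(np.argmin(encode(full, n)))
        cycles.append(np.roll(full, -shift, axis=0))
    return cycles


def find_attractors_complete(
    net: BooleanNetwork, limit: int = 24
) -> list[Attractor]:
    """Enumerate ALL attractors of the synchronous transition system.

    Complete for arbitrary cycle lengths.  ``limit`` bounds the number of
    free nodes a reduced subspace may have (2**limit states are
    enumerated); beyond it a :class:`CompletenessError` is raised rather
    than returning a silently truncated result.
    """
    input_names = net.input_nodes
    input_idx = [net.index(name) for name in input_names]
    attractors: list[Attractor] = []
    for combo in range(1 << len(input_idx)):
        base = {idx: (combo >> j) & 1 for j, idx in enumerate(input_idx)}
        assigned = _propagate_constants(net, base)
        cycles = _enumerate_subspace(net, assigned, limit)
        for cyc in cycles:
            signature = {
                name: int(cyc[0, net.index(name)]) for name in input_names
            }
            attractors.append(
                Attractor(
                    states=cyc,
                    node_names=list(net.node_names),
                    input_signature=signature,
                    metadata={
                        "method": "exhaustive-reduced-subspace",
                        "free_nodes": net.n - len(assigned),
                    },
                )
            )
    attractors.sort(key=lambda a: a.key)
    return attractors


def find_attractors_sampled(
    net: BooleanNetwork, n_samples: int, seed: int
) -> list[Attractor]:
    """Attractors reached from ``n_samples`` uniform random start states.

    A subset of the complete answer, with basin-fraction estimates from
    the sample.  Deterministic given ``seed``.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    states = rng.integers(0, 2, size=(n_samples, net.n), dtype=np.uint8)
    keys = batch_attractor_keys(net, states)
    uniq, counts = np.unique(keys, return_counts=True)
    input_names = net.input_nodes
    attractors = []
    for key, count in zip(uniq.tolist(), counts.tolist()):
        anchor = decode(np.uint64(key), net.n)[0]
        cyc = cycle_from_state(net, anchor)
        signature = {name: int(cyc[0, net.index(name)]) for name in input_names}
        attractors.append(
            Attractor(
                states=cyc,
                node_names=list(net.node_names),
                input_signature=signature,
                basin_fraction=count / n_samples,
                basin_samples=n_samples,
                metadata={"method": "sampled"},
            )
        )
    attractors.sort(key=lambda a: a.key)
    return attractors


def attractors_frame(net: BooleanNetwork, attractors: Sequence[Attractor]):
    """Attractor table: rows = nodes (display names), one column per
    attractor state (fixed points give one column each)."""
    import pandas as pd

    columns = {}
    for i, att in enumerate(attractors, start=1):
        for t in range(att.length):
            label = f"A{i}" if att.length == 1 else f"A{i}.s{t}"
            columns[label] = att.states[t]
    return pd.DataFrame(
        columns, index=[net.display(name) for name in net.node_names]
    )


def attractors_to_dict(
    net: BooleanNetwork, attractors: Sequence[Attractor]
) -> list[dict]:
    """JSON-ready representation of an attractor list."""
    out = []
    for att in attractors:
        out.append(
            {
                "length": att.length,
                "input_signature": {
                    net.display(k): v for k, v in att.input_signature.items()
                },
                "states": [
                    {net.display(name): int(v) for name, v in zip(att.node_names, row)}
                    for row in att.states
                ],
                "basin_fraction": att.basin_fraction,
                "metadata": att.metadata,
            }
        )
    return out
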