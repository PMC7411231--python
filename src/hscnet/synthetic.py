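"""Random Boolean networks and random state samplers.

The null ensemble for the robustness comparison: networks matched to a
template in node count and per-node in-degree (template mode) or with a
fixed in-degree, with truth-table outputs drawn independently at a
configurable bias.  Self-loops are permitted — the template itself has
self-regulating input nodes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .network import BooleanNetwork


@dataclass
class RandomNetworkSpec:
    """Specification of one random Boolean network draw.

    ``in_degrees[i]`` is the number of distinct regulators of node *i*;
    ``truth_table_bias`` is the probability a truth-table row outputs 1.
    """

    n_nodes: int
    in_degrees: tuple[int, ...]
    truth_table_bias: float = 0.5
    seed: int | None = None
    essential_inputs: bool = True

    def __post_init__(self):
        if len(self.in_degrees) != self.n_nodes:
            raise ValueError("one in-degree per node is required")
        if any(not 0 <= k <= self.n_nodes for k in self.in_degrees):
            raise ValueError("in-degrees must lie in [0, n_nodes]")
        if not 0 < self.truth_table_bias < 1:
            raise ValueError("truth_table_bias must lie in (0, 1)")

    @classmethod
    def from_template(
        cls, net: BooleanNetwork, bias: float = 0.5, seed: int | None = None
    ) -> "RandomNetworkSpec":
        degrees = tuple(len(fn.regulators) for fn in net.compiled())
        return cls(net.n, degrees, bias, seed)

    @classmethod
    def fixed_k(
        cls, n_nodes: int, k: int, bias: float = 0.5, seed: int | None = None
    ) -> "RandomNetworkSpec":
        return cls(n_nodes, (k,) * n_nodes, bias, seed)


def random_network(
    spec: RandomNetworkSpec, rng: np.random.Generator | None = None
) -> BooleanNetwork:
    """Draw one random Boolean network.

    Each node receives ``in_degrees[i]`` regulators drawn uniformly
    without replacement (self-loops allowed) and an independent random
    truth table.  With ``essential_inputs`` (the default) tables are
    redrawn until every listed regulator actually influences the output,
    so the realized wiring density matches the specification instead of
    silently containing fictitious inputs.  Deterministic given
    ``spec.seed`` (or a supplied generator).
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    n = spec.n_nodes
    names = [f"x{i}" for i in range(n)]
    regulators = []
    tables = []
    for k in spec.in_degrees:
        regs = np.sort(rng.choice(n, size=k, replace=False))
        while True:
            table = (rng.random(2**k) < spec.truth_table_bias).astype(np.uint8)
            if not spec.essential_inputs or _all_inputs_essential(table, k):
                break
        regulators.append(regs.tolist())
        tables.append(table)
    return BooleanNetwork.from_truth_tables(names, regulators, tables)


def _all_inputs_essential(table: np.ndarray, k: int) -> bool:
    """True iff every one of the k inputs changes the output somewhere."""
    if k == 0:
        return True
    rows = np.arange(2**k)
    for j in range(k):
        if (table[rows] == table[rows ^ (1 << j)]).all():
            return False
    return True


def random_network_from_template(
    net: BooleanNetwork,
    bias: float = 0.5,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> BooleanNetwork:
    """Random network with the template's node count and in-degrees."""
    spec = RandomNetworkSpec.from_template(net, bias=bias, seed=seed)
    return random_network(spec, rng=rng)


def random_states(n: int, count: int, seed: int) -> np.ndarray:
    """``count`` states drawn uniformly from the 2**n state space."""
    if count < 1:
        raise ValueError("count must be >= 1")
    rng = np.random.default_rng(seed)
    return rng.integers(0, 2, size=(count, n), dtype=np.uint8)
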