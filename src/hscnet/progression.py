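"""Niche-driven progression cascades between HSC phenotypes.

Starting from a fixed-point attractor, the external input bits are
overwritten and the network is simulated to convergence in the new
input subspace.  Reported step counts follow the convention that the
first computed successor of the input-modified start state is "time
step zero", i.e. ``reported_steps = raw_transitions - 1`` (the start
state itself is not counted); both counts are exposed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .attractors import Attractor
from .dynamics import Trajectory, encode, trajectory
from .network import BooleanNetwork
from .phenotypes import classify_attractor


class ProgressionError(ValueError):
    """Invalid start attractor or input change."""


@dataclass
class ProgressionResult:
    start_label: str
    target_label: str
    input_change: dict[str, int]
    trajectory: Trajectory
    raw_transitions: int
    reported_steps: int
    destination: Attractor


def progress(
    net: BooleanNetwork,
    start: Attractor,
    input_change: Mapping[str, int],
    max_steps: int = 1000,
) -> ProgressionResult:
    """Drive a fixed-point attractor into a new input condition.

    ``input_change`` may assign only input nodes.  The destination is the
    attractor the modified trajectory settles into; for the unperturbed
    HSC model every destination is again a fixed point.
    """
    if not start.is_fixed_point:
        raise ProgressionError("start attractor must be a fixed point")
    inputs = set(net.input_nodes)
    for name in input_change:
        if name not in inputs:
            raise ProgressionError(f"{name!r} is not an input node")

    s0 = start.states[0].copy()
    for name, val in input_change.items():
        s0[net.index(name)] = int(val)

    traj = trajectory(net, s0, max_steps=max_steps)
    if traj.truncated:
        raise ProgressionError("no attractor reached within max_steps")

    dest_states = traj.states[traj.attractor_entry :]
    codes = encode(dest_states, net.n)
    shift = int(np.argmin(codes))
    dest_cycle = np.roll(dest_states, -shift, axis=0)
    destination = Attractor(
        states=dest_cycle,
        node_names=list(net.node_names),
        input_signature={
            name: int(dest_cycle[0, net.index(name)]) for name in net.input_nodes
        },
        metadata={"method": "progression"},
    )

    # first trajectory index whose state equals a destination-cycle state
    dest_codes = set(int(c) for c in encode(dest_cycle, net.n))
    traj_codes = encode(traj.states, net.n)
    first_hit = next(
        t for t, c in enumerate(traj_codes) if int(c) in dest_codes
    )
    raw_transitions = first_hit
    reported_steps = max(raw_transitions - 1, 0)

    return ProgressionResult(
        start_label=classify_attractor(start),
        target_label=classify_attractor(destination),
        input_change=dict(input_change),
        trajectory=traj,
        raw_transitions=raw_transitions,
        reported_steps=reported_steps,
        destination=destination,
    )


def progression_matrix(net: BooleanNetwork, res: ProgressionResult) -> pd.DataFrame:
    """Nodes × time-steps 0/1 matrix of the cascade.

    Columns: ``start`` (the input-modified start state), then ``t0`` …
    ``t<reported_steps>``; the destination (last) column is flagged with
    a trailing ``*``.
    """
    n_cols = res.raw_transitions + 1
    states = res.trajectory.states[:n_cols]
    labels = ["start"] + [f"t{t}" for t in range(n_cols - 1)]
    labels[-1] += "*"
    return pd.DataFrame(
        states.T,
        index=[net.display(name) for name in net.node_names],
        columns=labels,
    )
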