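"""Synchronous-update dynamics: stepping, trajectories, Hamming distance.

States are numpy ``uint8`` vectors ordered by the network's node order
(bit *i* is node *i*).  Batches of states are 2-D arrays with one state
per row; all stepping is vectorized over the batch.  Integer encodings
use node 0 as the least-significant bit and fit in ``uint64`` (n ≤ 64).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .network import BooleanNetwork


class DimensionError(ValueError):
    """State width does not match the network."""


def as_state(net: BooleanNetwork, values) -> np.ndarray:
    """Coerce a sequence or {node: value} mapping into a state vector."""
    if isinstance(values, Mapping):
        state = np.zeros(net.n, dtype=np.uint8)
        for name, val in values.items():
            state[net.index(name)] = int(val)
        return state
    state = np.asarray(values, dtype=np.uint8)
    if state.shape != (net.n,):
        raise DimensionError(
            f"state width {state.shape} does not match network size {net.n}"
        )
    return state


def encode(states: np.ndarray, n: int) -> np.ndarray:
    """Integer encoding of a state or batch (node 0 = least-significant bit)."""
    states = np.atleast_2d(np.asarray(states, dtype=np.uint64))
    if states.shape[1] != n:
        raise DimensionError("state width does not match network size")
    weights = np.uint64(1) << np.arange(n, dtype=np.uint64)
    return (states * weights).sum(axis=1)


def decode(codes, n: int) -> np.ndarray:
    """Inverse of :func:`encode`; returns a batch of state vectors."""
    codes = np.atleast_1d(np.asarray(codes, dtype=np.uint64))
    bits = np.arange(n, dtype=np.uint64)
    return ((codes[:, None] >> bits[None, :]) & np.uint64(1)).astype(np.uint8)


def step_batch(net: BooleanNetwork, states: np.ndarray) -> np.ndarray:
    """Synchronous successor of every row of ``states``."""
    states = np.atleast_2d(states)
    if states.shape[1] != net.n:
        raise DimensionError("state width does not match network size")
    out = np.empty_like(states)
    for i, fn in enumerate(net.compiled()):
        if len(fn.regulators) == 0:
            out[:, i] = fn.table[0]
            continue
        idx = states[:, fn.regulators[0]].astype(np.int64)
        for j in range(1, len(fn.regulators)):
            idx += states[:, fn.regulators[j]].astype(np.int64) << j
        out[:, i] = fn.table[idx]
    return out


def step(net: BooleanNetwork, state) -> np.ndarray:
    """One synchronous update of a single state: s'_i = f_i(s) for all i."""
    state = as_state(net, state)
    return step_batch(net, state[None, :])[0]


@dataclass
class Trajectory:
    """A simulated path: ``states[t]`` is the state at time step *t*.

    ``attractor_entry`` is the index of the first state that later recurs
    (None if the run was truncated before a repeat); ``cycle_length`` is
    the period of the recurrent part.
    """

    states: np.ndarray  # (T, n) uint8
    attractor_entry: int | None
    cycle_length: int | None

    @property
    def truncated(self) -> bool:
        return self.attractor_entry is None

    def __len__(self) -> int:
        return self.states.shape[0]


def trajectory(net: BooleanNetwork, s0, max_steps: int = 1000) -> Trajectory:
    """Iterate synchronous updates from ``s0`` until a state repeats.

    The trajectory records every visited state; cycle detection uses a
    hash of integer encodings (transients in the networks studied here
    are tens of steps, so memory is not a concern).
    """
    if max_steps < 1:
        raise ValueError("max_steps must be >= 1")
    state = as_state(net, s0)
    seen: dict[int, int] = {}
    states = [state]
    code = int(encode(state, net.n)[0])
    seen[code] = 0
    for _ in range(max_steps):
        state = step_batch(net, states[-1][None, :])[0]
        code = int(encode(state, net.n)[0])
        if code in seen:
            entry = seen[code]
            return Trajectory(
                np.array(states, dtype=np.uint8), entry, len(states) - entry
            )
        seen[code] = len(states)
        states.append(state)
    return Trajectory(np.array(states, dtype=np.uint8), None, None)


def trajectory_frame(net: BooleanNetwork, traj: Trajectory):
    """Trajectory as a nodes × time-steps DataFrame of 0/1 (display names)."""
    import pandas as pd

    data = traj.states.T
    return pd.DataFrame(
        data,
        index=[net.display(name) for name in net.node_names],
        columns=[f"t{t}" for t in range(traj.states.shape[0])],
    )


def hamming(x, y) -> tuple[int, float]:
    """Hamming distance between two equal-width states.

    Returns ``(count, normalized)`` where ``normalized = count / n``.
    """
    x = np.asarray(x, dtype=np.uint8)
    y = np.asarray(y, dtype=np.uint8)
    if x.shape != y.shape:
        raise DimensionError("states have different widths")
    count = int((x != y).sum())
    return count, count / x.size


# ---------------------------------------------------------------------------
# Batch attractor identification (Brent cycle detection, vectorized)

def batch_attractor_keys(
    net: BooleanNetwork, states: np.ndarray, max_steps: int = 100_000
) -> np.ndarray:
    """Canonical attractor key for every row of ``states``.

    The key of an attractor is the minimal integer encoding over its
    cycle, so two states share a key iff their trajectories settle into
    the same attractor.  Cycle detection is Brent's algorithm run in
    lock-step over the whole batch; converged rows are compacted away.
    """
    states = np.atleast_2d(np.asarray(states, dtype=np.uint8))
    n = net.n
    batch = states.shape[0]

    cur = states.copy()
    anchor = encode(cur, n)
    power = np.ones(batch, dtype=np.int64)
    since = np.zeros(batch, dtype=np.int64)
    active_rows = np.arange(batch)
    cycle_states = np.empty((batch, n), dtype=np.uint8)

    steps = 0
    while active_rows.size:
        if steps >= max_steps:
            raise RuntimeError("cycle detection exceeded max_steps")
        cur = step_batch(net, cur)
        since += 1
        enc = encode(cur, n)
        found = enc == anchor
        if found.any():
            cycle_states[active_rows[found]] = cur[found]
            keep = ~found
            cur = cur[keep]
            anchor = anchor[keep]
            power = power[keep]
            since = since[keep]
            active_rows = active_rows[keep]
            enc = enc[keep]
        reset = since == power
        if reset.any():
            anchor[reset] = enc[reset]
            power[reset] *= 2
            since[reset] = 0
        steps += 1

    # Walk each detected cycle once, tracking the minimal encoding.
    cur = cycle_states
    start = encode(cur, n)
    best = start.copy()
    active_rows = np.arange(batch)
    keys = np.empty(batch, dtype=np.uint64)
    while active_rows.size:
        cur = step_batch(net, cur)
        enc = encode(cur, n)
        np.minimum(best, enc, out=best)
        done = enc == start
        if done.any():
            keys[active_rows[done]] = best[done]
            keep = ~done
            cur = cur[keep]
            start = start[keep]
            best = best[keep]
            active_rows = active_rows[keep]
    return keys


def cycle_from_state(
    net: BooleanNetwork, state: np.ndarray, max_len: int = 100_000
) -> np.ndarray:
    """The attractor cycle containing ``state`` (which must lie on a cycle),
    rotated so the minimal-encoding state comes first."""
    states = [np.asarray(state, dtype=np.uint8)]
    start = int(encode(states[0], net.n)[0])
    for _ in range(max_len):
        nxt = step_batch(net, states[-1][None, :])[0]
        if int(encode(nxt, net.n)[0]) == start:
            break
        states.append(nxt)
    else:
        raise RuntimeError("state does not return to itself within max_len")
    arr = np.array(states, dtype=np.uint8)
    codes = encode(arr, net.n)
    shift = int(np.argmin(codes))
    return np.roll(arr, -shift, axis=0)
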