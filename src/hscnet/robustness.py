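"""Noise robustness of Boolean networks.

Two complementary measures:

* **Basin robustness** — sample random initial states, toggle *k* node
  assignments in a copy, compute the attractor of original and copy
  independently, and report the fraction of identical attractor pairs.
* **Transition robustness** — mean normalized Hamming distance between
  the one-step successors of random states and their single-bit-flipped
  copies; compared against an ensemble of size/in-degree-matched random
  networks via a left-tail empirical p-value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .dynamics import batch_attractor_keys, step_batch
from .network import BooleanNetwork
from .synthetic import random_network_from_template, random_states


@dataclass
class RobustnessConfig:
    """Sampling design for the robustness measures.

    ``flip_mode='with_replacement'`` draws each flipped node
    independently and uniformly, so two flips may cancel on the same
    node; ``'distinct'`` draws k distinct nodes.
    """

    n_states: int = 100_000
    k_flips: tuple[int, ...] = (1, 2, 3)
    n_reps: int = 3
    seed: int = 0
    flip_mode: str = "with_replacement"

    def __post_init__(self):
        if self.n_states < 1:
            raise ValueError("n_states must be >= 1")
        if isinstance(self.k_flips, int):
            self.k_flips = (self.k_flips,)
        if any(k < 0 for k in self.k_flips):
            raise ValueError("k_flips must be >= 0")
        if self.flip_mode not in ("with_replacement", "distinct"):
            raise ValueError(f"unknown flip_mode {self.flip_mode!r}")


def flip_bits(
    states: np.ndarray,
    k: int,
    rng: np.random.Generator | int,
    mode: str = "with_replacement",
) -> np.ndarray:
    """Toggle ``k`` node assignments in each state (row).

    With-replacement mode draws the k nodes independently, so hitting
    the same node twice cancels out; distinct mode toggles k different
    nodes.  Deterministic given the generator state / seed.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    states = np.atleast_2d(np.asarray(states, dtype=np.uint8))
    batch, n = states.shape
    out = states.copy()
    if k == 0:
        return out
    if mode == "with_replacement":
        picks = rng.integers(0, n, size=(batch, k))
        rows = np.repeat(np.arange(batch), k)
        toggles = np.zeros((batch, n), dtype=np.uint8)
        np.add.at(toggles, (rows, picks.ravel()), 1)
        out ^= toggles & 1
    elif mode == "distinct":
        for b in range(batch):
            idx = rng.choice(n, size=k, replace=False)
            out[b, idx] ^= 1
    else:
        raise ValueError(f"unknown flip mode {mode!r}")
    return out


def basin_robustness(
    net: BooleanNetwork, cfg: RobustnessConfig
) -> pd.DataFrame:
    """Same-attractor fraction per flip count, repeated over seed blocks.

    Returns one row per (k, repetition) with the fraction of sampled
    states whose attractor is unchanged by the flips, plus per-k mean
    and standard deviation across repetitions.
    """
    root = np.random.SeedSequence(cfg.seed)
    rep_seeds = root.spawn(cfg.n_reps)
    rows = []
    for rep, seq in enumerate(rep_seeds):
        rng = np.random.default_rng(seq)
        states = rng.integers(0, 2, size=(cfg.n_states, net.n), dtype=np.uint8)
        base_keys = batch_attractor_keys(net, states)
        for k in cfg.k_flips:
            flipped = flip_bits(states, k, rng, mode=cfg.flip_mode)
            flip_keys = batch_attractor_keys(net, flipped)
            rows.append(
                {
                    "k_flips": k,
                    "rep": rep,
                    "fraction_same": float((base_keys == flip_keys).mean()),
                }
            )
    df = pd.DataFrame(rows)
    summary = df.groupby("k_flips")["fraction_same"].agg(["mean", "std"])
    df.attrs["summary"] = summary
    return df


def transition_robustness(
    net: BooleanNetwork,
    n_states: int = 1000,
    k_flips: int = 1,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> float:
    """Mean normalized Hamming distance after a one-step update.

    For each sampled state, flip ``k_flips`` node assignments, compute
    the synchronous successor of both versions, and average the Hamming
    distance between the successor pairs divided by the node count.
    This equals the network's average sensitivity divided by n when
    ``k_flips=1``.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    states = rng.integers(0, 2, size=(n_states, net.n), dtype=np.uint8)
    flipped = flip_bits(states, k_flips, rng)
    succ_a = step_batch(net, states)
    succ_b = step_batch(net, flipped)
    return float((succ_a != succ_b).sum(axis=1).mean() / net.n)


def robustness_pvalue(
    model_hd: float, ensemble_hds: Iterable[float]
) -> float:
    """Left-tail empirical p-value of the model against the ensemble.

    Fraction of random networks whose mean normalized Hamming distance
    is less than or equal to the model's; 0 when the model is more
    robust than every ensemble member.
    """
    hds = np.asarray(list(ensemble_hds), dtype=float)
    if hds.size == 0:
        raise ValueError("ensemble must be non-empty")
    return float((hds <= model_hd).mean())


@dataclass
class RobustnessSummary:
    """Full transition-robustness comparison against the random null."""

    model_mean_hd: float
    ensemble_mean_hds: np.ndarray
    p_value: float
    ensemble_size: int
    quantile_5: float

    @property
    def ensemble_mean(self) -> float:
        return float(self.ensemble_mean_hds.mean())

    def to_dict(self) -> dict:
        return {
            "model_mean_hd": self.model_mean_hd,
            "ensemble_mean": self.ensemble_mean,
            "ensemble_size": self.ensemble_size,
            "p_value": self.p_value,
            "quantile_5": self.quantile_5,
            "model_below_quantile_5": self.model_mean_hd < self.quantile_5,
        }


def ensemble_transition_robustness(
    net: BooleanNetwork,
    n_networks: int = 1000,
    n_states: int = 1000,
    seed: int = 0,
) -> RobustnessSummary:
    """Transition robustness of the model vs a matched random ensemble.

    The null ensemble preserves the model's node count and per-node
    in-degrees, with unbiased random truth tables.  Each ensemble
    member's statistic uses its own seeded state sample.
    """
    root = np.random.SeedSequence(seed)
    model_seq, ens_seq = root.spawn(2)
    model_hd = transition_robustness(
        net, n_states=n_states, rng=np.random.default_rng(model_seq)
    )
    hds = np.empty(n_networks, dtype=float)
    for i, seq in enumerate(ens_seq.spawn(n_networks)):
        net_rng = np.random.default_rng(seq)
        rnd = random_network_from_template(net, rng=net_rng)
        hds[i] = transition_robustness(rnd, n_states=n_states, rng=net_rng)
    return RobustnessSummary(
        model_mean_hd=model_hd,
        ensemble_mean_hds=hds,
        p_value=robustness_pvalue(model_hd, hds),
        ensemble_size=n_networks,
        quantile_5=float(np.quantile(hds, 0.05)),
    )
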