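"""In-silico interventions: knockouts, overexpressions, edgetic mutations.

A knockout clamps a node's update function to constant 0 and an
overexpression to constant 1.  A loss-of-interaction (edgetic) mutation
removes one regulator's influence on one target by substituting the
regulator's literal with constant 0 inside that target's function only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .attractors import Attractor, find_attractors_complete
from .logic import Const
from .network import BooleanNetwork, UnknownNodeError
from .phenotypes import (
    PhenotypeRule,
    classify_attractor,
    default_rules,
)


class PerturbationError(ValueError):
    """Invalid clamp or interaction removal."""


@dataclass
class PerturbationSpec:
    """Node clamps plus interaction deletions.

    ``clamps`` maps node name → fixed value (0 = knockout, 1 =
    overexpression); ``removed_interactions`` lists (regulator, target)
    pairs whose edge is deleted edgetically.
    """

    clamps: dict[str, int] = field(default_factory=dict)
    removed_interactions: list[tuple[str, str]] = field(default_factory=list)

    @classmethod
    def knockout(cls, *nodes: str) -> "PerturbationSpec":
        return cls(clamps={n: 0 for n in nodes})

    @classmethod
    def overexpression(cls, *nodes: str) -> "PerturbationSpec":
        return cls(clamps={n: 1 for n in nodes})

    def label(self) -> str:
        parts = [f"{n}-{'KO' if v == 0 else 'OE'}" for n, v in self.clamps.items()]
        parts += [f"del({r}->{t})" for r, t in self.removed_interactions]
        return "+".join(parts) if parts else "wildtype"


def apply_perturbation(
    net: BooleanNetwork, spec: PerturbationSpec
) -> BooleanNetwork:
    """Return a new network with the perturbation applied.

    The original network is not modified.  Clamped nodes get constant
    update functions; removed interactions substitute the regulator's
    literal by constant 0 in the target's function.
    """
    for name, val in spec.clamps.items():
        net.index(name)  # raises UnknownNodeError
        if val not in (0, 1):
            raise PerturbationError(
                f"clamp value for {name!r} must be 0 or 1, got {val!r}"
            )
    functions = list(net.functions)
    for reg, target in spec.removed_interactions:
        net.index(reg)
        t_idx = net.index(target)
        fn = functions[t_idx]
        if reg not in fn.variables():
            raise PerturbationError(
                f"no interaction {reg!r} -> {target!r} to remove"
            )
        functions[t_idx] = fn.substitute({reg: Const(0)})
    for name, val in spec.clamps.items():
        functions[net.index(name)] = Const(val)
    return BooleanNetwork(
        list(net.node_names), functions, dict(net.display_names)
    )


def perturbation_screen(
    net: BooleanNetwork,
    rules: Sequence[PhenotypeRule] | None = None,
    include_inputs: bool = False,
    limit: int = 24,
) -> pd.DataFrame:
    """All single-node knockout and overexpression conditions.

    Runs complete attractor search per condition (plus the wildtype
    baseline) and annotates phenotypes.  One tidy row per attractor:
    ``node, mode, input_signature, attractor_id, cycle_length, phenotype``
    plus one column per network node (0/1 or ``'osc'``).  Input nodes are
    excluded by default — their values define the niche conditions.
    """
    rules = default_rules() if rules is None else rules
    inputs = set(net.input_nodes)
    conditions: list[tuple[str, str, PerturbationSpec]] = [
        ("wildtype", "WT", PerturbationSpec())
    ]
    for name in net.node_names:
        if name in inputs and not include_inputs:
            continue
        conditions.append((name, "KO", PerturbationSpec.knockout(name)))
        conditions.append((name, "OE", PerturbationSpec.overexpression(name)))

    rows = []
    for node, mode, spec in conditions:
        perturbed = apply_perturbation(net, spec)
        for i, att in enumerate(find_attractors_complete(perturbed, limit=limit)):
            row = {
                "node": node,
                "mode": mode,
                "input_signature": _signature_label(att),
                "attractor_id": i,
                "cycle_length": att.length,
                "phenotype": classify_attractor(att, rules),
            }
            for name in net.node_names:
                row[name] = att.value_of(name)
            rows.append(row)
    return pd.DataFrame(rows)


def _signature_label(att: Attractor) -> str:
    return ",".join(f"{k}={v}" for k, v in sorted(att.input_signature.items()))


def compare_to_wildtype(
    wt: Sequence[Attractor], perturbed: Sequence[Attractor]
) -> dict[str, dict]:
    """Per-input-condition node differences between two attractor lists.

    For each input signature present in either list, reports the nodes
    whose attractor values differ; a signature with attractors on only
    one side is reported as lost/gained, and a signature with multiple
    attractors on a side is flagged (``multivalued``) rather than raised.
    """
    def by_sig(atts):
        groups: dict[str, list[Attractor]] = {}
        for a in atts:
            groups.setdefault(_signature_label(a), []).append(a)
        return groups

    wt_groups, pe_groups = by_sig(wt), by_sig(perturbed)
    report: dict[str, dict] = {}
    for sig in sorted(set(wt_groups) | set(pe_groups)):
        w, p = wt_groups.get(sig), pe_groups.get(sig)
        if w is None:
            report[sig] = {"status": "attractor gained", "differences": {}}
            continue
        if p is None:
            report[sig] = {"status": "attractor lost", "differences": {}}
            continue
        if len(w) > 1 or len(p) > 1:
            report[sig] = {"status": "multivalued", "differences": {}}
            continue
        wa, pa = w[0], p[0]
        diffs = {}
        for name in wa.node_names:
            wv, pv = wa.value_of(name), pa.value_of(name)
            if wv != pv:
                diffs[name] = {"wildtype": wv, "perturbed": pv}
        report[sig] = {"status": "compared", "differences": diffs}
    return report
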