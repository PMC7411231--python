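"""Mapping attractors onto hematopoietic stem cell phenotypes.

Each phenotype is a marker rule: a set of nodes required active, a set
required inactive, and optionally a required input signature.  The four
built-in rules describe the dormant LT-HSC, the activated-but-quiescent
ST-HSC, the proliferating cycling HSC, and the biologically implausible
unstimulated condition (both niche inputs absent).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .attractors import Attractor
from .network import BooleanNetwork

LT_HSC = "LT-HSC"
ST_HSC = "ST-HSC"
CYCLING = "Cycling HSC"
UNSTIMULATED = "Unstimulated"
UNCLASSIFIED = "unclassified"


@dataclass
class PhenotypeRule:
    label: str
    required_active: frozenset[str] = frozenset()
    required_inactive: frozenset[str] = frozenset()
    input_signature: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        self.required_active = frozenset(self.required_active)
        self.required_inactive = frozenset(self.required_inactive)
        if self.required_active & self.required_inactive:
            raise ValueError(
                f"rule {self.label!r}: a marker cannot be both active and inactive"
            )

    def matches(self, attractor: Attractor) -> bool:
        """True iff every cycle state satisfies all marker requirements.

        For cyclic attractors a marker only counts as (in)active when it
        holds that value in every state of the cycle; an oscillating
        marker fails both requirements.  A rule referencing nodes the
        attractor's network lacks never matches.
        """
        known = set(attractor.node_names)
        if not (
            self.required_active | self.required_inactive | set(self.input_signature)
        ) <= known:
            return False
        for name, val in self.input_signature.items():
            if attractor.input_signature.get(name, attractor.value_of(name)) != val:
                return False
        for name in self.required_active:
            if attractor.value_of(name) != 1:
                return False
        for name in self.required_inactive:
            if attractor.value_of(name) != 0:
                return False
        return True

    def violations(self, attractor: Attractor) -> list[str]:
        """Human-readable list of marker conditions the attractor breaks."""
        out = []
        for name in sorted(self.required_active):
            v = attractor.value_of(name)
            if v != 1:
                out.append(f"{name} expected active, is {v}")
        for name in sorted(self.required_inactive):
            v = attractor.value_of(name)
            if v != 0:
                out.append(f"{name} expected inactive, is {v}")
        for name, val in sorted(self.input_signature.items()):
            if attractor.input_signature.get(name, attractor.value_of(name)) != val:
                out.append(f"input {name} expected {val}")
        return out


def default_rules() -> list[PhenotypeRule]:
    """Marker rules for the four HSC model attractors.

    LT-HSC: deeply dormant — no ROS or mTORC1 signalling, active stress
    guardians and cell-cycle inhibitors, TP53 on, no S-phase.  ST-HSC:
    metabolically activated but still out of cycle — ROS/mTORC1/cMYC on,
    FOXO3A and TP53 off, CDKN1C still on.  Cycling HSC: cyclins and
    S-phase on.  Unstimulated: both niche inputs absent.
    """
    return [
        PhenotypeRule(
            LT_HSC,
            required_active={"FOXO3A", "TP53", "CDKN1C", "CDKN1A", "CDKN1B", "GFI1"},
            required_inactive={"ROS", "mTORC1", "cMYC", "S_phase"},
        ),
        PhenotypeRule(
            ST_HSC,
            required_active={"ROS", "mTORC1", "cMYC", "CDKN1C"},
            required_inactive={"FOXO3A", "TP53", "S_phase"},
        ),
        PhenotypeRule(
            CYCLING,
            required_active={"CCND1", "CCNE1", "S_phase"},
        ),
        PhenotypeRule(
            UNSTIMULATED,
            input_signature={"External_quiescence": 0, "External_cycling": 0},
        ),
    ]


def classify_attractor(
    attractor: Attractor, rules: Sequence[PhenotypeRule] | None = None
) -> str:
    """Label of the unique matching rule, or ``'unclassified'``.

    Returns ``'unclassified'`` when no rule matches or several do; the
    perturbation reports use :meth:`PhenotypeRule.violations` to describe
    partial matches instead of forcing a label.
    """
    rules = default_rules() if rules is None else rules
    hits = [r.label for r in rules if r.matches(attractor)]
    return hits[0] if len(hits) == 1 else UNCLASSIFIED


def classify_all(
    attractors: Sequence[Attractor],
    rules: Sequence[PhenotypeRule] | None = None,
    include_unstimulated: bool = False,
) -> dict[str, Attractor]:
    """Label → attractor for a full attractor list.

    By default the unstimulated attractor is excluded from reports (the
    no-stimulation condition is not biologically plausible) but it can be
    requested explicitly.
    """
    rules = default_rules() if rules is None else rules
    out: dict[str, Attractor] = {}
    for att in attractors:
        label = classify_attractor(att, rules)
        if label == UNSTIMULATED and not include_unstimulated:
            continue
        out[label] = att
    return out


def phenotype_frame(net: BooleanNetwork, attractors, rules=None):
    """Attractor table: rows = nodes, columns labeled by phenotype."""
    import pandas as pd

    rules = default_rules() if rules is None else rules
    columns = {}
    for att in attractors:
        label = classify_attractor(att, rules)
        for t in range(att.length):
            name = label if att.length == 1 else f"{label}.s{t}"
            columns[name] = att.states[t]
    return pd.DataFrame(
        columns, index=[net.display(n) for n in net.node_names]
    )
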