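import numpy as np
import pytest
from hypothesis import settings

import hscnet

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def hsc():
    return hscnet.hsc_model()


@pytest.fixture(scope="session")
def wt_attractors(hsc):
    return hscnet.find_attractors_complete(hsc)


@pytest.fixture(scope="session")
def wt_labels(hsc, wt_attractors):
    return hscnet.classify_all(wt_attractors, include_unstimulated=True)


def brute_force_attractors(net):
    """Independent oracle: enumerate every state of the full state space,
    follow successors computed by direct expression evaluation, and return
    the set of attractor cycles in canonical (min-first) rotation.

    Exponential in n; intended for n <= ~14.
    """
    n = net.n
    names = net.node_names

    def successor(code):
        assignment = {names[i]: (code >> i) & 1 for i in range(n)}
        out = 0
        for i, fn in enumerate(net.functions):
            out |= fn.evaluate(assignment) << i
        return out

    succ = [successor(c) for c in range(2**n)]
    color = [0] * (2**n)  # 0 unvisited, 1 in-progress-id, 2 done
    cycles = set()
    for start in range(2**n):
        if color[start]:
            continue
        path = []
        pos = {}
        cur = start
        while color[cur] == 0:
            color[cur] = 1
            pos[cur] = len(path)
            path.append(cur)
            cur = succ[cur]
        if color[cur] == 1 and cur in pos:
            cyc = path[pos[cur]:]
            k = cyc.index(min(cyc))
            cycles.add(tuple(cyc[k:] + cyc[:k]))
        for s in path:
            color[s] = 2
    return cycles


def canonical_cycles(attractors, n):
    """Package attractors as canonical tuples of integer encodings."""
    out = set()
    for att in attractors:
        codes = [
            int(hscnet.dynamics.encode(s, n)[0]) for s in att.states
        ]
        out.add(tuple(codes))
    return out
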