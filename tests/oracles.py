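"""Independent brute-force oracles used by the unit and acceptance tests.

These enumerate over all internal-node states and cladogenetic outcomes
using only the process tables and per-branch matrix exponentials — no
pruning, masking, or sampling code from the package's likelihood path.
All-biomes-always-available settings only (single stratum); exponential in
tip count, so 3–4-tip trees only.
"""

import numpy as np
from scipy.linalg import expm

from biomeshift.ranges import RangeStateSpace, build_process


def _setup(tree, occ, spec, avail):
    space = RangeStateSpace(avail)
    proc = build_process(space, spec)
    Q, tab = proc.Q[0], proc.clado[0]
    tip_state = dict(zip(occ.taxa, occ.state_masks()))
    P = {v: expm(Q * tree.branch_lengths[v]) for v in range(tree.n_nodes)}

    def clado(anc):
        rows = tab.rows_for(anc)
        return [(int(tab.left[r]), int(tab.right[r]), tab.prob[r]) for r in rows]

    return space, P, tip_state, clado


def _configs(tree, P, tip_state, clado, n_states, v, s_top):
    """All (weight, {node: pre-split state}) configurations below node v,
    given branch-top state s_top on the branch above v."""
    if v < tree.n_tips:
        w = P[v][s_top, tip_state[tree.tip_labels[v]]]
        return [(w, {})] if w > 0 else []
    out = []
    cl, cr = tree.children[v]
    for s in range(1, n_states):
        p = P[v][s_top, s]
        if p == 0:
            continue
        for l, r, w in clado(s):
            for wl, al in _configs(tree, P, tip_state, clado, n_states, cl, l):
                for wr, ar in _configs(tree, P, tip_state, clado, n_states,
                                       cr, r):
                    out.append((p * w * wl * wr, {v: s, **al, **ar}))
    return out


def _root_configs(tree, occ, spec, avail):
    space, P, tip_state, clado = _setup(tree, occ, spec, avail)
    root = tree.root
    cl, cr = tree.children[root]
    prior = 1.0 / (space.n_states - 1)
    out = []
    for s in range(1, space.n_states):
        for l, r, w in clado(s):
            for wl, al in _configs(tree, P, tip_state, clado, space.n_states,
                                   cl, l):
                for wr, ar in _configs(tree, P, tip_state, clado,
                                       space.n_states, cr, r):
                    out.append((prior * w * wl * wr, {root: s, **al, **ar}))
    return space, out


def brute_force_loglik(tree, occ, spec, avail):
    """Dense enumeration of the tip-data likelihood on a small tree."""
    _, configs = _root_configs(tree, occ, spec, avail)
    return np.log(sum(w for w, _ in configs))


def brute_force_node_marginals(tree, occ, spec, avail):
    """Marginal pre-split state probabilities for every internal node."""
    space, configs = _root_configs(tree, occ, spec, avail)
    total = sum(w for w, _ in configs)
    marg = {v: np.zeros(space.n_states) for v in tree.children}
    for w, assign in configs:
        for node, s in assign.items():
            marg[node][s] += w / total
    return marg
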