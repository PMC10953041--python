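"""Independent brute-force oracles for the test suite.

Everything here is written from the model definitions directly —
dense matrix exponentials, exhaustive enumeration over subsets and node
state assignments — and deliberately shares no code with the package's
pruning/ancestral machinery.
"""

from __future__ import annotations

import itertools

import numpy as np
import scipy.linalg

NULL = 0


def bits(mask: int) -> list[int]:
    return [a for a in range(mask.bit_length()) if mask >> a & 1]


def connected_bruteforce(mask: int, adjacency) -> bool:
    """Connectivity by exhaustive union-find over occupied areas."""
    members = bits(mask)
    parent = {a: a for a in members}

    def find(a):
        while parent[a] != a:
            a = parent[a]
        return a

    for a, b in itertools.combinations(members, 2):
        if adjacency[a][b]:
            parent[find(a)] = find(b)
    return len({find(a) for a in members}) == 1


def enumerate_ranges_bruteforce(adjacency, max_size: int) -> set[int]:
    n = len(adjacency)
    out = set()
    for mask in range(1, 1 << n):
        if 1 <= mask.bit_count() <= max_size and connected_bruteforce(mask, adjacency):
            out.add(mask)
    return out


def clado_outcomes_bruteforce(parent: int) -> dict[tuple[int, int], float]:
    """All ordered daughter pairs valid under DEC cladogenesis, uniform."""
    if parent.bit_count() == 1:
        return {(parent, parent): 1.0}
    n = parent.bit_length()
    valid = []
    for l in range(1, 1 << n):
        for r in range(1, 1 << n):
            subset_symp = (
                (l == parent and r.bit_count() == 1 and (r & parent) == r)
                or (r == parent and l.bit_count() == 1 and (l & parent) == l)
            )
            vic = (
                (l & r) == 0 and (l | r) == parent
                and (l.bit_count() == 1 or r.bit_count() == 1)
            )
            if subset_symp or vic:
                valid.append((l, r))
    w = 1.0 / len(valid)
    return {pair: w for pair in valid}


def dense_rate_matrix(states: list[int], allowed: set[int], adjacency,
                      d: float, e: float, max_size: int) -> np.ndarray:
    """Generator over an explicit state list (null first), loops only."""
    n = len(states)
    q = np.zeros((n, n))
    for i, s in enumerate(states):
        if s == NULL or s not in allowed:
            continue
        for j, t in enumerate(states):
            if i == j:
                continue
            gained = t & ~s
            lost = s & ~t
            if t != NULL and t not in allowed:
                continue
            if lost == 0 and gained.bit_count() == 1 and t.bit_count() <= max_size:
                a = bits(gained)[0]
                nsrc = sum(1 for b in bits(s) if adjacency[b][a])
                q[i, j] = d * nsrc
            elif gained == 0 and lost.bit_count() == 1:
                q[i, j] = e
    np.fill_diagonal(q, -q.sum(axis=1))
    return q


class DecOracle:
    """Exhaustive DEC likelihood on tiny trees.

    ``geo`` is the package GeoModel (shared *definitions*: state list,
    slices, allowed sets), but all probability math below is dense and
    enumerative.
    """

    def __init__(self, geo, d: float, e: float):
        self.geo = geo
        self.states = list(geo.global_state_space)
        self.qs = [
            dense_rate_matrix(
                self.states, set(geo.allowed_ranges_per_slice[k]),
                geo.slices[k].adjacency, d, e, geo.max_range_size)
            for k in range(len(geo.slices))
        ]

    def branch_prob(self, t_young: float, t_old: float) -> np.ndarray:
        """Transition probability matrix across a branch, slice by slice."""
        key = (round(t_young, 12), round(t_old, 12))
        if not hasattr(self, "_pcache"):
            self._pcache = {}
        if key in self._pcache:
            return self._pcache[key]
        cuts = sorted({t_young, t_old}
                      | {b for sl in self.geo.slices
                         for b in (sl.younger_bound, sl.older_bound)
                         if t_young < b < t_old})
        p = np.eye(len(self.states))
        # build from the old end downwards: P_total = P_seg1 @ P_seg2 ...
        for lo, hi in zip(cuts[:-1], cuts[1:]):
            k = self.geo.slice_at(0.5 * (lo + hi))
            p = scipy.linalg.expm(self.qs[k] * (hi - lo)) @ p
        self._pcache[key] = p
        return p

    def tip_vector(self, obs) -> np.ndarray:
        v = np.zeros(len(self.states))
        for i, s in enumerate(self.states):
            if s == NULL:
                continue
            if obs.ambiguous:
                v[i] = float((s & obs.observed_areas) == obs.observed_areas)
            else:
                v[i] = float(s == obs.observed_areas)
        return v

    def _allowed_at(self, age: float) -> set[int]:
        return set(self.geo.allowed_ranges_per_slice[self.geo.slice_at(age)])

    def partial(self, node, observations) -> np.ndarray:
        """Conditional likelihood of data below ``node`` per node state."""
        if node.is_tip:
            v = self.tip_vector(observations[node.label])
            allowed = self._allowed_at(node.age)
            return np.array([
                vi if s in allowed else 0.0 for vi, s in zip(v, self.states)
            ])
        c0, c1 = node.children
        below0 = self.partial(c0, observations)
        below1 = self.partial(c1, observations)
        p0 = self.branch_prob(c0.age, node.age)
        p1 = self.branch_prob(c1.age, node.age)
        corner0 = p0 @ below0
        corner1 = p1 @ below1
        allowed = self._allowed_at(node.age)
        out = np.zeros(len(self.states))
        for i, s in enumerate(self.states):
            if s == NULL or s not in allowed:
                continue
            total = 0.0
            for (l, r), w in clado_outcomes_bruteforce(s).items():
                li = self.states.index(l) if l in self.states else None
                ri = self.states.index(r) if r in self.states else None
                if li is None or ri is None:
                    continue
                total += w * corner0[li] * corner1[ri]
            out[i] = total
        return out

    def loglik(self, tree, observations) -> float:
        v = self.partial(tree.root, observations)
        allowed = self._allowed_at(tree.root_age)
        lik = sum(vi for vi, s in zip(v, self.states) if s != NULL and s in allowed)
        return float(np.log(lik))

    def joint_marginals(self, tree, observations) -> dict[int, np.ndarray]:
        """Node marginals by exhaustive summation over all internal-node
        (and tip) state assignments; normalized per node."""
        nodes = list(tree.postorder())
        nstates = len(self.states)
        probs = {nd.index: np.zeros(nstates) for nd in nodes}
        allowed_root = self._allowed_at(tree.root_age)
        order = list(reversed(nodes))

        def weight_of(states_by_node) -> float:
            w = 1.0
            for nd in nodes:
                if nd.is_tip:
                    continue
                c0, c1 = nd.children
                s = self.states[states_by_node[nd.index]]
                # sum over scenarios consistent with the daughters' states
                p0 = self.branch_prob(c0.age, nd.age)
                p1 = self.branch_prob(c1.age, nd.age)
                total = 0.0
                for (l, r), ww in clado_outcomes_bruteforce(s).items():
                    if l not in self.states or r not in self.states:
                        continue
                    li, ri = self.states.index(l), self.states.index(r)
                    total += (ww * p0[li, states_by_node[c0.index]]
                              * p1[ri, states_by_node[c1.index]])
                w *= total
            return w

        # full exhaustive enumeration over assignments
        idx_lists = []
        for nd in order:
            allowed = allowed_root if nd.parent is None else self._allowed_at(nd.age)
            ok = [si for si, s in enumerate(self.states)
                  if s != NULL and s in allowed]
            if nd.is_tip:
                tv = self.tip_vector(observations[nd.label])
                ok = [si for si in ok if tv[si] > 0]
            idx_lists.append((nd, ok))
        for combo in itertools.product(*[ok for _nd, ok in idx_lists]):
            states_by_node = {nd.index: si for (nd, _ok), si in zip(idx_lists, combo)}
            w = weight_of(states_by_node)
            for idx, si in states_by_node.items():
                probs[idx][si] += w
        for idx in probs:
            probs[idx] /= probs[idx].sum()
        return probs


def min_reconciliation_changes(parent_best: int, left_best: int,
                               right_best: int) -> int:
    """Minimal total anagenetic changes implied by the best ranges at a
    node and its daughters, by exhaustive enumeration of cladogenetic
    scenarios (symmetric difference between each daughter's inherited
    corner and its own best range)."""
    best = None
    for (l, r) in clado_outcomes_bruteforce(parent_best):
        cost = ((l ^ left_best).bit_count() + (r ^ right_best).bit_count())
        best = cost if best is None else min(best, cost)
    return best
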