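"""Directed modularity of a partition and its stochastic optimization.

For a directed graph with ω arcs and a partition P = {V_1..V_M}, the
modularity is

    M(P) = Σ_i ( ω_{ViVi}/ω − ω_i^out · ω_i^in / ω² )

where ω_{ViVi} counts arcs internal to module i and ω_i^out / ω_i^in count
arcs whose source / target lies in module i (internal arcs included in
both, the standard directed null term).  Arc signs are ignored.  The
network-level modularity is approximated by repeated stochastic local
search: each trial runs greedy label moves from a singleton start plus an
agglomerative merge phase, and the reported network value is the mean over
trials (the best trial is also kept).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import NetworkValidationError, Partition, SignedDigraph

_EPS = 1e-12


@dataclass(frozen=True)
class ModularityResult:
    trial_values: tuple[float, ...]
    mean_modularity: float
    best_partition: Partition
    best_value: float
    trials: int
    seed: int

    def __post_init__(self) -> None:
        assert len(self.trial_values) == self.trials >= 1


def _module_term(e: int, out: int, inc: int, omega: int, exclusive: bool) -> float:
    if exclusive:
        out, inc = out - e, inc - e
    return e / omega - (out * inc) / (omega * omega)


def partition_modularity(
    net: SignedDigraph,
    part: Partition,
    exclusive_boundary: bool = False,
) -> float:
    """Evaluate M(P); signs are ignored.

    ``exclusive_boundary`` switches the null term to count only arcs that
    cross the module boundary (the literal "starting or ending nodes only"
    reading) instead of the standard inclusive degree sums.
    """
    if net.n_arcs == 0:
        raise NetworkValidationError("modularity undefined for a zero-arc network")
    part.validate_against(net)
    m = part.n_modules
    e = [0] * m
    out = [0] * m
    inc = [0] * m
    mod_of = part.module_of
    for src, tgt, _ in net.arcs:
        a, b = mod_of[src], mod_of[tgt]
        out[a] += 1
        inc[b] += 1
        if a == b:
            e[a] += 1
    omega = net.n_arcs
    return sum(
        _module_term(e[i], out[i], inc[i], omega, exclusive_boundary) for i in range(m)
    )


class _LabelState:
    """Mutable module bookkeeping for the local search.

    Maintains per-module internal-arc counts and degree sums so that move
    and merge gains are O(deg) instead of O(ω).
    """

    def __init__(self, net: SignedDigraph, exclusive: bool):
        self.n = net.n_nodes
        self.omega = net.n_arcs
        self.exclusive = exclusive
        self.out_deg = [0] * self.n
        self.in_deg = [0] * self.n
        self.self_loop = [0] * self.n
        self.out_nbrs: list[list[int]] = [[] for _ in range(self.n)]
        self.in_nbrs: list[list[int]] = [[] for _ in range(self.n)]
        for i, j, _ in net.arcs_indexed:
            self.out_deg[i] += 1
            self.in_deg[j] += 1
            if i == j:
                self.self_loop[i] = 1
            else:
                self.out_nbrs[i].append(j)
                self.in_nbrs[j].append(i)
        # singleton start
        self.labels = list(range(self.n))
        self.e = {v: self.self_loop[v] for v in range(self.n)}
        self.out = {v: self.out_deg[v] for v in range(self.n)}
        self.inc = {v: self.in_deg[v] for v in range(self.n)}
        self.size = {v: 1 for v in range(self.n)}
        self._next_free = self.n

    def term(self, c: int) -> float:
        return _module_term(self.e[c], self.out[c], self.inc[c], self.omega, self.exclusive)

    def value(self) -> float:
        return sum(self.term(c) for c in self.e)

    def _links_to(self, v: int, c: int) -> int:
        """Arcs between v and module c, excluding v's self-loop."""
        lab = self.labels
        return sum(1 for u in self.out_nbrs[v] if lab[u] == c) + sum(
            1 for u in self.in_nbrs[v] if lab[u] == c
        )

    def move_gain(self, v: int, b: int) -> float:
        a = self.labels[v]
        if a == b:
            return 0.0
        d_a = self._links_to(v, a)
        d_b = self._links_to(v, b)
        sl = self.self_loop[v]
        od, idg = self.out_deg[v], self.in_deg[v]
        before = self.term(a) + (self.term(b) if b in self.e else 0.0)
        after = _module_term(
            self.e[a] - d_a - sl, self.out[a] - od, self.inc[a] - idg, self.omega, self.exclusive
        )
        eb = self.e.get(b, 0)
        ob = self.out.get(b, 0)
        ib = self.inc.get(b, 0)
        after += _module_term(eb + d_b + sl, ob + od, ib + idg, self.omega, self.exclusive)
        # a drained empty contributes a zero term automatically
        return after - before

    def move(self, v: int, b: int) -> None:
        a = self.labels[v]
        d_a = self._links_to(v, a)
        d_b = self._links_to(v, b)
        sl = self.self_loop[v]
        self.e[a] -= d_a + sl
        self.out[a] -= self.out_deg[v]
        self.inc[a] -= self.in_deg[v]
        self.size[a] -= 1
        if self.size[a] == 0:
            del self.e[a], self.out[a], self.inc[a], self.size[a]
        self.e[b] = self.e.get(b, 0) + d_b + sl
        self.out[b] = self.out.get(b, 0) + self.out_deg[v]
        self.inc[b] = self.inc.get(b, 0) + self.in_deg[v]
        self.size[b] = self.size.get(b, 0) + 1
        self.labels[v] = b

    def local_pass(self, order: np.ndarray) -> bool:
        """One sweep of best single-node moves; True if anything moved."""
        moved = False
        for v in order:
            v = int(v)
            a = self.labels[v]
            candidates = {self.labels[u] for u in self.out_nbrs[v]}
            candidates |= {self.labels[u] for u in self.in_nbrs[v]}
            candidates.discard(a)
            # escaping to a fresh singleton module is always an option
            if self.size[a] > 1:
                candidates.add(self._next_free)
            best_b, best_gain = a, _EPS
            for b in sorted(candidates):
                g = self.move_gain(v, b)
                if g > best_gain:
                    best_b, best_gain = b, g
            if best_b != a:
                if best_b == self._next_free:
                    self._next_free += 1
                self.move(v, best_b)
                moved = True
        return moved

    def merge_pass(self) -> bool:
        """Greedily merge connected module pairs while any merge helps."""
        merged_any = False
        while True:
            cross: dict[tuple[int, int], int] = {}
            lab = self.labels
            for v in range(self.n):
                for u in self.out_nbrs[v]:
                    a, b = lab[v], lab[u]
                    if a != b:
                        cross[(a, b)] = cross.get((a, b), 0) + 1
            pairs = {tuple(sorted(k)) for k in cross}
            best = None
            best_gain = _EPS
            for a, b in sorted(pairs):
                e_ab = cross.get((a, b), 0) + cross.get((b, a), 0)
                gain = (
                    _module_term(
                        self.e[a] + self.e[b] + e_ab,
                        self.out[a] + self.out[b],
                        self.inc[a] + self.inc[b],
                        self.omega,
                        self.exclusive,
                    )
                    - self.term(a)
                    - self.term(b)
                )
                if gain > best_gain:
                    best, best_gain = (a, b), gain
            if best is None:
                return merged_any
            a, b = best
            for v in range(self.n):
                if lab[v] == b:
                    lab[v] = a
            e_ab = cross.get((a, b), 0) + cross.get((b, a), 0)
            self.e[a] += self.e[b] + e_ab
            self.out[a] += self.out[b]
            self.inc[a] += self.inc[b]
            self.size[a] += self.size[b]
            del self.e[b], self.out[b], self.inc[b], self.size[b]
            merged_any = True

    def to_partition(self, net: SignedDigraph) -> Partition:
        groups: dict[int, set[str]] = {}
        for v, lab in enumerate(self.labels):
            groups.setdefault(lab, set()).add(net.nodes[v])
        return Partition(tuple(frozenset(groups[k]) for k in sorted(groups)))


def _one_trial(
    net: SignedDigraph,
    rng: np.random.Generator,
    exclusive: bool,
    random_start: bool,
):
    st = _LabelState(net, exclusive)
    if random_start:
        # scatter nodes over a random number of groups to diversify the
        # search basins across trials
        k = int(rng.integers(1, st.n + 1))
        for v, lab in enumerate(rng.integers(0, k, size=st.n)):
            st.move(v, st._next_free + int(lab))
        st._next_free += k
    improved = True
    while improved:
        improved = False
        while st.local_pass(rng.permutation(st.n)):
            improved = True
        if st.merge_pass():
            improved = True
    value = st.value()
    part = st.to_partition(net)
    if value < 0.0:
        # the trivial one-module partition always scores exactly 0
        part = Partition((frozenset(net.nodes),))
        value = 0.0
    return part, value


def optimize_modularity(
    net: SignedDigraph,
    trials: int = 30,
    seed: int = 0,
    exclusive_boundary: bool = False,
) -> ModularityResult:
    """Stochastic search for a high-modularity partition.

    Runs ``trials`` independent searches (randomized node visiting order per
    trial), reports the per-trial values, their mean (the network-level
    modularity estimate) and the best partition found.
    Deterministic under ``(seed, trials)``.
    """
    if net.n_arcs == 0:
        raise NetworkValidationError("modularity undefined for a zero-arc network")
    if trials < 1:
        raise ValueError("trials must be >= 1")
    rng = np.random.default_rng(seed)
    values: list[float] = []
    best_part: Partition | None = None
    best_value = -np.inf
    for t in range(trials):
        part, value = _one_trial(net, rng, exclusive_boundary, random_start=t > 0)
        values.append(value)
        if value > best_value:
            best_part, best_value = part, value
    assert best_part is not None
    return ModularityResult(
        trial_values=tuple(values),
        mean_modularity=float(np.mean(values)),
        best_partition=best_part,
        best_value=float(best_value),
        trials=trials,
        seed=seed,
    )
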