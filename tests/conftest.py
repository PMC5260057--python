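"""Shared fixtures and independent brute-force oracles.

The oracle implementations here deliberately avoid the package's internal
state encodings and algorithms: they work on plain bit tuples and literal
formula transcriptions, so agreement with the package is meaningful.
"""

from __future__ import annotations

import itertools
import math

import pytest

from modrob.network import Partition, SignedDigraph

# ---------------------------------------------------------------------------
# small named networks


@pytest.fixture
def triangle() -> SignedDigraph:
    return SignedDigraph.from_arcs([("A", "B", 1), ("B", "C", 1), ("C", "A", 1)])


@pytest.fixture
def two_triangles() -> SignedDigraph:
    return SignedDigraph.from_arcs(
        [
            ("A", "B", 1), ("B", "C", 1), ("C", "A", 1),
            ("D", "E", 1), ("E", "F", 1), ("F", "D", 1),
        ]
    )


@pytest.fixture
def swap_pair() -> SignedDigraph:
    """v1 and v2 activate each other; conjunction rules copy the partner."""
    return SignedDigraph.from_arcs([("v1", "v2", 1), ("v2", "v1", 1)])


@pytest.fixture
def copy_or_net() -> SignedDigraph:
    """v1 holds its value; v2 updates to v1 OR v2.  Exhaustive γ = 0.25."""
    return SignedDigraph.from_arcs([("v1", "v2", 1), ("v2", "v2", 1)])


# ---------------------------------------------------------------------------
# set-partition enumeration (restricted growth strings)


def iter_set_partitions(items):
    """All partitions of ``items`` as lists of lists."""
    items = list(items)
    n = len(items)
    if n == 0:
        return
    codes = [0] * n

    def rec(i, maxcode):
        if i == n:
            groups = {}
            for x, c in zip(items, codes):
                groups.setdefault(c, []).append(x)
            yield [groups[c] for c in sorted(groups)]
            return
        for c in range(maxcode + 2):
            codes[i] = c
            yield from rec(i + 1, max(maxcode, c))

    yield from rec(0, -1)


def literal_modularity(net: SignedDigraph, groups) -> float:
    """Direct transcription of the directed-modularity formula."""
    omega = net.n_arcs
    total = 0.0
    for grp in groups:
        grp = set(grp)
        e = sum(1 for s, t, _ in net.arcs if s in grp and t in grp)
        out = sum(1 for s, _, _ in net.arcs if s in grp)
        inc = sum(1 for _, t, _ in net.arcs if t in grp)
        total += e / omega - (out * inc) / (omega * omega)
    return total


def brute_force_best_partition(net: SignedDigraph) -> tuple[float, list]:
    best, best_groups = -math.inf, None
    for groups in iter_set_partitions(net.nodes):
        m = literal_modularity(net, groups)
        if m > best:
            best, best_groups = m, groups
    return best, best_groups


# ---------------------------------------------------------------------------
# independent Boolean dynamics on bit tuples


def oracle_step(net: SignedDigraph, rules: dict[str, str], state: tuple) -> tuple:
    """Evaluate every rule literally on a bits-by-node-order tuple."""
    idx = {v: i for i, v in enumerate(net.nodes)}
    regs: dict[str, list] = {v: [] for v in net.nodes}
    for s, t, sign in net.arcs:
        regs[t].append((s, sign))
    nxt = []
    for v in net.nodes:
        rule = rules[v]
        if rule == "identity":
            nxt.append(state[idx[v]])
            continue
        literals = [
            state[idx[r]] if sign > 0 else 1 - state[idx[r]] for r, sign in regs[v]
        ]
        nxt.append(min(literals) if rule == "conjunction" else max(literals))
    return tuple(nxt)


def oracle_canonical_cycle(cycle: list[tuple]) -> tuple:
    k = min(range(len(cycle)), key=lambda i: cycle[i])
    return tuple(cycle[k:] + cycle[:k])


def oracle_attractor(net, rules, state: tuple, memo=None) -> tuple:
    """Canonical attractor reached from ``state`` (tuple of state tuples)."""
    seen: dict[tuple, int] = {}
    path: list[tuple] = []
    s = tuple(state)
    while True:
        if memo is not None and s in memo:
            att = memo[s]
            for q in path:
                memo[q] = att
            return att
        if s in seen:
            att = oracle_canonical_cycle(path[seen[s]:])
            if memo is not None:
                for q in path:
                    memo[q] = att
            return att
        seen[s] = len(path)
        path.append(s)
        s = oracle_step(net, rules, s)


def oracle_all_attractors(net, rules) -> dict[tuple, tuple]:
    """Functional-graph decomposition: state tuple -> canonical attractor."""
    n = net.n_nodes
    memo: dict[tuple, tuple] = {}
    for bits in itertools.product((0, 1), repeat=n):
        oracle_attractor(net, rules, bits, memo)
    return memo


# ---------------------------------------------------------------------------
# literal robustness formulas


def oracle_H(seq_a, seq_b, dim: int) -> float:
    if len(seq_a) > len(seq_b):
        seq_a, seq_b = seq_b, seq_a
    l, lp = len(seq_a), len(seq_b)
    total = 0.0
    for j in range(l):
        h = sum(1 for x, y in zip(seq_a[j], seq_b[j]) if x != y)
        total += 1.0 - h / dim
    return total / lp


def _project(seq, cols):
    return [tuple(s[c] for c in cols) for s in seq]


def oracle_gamma(net, rules) -> float:
    n = net.n_nodes
    memo = oracle_all_attractors(net, rules)
    equal = 0
    states = list(itertools.product((0, 1), repeat=n))
    for s in states:
        for i in range(n):
            flipped = list(s)
            flipped[i] ^= 1
            if memo[s] == memo[tuple(flipped)]:
                equal += 1
    return equal / (n * len(states))


def oracle_minimal_period(seq):
    """Shortest prefix whose repetition reproduces the whole sequence."""
    n = len(seq)
    for d in range(1, n + 1):
        if n % d == 0 and seq == seq[: d] * (n // d):
            return seq[:d]
    return seq


def oracle_best_rotation_H(seq_a, seq_b, dim: int) -> float:
    """H maximized over relative rotations of the two (reduced) cycles."""
    if seq_a == seq_b:
        return 1.0
    if len(seq_a) > len(seq_b):
        seq_a, seq_b = seq_b, seq_a
    best = 0.0
    for r in range(len(seq_b)):
        rotated = seq_b[r:] + seq_b[:r]
        best = max(best, oracle_H(seq_a, rotated, dim))
    return best


def oracle_module_robustness(net, rules, groups):
    """Literal γ_in(V_i), γ_out(V_i) on the full state space."""
    n = net.n_nodes
    idx = {v: i for i, v in enumerate(net.nodes)}
    memo = oracle_all_attractors(net, rules)
    states = list(itertools.product((0, 1), repeat=n))
    per_in, per_out = [], []
    all_nodes = set(net.nodes)
    for grp in groups:
        grp = set(grp)
        cols_in = sorted(idx[v] for v in grp)
        comp = all_nodes - grp
        cols_out = sorted(idx[v] for v in comp)
        tot_in = tot_out = 0.0
        for s in states:
            sa = list(memo[s])
            for v in grp:
                flipped = list(s)
                flipped[idx[v]] ^= 1
                sb = list(memo[tuple(flipped)])
                tot_in += oracle_best_rotation_H(
                    oracle_minimal_period(_project(sa, cols_in)),
                    oracle_minimal_period(_project(sb, cols_in)),
                    len(cols_in),
                )
                if cols_out:
                    tot_out += oracle_best_rotation_H(
                        oracle_minimal_period(_project(sa, cols_out)),
                        oracle_minimal_period(_project(sb, cols_out)),
                        len(cols_out),
                    )
        denom = len(states) * len(grp)
        per_in.append(tot_in / denom)
        per_out.append(tot_out / denom if cols_out else math.nan)
    return per_in, per_out


# ---------------------------------------------------------------------------
# helpers


def random_partition(nodes, n_modules: int, rng) -> Partition:
    """A random partition with up to ``n_modules`` nonempty modules."""
    nodes = list(nodes)
    labels = rng.integers(0, n_modules, size=len(nodes))
    groups: dict[int, set] = {}
    for v, lab in zip(nodes, labels):
        groups.setdefault(int(lab), set()).add(v)
    return Partition(tuple(frozenset(groups[k]) for k in sorted(groups)))
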