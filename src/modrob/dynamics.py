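"""Synchronous Boolean dynamics on signed digraphs.

Each node holds a binary state.  A node with regulators updates by either a
conjunction (AND) or a disjunction (OR) over its regulator literals, where a
literal is the regulator's value, negated when the arc is inhibiting.  The
rule (AND vs OR) is drawn uniformly at random per node.  Nodes without
regulators hold their value (identity), so they act as constants of a
trajectory and perturbing them remains meaningful.

All N node values update simultaneously:  s(t+1) = F(s(t)).  Since the
state space is finite and the map deterministic, every trajectory ends in a
fixed point or a limit cycle; attractors are stored in a canonical rotation
(lexicographically smallest state first, bits read in node order) so that
attractor equality is plain sequence comparison.

States are encoded as Python integers with node ``i`` at bit ``N-1-i``
(node 0 most significant), which makes integer order coincide with
lexicographic order of the bit vector.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property
from typing import Sequence

import numpy as np

from .network import SignedDigraph

CONJUNCTION = "conjunction"
DISJUNCTION = "disjunction"
IDENTITY = "identity"

DEFAULT_MAX_STEPS = 1 << 20


class TrajectoryLimitError(RuntimeError):
    """Trajectory exceeded the configured step cap without repeating."""


def state_to_int(bits: Sequence[int], n: int) -> int:
    if len(bits) != n:
        raise ValueError(f"state length {len(bits)} != network size {n}")
    value = 0
    for b in bits:
        value = (value << 1) | (b & 1)
    return value


def int_to_state(value: int, n: int) -> tuple[int, ...]:
    return tuple((value >> (n - 1 - i)) & 1 for i in range(n))


@dataclass(frozen=True)
class Attractor:
    """A fixed point (length 1) or limit cycle in canonical rotation."""

    n: int
    states_int: tuple[int, ...]

    @property
    def length(self) -> int:
        return len(self.states_int)

    @property
    def is_fixed_point(self) -> bool:
        return len(self.states_int) == 1

    @property
    def states(self) -> tuple[tuple[int, ...], ...]:
        return tuple(int_to_state(s, self.n) for s in self.states_int)

    @classmethod
    def from_cycle(cls, cycle: Sequence[int], n: int) -> "Attractor":
        """Canonicalize: rotate so the smallest state comes first."""
        k = min(range(len(cycle)), key=cycle.__getitem__)
        return cls(n, tuple(cycle[k:]) + tuple(cycle[:k]))


@dataclass(frozen=True)
class BooleanNetwork:
    """A signed digraph endowed with per-node AND/OR update rules."""

    structure: SignedDigraph
    rules: tuple[str, ...]
    rule_seed: int | None = None

    def __post_init__(self) -> None:
        n = self.structure.n_nodes
        if len(self.rules) != n:
            raise ValueError("one rule per node required")
        for i, rule in enumerate(self.rules):
            has_regs = bool(self.structure.in_adjacency[i])
            if has_regs and rule not in (CONJUNCTION, DISJUNCTION):
                raise ValueError(f"regulated node {i} must be conjunction/disjunction")
            if not has_regs and rule != IDENTITY:
                raise ValueError(f"input-free node {i} must be identity")

    @property
    def n(self) -> int:
        return self.structure.n_nodes

    @cached_property
    def _masks(self) -> tuple[tuple[int, int, int, str], ...]:
        """Per node: (positive mask, negative mask, own bit, rule)."""
        n = self.n
        rows = []
        for i in range(n):
            pos = neg = 0
            for reg, sign in self.structure.in_adjacency[i]:
                bit = 1 << (n - 1 - reg)
                if sign > 0:
                    pos |= bit
                else:
                    neg |= bit
            rows.append((pos, neg, 1 << (n - 1 - i), self.rules[i]))
        return tuple(rows)

    def step_int(self, s: int) -> int:
        out = 0
        for pos, neg, own, rule in self._masks:
            if rule == CONJUNCTION:
                on = (s & pos) == pos and (s & neg) == 0
            elif rule == DISJUNCTION:
                on = (s & pos) != 0 or (s & neg) != neg
            else:
                on = bool(s & own)
            if on:
                out |= own
        return out


def assign_update_rules(net: SignedDigraph, seed: int) -> BooleanNetwork:
    """Draw a conjunction or disjunction rule per regulated node, p = 1/2 each.

    Input-free nodes get the identity rule.  Reproducible under ``seed``.
    """
    rng = np.random.default_rng(seed)
    draws = rng.integers(0, 2, size=net.n_nodes)
    rules = tuple(
        (CONJUNCTION if draws[i] == 0 else DISJUNCTION)
        if net.in_adjacency[i]
        else IDENTITY
        for i in range(net.n_nodes)
    )
    return BooleanNetwork(structure=net, rules=rules, rule_seed=seed)


def next_state(bn: BooleanNetwork, s: Sequence[int]) -> tuple[int, ...]:
    """Apply every update rule once, synchronously."""
    return int_to_state(bn.step_int(state_to_int(s, bn.n)), bn.n)


def find_attractor(
    bn: BooleanNetwork,
    s0: Sequence[int] | int,
    max_steps: int = DEFAULT_MAX_STEPS,
) -> Attractor:
    """Iterate the dynamics from ``s0`` until a state repeats.

    Returns the cycle portion as a canonical :class:`Attractor`.  The cap
    ``max_steps`` guards pathological large-N runs; exceeding it raises
    :class:`TrajectoryLimitError` rather than silently truncating.
    """
    s = s0 if isinstance(s0, int) else state_to_int(s0, bn.n)
    seen: dict[int, int] = {}
    path: list[int] = []
    for _ in range(max_steps + 1):
        if s in seen:
            return Attractor.from_cycle(path[seen[s]:], bn.n)
        seen[s] = len(path)
        path.append(s)
        s = bn.step_int(s)
    raise TrajectoryLimitError(
        f"no repeat within {max_steps} steps (N={bn.n}); raise max_steps"
    )


class AttractorCache:
    """Memoized basin lookup: maps every visited state to its attractor.

    Trajectories from different starting states share tails; caching the
    whole path makes repeated convergence queries (as in the robustness
    sweep) close to amortized O(1) per query.
    """

    def __init__(self, bn: BooleanNetwork, max_steps: int = DEFAULT_MAX_STEPS):
        self.bn = bn
        self.max_steps = max_steps
        self._basin: dict[int, Attractor] = {}

    def attractor_of(self, s: Sequence[int] | int) -> Attractor:
        s = s if isinstance(s, int) else state_to_int(s, self.bn.n)
        basin = self._basin
        path: list[int] = []
        pos: dict[int, int] = {}
        cur = s
        for _ in range(self.max_steps + 1):
            hit = basin.get(cur)
            if hit is not None:
                for st in path:
                    basin[st] = hit
                return hit
            if cur in pos:
                att = Attractor.from_cycle(path[pos[cur]:], self.bn.n)
                for st in path:
                    basin[st] = att
                return att
            pos[cur] = len(path)
            path.append(cur)
            cur = self.bn.step_int(cur)
        raise TrajectoryLimitError(
            f"no repeat within {self.max_steps} steps (N={self.bn.n})"
        )
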