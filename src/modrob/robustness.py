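"""Robustness of Boolean dynamics to single-bit state perturbations.

The network robustness

    γ(G) = (1/(N·|S̃|)) Σ_{s∈S̃} Σ_i I(⟨s⟩ = ⟨s_v̄i⟩)

is the fraction of (initial state, perturbed node) pairs whose perturbed
trajectory converges to exactly the same attractor as the unperturbed one.
S̃ is a uniform sample of initial states (default size 2N; the full state
space is enumerated whenever it is no larger than the requested sample).

Given a partition, the perturbation's effect is split into the perturbed
module's own dynamics and everything outside it:

    γ_in(V_i)  = (1/|S̃|) Σ_s Σ_{v∈V_i} H(Π_{V_i}⟨s⟩,   Π_{V_i}⟨s_v̄⟩)   / |V_i|
    γ_out(V_i) = (1/|S̃|) Σ_s Σ_{v∈V_i} H(Π_{V∖V_i}⟨s⟩, Π_{V∖V_i}⟨s_v̄⟩) / |V_i|

where Π restricts each attractor state to a node subset and H is a
Hamming-based attractor similarity: with cycle lengths l ≤ l′,

    H = (1/l′) Σ_{j=0}^{l-1} (1 − h(s_j, s′_j)/d)

with d the dimension of the compared (projected) vectors, so H ∈ [0, 1] and
H = 1 exactly for identical equal-length sequences.  Inside the robustness
decomposition the projection of a cycle is first reduced to its minimal
period (the node subset's own partial attractor: a module may sit at a
fixed point while the rest oscillates), and the two reduced cycles are
paired under their best relative rotation — attractors are
rotation-equivalence classes, so the measure is phase-free.  Consequently
identical attractors score 1 on every projection, and perturbing one of two
disconnected components leaves the other component's score at exactly 1.
The standalone :func:`attractor_similarity` compares whole canonical
attractors positionally.  Network-level γ_in/γ_out average the module
values over the M modules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from multiprocessing import get_context
from typing import Iterable, Sequence

import numpy as np

from .dynamics import Attractor, AttractorCache, BooleanNetwork
from .network import NetworkValidationError, Partition


@dataclass(frozen=True)
class RobustnessResult:
    """γ plus the per-module in/out decomposition for one sampled S̃."""

    gamma: float
    per_module_in: tuple[float, ...]
    per_module_out: tuple[float, ...]  # NaN where the complement is empty
    gamma_in: float
    gamma_out: float  # NaN when no module has a nonempty complement
    sample_size: int
    sample_seed: int


def _pair_similarity(a: Attractor, b: Attractor, mask: int, dim: int) -> float:
    """H on the projections of two canonical attractors onto ``mask``."""
    sa, sb = a.states_int, b.states_int
    if len(sa) > len(sb):
        sa, sb = sb, sa
    l, lp = len(sa), len(sb)
    total = 0.0
    for j in range(l):
        total += 1.0 - ((sa[j] ^ sb[j]) & mask).bit_count() / dim
    return total / lp


def _partial_attractor(a: Attractor, mask: int) -> list[int]:
    """Mask the cycle and reduce it to its minimal period.

    Reduction matters: a node subset may cycle with a shorter period than
    the full state (e.g. sit at a fixed point while the rest oscillates),
    and its partial attractor is that shorter cycle.
    """
    la = a.length
    proj = [s & mask for s in a.states_int]
    for d in range(1, la):
        if la % d == 0 and all(proj[j] == proj[j % d] for j in range(la)):
            return proj[:d]
    return proj


def _projected_similarity(a: Attractor, b: Attractor, mask: int, dim: int) -> float:
    """H between the partial attractors of ``a`` and ``b`` on ``mask``.

    An attractor is a rotation-equivalence class, so the two reduced
    projected cycles are paired under their best relative rotation.  This
    makes the measure phase-free: identical attractors score 1 on every
    projection, and a perturbation that never reaches a dynamically
    independent subsystem leaves that subsystem's score at 1.
    """
    if a == b:
        return 1.0
    pa = _partial_attractor(a, mask)
    pb = _partial_attractor(b, mask)
    if len(pa) > len(pb):
        pa, pb = pb, pa
    l, lp = len(pa), len(pb)
    best = 0.0
    for r in range(lp):
        total = 0.0
        for j in range(l):
            total += 1.0 - (pa[j] ^ pb[(j + r) % lp]).bit_count() / dim
        best = max(best, total / lp)
    return best


def attractor_similarity(a: Attractor, b: Attractor, dim: int) -> float:
    """Similarity H between two attractors of the same dimension."""
    if a.n != dim or b.n != dim:
        raise ValueError(f"attractor dimensions {a.n}/{b.n} != {dim}")
    return _pair_similarity(a, b, (1 << dim) - 1, dim)


def project_attractor(
    a: Attractor,
    subset: Iterable[str],
    net_order: Sequence[str],
) -> tuple[tuple[int, ...], ...]:
    """Restrict each attractor state to ``subset``'s coordinates.

    The sequence length and the parent's canonical alignment are preserved
    (duplicates retained, no re-canonicalization): projected sequences are
    meant to be compared positionally with projections of other attractors
    produced from the same canonical rotation.
    """
    subset = set(subset)
    cols = [i for i, v in enumerate(net_order) if v in subset]
    if not cols:
        raise ValueError("cannot project onto an empty node subset")
    states = a.states
    return tuple(tuple(s[i] for i in cols) for s in states)


def sample_states(n: int, sample_size: int, seed: int) -> list[int]:
    """Uniform sample of distinct N-bit states (full space if it is smaller).

    Deterministic under ``seed``; enumeration order of the full space is
    ascending, otherwise sample order is the draw order.
    """
    if sample_size < 1:
        raise ValueError("sample_size must be >= 1")
    space = 1 << n
    if sample_size >= space:
        return list(range(space))
    rng = np.random.default_rng(seed)
    if n <= 22:
        return [int(x) for x in rng.choice(space, size=sample_size, replace=False)]
    chosen: list[int] = []
    seen: set[int] = set()
    while len(chosen) < sample_size:
        x = int(rng.integers(0, space))
        if x not in seen:
            seen.add(x)
            chosen.append(x)
    return chosen


def _flip(s: int, node_idx: int, n: int) -> int:
    return s ^ (1 << (n - 1 - node_idx))


def _state_contributions(
    bn: BooleanNetwork,
    states: Sequence[int],
    masks: Sequence[tuple[int, int, tuple[int, ...]]] | None,
    max_steps: int,
) -> list[tuple[int, tuple[tuple[float, float], ...]]]:
    """Per initial state: (#attractor-preserving flips, per-module (H_in, H_out) sums).

    ``masks`` lists per module ``(in_mask, out_mask, member node indices)``;
    ``None`` requests the plain γ count only.  Pure function of its inputs,
    so the result is independent of how states are chunked over workers.
    """
    n = bn.n
    cache = AttractorCache(bn, max_steps=max_steps)
    out: list[tuple[int, tuple[tuple[float, float], ...]]] = []
    for s in states:
        a0 = cache.attractor_of(s)
        equal_count = 0
        if masks is None:
            for i in range(n):
                if cache.attractor_of(_flip(s, i, n)) == a0:
                    equal_count += 1
            out.append((equal_count, ()))
            continue
        per_module: list[tuple[float, float]] = []
        flipped = {i: cache.attractor_of(_flip(s, i, n)) for i in range(n)}
        for i in range(n):
            if flipped[i] == a0:
                equal_count += 1
        for in_mask, out_mask, members in masks:
            h_in = 0.0
            h_out = 0.0
            dim_in = in_mask.bit_count()
            dim_out = out_mask.bit_count()
            for v in members:
                a1 = flipped[v]
                h_in += _projected_similarity(a0, a1, in_mask, dim_in)
                if dim_out:
                    h_out += _projected_similarity(a0, a1, out_mask, dim_out)
            per_module.append((h_in, h_out))
        out.append((equal_count, tuple(per_module)))
    return out


def _map_states(bn, states, masks, max_steps, workers):
    if workers <= 1 or len(states) < 2:
        return _state_contributions(bn, states, masks, max_steps)
    chunks = np.array_split(np.asarray(states, dtype=object), workers)
    args = [(bn, [int(s) for s in c], masks, max_steps) for c in chunks if len(c)]
    with get_context("fork").Pool(processes=workers) as pool:
        parts = pool.starmap(_state_contributions, args)
    merged: list = []
    for p in parts:
        merged.extend(p)
    return merged


def network_robustness(
    bn: BooleanNetwork,
    sample_size: int | None = None,
    seed: int = 0,
    workers: int = 1,
    max_steps: int = 1 << 20,
) -> float:
    """Estimate γ(G) over a sampled S̃ (default |S̃| = 2N).

    Every (s, v_i) pair compares canonical attractors for exact equality.
    When the sample covers the whole state space the value is the exact γ.
    """
    n = bn.n
    if sample_size is None:
        sample_size = 2 * n
    states = sample_states(n, sample_size, seed)
    rows = _map_states(bn, states, None, max_steps, workers)
    equal = sum(r[0] for r in rows)
    return equal / (n * len(states))


def module_robustness(
    bn: BooleanNetwork,
    part: Partition,
    sample_size: int | None = None,
    seed: int = 0,
    workers: int = 1,
    max_steps: int = 1 << 20,
) -> RobustnessResult:
    """γ together with per-module γ_in/γ_out on one shared sample S̃.

    A module whose complement is empty (single-module partition) has an
    undefined γ_out, reported as NaN and excluded from the γ_out mean.
    """
    part.validate_against(bn.structure)
    n = bn.n
    if sample_size is None:
        sample_size = 2 * n
    states = sample_states(n, sample_size, seed)
    node_idx = bn.structure.index
    full_mask = (1 << n) - 1
    masks = []
    for mod in part.modules:
        members = tuple(sorted(node_idx[v] for v in mod))
        in_mask = 0
        for i in members:
            in_mask |= 1 << (n - 1 - i)
        masks.append((in_mask, full_mask ^ in_mask, members))
    rows = _map_states(bn, states, masks, max_steps, workers)
    equal = sum(r[0] for r in rows)
    gamma = equal / (n * len(states))
    per_in: list[float] = []
    per_out: list[float] = []
    nsamples = len(states)
    for k, (in_mask, out_mask, members) in enumerate(masks):
        size = len(members)
        total_in = sum(r[1][k][0] for r in rows)
        per_in.append(total_in / (nsamples * size))
        if out_mask:
            total_out = sum(r[1][k][1] for r in rows)
            per_out.append(total_out / (nsamples * size))
        else:
            per_out.append(math.nan)
    defined_out = [x for x in per_out if not math.isnan(x)]
    return RobustnessResult(
        gamma=gamma,
        per_module_in=tuple(per_in),
        per_module_out=tuple(per_out),
        gamma_in=float(np.mean(per_in)),
        gamma_out=float(np.mean(defined_out)) if defined_out else math.nan,
        sample_size=len(states),
        sample_seed=seed,
    )
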