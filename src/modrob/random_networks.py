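"""Random signed directed network generators and null-model shuffles.

Five models are supported:

* ``ba`` — directed preferential attachment: each arriving node sends ``m``
  arcs to distinct existing nodes chosen proportionally to their current
  total degree (new → old direction).
* ``er`` — exactly ``m`` arcs placed uniformly among ordered node pairs
  without duplicates or self-loops.
* ``er-variant`` — every ordered pair independently becomes an arc with
  probability ``p``.
* ``shuffle-dp`` — degree-preserving rewiring of a template by repeated
  double-edge swaps (a→b, c→d) ⇒ (a→d, c→b), rejecting self-loops and
  duplicates; joint (in, out) degree sequence preserved exactly.
* ``shuffle-st`` — targets permuted uniformly (rejection of self-loops and
  duplicates); out-degrees preserved only.

Shuffles rewire ignoring signs and each moved arc keeps the sign it carried
in its source slot.  Generated arcs get signs via :func:`assign_signs`
(activating with probability ``sign_probability``, default 0.5).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import ACTIVATING, INHIBITING, SignedDigraph

MODELS = ("ba", "er", "er-variant", "shuffle-dp", "shuffle-st")


class GenerationError(RuntimeError):
    """Generator could not satisfy its constraints."""


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of one random-network draw."""

    model: str
    n: int | None = None
    m: int | None = None  # arcs per new node (ba) or total arcs (er)
    p: float | None = None  # arc probability (er-variant)
    sign_probability: float = 0.5
    seed: int = 0
    template: SignedDigraph | None = None
    n_swaps: int | None = None  # shuffle-dp; default 10x arc count

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}; choose from {MODELS}")
        if not 0.0 <= self.sign_probability <= 1.0:
            raise ValueError("sign_probability must lie in [0, 1]")
        if self.model in ("shuffle-dp", "shuffle-st"):
            if self.template is None:
                raise ValueError(f"model {self.model!r} requires a template network")
        else:
            if self.n is None or self.n < 1:
                raise ValueError(f"model {self.model!r} requires n >= 1")
            if self.model in ("ba", "er") and (self.m is None or self.m < 0):
                raise ValueError(f"model {self.model!r} requires m >= 0")
            if self.model == "er-variant" and not (
                self.p is not None and 0.0 <= self.p <= 1.0
            ):
                raise ValueError("model 'er-variant' requires p in [0, 1]")


def _node_names(n: int) -> tuple[str, ...]:
    return tuple(f"v{i}" for i in range(n))


def assign_signs(
    net: SignedDigraph, sign_probability: float = 0.5, seed: int = 0
) -> SignedDigraph:
    """Redraw every arc's sign independently: activating w.p. ``sign_probability``."""
    if not 0.0 <= sign_probability <= 1.0:
        raise ValueError("sign_probability must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    draws = rng.random(net.n_arcs) < sign_probability
    arcs = tuple(
        (s, t, ACTIVATING if keep else INHIBITING)
        for (s, t, _), keep in zip(net.arcs, draws)
    )
    return SignedDigraph(net.nodes, arcs)


def _ba_arcs(n: int, m: int, rng: np.random.Generator) -> list[tuple[int, int]]:
    if n < 2:
        return []
    m0 = max(1, min(m, n - 1))
    degree = np.zeros(n, dtype=float)
    arcs: list[tuple[int, int]] = []
    for new in range(m0, n):
        existing = np.arange(new)
        k = min(m0, new)
        weights = degree[:new] + 1.0  # +1 smoothing so isolated seeds are reachable
        weights = weights / weights.sum()
        targets = rng.choice(existing, size=k, replace=False, p=weights)
        for t in targets:
            arcs.append((new, int(t)))
            degree[new] += 1
            degree[int(t)] += 1
    return arcs


def generate_random_network(spec: GeneratorSpec) -> SignedDigraph:
    """Draw one network according to ``spec``; reproducible under its seed."""
    rng = np.random.default_rng(spec.seed)
    if spec.model in ("shuffle-dp", "shuffle-st"):
        assert spec.template is not None
        n_swaps = spec.n_swaps
        if n_swaps is None:
            n_swaps = 10 * spec.template.n_arcs
        model = "degree-preserving" if spec.model == "shuffle-dp" else "source-target"
        return shuffle_network(spec.template, model, n_swaps, spec.seed)
    n = spec.n
    assert n is not None
    if spec.model == "ba":
        pairs = _ba_arcs(n, spec.m or 1, rng)
    elif spec.model == "er":
        m = spec.m or 0
        max_pairs = n * (n - 1)
        if m > max_pairs:
            raise GenerationError(f"m={m} exceeds n(n-1)={max_pairs} ordered pairs")
        idx = rng.choice(max_pairs, size=m, replace=False)
        pairs = [_pair_from_index(int(k), n) for k in idx]
    else:  # er-variant
        max_pairs = n * (n - 1)
        hits = np.nonzero(rng.random(max_pairs) < spec.p)[0]
        pairs = [_pair_from_index(int(k), n) for k in hits]
    names = _node_names(n)
    net = SignedDigraph(names, tuple((names[a], names[b], ACTIVATING) for a, b in pairs))
    sign_seed = int(rng.integers(0, 2**31 - 1))
    return assign_signs(net, spec.sign_probability, sign_seed)


def _pair_from_index(k: int, n: int) -> tuple[int, int]:
    """Enumerate ordered pairs (i, j), i != j, by a flat index."""
    i, r = divmod(k, n - 1)
    j = r if r < i else r + 1
    return i, j


def shuffle_network(
    template: SignedDigraph,
    model: str,
    n_swaps: int | None = None,
    seed: int = 0,
    max_tries_factor: int = 100,
) -> SignedDigraph:
    """Rewire ``template`` under a null model; see module docstring."""
    if template.n_arcs < 2:
        raise GenerationError("shuffling requires a template with >= 2 arcs")
    rng = np.random.default_rng(seed)
    arcs = [(s, t, g) for s, t, g in template.arcs]
    if model == "degree-preserving":
        if n_swaps is None:
            n_swaps = 10 * len(arcs)
        present = {(s, t) for s, t, _ in arcs}
        done = 0
        tries = 0
        max_tries = max_tries_factor * max(n_swaps, 1)
        while done < n_swaps:
            tries += 1
            if tries > max_tries:
                raise GenerationError(
                    f"only {done}/{n_swaps} swaps succeeded after {tries - 1} "
                    "attempts; template too constrained"
                )
            i, j = rng.integers(0, len(arcs), size=2)
            if i == j:
                continue
            a, b, ga = arcs[int(i)]
            c, d, gc = arcs[int(j)]
            if a == d or c == b:  # would create a self-loop
                continue
            if (a, d) in present or (c, b) in present:
                continue
            present -= {(a, b), (c, d)}
            present |= {(a, d), (c, b)}
            arcs[int(i)] = (a, d, ga)
            arcs[int(j)] = (c, b, gc)
            done += 1
        return SignedDigraph(template.nodes, tuple(arcs))
    if model == "source-target":
        sources = [(s, g) for s, _, g in arcs]
        targets = [t for _, t, _ in arcs]
        for _ in range(1000):
            perm = rng.permutation(len(targets))
            new = [(sources[k][0], targets[int(perm[k])], sources[k][1]) for k in range(len(arcs))]
            seen = {(s, t) for s, t, _ in new}
            if len(seen) == len(new) and all(s != t for s, t, _ in new):
                return SignedDigraph(template.nodes, tuple(new))
        raise GenerationError(
            "could not find a valid target permutation in 1000 attempts"
        )
    raise ValueError(f"unknown shuffle model {model!r}")
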