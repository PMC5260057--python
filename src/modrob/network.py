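"""Signed directed networks and node partitions, with plain-text I/O.

A regulatory network is modelled as a directed graph whose arcs carry a
sign: activating (+1) or inhibiting (-1).  Node order is significant — it
is fixed at construction (first-appearance order when parsed from a file)
and defines the bit positions used by the Boolean dynamics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import cached_property
from pathlib import Path
from typing import Iterable, Mapping

logger = logging.getLogger(__name__)

ACTIVATING = 1
INHIBITING = -1

_SIGN_TOKENS = {
    "+": ACTIVATING,
    "-": INHIBITING,
    "1": ACTIVATING,
    "+1": ACTIVATING,
    "-1": INHIBITING,
    "activates": ACTIVATING,
    "inhibits": INHIBITING,
    "activating": ACTIVATING,
    "inhibiting": INHIBITING,
}

_SIF_TOKENS = {"activates": ACTIVATING, "inhibits": INHIBITING}


class NetworkFormatError(ValueError):
    """Malformed network or partition file."""


class NetworkValidationError(ValueError):
    """Structurally invalid network, partition or argument combination."""


@dataclass(frozen=True)
class SignedDigraph:
    """Directed graph with signed arcs and a stable node order.

    Parameters
    ----------
    nodes
        Node identifiers in their canonical order.  Identifiers are
        case-sensitive strings without whitespace.
    arcs
        ``(source, target, sign)`` triples with ``sign`` in ``{+1, -1}``.
        At most one arc per ordered ``(source, target)`` pair.
    """

    nodes: tuple[str, ...]
    arcs: tuple[tuple[str, str, int], ...]

    def __post_init__(self) -> None:
        if len(set(self.nodes)) != len(self.nodes):
            raise NetworkValidationError("duplicate node identifiers")
        declared = set(self.nodes)
        seen: dict[tuple[str, str], int] = {}
        for src, tgt, sign in self.arcs:
            if src not in declared or tgt not in declared:
                raise NetworkValidationError(
                    f"arc ({src!r}, {tgt!r}) references an undeclared node"
                )
            if sign not in (ACTIVATING, INHIBITING):
                raise NetworkValidationError(f"invalid sign {sign!r} on arc ({src!r}, {tgt!r})")
            if (src, tgt) in seen:
                raise NetworkValidationError(f"duplicate arc ({src!r}, {tgt!r})")
            seen[(src, tgt)] = sign

    @classmethod
    def from_arcs(
        cls,
        arcs: Iterable[tuple[str, str, int]],
        nodes: Iterable[str] | None = None,
    ) -> "SignedDigraph":
        """Build a network, collapsing exact duplicate arcs with a warning.

        Duplicate ``(source, target)`` pairs with the *same* sign collapse to
        one arc; the same pair with conflicting signs is an error, because a
        node's conjunction/disjunction rule admits one literal per regulator.
        """
        order: list[str] = list(nodes) if nodes is not None else []
        known = set(order)
        kept: dict[tuple[str, str], int] = {}
        for src, tgt, sign in arcs:
            for v in (src, tgt):
                if nodes is None and v not in known:
                    known.add(v)
                    order.append(v)
            key = (src, tgt)
            if key in kept:
                if kept[key] != sign:
                    raise NetworkValidationError(
                        f"conflicting signs for arc ({src!r}, {tgt!r})"
                    )
                logger.warning("duplicate arc (%s, %s) collapsed", src, tgt)
                continue
            kept[key] = sign
        return cls(tuple(order), tuple((s, t, g) for (s, t), g in kept.items()))

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_arcs(self) -> int:
        return len(self.arcs)

    @cached_property
    def index(self) -> dict[str, int]:
        """Node identifier -> position in the canonical order."""
        return {v: i for i, v in enumerate(self.nodes)}

    @cached_property
    def arcs_indexed(self) -> tuple[tuple[int, int, int], ...]:
        return tuple((self.index[s], self.index[t], g) for s, t, g in self.arcs)

    @cached_property
    def out_adjacency(self) -> tuple[tuple[int, ...], ...]:
        adj: list[list[int]] = [[] for _ in self.nodes]
        for i, j, _ in self.arcs_indexed:
            adj[i].append(j)
        return tuple(tuple(a) for a in adj)

    @cached_property
    def in_adjacency(self) -> tuple[tuple[tuple[int, int], ...], ...]:
        """Per node: ``(regulator index, sign)`` pairs in arc order."""
        adj: list[list[tuple[int, int]]] = [[] for _ in self.nodes]
        for i, j, g in self.arcs_indexed:
            adj[j].append((i, g))
        return tuple(tuple(a) for a in adj)

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for s, t, sign in self.arcs:
            g.add_edge(s, t, sign=sign)
        return g


@dataclass(frozen=True)
class Partition:
    """Disjoint nonempty node sets covering a network's node set.

    The position of a module in ``modules`` is its identifier; ``labels``
    keeps the original module labels when the partition was read from a
    table (sorted for stable indexing).
    """

    modules: tuple[frozenset[str], ...]
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if not self.modules:
            raise NetworkValidationError("partition has no modules")
        seen: set[str] = set()
        for i, mod in enumerate(self.modules):
            if not mod:
                raise NetworkValidationError(f"module {i} is empty")
            if seen & mod:
                raise NetworkValidationError("modules are not disjoint")
            seen |= mod
        if self.labels is not None and len(self.labels) != len(self.modules):
            raise NetworkValidationError("labels/modules length mismatch")

    @classmethod
    def from_labels(cls, assignment: Mapping[str, str]) -> "Partition":
        if not assignment:
            raise NetworkFormatError("empty partition table (no nonempty module)")
        by_label: dict[str, set[str]] = {}
        for node, label in assignment.items():
            by_label.setdefault(label, set()).add(node)
        labels = sorted(by_label, key=_label_sort_key)
        return cls(tuple(frozenset(by_label[l]) for l in labels), tuple(labels))

    @property
    def n_modules(self) -> int:
        return len(self.modules)

    @cached_property
    def module_of(self) -> dict[str, int]:
        return {v: i for i, mod in enumerate(self.modules) for v in mod}

    @property
    def node_set(self) -> frozenset[str]:
        return frozenset(self.module_of)

    def validate_against(self, net: SignedDigraph) -> None:
        """Require the partition to cover exactly the network's node set."""
        nodes = set(net.nodes)
        covered = set(self.module_of)
        if covered != nodes:
            extra = covered - nodes
            missing = nodes - covered
            raise NetworkValidationError(
                f"partition/network node mismatch: "
                f"{len(extra)} unknown, {len(missing)} uncovered"
            )


def _label_sort_key(label: str):
    try:
        return (0, int(label), label)
    except ValueError:
        return (1, 0, label)


def _parse_sign(token: str, path: Path, lineno: int) -> int:
    try:
        return _SIGN_TOKENS[token.lower()]
    except KeyError:
        raise NetworkFormatError(
            f"{path}:{lineno}: unknown sign token {token!r}"
        ) from None


def read_network(path: str | Path, format: str = "edge-list") -> SignedDigraph:
    """Read a signed network from a whitespace/tab-delimited text file.

    ``edge-list`` lines are ``source target sign`` with sign one of
    ``+ - 1 -1 activates inhibits``; the SIF dialect uses
    ``source interaction target`` with interaction ``activates``/``inhibits``.
    ``#`` starts a comment; blank lines are ignored.
    """
    path = Path(path)
    if format not in ("edge-list", "sif"):
        raise ValueError(f"unknown format {format!r}")
    arcs: list[tuple[str, str, int]] = []
    declared: list[str] | None = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            stripped = raw.strip()
            if stripped.startswith("# nodes:"):
                # optional directive fixing node order (and isolated nodes)
                declared = stripped[len("# nodes:"):].split()
                continue
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) != 3:
                raise NetworkFormatError(
                    f"{path}:{lineno}: expected 3 fields, got {len(fields)}"
                )
            if format == "edge-list":
                src, tgt, tok = fields
                sign = _parse_sign(tok, path, lineno)
            else:
                src, tok, tgt = fields
                if tok.lower() not in _SIF_TOKENS:
                    raise NetworkFormatError(
                        f"{path}:{lineno}: unknown interaction {tok!r}"
                    )
                sign = _SIF_TOKENS[tok.lower()]
            arcs.append((src, tgt, sign))
    if not arcs:
        raise NetworkFormatError(f"{path}: no arcs found")
    return SignedDigraph.from_arcs(arcs, nodes=declared)


def write_network(net: SignedDigraph, path: str | Path, format: str = "edge-list") -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# nodes: " + " ".join(net.nodes) + "\n")
        for src, tgt, sign in net.arcs:
            if format == "edge-list":
                fh.write(f"{src}\t{tgt}\t{'+' if sign == ACTIVATING else '-'}\n")
            elif format == "sif":
                word = "activates" if sign == ACTIVATING else "inhibits"
                fh.write(f"{src}\t{word}\t{tgt}\n")
            else:
                raise ValueError(f"unknown format {format!r}")


def read_partition(path: str | Path, net: SignedDigraph | None = None) -> Partition:
    """Read a two-column ``node<TAB>module_label`` table.

    When ``net`` is given the partition is cross-validated against it:
    every node must belong to the network and cover it completely.
    """
    path = Path(path)
    assignment: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) != 2:
                raise NetworkFormatError(
                    f"{path}:{lineno}: expected 2 fields, got {len(fields)}"
                )
            node, label = fields
            if node in assignment and assignment[node] != label:
                raise NetworkFormatError(
                    f"{path}:{lineno}: node {node!r} assigned to two modules"
                )
            assignment[node] = label
    part = Partition.from_labels(assignment)
    if net is not None:
        part.validate_against(net)
    return part


def write_partition(part: Partition, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for i, mod in enumerate(part.modules):
            label = part.labels[i] if part.labels is not None else str(i)
            for node in sorted(mod):
                fh.write(f"{node}\t{label}\n")
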