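"""Signed causal loop diagrams and feedback-loop polarity.

A causal loop diagram (CLD) is a signed digraph of cause→effect influences:
a ``+`` edge means effect moves with cause, a ``-`` edge means it moves
against it. A feedback cycle is *reinforcing* (R) when the product of its
edge signs is positive — perturbations amplify around the loop — and
*balancing* (B) when the product is negative, so perturbations self-correct.

The module also ships the packaged diagram of social determinants of health
driving CKD incidence in minority communities, with its ten labeled loops:
six reinforcing (R1–R6, e.g. underpaid employment → low income → poverty →
unemployment → underpaid employment) and four balancing (B1–B4, closed by
corrective channels such as public assistance). Edges carry a ``channel``
tag distinguishing disparity-specific influences from general social ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

__all__ = [
    "SignedEdge",
    "CausalDiagram",
    "FeedbackLoop",
    "LoopReport",
    "DiagramError",
    "build_diagram",
    "enumerate_simple_cycles",
    "loop_polarity",
    "figure1_diagram",
    "figure1_loop_labels",
    "classify_labeled_loops",
]

REINFORCING = "reinforcing"
BALANCING = "balancing"


class DiagramError(ValueError):
    """Raised for ill-formed diagrams or labeled cycles."""


@dataclass(frozen=True)
class SignedEdge:
    """One cause→effect influence with polarity and disparity channel."""

    src: str
    dst: str
    sign: int
    channel: str = "general"

    def __post_init__(self) -> None:
        if self.sign not in (+1, -1):
            raise ValueError(f"edge {self.src!r}->{self.dst!r}: sign must be +1 or -1")
        if self.channel not in ("disparity", "general"):
            raise ValueError(f"edge {self.src!r}->{self.dst!r}: bad channel")


@dataclass
class CausalDiagram:
    """Signed digraph; at most one edge per ordered (src, dst) pair."""

    nodes: set[str] = field(default_factory=set)
    edges: dict[tuple[str, str], SignedEdge] = field(default_factory=dict)

    def sign(self, src: str, dst: str) -> int:
        return self.edges[(src, dst)].sign

    def edge(self, src: str, dst: str) -> SignedEdge:
        return self.edges[(src, dst)]

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for (src, dst), e in self.edges.items():
            g.add_edge(src, dst, sign=e.sign, channel=e.channel)
        return g


@dataclass(frozen=True)
class FeedbackLoop:
    """A simple directed cycle with its traversed edges and polarity."""

    cycle: tuple[str, ...]  # first node implied to follow the last
    edges: tuple[SignedEdge, ...]
    polarity: str
    label: str | None = None


def build_diagram(edges: list[SignedEdge]) -> CausalDiagram:
    """Assemble a diagram; nodes inferred, duplicate edges must agree."""
    diagram = CausalDiagram()
    for e in edges:
        key = (e.src, e.dst)
        if key in diagram.edges and diagram.edges[key].sign != e.sign:
            raise DiagramError(
                f"conflicting signs for edge {e.src!r} -> {e.dst!r}: "
                f"{diagram.edges[key].sign:+d} vs {e.sign:+d}"
            )
        diagram.edges[key] = e
        diagram.nodes.update(key)
    return diagram


def loop_polarity(edges: list[SignedEdge] | tuple[SignedEdge, ...]) -> str:
    """Reinforcing iff the product of edge signs is +1, else balancing."""
    product = 1
    for e in edges:
        product *= e.sign
    return REINFORCING if product > 0 else BALANCING


def _canonical_rotation(cycle: list[str]) -> tuple[str, ...]:
    pivot = cycle.index(min(cycle))
    return tuple(cycle[pivot:] + cycle[:pivot])


def _loop_from_cycle(diagram: CausalDiagram, cycle: tuple[str, ...], label=None):
    edges = tuple(
        diagram.edge(cycle[i], cycle[(i + 1) % len(cycle)]) for i in range(len(cycle))
    )
    return FeedbackLoop(cycle=cycle, edges=edges, polarity=loop_polarity(edges), label=label)


def enumerate_simple_cycles(diagram: CausalDiagram, max_len: int | None = None):
    """All simple directed cycles of length ≤ ``max_len`` (default: n nodes).

    Each cycle is reported once, rotated to start at its lexicographically
    smallest node; direction is preserved (cycles are not identified with
    their reversal). Output order: length, then rotated node sequence.
    """
    if max_len is None:
        max_len = max(len(diagram.nodes), 2)
    if max_len < 2:
        raise ValueError("max_len must be at least 2")
    cycles = [
        _canonical_rotation(c)
        for c in nx.simple_cycles(diagram.to_networkx(), length_bound=max_len)
        if len(c) >= 2  # a CLD self-influence is not a feedback loop
    ]
    cycles.sort(key=lambda c: (len(c), c))
    return [_loop_from_cycle(diagram, c) for c in cycles]


@dataclass
class LoopReport:
    """Polarity per labeled loop plus summary counts."""

    loops: dict[str, FeedbackLoop]

    @property
    def polarities(self) -> dict[str, str]:
        return {label: loop.polarity for label, loop in self.loops.items()}

    @property
    def counts(self) -> dict[str, int]:
        values = list(self.polarities.values())
        return {
            REINFORCING: values.count(REINFORCING),
            BALANCING: values.count(BALANCING),
        }

    def table(self) -> str:
        lines = [f"{'label':6} {'polarity':12} cycle"]
        for label in sorted(self.loops):
            loop = self.loops[label]
            path = " -> ".join(loop.cycle + (loop.cycle[0],))
            lines.append(f"{label:6} {loop.polarity:12} {path}")
        c = self.counts
        lines.append(f"total: {c[REINFORCING]} reinforcing, {c[BALANCING]} balancing")
        return "\n".join(lines)


def classify_labeled_loops(
    diagram: CausalDiagram, labels: dict[str, tuple[str, ...]]
) -> LoopReport:
    """Polarity of each labeled node cycle; errors name the missing label."""
    loops: dict[str, FeedbackLoop] = {}
    for label, cycle in labels.items():
        cycle = tuple(cycle)
        if len(cycle) < 2 or len(set(cycle)) != len(cycle):
            raise DiagramError(f"label {label!r}: {cycle} is not a simple cycle")
        for i in range(len(cycle)):
            key = (cycle[i], cycle[(i + 1) % len(cycle)])
            if key not in diagram.edges:
                raise DiagramError(
                    f"label {label!r}: edge {key[0]!r} -> {key[1]!r} not in diagram"
                )
        loops[label] = _loop_from_cycle(diagram, cycle, label=label)
    return LoopReport(loops=loops)


# --- packaged social-determinants diagram -----------------------------------

_P = +1
_N = -1

#: Labeled feedback cycles of the packaged diagram (node sequences; the
#: closing edge back to the first node is implied).
_FIGURE1_LOOPS: dict[str, tuple[str, ...]] = {
    "R1": ("Underpaid Employment", "Low Income", "Poverty", "Unemployment"),
    "R2": ("Substandard Education", "Underpaid Employment", "Low Income", "Poverty"),
    "R3": ("Underpaid Employment", "Stress", "Poor Health", "Unemployment"),
    "R4": ("Poor Health", "Morbidity", "Mortality", "Poverty"),
    "R5": ("Poor Health", "Mortality", "Poverty"),
    "R6": ("Poverty", "Limited Access To Care", "Poor Health"),
    "B1": (
        "Underpaid Employment",
        "Less Sick Leave",
        "Medical Care Access",
        "Poor Health",
    ),
    "B2": ("Poverty", "Limited Healthy Food", "Poor Health", "Public Assistance"),
    "B3": (
        "Quality Stable Housing",
        "Environmental Toxins",
        "Poor Health",
        "Public Assistance",
    ),
    "B4": ("Poverty", "Limited Access To Care", "Poor Health", "Public Assistance"),
}

# Edge signs of the labeled cycles. Shared edges are sign-consistent, so the
# union below is conflict-free; disparity-channel tagging marks the
# influences specific to inequity in access and environment.
_DISPARITY_NODES = {
    "Less Sick Leave",
    "Limited Access To Care",
    "Limited Healthy Food",
    "Environmental Toxins",
    "Poor Insurance Coverage",
    "Poor Transportation",
    "Social Support",
}

_FIGURE1_CYCLE_SIGNS: dict[str, tuple[int, ...]] = {
    "R1": (_P, _P, _P, _P),
    "R2": (_P, _P, _P, _P),
    "R3": (_P, _P, _P, _P),
    "R4": (_P, _P, _P, _P),
    "R5": (_P, _P, _P),
    "R6": (_P, _P, _P),
    "B1": (_P, _N, _N, _N),
    "B2": (_P, _P, _P, _N),
    "B3": (_N, _P, _P, _P),
    "B4": (_P, _P, _P, _N),
}

#: Disparity influences outside any labeled loop.
_FIGURE1_EXTRA_EDGES = [
    SignedEdge("Poverty", "Stress", _P, "disparity"),
    SignedEdge("Poverty", "Social Support", _N, "disparity"),
    SignedEdge("Unemployment", "Poor Insurance Coverage", _P, "disparity"),
    SignedEdge("Poverty", "Poor Transportation", _P, "disparity"),
]


def figure1_diagram() -> CausalDiagram:
    """The packaged diagram of social determinants of health driving CKD.

    Encodes the ten labeled feedback loops among poverty, employment,
    education, stress, housing, food and care access, plus the non-loop
    disparity edges (reduced social support, insurance and transportation).
    """
    edges: list[SignedEdge] = []
    for label, cycle in _FIGURE1_LOOPS.items():
        signs = _FIGURE1_CYCLE_SIGNS[label]
        for i, sign in enumerate(signs):
            src = cycle[i]
            dst = cycle[(i + 1) % len(cycle)]
            channel = (
                "disparity"
                if src in _DISPARITY_NODES or dst in _DISPARITY_NODES
                else "general"
            )
            edges.append(SignedEdge(src, dst, sign, channel))
    edges.extend(_FIGURE1_EXTRA_EDGES)
    return build_diagram(edges)


def figure1_loop_labels() -> dict[str, tuple[str, ...]]:
    """Label → node-cycle map of the packaged diagram (R1–R6, B1–B4)."""
    return dict(_FIGURE1_LOOPS)


def to_dot(diagram: CausalDiagram) -> str:
    """DOT export; disparity edges red, general edges blue, sign as label."""
    lines = ["digraph cld {"]
    for node in sorted(diagram.nodes):
        lines.append(f'    "{node}";')
    for (src, dst), e in sorted(diagram.edges.items()):
        color = "red" if e.channel == "disparity" else "blue"
        label = "+" if e.sign > 0 else "-"
        lines.append(f'    "{src}" -> "{dst}" [label="{label}", color={color}];')
    lines.append("}")
    return "\n".join(lines) + "\n"


def read_edge_list(text: str) -> CausalDiagram:
    """Parse the edge-list format: ``src; dst; sign; channel`` per line."""
    edges = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = [p.strip() for p in line.split(";")]
        if len(parts) not in (3, 4):
            raise DiagramError(f"line {lineno}: expected 'src; dst; sign[; channel]'")
        src, dst, sign = parts[0], parts[1], parts[2]
        channel = parts[3] if len(parts) == 4 else "general"
        if sign not in ("+", "-", "+1", "-1"):
            raise DiagramError(f"line {lineno}: sign must be + or -, got {sign!r}")
        edges.append(SignedEdge(src, dst, +1 if sign.startswith("+") else -1, channel))
    return build_diagram(edges)


def write_edge_list(diagram: CausalDiagram) -> str:
    """Serialize to the edge-list format read by :func:`read_edge_list`."""
    lines = []
    for (src, dst), e in sorted(diagram.edges.items()):
        sign = "+" if e.sign > 0 else "-"
        lines.append(f"{src}; {dst}; {sign}; {e.channel}")
    return "\n".join(lines) + "\n"
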