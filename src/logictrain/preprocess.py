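"""Map data onto the PKN and build the candidate-gate scaffold.

Preprocessing has three steps.  First the experimental role of each network
node is resolved (stimulated / inhibited / measured).  Second, species that
carry no information are removed: nodes that no cue can influence or that
cannot influence any readout are pruned, and undesignated pass-through nodes
are compressed away (rewiring their neighbours with the product of the two
edge signs) whenever this does not change the input-output logic.  Third,
every remaining edge set converging on a node is expanded into candidate
logic gates: one single-input gate per signed edge plus AND gates over input
combinations.  OR is encoded implicitly — co-selecting several gates with the
same target ORs them — so a node with inputs B and C yields the three
hyperedges {B->A}, {C->A}, {B AND C->A}, covering the four Boolean wiring
options (B, C, B AND C, B OR C).

The resulting :class:`Scaffold` fixes a deterministic gate ordering so that
model bitstrings are portable across runs.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .formats import MidasDataset, PriorKnowledgeNetwork

__all__ = ["StatusMap", "Gate", "Scaffold", "mark_status", "cut_unreachable",
           "compress", "expand"]

Edge = tuple[str, int, str]


@dataclass(frozen=True)
class StatusMap:
    """Node roles plus the data-name -> network-node resolution used."""

    status: dict[str, frozenset[str]]
    stimulus_nodes: dict[str, str]   # data cue name -> node
    inhibitor_nodes: dict[str, str]  # data cue name -> node
    signal_nodes: dict[str, str]     # data signal name -> node

    def designated(self) -> set[str]:
        return {n for n, st in self.status.items() if st}

    def of(self, node: str) -> frozenset[str]:
        return self.status.get(node, frozenset())


def _resolve(names, nodes_by_lower, aliases, kind, missing):
    out = {}
    for name in names:
        target = aliases.get(name, name)
        node = nodes_by_lower.get(target.lower())
        if node is None:
            missing.append(f"{kind} {name!r}")
        else:
            out[name] = node
    return out


def mark_status(
    net: PriorKnowledgeNetwork,
    data: MidasDataset,
    aliases: dict[str, str] | None = None,
) -> StatusMap:
    """Label nodes as stimulated / inhibited / measured from the dataset.

    Data names are matched to node names case-insensitively; ``aliases`` maps
    data names to node names explicitly where spelling differs.  Unresolvable
    cue/signal names raise with the full offender list.
    """
    aliases = aliases or {}
    nodes_by_lower: dict[str, str] = {}
    for n in net.nodes:
        if n.lower() in nodes_by_lower and nodes_by_lower[n.lower()] != n:
            raise ValueError(f"case-insensitive node name clash on {n!r}")
        nodes_by_lower[n.lower()] = n
    missing: list[str] = []
    stim = _resolve(data.stimuli, nodes_by_lower, aliases, "stimulus", missing)
    inhib = _resolve(data.inhibitors, nodes_by_lower, aliases, "inhibitor", missing)
    sig = _resolve(data.signals, nodes_by_lower, aliases, "signal", missing)
    if missing:
        raise ValueError("names not found in network: " + ", ".join(missing))
    status: dict[str, set[str]] = {n: set() for n in net.nodes}
    for node in stim.values():
        status[node].add("stimulated")
    for node in inhib.values():
        status[node].add("inhibited")
    for node in sig.values():
        status[node].add("measured")
    return StatusMap(
        status={n: frozenset(s) for n, s in status.items()},
        stimulus_nodes=stim,
        inhibitor_nodes=inhib,
        signal_nodes=sig,
    )


def cut_unreachable(
    net: PriorKnowledgeNetwork, status: StatusMap
) -> PriorKnowledgeNetwork:
    """Drop non-controllable / non-observable undesignated nodes.

    A node survives iff it lies on some directed cue-to-signal path section:
    it is reachable from a cue AND reaches a signal.  Designated nodes are
    always kept (with a warning if isolated).
    """
    g = nx.DiGraph()
    g.add_nodes_from(net.nodes)
    g.add_edges_from((s, t) for s, _, t in net.edges)
    cues = set(status.stimulus_nodes.values()) | set(status.inhibitor_nodes.values())
    signals = set(status.signal_nodes.values())
    from_cues: set[str] = set(cues)
    for c in cues:
        from_cues |= nx.descendants(g, c)
    to_signals: set[str] = set(signals)
    rev = g.reverse(copy=False)
    for s in signals:
        to_signals |= nx.descendants(rev, s)
    keep = from_cues & to_signals
    designated = status.designated()
    for node in designated - keep:
        warnings.warn(f"designated node {node!r} is disconnected from the cue/signal flow")
    keep |= designated
    return PriorKnowledgeNetwork.from_edges(
        [(s, sg, t) for s, sg, t in net.edges if s in keep and t in keep],
        extra_nodes=keep,
    )


def compress(
    net: PriorKnowledgeNetwork, status: StatusMap
) -> tuple[PriorKnowledgeNetwork, list[str], dict[Edge, frozenset[Edge]]]:
    """Remove undesignated pass-through nodes, rewiring around them.

    A node with exactly one incoming or exactly one outgoing edge is removed
    and each (in, out) pair replaced by a direct edge whose sign is the
    product of the two signs.  Removal is skipped when it would create a
    self-loop or contradict an existing edge (same endpoints, opposite sign).
    Returns the compressed network, the removed-node list, and a provenance
    map from each surviving edge to the original PKN edges it summarises.
    """
    edges: dict[Edge, set[Edge]] = {e: {e} for e in net.edges}
    nodes = set(net.nodes)
    designated = status.designated()
    compressed: list[str] = []

    changed = True
    while changed:
        changed = False
        for node in sorted(nodes):
            if node in designated:
                continue
            ins = [(s, sg) for (s, sg, t) in edges if t == node]
            outs = [(t, sg) for (s, sg, t) in edges if s == node]
            if not ins and not outs:
                # isolated undesignated node (cut_unreachable normally
                # removes these already)
                nodes.discard(node)
                compressed.append(node)
                changed = True
                continue
            if not ins or not outs:
                for e in [e for e in edges if node in (e[0], e[2])]:
                    del edges[e]
                nodes.discard(node)
                compressed.append(node)
                changed = True
                continue
            if len(ins) != 1 and len(outs) != 1:
                continue
            if len(ins) > 1 and any(sg < 0 for _, sg in outs):
                # removing a multi-input node through a negative output
                # would turn OR into AND (De Morgan) and change the logic
                continue
            new_edges = {}
            ok = True
            for (s, sg_in) in ins:
                for (t, sg_out) in outs:
                    sign = sg_in * sg_out
                    if s == t:
                        ok = False  # would create a self-loop
                        break
                    if (s, -sign, t) in edges:
                        ok = False  # would contradict an existing edge
                        break
                    prov = set()
                    for e in edges:
                        if e[2] == node and e[0] == s and e[1] == sg_in:
                            prov |= edges[e]
                        if e[0] == node and e[2] == t and e[1] == sg_out:
                            prov |= edges[e]
                    new_edges.setdefault((s, sign, t), set()).update(prov)
                if not ok:
                    break
            if not ok:
                continue
            for e in [e for e in edges if node in (e[0], e[2])]:
                del edges[e]
            for e, prov in new_edges.items():
                edges.setdefault(e, set()).update(prov)
            nodes.discard(node)
            compressed.append(node)
            changed = True
    out_net = PriorKnowledgeNetwork.from_edges(list(edges), extra_nodes=nodes)
    provenance = {e: frozenset(p) for e, p in edges.items()}
    return out_net, compressed, provenance


@dataclass(frozen=True)
class Gate:
    """One candidate hyperedge: AND over signed input literals -> output."""

    inputs: tuple[tuple[str, int], ...]
    output: str

    def __post_init__(self):
        names = [n for n, _ in self.inputs]
        if len(set(names)) != len(names):
            raise ValueError(f"gate into {self.output!r} has duplicate input nodes")

    @property
    def n_inputs(self) -> int:
        return len(self.inputs)

    def label(self) -> str:
        lits = "^".join(("!" if sg < 0 else "") + n for n, sg in self.inputs)
        return f"{lits}=>{self.output}"


@dataclass(frozen=True)
class Scaffold:
    """Compressed + expanded hypergraph of candidate logic gates.

    Gate order is deterministic (sorted by output, then arity, then inputs)
    so that bitstring position ``e`` always refers to the same gate.  ``v``
    holds the per-gate input count and ``v_es`` its total, the normaliser of
    the size penalty.
    """

    nodes: tuple[str, ...]
    gates: tuple[Gate, ...]
    provenance: tuple[frozenset[Edge], ...] = field(default=())

    @property
    def n_gates(self) -> int:
        return len(self.gates)

    @property
    def v(self) -> np.ndarray:
        return np.array([g.n_inputs for g in self.gates], dtype=float)

    @property
    def v_es(self) -> float:
        return float(self.v.sum())

    def node_index(self) -> dict[str, int]:
        return {n: i for i, n in enumerate(self.nodes)}

    def gates_into(self, node: str) -> list[int]:
        return [i for i, g in enumerate(self.gates) if g.output == node]

    def gate_labels(self) -> list[str]:
        return [g.label() for g in self.gates]

    def to_sif_lines(self) -> list[str]:
        """Extended SIF dialect: AND gates go through auxiliary and_k nodes."""
        lines = []
        k = 0
        for g in self.gates:
            if g.n_inputs == 1:
                (n, sg), = g.inputs
                lines.append(f"{n}\t{sg}\t{g.output}")
            else:
                k += 1
                aux = f"and_{k}"
                for n, sg in g.inputs:
                    lines.append(f"{n}\t{sg}\t{aux}")
                lines.append(f"{aux}\t1\t{g.output}")
        return lines

    def to_json_dict(self) -> dict:
        return {
            "nodes": list(self.nodes),
            "gates": [
                {
                    "output": g.output,
                    "inputs": [[n, sg] for n, sg in g.inputs],
                    "pkn_edges": sorted(
                        [list(e) for e in (self.provenance[i] if self.provenance else [])]
                    ),
                }
                for i, g in enumerate(self.gates)
            ],
        }


def expand(
    net: PriorKnowledgeNetwork,
    max_and_arity: int = 2,
    provenance: dict[Edge, frozenset[Edge]] | None = None,
) -> Scaffold:
    """Expand each node's input edges into candidate gates.

    For a node with ``d`` distinct inputs and arity 2 this yields
    ``d + C(d, 2)`` hyperedges.  Raising ``max_and_arity`` only ever adds
    gates.  Edge signs are carried into the gate literals.
    """
    if max_and_arity < 1:
        raise ValueError("max_and_arity must be >= 1")
    provenance = provenance or {e: frozenset({e}) for e in net.edges}
    gates: list[Gate] = []
    gate_prov: list[frozenset[Edge]] = []
    for target in sorted(net.nodes):
        incoming = sorted(set((s, sg) for s, sg, t in net.edges if t == target))
        for size in range(1, min(max_and_arity, len(incoming)) + 1):
            for combo in itertools.combinations(incoming, size):
                if len({n for n, _ in combo}) != size:
                    continue  # same node with both signs cannot share an AND
                gates.append(Gate(inputs=tuple(sorted(combo)), output=target))
                prov: set[Edge] = set()
                for n, sg in combo:
                    prov |= set(provenance.get((n, sg, target), {(n, sg, target)}))
                gate_prov.append(frozenset(prov))
    order = sorted(
        range(len(gates)),
        key=lambda i: (gates[i].output, gates[i].n_inputs, gates[i].inputs),
    )
    return Scaffold(
        nodes=tuple(sorted(net.nodes)),
        gates=tuple(gates[i] for i in order),
        provenance=tuple(gate_prov[i] for i in order),
    )
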