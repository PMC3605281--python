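"""Synchronous Boolean simulation of a selected sub-model.

A candidate model is a bitstring over the scaffold gates.  Simulation starts
from the cue pattern of one experimental condition (stimulated nodes at their
treatment value, everything else 0), clamps inhibited nodes to 0 and stimuli
to their treatment value at every step, and synchronously updates all other
nodes: a node's next value is the OR over its selected gates of the AND over
each gate's literals (a literal is the input value, or its complement for a
negative sign).  Nodes with no selected incoming gate hold their initial /
clamped value, which makes the empty model well defined.  Iteration stops at
a fixpoint or after ``max_iter`` steps; nodes still changing at the cutoff
are flagged UNRESOLVED (NaN) — this is how oscillations (e.g. negative
feedback loops) are detected and later penalised as mismatches.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .preprocess import Scaffold, StatusMap
from .formats import MidasDataset

__all__ = ["CompiledModel", "SimResult", "condition_clamps", "simulate_steady",
           "simulate_all", "default_max_iter"]


def default_max_iter(scaffold: Scaffold) -> int:
    return math.ceil(1.2 * len(scaffold.nodes))


@dataclass
class CompiledModel:
    """Flattened gate arrays for one (scaffold, bitstring) pair.

    ``lit_node``/``lit_neg`` list every literal of every selected gate;
    ``seg_starts`` delimits gates within the literal arrays (for
    ``minimum.reduceat``); ``gate_target`` maps each selected gate to its
    output node index.
    """

    n_nodes: int
    lit_node: np.ndarray
    lit_neg: np.ndarray
    seg_starts: np.ndarray
    gate_target: np.ndarray
    has_gate: np.ndarray  # bool per node: any selected incoming gate

    def step(self, x: np.ndarray, base: np.ndarray) -> np.ndarray:
        """One synchronous update (works for Boolean 0/1 and fuzzy values)."""
        new = np.where(self.has_gate, 0.0, base)
        if len(self.gate_target):
            lit = x[self.lit_node]
            np.subtract(1.0, lit, out=lit, where=self.lit_neg)
            gate_vals = np.minimum.reduceat(lit, self.seg_starts)
            np.maximum.at(new, self.gate_target, gate_vals)
        return new


def compile_model(scaffold: Scaffold, bits: np.ndarray) -> CompiledModel:
    bits = np.asarray(bits)
    if bits.shape != (scaffold.n_gates,):
        raise ValueError(
            f"bitstring length {bits.shape} does not match scaffold "
            f"gate count {scaffold.n_gates}"
        )
    idx = scaffold.node_index()
    lit_node, lit_neg, seg_starts, gate_target = [], [], [], []
    pos = 0
    for e, gate in enumerate(scaffold.gates):
        if not bits[e]:
            continue
        seg_starts.append(pos)
        gate_target.append(idx[gate.output])
        for name, sign in gate.inputs:
            lit_node.append(idx[name])
            lit_neg.append(sign < 0)
            pos += 1
    has_gate = np.zeros(len(scaffold.nodes), dtype=bool)
    has_gate[gate_target] = True
    return CompiledModel(
        n_nodes=len(scaffold.nodes),
        lit_node=np.array(lit_node, dtype=np.intp),
        lit_neg=np.array(lit_neg, dtype=bool),
        seg_starts=np.array(seg_starts, dtype=np.intp),
        gate_target=np.array(gate_target, dtype=np.intp),
        has_gate=has_gate,
    )


@dataclass
class SimResult:
    """Per-condition steady states over the scaffold nodes.

    ``states[k, i]`` is the value of node ``i`` under condition ``k``; NaN
    marks UNRESOLVED nodes of non-converged conditions.  Clamped cues always
    retain their clamp value.
    """

    nodes: tuple[str, ...]
    states: np.ndarray
    converged: np.ndarray
    iterations_used: np.ndarray

    def by_node(self, name: str) -> np.ndarray:
        return self.states[:, self.nodes.index(name)]


def condition_clamps(
    data: MidasDataset, status: StatusMap, k: int
) -> tuple[dict[str, float], set[str]]:
    """Cue clamps of condition ``k``: stimulus values and inhibited nodes."""
    stim_vals: dict[str, float] = {}
    inhibited: set[str] = set()
    for j, cue in enumerate(data.cues):
        v = data.treatments[k, j]
        if cue in data.stimuli:
            stim_vals[status.stimulus_nodes[cue]] = float(v)
        elif v:  # inhibitor present -> full block
            inhibited.add(status.inhibitor_nodes[cue])
    return stim_vals, inhibited


def _apply_clamps(x, stim_idx, stim_val, inhib_idx, extra_idx=None, extra_val=None):
    x[stim_idx] = stim_val
    x[inhib_idx] = 0.0
    if extra_idx is not None:
        x[extra_idx] = extra_val
    return x


def simulate_steady(
    scaffold: Scaffold,
    bits: np.ndarray,
    stimuli: dict[str, float],
    inhibited=(),
    max_iter: int | None = None,
    initial: np.ndarray | None = None,
    clamps: dict[str, float] | None = None,
    compiled: CompiledModel | None = None,
) -> tuple[np.ndarray, bool, int]:
    """Run one condition to (pseudo-)steady state.

    Returns ``(states, converged, iterations)``; non-converged runs report
    NaN for the nodes that changed in the final step.  ``initial`` overrides
    the all-zero start (used by the two-time-scale trainer) and ``clamps``
    holds arbitrary extra nodes fixed (node locking).
    """
    model = compiled if compiled is not None else compile_model(scaffold, bits)
    idx = scaffold.node_index()
    max_iter = max_iter or default_max_iter(scaffold)
    stim_idx = np.array([idx[n] for n in stimuli], dtype=np.intp)
    stim_val = np.array([stimuli[n] for n in stimuli], dtype=float)
    inhib_idx = np.array([idx[n] for n in inhibited], dtype=np.intp)
    extra_idx = extra_val = None
    if clamps:
        extra_idx = np.array([idx[n] for n in clamps], dtype=np.intp)
        extra_val = np.array(list(clamps.values()), dtype=float)

    if initial is not None:
        x = np.asarray(initial, dtype=float).copy()
    else:
        x = np.zeros(model.n_nodes)
    _apply_clamps(x, stim_idx, stim_val, inhib_idx, extra_idx, extra_val)
    base = x.copy()  # hold value for gate-less nodes

    for it in range(1, max_iter + 1):
        new = model.step(x, base)
        _apply_clamps(new, stim_idx, stim_val, inhib_idx, extra_idx, extra_val)
        if np.array_equal(new, x):
            return x, True, it
        x = new
    # non-convergence: probe further synchronous steps and flag every node
    # that still changes (a single-step check would miss half the nodes of
    # longer-period cycles)
    changed = np.zeros(model.n_nodes, dtype=bool)
    y = x
    for _ in range(max(4, max_iter)):
        y2 = model.step(y, base)
        _apply_clamps(y2, stim_idx, stim_val, inhib_idx, extra_idx, extra_val)
        changed |= y2 != y
        y = y2
    out = x.copy()
    out[changed] = np.nan
    return out, False, max_iter


def simulate_all(
    scaffold: Scaffold,
    bits: np.ndarray,
    data: MidasDataset,
    status: StatusMap,
    max_iter: int | None = None,
) -> SimResult:
    """Apply :func:`simulate_steady` to every treatment row of the dataset."""
    model = compile_model(scaffold, bits)
    n = data.n_conditions
    states = np.zeros((n, len(scaffold.nodes)))
    converged = np.zeros(n, dtype=bool)
    iters = np.zeros(n, dtype=int)
    for k in range(n):
        stim, inhib = condition_clamps(data, status, k)
        states[k], converged[k], iters[k] = simulate_steady(
            scaffold, bits, stim, inhib, max_iter=max_iter, compiled=model
        )
    return SimResult(
        nodes=scaffold.nodes, states=states, converged=converged,
        iterations_used=iters,
    )
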