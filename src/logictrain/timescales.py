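"""Boolean training against two pseudo-steady states (tau1 then tau2).

When measurements at two post-perturbation times reflect mechanisms acting on
different time scales (fast post-translational signaling, then slower
expression-dependent feedback), the model is trained in two passes.  The
first pass is ordinary steady-state training against the tau1 time point.
The second pass searches only the gates *absent* from the tau1 optimum and
scores them against tau2: each condition is re-simulated from its tau1 steady
state, with every node that receives a selected tau2 gate locked to that
gate's output evaluated at the tau1 state (OR across multiple tau2 gates into
the same node) and held there while the rest of the network relaxes through
the combined tau1+tau2 model.  Locking is what lets a slow negative feedback
switch its target off permanently instead of oscillating forever.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .boolean_engine import (
    SimResult, compile_model, condition_clamps, simulate_steady, simulate_all,
)
from .formats import MidasDataset
from .preprocess import Scaffold, StatusMap
from .scoring import ScoringConfig, theta_f, theta_s
from .search import GAConfig, SearchResult, ga_optimize, optimize_boolean

__all__ = ["TwoStepResult", "simulate_two_step", "train_two_steps"]


@dataclass
class TwoStepResult:
    """tau1 search, tau2 search over the complementary gate space, lock info."""

    tau1: SearchResult
    tau2: SearchResult
    tau1_states: SimResult
    t1_index: int
    t2_index: int

    @property
    def combined_bits(self) -> np.ndarray:
        return (self.tau1.best_bits | self.tau2.best_bits).astype(int)


def _tau1_initial(states: np.ndarray) -> np.ndarray:
    # an UNRESOLVED tau1 node restarts at 0 for the tau2 relaxation
    return np.where(np.isfinite(states), states, 0.0)


def simulate_two_step(
    scaffold: Scaffold,
    bits1: np.ndarray,
    bits2: np.ndarray,
    data: MidasDataset,
    status: StatusMap,
    tau1_states: SimResult,
    max_iter: int | None = None,
) -> SimResult:
    """Simulate the tau2 phase for every condition.

    ``bits2`` selects the added gates; their targets are locked to the gate
    outputs evaluated at the tau1 steady state, then the combined model
    relaxes from that state.
    """
    bits1 = np.asarray(bits1, dtype=int)
    bits2 = np.asarray(bits2, dtype=int)
    combined = (bits1 | bits2).astype(int)
    model2 = compile_model(scaffold, bits2)
    model_c = compile_model(scaffold, combined)
    idx = scaffold.node_index()
    n = data.n_conditions
    states = np.zeros((n, len(scaffold.nodes)))
    converged = np.zeros(n, dtype=bool)
    iters = np.zeros(n, dtype=int)
    tau2_targets = sorted({g.output for e, g in enumerate(scaffold.gates) if bits2[e]})
    for k in range(n):
        stim, inhib = condition_clamps(data, status, k)
        x1 = _tau1_initial(tau1_states.states[k])
        locks: dict[str, float] = {}
        if tau2_targets:
            stepped = model2.step(x1.copy(), np.zeros_like(x1))
            for node in tau2_targets:
                locks[node] = float(stepped[idx[node]])
        states[k], converged[k], iters[k] = simulate_steady(
            scaffold, combined, stim, inhib, max_iter=max_iter,
            initial=x1, clamps=locks, compiled=model_c,
        )
    return SimResult(nodes=scaffold.nodes, states=states, converged=converged,
                     iterations_used=iters)


def train_two_steps(
    scaffold: Scaffold,
    data: MidasDataset,
    status: StatusMap,
    t1_index: int,
    t2_index: int,
    scoring: ScoringConfig,
    ga: GAConfig,
) -> TwoStepResult:
    """Two-pass training; the tau2 size penalty covers the added gates only."""
    if t1_index == t2_index:
        raise ValueError("t1_index and t2_index must differ")
    n_times = len(data.times)
    if not (0 <= t1_index < n_times and 0 <= t2_index < n_times):
        raise ValueError("time index out of range")

    res1 = optimize_boolean(scaffold, data, status, scoring, ga,
                            time_index=t1_index)
    bits1 = res1.best_bits
    tau1_states = simulate_all(scaffold, bits1, data, status)

    mask = [0 if bits1[e] else None for e in range(scaffold.n_gates)]

    def objective2(bits2: np.ndarray) -> float:
        sim2 = simulate_two_step(scaffold, bits1, bits2, data, status,
                                 tau1_states)
        return (
            theta_f(sim2, data, status, t2_index, scoring.na_penalty)
            + scoring.alpha * theta_s(scaffold, bits2)
        )

    res2 = ga_optimize(scaffold.n_gates, objective2, ga, search_mask=mask)
    return TwoStepResult(tau1=res1, tau2=res2, tau1_states=tau1_states,
                         t1_index=t1_index, t2_index=t2_index)
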