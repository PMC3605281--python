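"""Constrained fuzzy logic at steady state.

Node states are continuous in [0, 1].  Each selected gate input passes
through a transfer function from a small menu of normalized Hill curves

    f(x) = g * x^n * (1 + K^n) / (x^n + K^n)

(normalisation makes f(1) = g and f(0) = 0; with unit gain g = 1 the
function agrees with Boolean logic at the extremes, which keeps the fuzzy
model consistent with the Boolean one at 0/1 vertices).  Gains below 1 let a
gate drive its target only partially — this is what captures sub-maximal
activation that no Boolean model can express.  Gate composition is AND = min
over transferred literals and OR = max over co-selected gates; a negative
literal transfers the complement, f(1 - x).

Training couples the topology bitstring with one menu index per gate input
(reusing the binary GA), and is followed by a refinement step (continuous
local optimisation of the selected transfer parameters) and a reduction step
(greedy removal of gates / demotion of transfers to identity whenever the
objective worsens by less than a threshold).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize as sciopt

from .boolean_engine import SimResult, condition_clamps
from .formats import MidasDataset
from .preprocess import Scaffold, StatusMap
from .scoring import ScoringConfig, theta_f, theta_s
from .search import GAConfig, SearchResult, ga_optimize

__all__ = ["TransferFunction", "FuzzyModel", "default_menu", "eval_transfer",
           "simulate_fuzzy", "simulate_fuzzy_all", "fuzzy_theta",
           "train_fuzzy", "refine_and_reduce", "encode_boolean_chromosome"]


@dataclass(frozen=True)
class TransferFunction:
    """Normalized Hill transfer; ``identity`` bypasses the Hill curve."""

    n_h: float = 2.0
    k: float = 0.5
    gain: float = 1.0
    identity: bool = False

    def __post_init__(self):
        if not self.identity:
            if self.n_h <= 0 or not (0 < self.k <= 1):
                raise ValueError("need n_h > 0 and K in (0, 1]")
            if not (0 < self.gain <= 1):
                raise ValueError("gain must be in (0, 1]")

    def __call__(self, x: float) -> float:
        return eval_transfer(self, x)


IDENTITY = TransferFunction(identity=True)


def eval_transfer(tf: TransferFunction, x) -> float:
    """Evaluate on [0, 1]; out-of-range inputs are clipped with a warning."""
    x = np.asarray(x, dtype=float)
    if np.any((x < -1e-12) | (x > 1 + 1e-12)):
        warnings.warn("transfer-function input outside [0, 1]; clipping")
    x = np.clip(x, 0.0, 1.0)
    if tf.identity:
        out = x
    else:
        xn = x**tf.n_h
        kn = tf.k**tf.n_h
        out = tf.gain * xn * (1.0 + kn) / (xn + kn)
    return float(out) if out.ndim == 0 else out


def default_menu() -> tuple[TransferFunction, ...]:
    """Discrete transfer menu searched by the GA (configurable).

    A grid of normalized Hill curves (two steepnesses, seven midpoints, unit
    and half gain) plus the identity.
    """
    menu = [IDENTITY]
    for gain in (1.0, 0.5):
        for n_h in (2.0, 4.0):
            for k in (0.2, 0.3, 0.4, 0.55, 0.7, 0.85, 1.0):
                menu.append(TransferFunction(n_h=n_h, k=k, gain=gain))
    return tuple(menu)


@dataclass
class FuzzyModel:
    """Topology bits plus one transfer function per selected gate input.

    ``transfers[(e, j)]`` is the transfer of input ``j`` of gate ``e``;
    entries exist exactly for selected gates.
    """

    bits: np.ndarray
    transfers: dict[tuple[int, int], TransferFunction]

    def validate(self, scaffold: Scaffold) -> None:
        expected = {
            (e, j)
            for e, g in enumerate(scaffold.gates)
            if self.bits[e]
            for j in range(g.n_inputs)
        }
        if expected != set(self.transfers):
            raise ValueError("transfer parameters do not match selected gates")


def _compile_fuzzy(scaffold: Scaffold, model: FuzzyModel):
    idx = scaffold.node_index()
    gates = []
    for e, gate in enumerate(scaffold.gates):
        if not model.bits[e]:
            continue
        lits = []
        for j, (name, sign) in enumerate(gate.inputs):
            lits.append((idx[name], sign, model.transfers[(e, j)]))
        gates.append((idx[gate.output], lits))
    has_gate = np.zeros(len(scaffold.nodes), dtype=bool)
    for tgt, _ in gates:
        has_gate[tgt] = True
    return gates, has_gate


def simulate_fuzzy(
    scaffold: Scaffold,
    model: FuzzyModel,
    stimuli: dict[str, float],
    inhibited=(),
    tol: float = 1e-4,
    max_iter: int = 100,
    _compiled=None,
) -> tuple[np.ndarray, bool, int]:
    """Synchronous fixed-point iteration of the continuous update map."""
    gates, has_gate = _compiled if _compiled is not None else _compile_fuzzy(
        scaffold, model)
    idx = scaffold.node_index()
    stim_idx = np.array([idx[n] for n in stimuli], dtype=np.intp)
    stim_val = np.array([stimuli[n] for n in stimuli], dtype=float)
    inhib_idx = np.array([idx[n] for n in inhibited], dtype=np.intp)
    x = np.zeros(len(scaffold.nodes))
    x[stim_idx] = stim_val
    x[inhib_idx] = 0.0
    base = x.copy()
    for it in range(1, max_iter + 1):
        new = np.where(has_gate, 0.0, base)
        for tgt, lits in gates:
            val = 1.0
            for node, sign, tf in lits:
                xin = x[node] if sign > 0 else 1.0 - x[node]
                val = min(val, eval_transfer(tf, xin))  # AND = min
            new[tgt] = max(new[tgt], val)               # OR = max
        new[stim_idx] = stim_val
        new[inhib_idx] = 0.0
        if np.max(np.abs(new - x)) < tol:
            return new, True, it
        x = new
    # non-convergence: probe a further window and flag every node that still
    # moves by more than the tolerance (longer-period cycles alias a
    # single-step check)
    changed = np.zeros(len(scaffold.nodes), dtype=bool)
    y = x
    for _ in range(8):
        y2 = np.where(has_gate, 0.0, base)
        for tgt, lits in gates:
            val = 1.0
            for node, sign, tf in lits:
                xin = y[node] if sign > 0 else 1.0 - y[node]
                val = min(val, eval_transfer(tf, xin))
            y2[tgt] = max(y2[tgt], val)
        y2[stim_idx] = stim_val
        y2[inhib_idx] = 0.0
        changed |= np.abs(y2 - y) >= tol
        y = y2
    out = x.copy()
    out[changed] = np.nan
    return out, False, max_iter


def simulate_fuzzy_all(
    scaffold: Scaffold,
    model: FuzzyModel,
    data: MidasDataset,
    status: StatusMap,
    tol: float = 1e-4,
    max_iter: int = 100,
) -> SimResult:
    compiled = _compile_fuzzy(scaffold, model)
    n = data.n_conditions
    states = np.zeros((n, len(scaffold.nodes)))
    converged = np.zeros(n, dtype=bool)
    iters = np.zeros(n, dtype=int)
    for k in range(n):
        stim, inhib = condition_clamps(data, status, k)
        states[k], converged[k], iters[k] = simulate_fuzzy(
            scaffold, model, stim, inhib, tol=tol, max_iter=max_iter,
            _compiled=compiled,
        )
    return SimResult(nodes=scaffold.nodes, states=states, converged=converged,
                     iterations_used=iters)


def fuzzy_theta(
    scaffold: Scaffold,
    model: FuzzyModel,
    data: MidasDataset,
    status: StatusMap,
    scoring: ScoringConfig,
    time_index: int,
) -> float:
    sim = simulate_fuzzy_all(scaffold, model, data, status)
    return (
        theta_f(sim, data, status, time_index, scoring.na_penalty)
        + scoring.alpha * theta_s(scaffold, model.bits)
    )


# ---------------------------------------------------------------------------
# Training


def _input_slots(scaffold: Scaffold) -> list[tuple[int, int]]:
    return [
        (e, j)
        for e, g in enumerate(scaffold.gates)
        for j in range(g.n_inputs)
    ]


def _menu_gene_bits(menu_size: int) -> int:
    return max(1, math.ceil(math.log2(menu_size))) if menu_size > 1 else 0


def decode_chromosome(
    chrom: np.ndarray, scaffold: Scaffold, menu
) -> FuzzyModel:
    r = scaffold.n_gates
    slots = _input_slots(scaffold)
    b = _menu_gene_bits(len(menu))
    bits = np.asarray(chrom[:r], dtype=int)
    transfers = {}
    for s, (e, j) in enumerate(slots):
        if not bits[e]:
            continue
        gene = chrom[r + s * b: r + (s + 1) * b] if b else []
        index = 0
        for bit in gene:
            index = (index << 1) | int(bit)
        transfers[(e, j)] = menu[index % len(menu)]
    return FuzzyModel(bits=bits, transfers=transfers)


def encode_boolean_chromosome(bits: np.ndarray, scaffold: Scaffold, menu,
                              menu_index: int | None = None) -> np.ndarray:
    """Chromosome for a Boolean model: given bits, unit-gain transfers.

    Used to seed the fuzzy GA with the Boolean steady-state optimum (any
    unit-gain normalized Hill agrees with Boolean logic on {0, 1} states).
    """
    if menu_index is None:
        menu_index = next(
            i for i, tf in enumerate(menu)
            if (tf.identity or tf.gain == 1.0)
        )
    slots = _input_slots(scaffold)
    b = _menu_gene_bits(len(menu))
    chrom = np.zeros(scaffold.n_gates + b * len(slots), dtype=int)
    chrom[: scaffold.n_gates] = np.asarray(bits, dtype=int)
    gene = [(menu_index >> (b - 1 - i)) & 1 for i in range(b)]
    for s in range(len(slots)):
        chrom[scaffold.n_gates + s * b: scaffold.n_gates + (s + 1) * b] = gene
    return chrom


def train_fuzzy(
    scaffold: Scaffold,
    data: MidasDataset,
    status: StatusMap,
    scoring: ScoringConfig,
    ga: GAConfig,
    menu=None,
    time_index: int = 1,
    seeds=(),
) -> tuple[FuzzyModel, SearchResult]:
    """GA over topology bits + per-input transfer menu indices."""
    menu = tuple(menu) if menu is not None else default_menu()
    slots = _input_slots(scaffold)
    b = _menu_gene_bits(len(menu))
    n_bits = scaffold.n_gates + b * len(slots)

    def objective(chrom: np.ndarray) -> float:
        model = decode_chromosome(chrom, scaffold, menu)
        return fuzzy_theta(scaffold, model, data, status, scoring, time_index)

    res = ga_optimize(n_bits, objective, ga, seeds=seeds)
    return decode_chromosome(res.best_bits, scaffold, menu), res


def refine_and_reduce(
    scaffold: Scaffold,
    model: FuzzyModel,
    data: MidasDataset,
    status: StatusMap,
    scoring: ScoringConfig,
    time_index: int = 1,
    reduction_threshold: float = 1e-4,
    refine_maxiter: int = 200,
) -> FuzzyModel:
    """Fine-tune transfer parameters, then greedily simplify the topology.

    Refinement runs a Nelder-Mead local search over the (n_h, K, gain)
    triples of all selected non-identity transfers, keeping the result only
    if it does not worsen the objective.  Reduction repeatedly tries to drop
    a gate or demote a transfer to the identity, accepting any move that
    worsens the objective by less than ``reduction_threshold``.
    """

    def score(m: FuzzyModel) -> float:
        return fuzzy_theta(scaffold, m, data, status, scoring, time_index)

    current = FuzzyModel(bits=model.bits.copy(), transfers=dict(model.transfers))
    best = score(current)

    # --- refinement
    keys = [k for k, tf in current.transfers.items() if not tf.identity]
    if keys:
        x0 = np.concatenate(
            [[current.transfers[k].n_h, current.transfers[k].k,
              current.transfers[k].gain] for k in keys]
        )

        def unpack(x):
            tr = dict(current.transfers)
            for i, key in enumerate(keys):
                n_h = float(np.clip(x[3 * i], 1.0, 10.0))
                kk = float(np.clip(x[3 * i + 1], 0.01, 1.0))
                g = float(np.clip(x[3 * i + 2], 0.01, 1.0))
                tr[key] = TransferFunction(n_h=n_h, k=kk, gain=g)
            return FuzzyModel(bits=current.bits, transfers=tr)

        opt = sciopt.minimize(
            lambda x: score(unpack(x)), x0, method="Nelder-Mead",
            options={"maxiter": refine_maxiter, "xatol": 1e-3, "fatol": 1e-8},
        )
        refined = unpack(opt.x)
        refined_score = score(refined)
        if refined_score <= best:
            current, best = refined, refined_score

    # --- reduction
    improved = True
    while improved:
        improved = False
        for e in np.flatnonzero(current.bits):
            bits = current.bits.copy()
            bits[e] = 0
            tr = {k: v for k, v in current.transfers.items() if k[0] != e}
            cand = FuzzyModel(bits=bits, transfers=tr)
            s = score(cand)
            if s - best <= reduction_threshold:
                current, best = cand, min(best, s)
                improved = True
                break
        if improved:
            continue
        for key, tf in list(current.transfers.items()):
            if tf.identity:
                continue
            tr = dict(current.transfers)
            tr[key] = IDENTITY
            cand = FuzzyModel(bits=current.bits, transfers=tr)
            s = score(cand)
            if s - best <= reduction_threshold:
                current, best = cand, min(best, s)
                improved = True
                break
    return current
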