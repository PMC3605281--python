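"""Discrete-time Boolean fitting of full time courses.

The synchronous Boolean update of the steady-state engine is reused, but the
whole trajectory is kept and compared against every measured time point.  A
single time-scale factor ``delta`` (data-time units per synchronous update
step) stretches the simulated step sequence onto the data's clock: the model
value at data time ``t`` is the state at step ``round(t / delta)`` (states
are step functions, so nearest-step sampling rather than interpolation;
steps beyond the simulated horizon hold the last state).  Because no
convergence is required, oscillations and transients are fitted directly.
Training couples the model bitstring with one extra chromosome gene indexing
a discretised delta grid, and reuses the GA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .boolean_engine import compile_model, condition_clamps
from .formats import MidasDataset
from .preprocess import Scaffold, StatusMap
from .scoring import ScoringConfig, theta_s
from .search import GAConfig, SearchResult, ga_optimize, exhaustive_optimize

__all__ = ["DtConfig", "DtResult", "simulate_trajectory", "score_dt",
           "train_dt"]


@dataclass(frozen=True)
class DtConfig:
    """Delta grid bounds (data-time units per step) and trajectory cap."""

    delta_min: float | None = None   # default: max_time / 100
    delta_max: float | None = None   # default: max_time
    grid_size: int = 20
    n_steps_cap: int = 1000

    def grid(self, max_time: float) -> np.ndarray:
        lo = self.delta_min if self.delta_min is not None else max_time / 100.0
        hi = self.delta_max if self.delta_max is not None else max_time
        if not (0 < lo <= hi):
            raise ValueError("need 0 < delta_min <= delta_max")
        if self.grid_size < 1:
            raise ValueError("grid_size must be >= 1")
        if self.grid_size == 1:
            return np.array([lo])
        return np.geomspace(lo, hi, self.grid_size)


def simulate_trajectory(
    scaffold: Scaffold,
    bits: np.ndarray,
    stimuli: dict[str, float],
    inhibited=(),
    n_steps: int = 10,
    compiled=None,
) -> np.ndarray:
    """Record every synchronous update step 0..n_steps ((n_steps+1) x nodes)."""
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    model = compiled if compiled is not None else compile_model(scaffold, bits)
    idx = scaffold.node_index()
    stim_idx = np.array([idx[n] for n in stimuli], dtype=np.intp)
    stim_val = np.array([stimuli[n] for n in stimuli], dtype=float)
    inhib_idx = np.array([idx[n] for n in inhibited], dtype=np.intp)
    x = np.zeros(model.n_nodes)
    x[stim_idx] = stim_val
    x[inhib_idx] = 0.0
    base = x.copy()
    traj = np.zeros((n_steps + 1, model.n_nodes))
    traj[0] = x
    for s in range(1, n_steps + 1):
        x = model.step(x, base)
        x[stim_idx] = stim_val
        x[inhib_idx] = 0.0
        traj[s] = x
    return traj


def _steps_for(times: np.ndarray, delta: float, cap: int) -> np.ndarray:
    return np.minimum(np.round(times / delta).astype(int), cap)


def score_dt(
    scaffold: Scaffold,
    bits: np.ndarray,
    delta: float,
    data: MidasDataset,
    status: StatusMap,
    scoring: ScoringConfig,
    n_steps_cap: int = 1000,
) -> float:
    """theta over ALL data times with the trajectory sampled at t/delta."""
    if delta <= 0:
        raise ValueError("delta must be > 0")
    model = compile_model(scaffold, bits)
    steps = _steps_for(data.times, delta, n_steps_cap)
    n_steps = max(int(steps.max()), 1)
    node_pos = scaffold.node_index()
    cols = [node_pos[status.signal_nodes[s]] for s in data.signals]
    total, n_g = 0.0, 0
    for k in range(data.n_conditions):
        stim, inhib = condition_clamps(data, status, k)
        traj = simulate_trajectory(scaffold, bits, stim, inhib,
                                   n_steps=n_steps, compiled=model)
        pred = traj[np.minimum(steps, n_steps)][:, cols].T  # signals x times
        obs = data.values[k]
        mask = np.isfinite(obs)
        total += float(((pred - obs) ** 2)[mask].sum())
        n_g += int(mask.sum())
    if n_g == 0:
        raise ValueError("no comparable data points")
    return total / n_g + scoring.alpha * theta_s(scaffold, bits)


@dataclass
class DtResult:
    search: SearchResult
    best_bits: np.ndarray
    best_delta: float
    delta_grid: np.ndarray


def _delta_gene_bits(grid_size: int) -> int:
    return max(1, math.ceil(math.log2(grid_size))) if grid_size > 1 else 0


def _decode(chrom: np.ndarray, r: int, grid: np.ndarray):
    bits = chrom[:r]
    gene = chrom[r:]
    index = 0
    for b in gene:
        index = (index << 1) | int(b)
    return bits, grid[index % len(grid)]


def train_dt(
    scaffold: Scaffold,
    data: MidasDataset,
    status: StatusMap,
    scoring: ScoringConfig,
    ga: GAConfig,
    dt_cfg: DtConfig = DtConfig(),
    exhaustive: bool = False,
) -> DtResult:
    """Joint GA over (bitstring, delta-grid index).

    With ``grid_size == 1`` this reduces to a Boolean fit at fixed delta.
    ``exhaustive=True`` enumerates the full chromosome space instead (oracle
    for small scaffolds).
    """
    max_time = float(data.times.max())
    grid = dt_cfg.grid(max_time)
    r = scaffold.n_gates
    n_gene = _delta_gene_bits(len(grid))

    def objective(chrom: np.ndarray) -> float:
        bits, delta = _decode(chrom, r, grid)
        return score_dt(scaffold, bits, delta, data, status, scoring,
                        dt_cfg.n_steps_cap)

    n_bits = r + n_gene
    if exhaustive:
        res = exhaustive_optimize(n_bits, objective, tolerance=ga.tolerance)
    else:
        res = ga_optimize(n_bits, objective, ga)
    best_bits, best_delta = _decode(res.best_bits, r, grid)
    return DtResult(search=res, best_bits=best_bits.copy(),
                    best_delta=float(best_delta), delta_grid=grid)
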