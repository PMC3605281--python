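"""Bipartite objective: fit term + size penalty.

The training score of a candidate model P is

    theta(P) = theta_f(P) + alpha * theta_s(P)

where ``theta_f`` is the mean squared deviation between model predictions and
normalized data over all matched (condition, readout, time) points, and
``theta_s = (1/v_es) * sum_e v_e P_e`` charges each selected gate its input
count, normalised by the total input count of the scaffold.  Because the data
is normalised rather than discretised, intermediate measurements contribute
intermediate penalties: a readout at 0.5 costs 0.25 whichever Boolean value
the model predicts.  UNRESOLVED predictions (oscillating nodes) are charged
``na_penalty`` per matched point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .boolean_engine import SimResult
from .formats import MidasDataset
from .preprocess import Scaffold, StatusMap

__all__ = ["ScoringConfig", "theta_f", "theta_s", "theta", "residual_table"]


@dataclass(frozen=True)
class ScoringConfig:
    """alpha balances fit against size; na_penalty prices an oscillating node."""

    alpha: float = 0.1
    na_penalty: float = 1.0

    def __post_init__(self):
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.na_penalty < 0:
            raise ValueError("na_penalty must be >= 0")


def _matched_arrays(sim: SimResult, data: MidasDataset, status: StatusMap,
                    time_index: int):
    node_pos = {n: i for i, n in enumerate(sim.nodes)}
    cols = [node_pos[status.signal_nodes[s]] for s in data.signals]
    pred = sim.states[:, cols]                    # conditions x signals
    obs = data.values[:, :, time_index]
    return pred, obs


def theta_f(
    sim: SimResult,
    data: MidasDataset,
    status: StatusMap,
    time_index: int,
    na_penalty: float = 1.0,
) -> float:
    """Mean squared deviation at the chosen pseudo-steady-state time.

    Missing data points are excluded from both the sum and the divisor
    ``n_g``; UNRESOLVED predictions contribute ``na_penalty`` each.
    """
    pred, obs = _matched_arrays(sim, data, status, time_index)
    mask = np.isfinite(obs)
    n_g = int(mask.sum())
    if n_g == 0:
        raise ValueError("no comparable data points (all missing)")
    sq = np.where(np.isfinite(pred), (pred - obs) ** 2, na_penalty)
    return float(sq[mask].sum() / n_g)


def theta_s(scaffold: Scaffold, bits: np.ndarray) -> float:
    """Size penalty (1/v_es) * sum of selected gates' input counts."""
    bits = np.asarray(bits, dtype=float)
    if bits.shape != (scaffold.n_gates,):
        raise ValueError("bitstring length does not match scaffold")
    if scaffold.v_es == 0:
        raise ValueError("empty scaffold (v_es = 0)")
    return float((scaffold.v * bits).sum() / scaffold.v_es)


def theta(
    scaffold: Scaffold,
    bits: np.ndarray,
    sim: SimResult,
    data: MidasDataset,
    status: StatusMap,
    cfg: ScoringConfig,
    time_index: int,
) -> float:
    return (
        theta_f(sim, data, status, time_index, cfg.na_penalty)
        + cfg.alpha * theta_s(scaffold, bits)
    )


def residual_table(
    sim: SimResult, data: MidasDataset, status: StatusMap, time_index: int,
    na_penalty: float = 1.0,
) -> dict[str, float]:
    """Per-readout mean squared residual (for score reports)."""
    pred, obs = _matched_arrays(sim, data, status, time_index)
    out = {}
    for l, sig in enumerate(data.signals):
        mask = np.isfinite(obs[:, l])
        if not mask.any():
            out[sig] = float("nan")
            continue
        sq = np.where(np.isfinite(pred[:, l]), (pred[:, l] - obs[:, l]) ** 2,
                      na_penalty)
        out[sig] = float(sq[mask].mean())
    return out
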