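"""Logic-derived ordinary differential equations.

Each non-cue species follows

    dx_i/dt = (Bbar_i(x) - x_i) / tau_i

where ``Bbar_i`` is a smooth continuous relaxation of node i's Boolean
update: every selected gate contributes the product of its transferred
literals (normalized Hill h(x) for an activating input, 1 - h(x) for an
inhibiting one), and co-selected gates combine through the probabilistic OR
``1 - prod(1 - gate)``.  At Boolean vertex inputs every transferred literal
is exactly 0 or 1, so ``Bbar`` reproduces the Boolean gate output — the
continuous model and the Boolean model agree at the extremes.  Because
``Bbar`` stays in [0, 1], the flow cannot leave the unit cube: the derivative
is non-negative at x_i = 0 and non-positive at x_i = 1.

Stimulated nodes are held at their treatment value and inhibited nodes at 0
for the whole trajectory; nodes with no selected input relax to 0.  Fitting
adjusts all transfer parameters (n_h, K per gate input) and time constants
(tau per dynamic node) against time-course data with a bound-constrained
global optimiser (differential evolution by default; any optimiser with the
same calling convention can be plugged in).  K and tau are searched in log
space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import differential_evolution, least_squares

from .boolean_engine import condition_clamps
from .formats import MidasDataset
from .preprocess import Scaffold, StatusMap

__all__ = ["OdeParams", "OdeFitConfig", "default_params", "build_rhs",
           "integrate", "simulate_ode_all", "fit_ode"]


def _hill(x, n, k):
    xn = np.maximum(x, 0.0) ** n
    kn = k**n
    return xn * (1.0 + kn) / (xn + kn)


@dataclass
class OdeParams:
    """Transfer parameters per selected gate input and tau per dynamic node.

    ``transfers[(e, j)] = (n_h, K)``; ``tau[node] > 0`` in data-time units
    for every node with at least one selected gate.
    """

    transfers: dict[tuple[int, int], tuple[float, float]]
    tau: dict[str, float]

    def __post_init__(self):
        for node, t in self.tau.items():
            if t <= 0:
                raise ValueError(f"tau for {node!r} must be > 0")


def default_params(scaffold: Scaffold, bits, n_h: float = 3.0, k: float = 0.5,
                   tau: float = 1.0) -> OdeParams:
    bits = np.asarray(bits, dtype=int)
    transfers = {
        (e, j): (n_h, k)
        for e, g in enumerate(scaffold.gates)
        if bits[e]
        for j in range(g.n_inputs)
    }
    taus = {g.output: tau for e, g in enumerate(scaffold.gates) if bits[e]}
    return OdeParams(transfers=transfers, tau=taus)


def build_rhs(
    scaffold: Scaffold,
    bits,
    params: OdeParams,
    stimuli: dict[str, float] | None = None,
    inhibited=(),
):
    """Vector field ``f(t, x) -> dx`` for one experimental condition.

    Raises if a selected gate input lacks transfer parameters or a driven
    node lacks a time constant.
    """
    bits = np.asarray(bits, dtype=int)
    idx = scaffold.node_index()
    n = len(scaffold.nodes)
    lit_node, lit_neg, lit_n, lit_kn, seg_starts, gate_target = \
        [], [], [], [], [], []
    pos = 0
    driven = set()
    for e, gate in enumerate(scaffold.gates):
        if not bits[e]:
            continue
        seg_starts.append(pos)
        gate_target.append(idx[gate.output])
        driven.add(gate.output)
        for j, (name, sign) in enumerate(gate.inputs):
            if (e, j) not in params.transfers:
                raise ValueError(
                    f"missing transfer parameters for gate {gate.label()!r} "
                    f"input {name!r}"
                )
            n_h, k = params.transfers[(e, j)]
            lit_node.append(idx[name])
            lit_neg.append(sign < 0)
            lit_n.append(float(n_h))
            lit_kn.append(float(k) ** float(n_h))
            pos += 1
    for node in driven:
        if node not in params.tau:
            raise ValueError(f"missing tau for node {node!r}")
    lit_node = np.array(lit_node, dtype=np.intp)
    lit_neg = np.array(lit_neg, dtype=bool)
    lit_n = np.array(lit_n)
    lit_kn = np.array(lit_kn)
    seg_starts = np.array(seg_starts, dtype=np.intp)
    gate_target = np.array(gate_target, dtype=np.intp)
    has_gate = np.zeros(n, dtype=bool)
    has_gate[gate_target] = True

    inv_tau = np.ones(n)
    for node, t in params.tau.items():
        inv_tau[idx[node]] = 1.0 / t
    stimuli = stimuli or {}
    clamped = np.zeros(n, dtype=bool)
    clamp_val = np.zeros(n)
    for name, v in stimuli.items():
        clamped[idx[name]] = True
        clamp_val[idx[name]] = v
    for name in inhibited:
        clamped[idx[name]] = True
        clamp_val[idx[name]] = 0.0

    def rhs(t, x):
        x = np.clip(x, 0.0, 1.0)
        bbar = np.zeros(n)
        if len(gate_target):
            xn = x[lit_node] ** lit_n
            h = xn * (1.0 + lit_kn) / (xn + lit_kn)
            np.subtract(1.0, h, out=h, where=lit_neg)
            gate_vals = np.multiply.reduceat(h, seg_starts)
            prod_not = np.ones(n)
            np.multiply.at(prod_not, gate_target, 1.0 - gate_vals)
            bbar[has_gate] = 1.0 - prod_not[has_gate]
        dx = (bbar - x) * inv_tau
        dx[clamped] = 0.0
        return dx

    return rhs, clamped, clamp_val


def integrate(
    rhs,
    x0: np.ndarray,
    times: np.ndarray,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
) -> np.ndarray:
    """Integrate to the requested times (times x nodes); stiff-capable."""
    times = np.asarray(times, dtype=float)
    if np.any(np.diff(times) < 0):
        raise ValueError("times must be sorted")
    t0 = times[0]
    sol = solve_ivp(
        rhs, (t0, times[-1] if times[-1] > t0 else t0 + 1e-9), x0,
        t_eval=times, rtol=rtol, atol=atol, method=method,
    )
    if not sol.success:
        raise RuntimeError(f"ODE solver failed: {sol.message}")
    return np.clip(sol.y.T, 0.0, 1.0)


def simulate_ode_all(
    scaffold: Scaffold,
    bits,
    params: OdeParams,
    data: MidasDataset,
    status: StatusMap,
    times: np.ndarray | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    x0: np.ndarray | None = None,
) -> np.ndarray:
    """Trajectories for every condition (conditions x times x nodes).

    ``x0`` sets the shared pre-perturbation state (e.g. the unstimulated
    equilibrium); per-condition cue clamps override it.  Default: all zeros.
    """
    times = np.asarray(times if times is not None else data.times, dtype=float)
    n = len(scaffold.nodes)
    base = np.zeros(n) if x0 is None else np.asarray(x0, dtype=float)
    out = np.zeros((data.n_conditions, len(times), n))
    for c in range(data.n_conditions):
        stim, inhib = condition_clamps(data, status, c)
        rhs, clamped, clamp_val = build_rhs(scaffold, bits, params, stim, inhib)
        xinit = np.where(clamped, clamp_val, base)
        out[c] = integrate(rhs, xinit, times, rtol=rtol, atol=atol)
    return out


def _batched_predictor(scaffold: Scaffold, bits, data: MidasDataset,
                       status: StatusMap, rtol: float, atol: float):
    """Factory: params -> (conditions x times x nodes), integrating all
    conditions as one stacked system (cheaper than per-condition solves)."""
    n = len(scaffold.nodes)
    n_c = data.n_conditions
    conds = [condition_clamps(data, status, c) for c in range(n_c)]
    clamped = np.zeros((n_c, n), dtype=bool)
    clamp_val = np.zeros((n_c, n))
    idx = scaffold.node_index()
    for c, (stim, inhib) in enumerate(conds):
        for name, v in stim.items():
            clamped[c, idx[name]] = True
            clamp_val[c, idx[name]] = v
        for name in inhib:
            clamped[c, idx[name]] = True
    times = data.times

    def predict(params: OdeParams) -> np.ndarray:
        lit_node, lit_neg, lit_n, lit_kn, seg_starts, gate_target = \
            _compile_arrays(scaffold, bits, params)
        lit_neg_b = np.tile(lit_neg, (n_c, 1))
        has_gate = np.zeros(n, dtype=bool)
        if len(gate_target):
            has_gate[gate_target] = True
        inv_tau = np.ones(n)
        for node, t in params.tau.items():
            inv_tau[idx[node]] = 1.0 / t

        def rhs(t, xflat):
            x = np.clip(xflat.reshape(n_c, n), 0.0, 1.0)
            bbar = np.zeros((n_c, n))
            if len(gate_target):
                xn = x[:, lit_node] ** lit_n
                h = xn * (1.0 + lit_kn) / (xn + lit_kn)
                np.subtract(1.0, h, out=h, where=lit_neg_b)
                gate_vals = np.multiply.reduceat(h, seg_starts, axis=1)
                prod_not = np.ones((n_c, n))
                np.multiply.at(prod_not, (slice(None), gate_target),
                               1.0 - gate_vals)
                bbar[:, has_gate] = 1.0 - prod_not[:, has_gate]
            dx = (bbar - x) * inv_tau
            dx[clamped] = 0.0
            return dx.ravel()

        x0 = np.where(clamped, clamp_val, 0.0).ravel()
        sol = solve_ivp(rhs, (times[0], times[-1]), x0, t_eval=times,
                        rtol=rtol, atol=atol, method="LSODA")
        if not sol.success:
            raise RuntimeError(f"ODE solver failed: {sol.message}")
        return np.clip(sol.y.T.reshape(len(times), n_c, n), 0.0,
                       1.0).transpose(1, 0, 2)

    return predict


def _compile_arrays(scaffold: Scaffold, bits, params: OdeParams):
    bits = np.asarray(bits, dtype=int)
    idx = scaffold.node_index()
    lit_node, lit_neg, lit_n, lit_kn, seg_starts, gate_target = \
        [], [], [], [], [], []
    pos = 0
    for e, gate in enumerate(scaffold.gates):
        if not bits[e]:
            continue
        seg_starts.append(pos)
        gate_target.append(idx[gate.output])
        for j, (name, sign) in enumerate(gate.inputs):
            n_h, k = params.transfers[(e, j)]
            lit_node.append(idx[name])
            lit_neg.append(sign < 0)
            lit_n.append(float(n_h))
            lit_kn.append(float(k) ** float(n_h))
            pos += 1
    return (np.array(lit_node, dtype=np.intp), np.array(lit_neg, dtype=bool),
            np.array(lit_n), np.array(lit_kn),
            np.array(seg_starts, dtype=np.intp),
            np.array(gate_target, dtype=np.intp))


@dataclass(frozen=True)
class OdeFitConfig:
    """Bounds and optimiser budget for parameter fitting.

    K and tau are searched on a log scale; ``tau_max`` defaults to
    10 x the largest data time.
    """

    n_h_bounds: tuple[float, float] = (1.0, 10.0)
    k_bounds: tuple[float, float] = (0.01, 1.0)
    tau_min: float = 0.01
    tau_max: float | None = None
    seed: int = 0
    maxiter: int = 60
    popsize: int = 12
    polish: bool = True
    rtol: float = 1e-6
    atol: float = 1e-8


@dataclass
class OdeFitResult:
    params: OdeParams
    mse: float
    n_evaluations: int
    optimizer_message: str = ""


def _param_layout(scaffold: Scaffold, bits):
    bits = np.asarray(bits, dtype=int)
    slots = [
        (e, j)
        for e, g in enumerate(scaffold.gates)
        if bits[e]
        for j in range(g.n_inputs)
    ]
    nodes = sorted({g.output for e, g in enumerate(scaffold.gates) if bits[e]})
    return slots, nodes


def _vector_to_params(x, slots, nodes, cfg: OdeFitConfig) -> OdeParams:
    transfers = {}
    for i, key in enumerate(slots):
        n_h = x[2 * i]
        k = 10.0 ** x[2 * i + 1]
        transfers[key] = (float(n_h), float(k))
    tau = {}
    off = 2 * len(slots)
    for i, node in enumerate(nodes):
        tau[node] = float(10.0 ** x[off + i])
    return OdeParams(transfers=transfers, tau=tau)


def fit_ode(
    scaffold: Scaffold,
    bits,
    data: MidasDataset,
    status: StatusMap,
    optimizer=None,
    cfg: OdeFitConfig = OdeFitConfig(),
    method: str = "global",
    init_params: OdeParams | None = None,
) -> OdeFitResult:
    """Fit (n_h, K) per gate input and tau per node to time-course data.

    The topology ``bits`` is fixed (structure comes from one of the discrete
    trainers).  ``method='global'`` runs the built-in stochastic global
    optimiser (differential evolution + local polish); ``method='local'``
    runs bound-constrained least squares from ``init_params`` (or neutral
    defaults), appropriate when the structure is trusted and the landscape
    smooth.  ``optimizer(fun, bounds, seed)`` may replace the global
    optimiser; it must return an object with ``x`` and ``fun`` attributes.
    """
    if len(data.times) < 3:
        raise ValueError("ODE fitting needs time-course data (>= 3 times)")
    slots, nodes = _param_layout(scaffold, bits)
    node_pos = scaffold.node_index()
    cols = [node_pos[status.signal_nodes[s]] for s in data.signals]

    measured_nodes = {status.signal_nodes[s] for s in data.signals}
    reachable = set()
    for e, g in enumerate(scaffold.gates):
        if np.asarray(bits)[e]:
            reachable.add(g.output)
    if not (measured_nodes & reachable):
        warnings.warn("no measured node is driven by a selected gate; "
                      "parameters are unidentifiable")

    obs = data.values  # conditions x signals x times
    mask = np.isfinite(obs)
    n_g = int(mask.sum())
    if n_g == 0:
        raise ValueError("no data points to fit")
    n_evals = 0

    predictor = _batched_predictor(scaffold, bits, data, status,
                                   cfg.rtol, cfg.atol)

    def mse_of(params: OdeParams) -> float:
        traj = predictor(params)
        pred = traj[:, :, cols].transpose(0, 2, 1)  # cond x sig x time
        return float(((pred - obs) ** 2)[mask].sum() / n_g)

    def fun(x):
        nonlocal n_evals
        n_evals += 1
        try:
            return mse_of(_vector_to_params(x, slots, nodes, cfg))
        except RuntimeError:
            return 1e6  # solver failure under pathological parameters

    tau_max = cfg.tau_max if cfg.tau_max is not None else 10.0 * float(
        data.times.max())
    bounds = []
    for _ in slots:
        bounds.append(cfg.n_h_bounds)
        bounds.append((np.log10(cfg.k_bounds[0]), np.log10(cfg.k_bounds[1])))
    for _ in nodes:
        bounds.append((np.log10(cfg.tau_min), np.log10(tau_max)))

    if method == "local":
        start = init_params or default_params(scaffold, bits)
        x0 = []
        for key in slots:
            n_h, k = start.transfers[key]
            x0 += [n_h, np.log10(k)]
        x0 += [np.log10(start.tau.get(node, 1.0)) for node in nodes]
        lo = np.array([b[0] for b in bounds])
        hi = np.array([b[1] for b in bounds])
        x0 = np.clip(np.array(x0, dtype=float), lo, hi)

        def residuals(x):
            nonlocal n_evals
            n_evals += 1
            try:
                traj = predictor(_vector_to_params(x, slots, nodes, cfg))
            except RuntimeError:
                return np.full(n_g, 1e3)
            pred = traj[:, :, cols].transpose(0, 2, 1)
            return (pred - obs)[mask]

        res = least_squares(residuals, x0, bounds=(lo, hi), x_scale="jac",
                            xtol=1e-8, ftol=1e-8, max_nfev=cfg.maxiter)
        x = res.x
        fval = mse_of(_vector_to_params(x, slots, nodes, cfg))
        return OdeFitResult(
            params=_vector_to_params(x, slots, nodes, cfg),
            mse=fval, n_evaluations=n_evals,
            optimizer_message=str(res.message),
        )

    if optimizer is None:
        res = differential_evolution(
            fun, bounds, seed=cfg.seed, maxiter=cfg.maxiter,
            popsize=cfg.popsize, tol=1e-8, polish=cfg.polish, init="sobol",
        )
        message = str(res.message)
        x, fval = res.x, float(res.fun)
    else:
        res = optimizer(fun, bounds, cfg.seed)
        message = getattr(res, "message", "")
        x, fval = np.asarray(res.x), float(res.fun)

    return OdeFitResult(
        params=_vector_to_params(x, slots, nodes, cfg),
        mse=fval, n_evaluations=n_evals, optimizer_message=message,
    )
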