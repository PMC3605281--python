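"""Self-contained toy study: a small signaling network and simulated data.

The network represents the canonical pathways downstream of EGF and TNFa:
an EGF -> SOS-1 -> ras -> ERK cascade shut off by a slowly accumulating
ERK-induced phosphatase (transient ERK activation, with the classic ERK -|
SOS-1 feedback annotation also present), a TNFa -> map3k -> ikk -| ikb -|
nfkb branch whose three-step nfkb -> ikbm -> ikb feedback sustains nfkb
oscillations, and a p38 branch fed by both pathways and restrained by a
p38-induced phosphatase (dusp), which yields a sustained sub-maximal p38
level that is strongest when both stimuli are applied together.

Data are generated by the package's own logic-ODE engine from a known
sub-model ("true" gate selection + kinetic constants, all documented below),
sampled on a fixed time grid under the four cue combinations (none, EGF,
TNFa, both), with truncated Gaussian noise.  The three planted behaviours —
transient ERK, oscillating nfkb, partial p38 — discriminate between the
logic formalisms: a single-steady-state Boolean fit cannot represent any of
them, the two-time-scale Boolean fit recovers the ERK feedback, the
discrete-time fit also tracks the oscillation, the fuzzy fit captures the
partial p38 level, and the ODE fit captures all three.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .formats import MidasDataset, PriorKnowledgeNetwork
from .ode import OdeParams, simulate_ode_all
from .preprocess import (Scaffold, StatusMap, compress, cut_unreachable,
                         expand, mark_status)

__all__ = ["ToySpec", "ToyTruth", "toy_pkn", "toy_scaffold", "toy_truth",
           "toy_data", "DEFAULT_TIMES", "TAU1_INDEX", "TAU2_INDEX"]

DEFAULT_TIMES = np.array([0.0, 3, 6, 9, 12, 15, 20, 25, 30, 40, 50, 60])
# pseudo-steady-state time points used throughout the examples:
# tau1 = 6 min (ERK near its transient peak), tau2 = 60 min (late phase)
TAU1_INDEX = 2
TAU2_INDEX = 11


@dataclass(frozen=True)
class ToySpec:
    """Study conditions for the simulated dataset (reproducible given seed)."""

    seed: int = 0
    noise_sd: float = 0.03
    times: np.ndarray = field(default_factory=lambda: DEFAULT_TIMES.copy())
    plant_erk_feedback: bool = True
    plant_nfkb_oscillation: bool = True
    plant_partial_p38: bool = True


def toy_pkn() -> PriorKnowledgeNetwork:
    """The prior knowledge network (13 species, 17 signed edges).

    The nfkb feedback runs through de-novo inhibitor synthesis
    (nfkb -> ikbm -> ikb -| nfkb); the PKN also carries the commonly
    annotated direct negative nfkb -| ikb link (NF-kB-driven IkB
    degradation), a contradictory annotation pair of the kind real prior
    knowledge networks contain — it is what protects ikbm from compression.
    """
    edges = [
        ("EGF", 1, "SOS-1"),
        ("SOS-1", 1, "ras"),
        ("ras", 1, "ERK"),
        ("ERK", -1, "SOS-1"),      # negative feedback onto the adaptor
        ("ERK", 1, "mkp"),         # ERK-induced phosphatase ...
        ("mkp", -1, "ERK"),        # ... slow shutoff -> transient ERK
        ("TNFa", 1, "map3k"),
        ("map3k", 1, "ikk"),
        ("map3k", 1, "p38"),
        ("ras", 1, "p38"),
        ("ikk", -1, "ikb"),
        ("ikb", -1, "nfkb"),
        ("nfkb", 1, "ikbm"),       # three-step feedback -> nfkb limit cycle
        ("ikbm", 1, "ikb"),
        ("nfkb", -1, "ikb"),
        ("p38", 1, "dusp"),
        ("dusp", -1, "p38"),       # induced phosphatase -> partial p38
    ]
    return PriorKnowledgeNetwork.from_edges(edges)


def _data_template(times: np.ndarray) -> MidasDataset:
    treatments = np.array(
        [[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.0, 1.0]]  # none, EGF, TNFa, both
    )
    return MidasDataset(
        stimuli=["EGF", "TNFa"],
        inhibitors=[],
        signals=["ERK", "nfkb", "p38"],
        times=np.asarray(times, dtype=float),
        treatments=treatments,
        values=np.full((4, 3, len(times)), np.nan),
    )


def toy_scaffold(times: np.ndarray = DEFAULT_TIMES):
    """Preprocess the toy PKN against the toy cue/signal layout.

    Returns (scaffold, status, compressed_nodes, data_template).  The
    compression step keeps ras, mkp, dusp, ikb and ikbm (removal would
    create self-loops through the feedbacks, or a contradiction with the
    direct nfkb -| ikb annotation) and removes the pure pass-through
    intermediates SOS-1, map3k and ikk.
    """
    pkn = toy_pkn()
    template = _data_template(times)
    status = mark_status(pkn, template)
    cut = cut_unreachable(pkn, status)
    compressed_net, removed, prov = compress(cut, status)
    scaffold = expand(compressed_net, max_and_arity=2, provenance=prov)
    status = mark_status(compressed_net, template)
    return scaffold, status, removed, template


def _gate_index(scaffold: Scaffold, label: str) -> int:
    labels = scaffold.gate_labels()
    try:
        return labels.index(label)
    except ValueError as exc:
        raise KeyError(f"gate {label!r} not in scaffold: {labels}") from exc


# --- kinetic constants of the generating model -----------------------------
# Time constants (minutes): ras and ERK respond fast, the mkp phosphatase
# accumulates slowly (sets the ERK transient peak near t ~ 3-6 and a low late
# level), the steep nfkb -> ikbm -> ikb cycle gives a sustained ~15 min
# oscillation, dusp rises slowly so the p38 brake engages late.
_TAU = {"ras": 1.0, "ERK": 1.5, "mkp": 12.0, "p38": 2.0, "dusp": 8.0,
        "ikbm": 5.0, "ikb": 5.0, "nfkb": 5.0}
_TF = {
    "EGF->ras": (2.0, 0.5),
    "ras->ERK": (2.0, 0.4),
    "mkp->ERK": (4.0, 0.3),     # sensitive brake: low late ERK level
    "ERK->mkp": (2.0, 0.2),
    "TNFa->p38": (2.0, 0.5),
    "dusp@TNFa->p38": (2.0, 0.4),
    "ras->p38": (2.0, 0.5),
    "dusp@ras->p38": (2.0, 0.4),
    "TNFa->ikb": (8.0, 0.5),
    "nfkb->ikbm": (10.0, 0.5),  # steep three-step loop -> sustained cycle
    "ikbm->ikb": (10.0, 0.5),
    "ikb->nfkb": (10.0, 0.5),
    "p38->dusp": (2.0, 0.5),
}


@dataclass
class ToyTruth:
    """Everything about the generating model, for planted-recovery tests."""

    pkn: PriorKnowledgeNetwork
    scaffold: Scaffold
    status: StatusMap
    template: MidasDataset
    bits: np.ndarray
    params: OdeParams
    tau1_index: int = TAU1_INDEX
    tau2_index: int = TAU2_INDEX

    def gate(self, label: str) -> int:
        return _gate_index(self.scaffold, label)


def toy_truth(spec: ToySpec | None = None) -> ToyTruth:
    """The generating sub-model on the toy scaffold."""
    spec = spec or ToySpec()
    scaffold, status, _, template = toy_scaffold(spec.times)
    bits = np.zeros(scaffold.n_gates, dtype=int)
    transfers: dict[tuple[int, int], tuple[float, float]] = {}

    def select(label: str, *tf_names: str):
        e = _gate_index(scaffold, label)
        bits[e] = 1
        for j, name in enumerate(tf_names):
            transfers[(e, j)] = _TF[name]

    # ras/ERK branch (input literals are sorted by node name within a gate)
    select("EGF=>ras", "EGF->ras")
    if spec.plant_erk_feedback:
        select("!mkp^ras=>ERK", "mkp->ERK", "ras->ERK")
        select("ERK=>mkp", "ERK->mkp")
    else:
        select("ras=>ERK", "ras->ERK")
    # p38 branch
    if spec.plant_partial_p38:
        select("TNFa^!dusp=>p38", "TNFa->p38", "dusp@TNFa->p38")
        select("!dusp^ras=>p38", "dusp@ras->p38", "ras->p38")
        select("p38=>dusp", "p38->dusp")
    else:
        select("TNFa=>p38", "TNFa->p38")
        select("ras=>p38", "ras->p38")
    # nfkb branch
    select("!TNFa=>ikb", "TNFa->ikb")
    if spec.plant_nfkb_oscillation:
        select("ikbm=>ikb", "ikbm->ikb")
        select("nfkb=>ikbm", "nfkb->ikbm")
    select("!ikb=>nfkb", "ikb->nfkb")

    tau = {n: _TAU[n] for n in _TAU}
    params = OdeParams(transfers=transfers, tau=tau)
    return ToyTruth(pkn=toy_pkn(), scaffold=scaffold, status=status,
                    template=template, bits=bits, params=params)


def resting_state(truth: ToyTruth) -> np.ndarray:
    """Unstimulated equilibrium (the pre-perturbation baseline state)."""
    from .ode import build_rhs, integrate

    stim = {truth.status.stimulus_nodes[c]: 0.0 for c in truth.template.stimuli}
    rhs, clamped, clamp_val = build_rhs(truth.scaffold, truth.bits,
                                        truth.params, stim, ())
    x0 = np.where(clamped, clamp_val, 0.0)
    return integrate(rhs, x0, np.array([0.0, 500.0]))[-1]


def toy_data(spec: ToySpec | None = None,
             truth: ToyTruth | None = None) -> MidasDataset:
    """Simulate the toy with the logic-ODE engine and add truncated noise."""
    spec = spec or ToySpec()
    truth = truth or toy_truth(spec)
    traj = simulate_ode_all(
        truth.scaffold, truth.bits, truth.params, truth.template, truth.status,
        times=spec.times, x0=resting_state(truth),
    )  # conditions x times x nodes
    node_pos = truth.scaffold.node_index()
    cols = [node_pos[truth.status.signal_nodes[s]]
            for s in truth.template.signals]
    values = traj[:, :, cols].transpose(0, 2, 1)  # cond x signal x time
    rng = np.random.default_rng(spec.seed)
    if spec.noise_sd > 0:
        values = values + rng.normal(0.0, spec.noise_sd, values.shape)
    values = np.clip(values, 0.0, 1.0)
    data = truth.template.copy()
    data.values = values
    return data
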