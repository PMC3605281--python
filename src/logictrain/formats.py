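"""Reading, writing and normalising the two input formats.

A prior knowledge network (PKN) arrives as a SIF file: one signed, directed
interaction per row (``source sign target``).  Perturbation data arrives as a
MIDAS CSV: ``TR:`` columns give the cue layout of each experimental condition
(stimuli set to 1, inhibitors present = 1), and each readout contributes a
``DA:`` (time) / ``DV:`` (value) column pair, one row per condition/time
combination.

Raw measurements are mapped to [0, 1] with a fold-change / Hill /
background-penalty scheme so that logic-model predictions (which live on the
Boolean cube) can be compared with them directly, without discretising the
data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PriorKnowledgeNetwork",
    "MidasDataset",
    "NormalizationConfig",
    "SifParseError",
    "MidasFormatError",
    "read_sif",
    "write_sif",
    "read_midas",
    "write_midas",
    "normalize",
    "write_dot",
    "write_network_outputs",
]

_POSITIVE_TOKENS = {"1", "+", "+1", "activates", "activate"}
_NEGATIVE_TOKENS = {"-1", "-", "−", "−1", "inhibits", "inhibit"}


class SifParseError(ValueError):
    """Raised for malformed SIF rows (wrong field count, unknown sign token)."""


class MidasFormatError(ValueError):
    """Raised for malformed MIDAS files."""


@dataclass(frozen=True)
class PriorKnowledgeNetwork:
    """Signed directed interaction graph.

    ``edges`` is a tuple of ``(source, sign, target)`` triples with
    ``sign`` in ``{+1, -1}``.  Duplicate triples are collapsed; every edge
    endpoint is a node.
    """

    nodes: frozenset[str]
    edges: tuple[tuple[str, int, str], ...]

    @staticmethod
    def from_edges(edges, extra_nodes=()) -> "PriorKnowledgeNetwork":
        seen: dict[tuple[str, int, str], None] = {}
        for source, sign, target in edges:
            if sign not in (1, -1):
                raise ValueError(f"edge sign must be +1 or -1, got {sign!r}")
            seen.setdefault((str(source), int(sign), str(target)))
        edges = tuple(seen)
        nodes = frozenset(extra_nodes).union(
            *[{s, t} for s, _, t in edges] or [frozenset()]
        )
        return PriorKnowledgeNetwork(nodes=nodes, edges=edges)

    def in_edges(self, node: str):
        return [(s, sg) for s, sg, t in self.edges if t == node]

    def out_edges(self, node: str):
        return [(t, sg) for s, sg, t in self.edges if s == node]

    def to_networkx(self):
        import networkx as nx

        g = nx.MultiDiGraph()
        g.add_nodes_from(sorted(self.nodes))
        for s, sg, t in self.edges:
            g.add_edge(s, t, sign=sg)
        return g

    def __eq__(self, other):
        if not isinstance(other, PriorKnowledgeNetwork):
            return NotImplemented
        return self.nodes == other.nodes and set(self.edges) == set(other.edges)

    def __hash__(self):
        return hash((self.nodes, frozenset(self.edges)))


@dataclass
class MidasDataset:
    """Conditions x signals x times measurement cube with cue annotations.

    ``treatments`` is a binary (conditions x cues) matrix whose columns follow
    ``stimuli + inhibitors``; ``values[k, l, t]`` holds the measurement of
    signal ``l`` at time ``t`` under condition ``k`` (NaN = missing).
    """

    stimuli: list[str]
    inhibitors: list[str]
    signals: list[str]
    times: np.ndarray
    treatments: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.treatments = np.asarray(self.treatments, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        n_cond = self.treatments.shape[0]
        if set(self.stimuli) & set(self.inhibitors):
            raise ValueError("stimuli and inhibitors must be disjoint")
        if self.treatments.shape != (n_cond, len(self.stimuli) + len(self.inhibitors)):
            raise ValueError("treatments shape inconsistent with cue lists")
        if not np.isin(self.treatments, (0.0, 1.0)).all():
            raise ValueError("treatment entries must be 0 or 1")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.values.shape != (n_cond, len(self.signals), len(self.times)):
            raise ValueError("values shape inconsistent with conditions/signals/times")

    @property
    def n_conditions(self) -> int:
        return self.treatments.shape[0]

    @property
    def cues(self) -> list[str]:
        return self.stimuli + self.inhibitors

    @property
    def baseline_index(self) -> int:
        # baseline = smallest time in the file
        return 0

    def condition_label(self, k: int) -> str:
        parts = [c for c, v in zip(self.cues, self.treatments[k]) if v]
        return "+".join(parts) if parts else "control"

    def copy(self) -> "MidasDataset":
        return MidasDataset(
            stimuli=list(self.stimuli),
            inhibitors=list(self.inhibitors),
            signals=list(self.signals),
            times=self.times.copy(),
            treatments=self.treatments.copy(),
            values=self.values.copy(),
        )


@dataclass(frozen=True)
class NormalizationConfig:
    """Parameters of the fold-change -> Hill -> background-penalty mapping.

    mode
        ``increase`` scores signals rising above the baseline,
        ``decrease`` signals falling below it, ``two-sided`` any deviation.
    hill_exponent, hill_ec50
        Hill transform of the relative fold change (dimensionless / in
        fold-change units).
    background_threshold
        Raw values below this (in raw signal units) are set to 0.
    """

    mode: str = "increase"
    hill_exponent: float = 2.0
    hill_ec50: float = 0.5
    background_threshold: float = 0.0

    def __post_init__(self):
        if self.mode not in ("increase", "decrease", "two-sided"):
            raise ValueError(f"unknown normalization mode {self.mode!r}")
        if self.hill_exponent <= 0 or self.hill_ec50 <= 0:
            raise ValueError("hill_exponent and hill_ec50 must be > 0")


# ---------------------------------------------------------------------------
# SIF


def _parse_sign(token: str, lineno: int) -> int:
    if token in _POSITIVE_TOKENS:
        return 1
    if token in _NEGATIVE_TOKENS:
        return -1
    raise SifParseError(f"line {lineno}: unknown interaction sign token {token!r}")


def read_sif(path) -> PriorKnowledgeNetwork:
    """Load a 3-column (source sign target) interaction file."""
    edges = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) != 3:
                raise SifParseError(
                    f"line {lineno}: expected 3 whitespace-separated fields, "
                    f"got {len(fields)}"
                )
            source, sign_token, target = fields
            edges.append((source, _parse_sign(sign_token, lineno), target))
    return PriorKnowledgeNetwork.from_edges(edges)


def write_sif(net: PriorKnowledgeNetwork, path) -> None:
    with open(path, "w") as fh:
        for s, sg, t in sorted(net.edges):
            fh.write(f"{s}\t{sg}\t{t}\n")
        # isolated nodes cannot be represented in SIF rows; they are dropped
        # on round-trip by design.


# ---------------------------------------------------------------------------
# MIDAS


def read_midas(
    path,
    inhibitor_suffix: str = "i",
    inhibitors: set[str] | None = None,
    merge_duplicates: bool = False,
) -> MidasDataset:
    """Parse a MIDAS CSV into a conditions x signals x times cube.

    Rows sharing a treatment vector are grouped into one condition.  A
    ``TR:`` column is taken as an inhibitor when its cue name ends with
    ``inhibitor_suffix`` (the suffix is stripped to give the node name) or
    when it appears in the explicit ``inhibitors`` override set.
    ``TR:...:CellLine`` columns are ignored.  Duplicate condition/time cells
    raise unless ``merge_duplicates`` (merge by mean) is set.
    """
    df = pd.read_csv(path)
    tr_cols, da_cols, dv_cols = [], {}, {}
    for col in df.columns:
        if col.startswith("TR:"):
            if col.lower().endswith(":cellline"):
                continue
            tr_cols.append(col)
        elif col.startswith("DA:"):
            da_cols[col[3:]] = col
        elif col.startswith("DV:"):
            dv_cols[col[3:]] = col
    if not tr_cols:
        raise MidasFormatError("no TR: treatment column found")
    unmatched = set(da_cols) ^ set(dv_cols)
    if unmatched:
        raise MidasFormatError(
            "unpaired DA:/DV: columns for readouts: " + ", ".join(sorted(unmatched))
        )
    if not da_cols:
        raise MidasFormatError("no DA:/DV: readout column pair found")

    stimuli, inhib = [], []
    cue_cols = {}
    override = set(inhibitors or ())
    for col in tr_cols:
        name = col[3:]
        if name in override:
            inhib.append(name)
            cue_cols[name] = col
        elif (
            inhibitor_suffix
            and name.endswith(inhibitor_suffix)
            and len(name) > len(inhibitor_suffix)
        ):
            node = name[: -len(inhibitor_suffix)]
            inhib.append(node)
            cue_cols[node] = col
        else:
            stimuli.append(name)
            cue_cols[name] = col

    tr = df[[cue_cols[c] for c in stimuli + inhib]].to_numpy(dtype=float)
    if not np.isin(tr[~np.isnan(tr)], (0.0, 1.0)).all() or np.isnan(tr).any():
        raise MidasFormatError("non-binary TR: entry")

    signals = sorted(dv_cols)
    times = np.unique(
        np.concatenate([df[da_cols[s]].dropna().to_numpy(dtype=float) for s in signals])
    )
    time_index = {t: i for i, t in enumerate(times)}

    cond_keys: list[tuple] = []
    cond_of: dict[tuple, int] = {}
    for row in map(tuple, tr):
        if row not in cond_of:
            cond_of[row] = len(cond_keys)
            cond_keys.append(row)

    values = np.full((len(cond_keys), len(signals), len(times)), np.nan)
    counts = np.zeros_like(values)
    for ridx, row in enumerate(map(tuple, tr)):
        k = cond_of[row]
        for l, sig in enumerate(signals):
            t_raw = df.at[ridx, da_cols[sig]]
            v_raw = df.at[ridx, dv_cols[sig]]
            if pd.isna(t_raw) or pd.isna(v_raw):
                continue
            t = time_index[float(t_raw)]
            if counts[k, l, t] and not merge_duplicates:
                raise MidasFormatError(
                    f"duplicate measurement cell: condition {k}, readout "
                    f"{sig!r}, time {t_raw} (pass merge_duplicates=True to average)"
                )
            if counts[k, l, t]:
                values[k, l, t] += float(v_raw)
            else:
                values[k, l, t] = float(v_raw)
            counts[k, l, t] += 1
    with np.errstate(invalid="ignore"):
        values = np.where(counts > 1, values / np.maximum(counts, 1), values)

    return MidasDataset(
        stimuli=stimuli,
        inhibitors=inhib,
        signals=signals,
        times=times,
        treatments=np.array(cond_keys, dtype=float),
        values=values,
    )


def write_midas(data: MidasDataset, path, inhibitor_suffix: str = "i") -> None:
    """Write one row per condition/time combination (lossless round-trip)."""
    cue_headers = [f"TR:{c}" for c in data.stimuli] + [
        f"TR:{c}{inhibitor_suffix}" for c in data.inhibitors
    ]
    col_order = list(cue_headers)
    for sig in data.signals:
        col_order += [f"DA:{sig}", f"DV:{sig}"]
    rows = []
    for k in range(data.n_conditions):
        for t_i, t in enumerate(data.times):
            row = {h: int(v) for h, v in zip(cue_headers, data.treatments[k])}
            for l, sig in enumerate(data.signals):
                v = data.values[k, l, t_i]
                row[f"DA:{sig}"] = t
                row[f"DV:{sig}"] = v if np.isfinite(v) else np.nan
            rows.append(row)
    pd.DataFrame(rows, columns=col_order).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Normalization


def normalize(data: MidasDataset, cfg: NormalizationConfig | None = None) -> MidasDataset:
    """Map raw measurements to [0, 1].

    For each condition/readout, with baseline value ``x0`` (value at the
    smallest time) and ``M`` the maximum raw measurement of that readout over
    all conditions and times::

        fc  = max(0, (x - x0) / x0)          (increase mode)
        H   = fc^k / (ec50^k + fc^k)
        Pen = min(1, x / M)
        out = H * Pen

    ``decrease`` mode uses ``fc = max(0, (x0 - x)/x0)``; ``two-sided`` uses
    ``fc = |x - x0|/x0``.  Raw values below ``background_threshold`` map to 0.
    A zero or missing baseline leaves the cell missing (division guard).
    """
    cfg = cfg or NormalizationConfig()
    out = data.copy()
    k = cfg.hill_exponent
    ec50 = cfg.hill_ec50
    b = data.baseline_index
    for l, sig in enumerate(data.signals):
        raw = data.values[:, l, :]
        if np.all(~np.isfinite(raw)):
            warnings.warn(f"readout {sig!r} is all-missing; left missing")
            continue
        m = np.nanmax(raw)
        for c in range(data.n_conditions):
            x0 = raw[c, b]
            for t in range(len(data.times)):
                x = raw[c, t]
                if not np.isfinite(x):
                    continue
                if x < cfg.background_threshold:
                    out.values[c, l, t] = 0.0
                    continue
                if not np.isfinite(x0) or x0 == 0:
                    out.values[c, l, t] = np.nan
                    continue
                if cfg.mode == "increase":
                    fc = max(0.0, (x - x0) / x0)
                elif cfg.mode == "decrease":
                    fc = max(0.0, (x0 - x) / x0)
                else:
                    fc = abs(x - x0) / x0
                hill = fc**k / (ec50**k + fc**k) if fc > 0 else 0.0
                pen = min(1.0, x / m) if m > 0 else 0.0
                out.values[c, l, t] = min(1.0, max(0.0, hill * pen))
    return out


# ---------------------------------------------------------------------------
# Network report outputs


def write_dot(
    net: PriorKnowledgeNetwork,
    path,
    node_status: dict[str, str] | None = None,
    edge_freq: dict[tuple[str, int, str], float] | None = None,
) -> None:
    """Graphviz DOT export with the usual colour conventions.

    green = stimulated, red = inhibited, blue = measured, dashed = compressed;
    edge pen width scales with selection frequency.
    """
    node_status = node_status or {}
    edge_freq = edge_freq or {}
    colors = {
        "stimulated": "forestgreen",
        "inhibited": "firebrick",
        "measured": "dodgerblue",
        "compressed": "grey",
        "unknown": "black",
    }
    with open(path, "w") as fh:
        fh.write("digraph PKN {\n")
        for node in sorted(net.nodes):
            status = node_status.get(node, "unknown")
            style = "dashed" if status == "compressed" else "solid"
            fh.write(
                f'  "{node}" [color={colors.get(status, "black")}, style={style}];\n'
            )
        for s, sg, t in sorted(net.edges):
            arrow = "normal" if sg > 0 else "tee"
            width = 1.0 + 3.0 * edge_freq.get((s, sg, t), 0.0)
            fh.write(
                f'  "{s}" -> "{t}" [arrowhead={arrow}, penwidth={width:.2f}];\n'
            )
        fh.write("}\n")


def write_network_outputs(
    net: PriorKnowledgeNetwork,
    outdir,
    basename: str = "network",
    node_status: dict[str, str] | None = None,
    edge_freq: dict[tuple[str, int, str], float] | None = None,
) -> dict[str, str]:
    """Write SIF + DOT + node/edge attribute tables; returns written paths.

    Attribute keys must refer to elements of ``net``; nodes without a status
    entry are written with status ``unknown``.
    """
    import os

    node_status = dict(node_status or {})
    edge_freq = dict(edge_freq or {})
    bad_nodes = sorted(set(node_status) - net.nodes)
    bad_edges = sorted(set(edge_freq) - set(net.edges))
    if bad_nodes or bad_edges:
        raise ValueError(
            f"attribute keys not in network: nodes={bad_nodes} edges={bad_edges}"
        )
    paths = {
        "sif": os.path.join(outdir, f"{basename}.sif"),
        "dot": os.path.join(outdir, f"{basename}.dot"),
        "node_attrs": os.path.join(outdir, f"{basename}_nodes.txt"),
        "edge_attrs": os.path.join(outdir, f"{basename}_edges.txt"),
    }
    write_sif(net, paths["sif"])
    write_dot(net, paths["dot"], node_status, edge_freq)
    with open(paths["node_attrs"], "w") as fh:
        for node in sorted(net.nodes):
            fh.write(f"{node}\t{node_status.get(node, 'unknown')}\n")
    with open(paths["edge_attrs"], "w") as fh:
        for edge in sorted(net.edges):
            s, sg, t = edge
            fh.write(f"{s} ({sg:+d}) {t}\t{edge_freq.get(edge, 0.0):.4f}\n")
    return paths
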