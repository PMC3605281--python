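"""Run-summary outputs: fit plots, score summaries, manifests, archives.

Every training run writes a self-contained bundle: the normalized data copy,
the scaffold (extended SIF + JSON sidecar), the evaluated-model archive, the
edge/gate selection frequencies, the best model as SIF, per-readout fit
plots (simulation overlaid on data, background shaded by goodness of fit)
and a JSON score summary plus a reproducibility manifest (config, seed,
package versions).
"""

from __future__ import annotations

import json
import os
import platform
from dataclasses import asdict, is_dataclass

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .formats import MidasDataset
from .preprocess import Scaffold
from .search import SearchResult

__all__ = ["write_scaffold", "write_archive", "write_frequencies",
           "write_best_model_sif", "write_score_summary", "write_manifest",
           "plot_fits", "write_summary_markdown"]


def _jsonable(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_scaffold(scaffold: Scaffold, outdir, basename: str = "scaffold"):
    sif_path = os.path.join(outdir, f"{basename}.sif")
    with open(sif_path, "w") as fh:
        fh.write("\n".join(scaffold.to_sif_lines()) + "\n")
    json_path = os.path.join(outdir, f"{basename}.json")
    with open(json_path, "w") as fh:
        json.dump(scaffold.to_json_dict(), fh, indent=1)
    return sif_path, json_path


def write_archive(result: SearchResult, path):
    """CSV dump of every evaluated model: bitstring, score."""
    with open(path, "w") as fh:
        fh.write("bitstring,score\n")
        for bits, score in result.archive_rows():
            fh.write("".join(map(str, bits)) + f",{score:.6g}\n")


def write_frequencies(scaffold: Scaffold, frequencies, path):
    """Gate selection frequencies as an attribute table (gate<TAB>freq)."""
    with open(path, "w") as fh:
        for label, f in zip(scaffold.gate_labels(), frequencies):
            fh.write(f"{label}\t{f:.4f}\n")


def write_best_model_sif(scaffold: Scaffold, bits, path):
    lines = []
    k = 0
    for e, gate in enumerate(scaffold.gates):
        if not bits[e]:
            continue
        if gate.n_inputs == 1:
            (n, sg), = gate.inputs
            lines.append(f"{n}\t{sg}\t{gate.output}")
        else:
            k += 1
            aux = f"and_{k}"
            for n, sg in gate.inputs:
                lines.append(f"{n}\t{sg}\t{aux}")
            lines.append(f"{aux}\t1\t{gate.output}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + ("\n" if lines else ""))


def write_score_summary(path, **scores):
    with open(path, "w") as fh:
        json.dump(_jsonable(scores), fh, indent=1, sort_keys=True)


def write_manifest(path, config: dict, seed: int):
    import importlib.metadata

    versions = {}
    for pkg in ("numpy", "scipy", "pandas", "networkx", "matplotlib"):
        try:
            versions[pkg] = importlib.metadata.version(pkg)
        except importlib.metadata.PackageNotFoundError:
            versions[pkg] = "unknown"
    manifest = {
        "config": _jsonable(config),
        "seed": seed,
        "python": platform.python_version(),
        "versions": versions,
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)


def plot_fits(
    data: MidasDataset,
    predictions: np.ndarray,
    path,
    pred_times: np.ndarray | None = None,
):
    """Grid of per-condition / per-readout panels, data vs simulation.

    ``predictions`` is (conditions x signals x n_pred_times); steady-state
    predictions pass a single column.  The panel background encodes the mean
    squared mismatch (green = good fit, red = poor).
    """
    n_c, n_s = data.n_conditions, len(data.signals)
    fig, axes = plt.subplots(
        n_c, n_s, figsize=(2.4 * n_s, 1.8 * n_c), squeeze=False,
        sharex=True, sharey=True,
    )
    pred_times = (np.asarray(pred_times) if pred_times is not None
                  else data.times[-predictions.shape[2]:])
    for k in range(n_c):
        for l in range(n_s):
            ax = axes[k][l]
            obs = data.values[k, l]
            ax.plot(data.times, obs, "k-", lw=1.2)
            ax.plot(pred_times, predictions[k, l], "b--", lw=1.2)
            finite = np.isfinite(obs)
            if finite.any() and len(pred_times) == len(data.times):
                mse = np.nanmean((predictions[k, l][finite] - obs[finite]) ** 2)
            elif finite.any():
                mse = np.nanmean((predictions[k, l][-1] - obs[finite][-1]) ** 2)
            else:
                mse = np.nan
            if np.isfinite(mse):
                # green (good) -> red (poor) background shading
                frac = min(1.0, mse / 0.25)
                ax.set_facecolor((1.0 * frac + 0.9 * (1 - frac),
                                  0.9 * (1 - frac) + 0.8 * frac * 0.4,
                                  0.75 * (1 - frac)))
            ax.set_ylim(-0.05, 1.05)
            if k == 0:
                ax.set_title(data.signals[l], fontsize=8)
            if l == 0:
                ax.set_ylabel(data.condition_label(k), fontsize=7)
            ax.tick_params(labelsize=6)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def write_summary_markdown(path, title: str, sections: dict[str, str]):
    with open(path, "w") as fh:
        fh.write(f"# {title}\n\n")
        for heading, body in sections.items():
            fh.write(f"## {heading}\n\n{body}\n\n")
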