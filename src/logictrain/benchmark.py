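"""Loader for an externally provided benchmark dataset (PKN + MIDAS).

The published liver-cancer (HepG2) case study — phosphoproteomic responses
to inflammation/proliferation cues at 30 minutes and 3 hours — is not
redistributed with this package; to reproduce it, place the network file
and the measurement file in a directory:

    <dir>/pkn.sif     signed directed prior knowledge network
    <dir>/data.csv    MIDAS measurements (TR:/DA:/DV: columns)

``load_benchmark`` then returns the preprocessed scaffold and normalized
dataset ready for two-time-scale training.  Quantities to compare against
the published analysis: scaffold interaction count, empty-model and
full-model scores, and average trained scores at each time scale.
"""

from __future__ import annotations

import os

from .formats import NormalizationConfig, normalize, read_midas, read_sif
from .preprocess import compress, cut_unreachable, expand, mark_status

__all__ = ["load_benchmark"]


def load_benchmark(directory, aliases=None, norm: NormalizationConfig | None = None,
                   max_and_arity: int = 2):
    """Read <dir>/pkn.sif and <dir>/data.csv, preprocess, and return
    (scaffold, status, normalized_data, compressed_nodes)."""
    sif_path = os.path.join(directory, "pkn.sif")
    midas_path = os.path.join(directory, "data.csv")
    for path in (sif_path, midas_path):
        if not os.path.exists(path):
            raise FileNotFoundError(
                f"benchmark input {path!r} not found; this dataset is not "
                "bundled and must be supplied by the user"
            )
    net = read_sif(sif_path)
    data = read_midas(midas_path)
    data = normalize(data, norm or NormalizationConfig())
    status = mark_status(net, data, aliases=aliases)
    cut = cut_unreachable(net, status)
    compressed_net, removed, prov = compress(cut, status)
    scaffold = expand(compressed_net, max_and_arity=max_and_arity,
                      provenance=prov)
    status = mark_status(compressed_net, data, aliases=aliases)
    return scaffold, status, data, removed
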