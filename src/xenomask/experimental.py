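"""Experimental cross-species mask from host-only hybridisations.

Pure host tissue (non-engrafted spleen, NES) hybridised to the human array
yields mostly low signal, but a small tail of transcript clusters
cross-hybridise strongly.  The mask takes the top fraction (default 1%) of
clusters by mean normalised log2 signal across the NES replicates; the
realised signal threshold (the minimum selected mean) is recorded with the
mask.  Selection is rank-based: the "top 1%" rule defines the mask, the
threshold is an outcome, and clusters tied with the cutoff value are
included.
"""

from __future__ import annotations

import math
import warnings

from .maskops import MaskSet
from .preprocess import ExpressionMatrix


def derive_experimental_mask(nes: ExpressionMatrix,
                             top_fraction: float = 0.01) -> MaskSet:
    """Mask the top ``top_fraction`` of clusters by mean host-only signal.

    ``nes`` must be a cluster-level log2 matrix whose columns are the
    host-only replicates.  Selects the ceil(top_fraction * N) highest
    cluster means, extended to include ties at the cutoff; the recorded
    threshold is the minimum selected mean.
    """
    if not 0 < top_fraction < 1:
        raise ValueError(f"top_fraction must be in (0, 1), got {top_fraction}")
    if nes.scale != "log2":
        raise ValueError("experimental mask requires a log2 cluster matrix")
    if nes.n_samples < 1 or nes.values.shape[0] == 0:
        raise ValueError("need at least one sample and one cluster")
    means = nes.values.mean(axis=1)
    n = len(means)
    k = math.ceil(top_fraction * n)
    cutoff = float(means.sort_values(ascending=False).iloc[k - 1])
    selected = means.index[means >= cutoff]
    if len(selected) == n and means.nunique() == 1 and n > 1:
        warnings.warn("all cluster means identical; entire universe selected")
    threshold = float(means.loc[selected].min())
    metadata = {
        "n_clusters": n,
        "n_selected": len(selected),
        "n_rank_selected": k,
        "n_host_samples": nes.n_samples,
    }
    return MaskSet(frozenset(selected), "experimental",
                   params={"top_fraction": top_fraction, "threshold": threshold},
                   metadata=metadata)
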