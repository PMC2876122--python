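"""Mask sets over transcript clusters: combination and application."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .preprocess import ExpressionMatrix

logger = logging.getLogger(__name__)

PROVENANCES = ("insilico", "experimental", "combined")


@dataclass(frozen=True)
class MaskSet:
    """A set of transcript-cluster ids flagged as susceptible to
    cross-species hybridisation, with the provenance and parameters of
    its derivation."""

    clusters: frozenset[str]
    provenance: str
    params: Mapping = field(default_factory=dict)
    metadata: Mapping = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "clusters", frozenset(self.clusters))
        if self.provenance not in PROVENANCES:
            raise ValueError(
                f"provenance must be one of {PROVENANCES}, got {self.provenance!r}"
            )

    def __len__(self) -> int:
        return len(self.clusters)

    def __contains__(self, cluster_id: str) -> bool:
        return cluster_id in self.clusters


def combine_masks(a: MaskSet, b: MaskSet) -> MaskSet:
    """Set union of two masks, with size bookkeeping in the metadata."""
    union = a.clusters | b.clusters
    intersection = a.clusters & b.clusters
    # inclusion-exclusion sanity check on every combination
    assert len(union) == len(a) + len(b) - len(intersection)
    metadata = {
        "n_a": len(a),
        "n_b": len(b),
        "n_intersection": len(intersection),
        "n_union": len(union),
        "provenance_a": a.provenance,
        "provenance_b": b.provenance,
    }
    return MaskSet(union, "combined",
                   params={"a": dict(a.params), "b": dict(b.params)},
                   metadata=metadata)


def apply_mask(m: ExpressionMatrix, mask: MaskSet | Iterable[str]) -> ExpressionMatrix:
    """Drop masked transcript-cluster rows; surviving row order is preserved."""
    masked_ids = mask.clusters if isinstance(mask, MaskSet) else frozenset(mask)
    present = set(m.values.index)
    absent = masked_ids - present
    if absent:
        logger.warning("%d masked cluster ids absent from the matrix", len(absent))
    keep = [rid for rid in m.values.index if rid not in masked_ids]
    logger.info("masked %d of %d rows", len(present) - len(keep), len(present))
    return ExpressionMatrix(m.values.loc[keep].copy(), m.scale)
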