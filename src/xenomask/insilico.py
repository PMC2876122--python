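"""In silico cross-species mask from probe/genome hits.

Probes that hit the host genome (perfect or single-mismatch placement) are
removed from every probeset they belong to; probesets left with strictly
less than half of their original probes are removed from their transcript
clusters; a cluster is masked once at least half of its original probesets
have been removed.  Denominators are always the design-time association
counts from the mapping table.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Iterable

from .mapping import MappingTable
from .maskops import MaskSet


@dataclass(frozen=True)
class MaskRuleConfig:
    """Thresholds of the hierarchical removal rules.

    probe_remaining_threshold: a probeset is removed when the fraction of
        its probes remaining after hit removal is strictly below this
        (default 0.5, i.e. "< 50% of their associated probes remaining").
    probeset_removed_threshold: a cluster is masked when the fraction of
        its probesets removed is at least this (default 0.5).
    max_mismatches: hit criterion used upstream, recorded for provenance.
    """

    probe_remaining_threshold: float = 0.5
    probeset_removed_threshold: float = 0.5
    max_mismatches: int = 1

    def __post_init__(self):
        for name in ("probe_remaining_threshold", "probeset_removed_threshold"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")


def derive_insilico_mask(hits: Iterable[str], mapping: MappingTable,
                         rules: MaskRuleConfig = MaskRuleConfig()) -> MaskSet:
    """Transcript-cluster mask from the set of hit probe ids.

    Stage 1 removes each hit probe from every probeset containing it;
    stage 2 removes probesets with < probe_remaining_threshold of their
    original probes remaining; stage 3 masks clusters with
    >= probeset_removed_threshold of their original probesets removed.
    """
    hit_probes = set(hits)
    unknown = hit_probes - set(mapping.probe_ids)
    if unknown:
        shown = sorted(unknown)[:10]
        raise ValueError(
            f"{len(unknown)} hit probe ids absent from mapping table, e.g. {shown}"
        )
    removed_probesets = {
        ps for ps, probes in mapping.probes_of_probeset.items()
        if len(probes - hit_probes) / len(probes) < rules.probe_remaining_threshold
    }
    masked_clusters = {
        c for c, probesets in mapping.probesets_of_cluster.items()
        if len(probesets & removed_probesets) / len(probesets)
        >= rules.probeset_removed_threshold
    }
    metadata = {
        "n_hit_probes": len(hit_probes),
        "n_probes": len(mapping.probe_ids),
        "n_removed_probesets": len(removed_probesets),
        "n_probesets": len(mapping.probeset_ids),
        "n_masked_clusters": len(masked_clusters),
        "n_clusters": len(mapping.cluster_ids),
    }
    return MaskSet(frozenset(masked_clusters), "insilico",
                   params=asdict(rules), metadata=metadata)
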