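"""Three-tier probe / probeset / transcript-cluster mapping table.

On Gene ST-style arrays every 25-mer probe belongs to one or more probesets,
and every probeset to one (occasionally more) transcript cluster, the unit
approximating a gene.  The masking rules operate on this hierarchy, always
using the design-time association counts as denominators.
"""

from __future__ import annotations

from typing import Iterable

import pandas as pd

MAPPING_COLUMNS = ("probe_id", "probeset_id", "transcript_cluster_id")


class MappingTable:
    """Deduplicated probe->probeset->transcript-cluster associations."""

    def __init__(self, frame: pd.DataFrame):
        missing = set(MAPPING_COLUMNS) - set(frame.columns)
        if missing:
            raise ValueError(f"mapping table missing columns: {sorted(missing)}")
        frame = frame.loc[:, list(MAPPING_COLUMNS)].astype(str)
        if frame.isna().any().any():
            raise ValueError("mapping table contains missing values")
        frame = frame.drop_duplicates(ignore_index=True)
        if len(frame) == 0:
            raise ValueError("mapping table is empty")
        self._frame = frame

        self.probes_of_probeset: dict[str, frozenset[str]] = {
            ps: frozenset(g)
            for ps, g in frame.groupby("probeset_id")["probe_id"]
        }
        self.probesets_of_probe: dict[str, frozenset[str]] = {
            p: frozenset(g)
            for p, g in frame.groupby("probe_id")["probeset_id"]
        }
        ps_cl = frame.drop_duplicates(["probeset_id", "transcript_cluster_id"])
        self.probesets_of_cluster: dict[str, frozenset[str]] = {
            c: frozenset(g)
            for c, g in ps_cl.groupby("transcript_cluster_id")["probeset_id"]
        }
        self.clusters_of_probeset: dict[str, frozenset[str]] = {
            ps: frozenset(g)
            for ps, g in ps_cl.groupby("probeset_id")["transcript_cluster_id"]
        }

    @classmethod
    def from_records(cls, records: Iterable[tuple[str, str, str]]) -> "MappingTable":
        return cls(pd.DataFrame(list(records), columns=list(MAPPING_COLUMNS)))

    @property
    def probe_ids(self) -> frozenset[str]:
        return frozenset(self.probesets_of_probe)

    @property
    def probeset_ids(self) -> frozenset[str]:
        return frozenset(self.probes_of_probeset)

    @property
    def cluster_ids(self) -> frozenset[str]:
        return frozenset(self.probesets_of_cluster)

    def n_probes_in_probeset(self, probeset_id: str) -> int:
        return len(self.probes_of_probeset[probeset_id])

    def n_probesets_in_cluster(self, cluster_id: str) -> int:
        return len(self.probesets_of_cluster[cluster_id])

    def clusters_of_probe(self, probe_id: str) -> frozenset[str]:
        out: set[str] = set()
        for ps in self.probesets_of_probe[probe_id]:
            out |= self.clusters_of_probeset[ps]
        return frozenset(out)

    def probes_of_cluster(self, cluster_id: str) -> frozenset[str]:
        out: set[str] = set()
        for ps in self.probesets_of_cluster[cluster_id]:
            out |= self.probes_of_probeset[ps]
        return frozenset(out)

    def to_frame(self) -> pd.DataFrame:
        return self._frame.copy()

    def __len__(self) -> int:
        return len(self._frame)

    def __eq__(self, other) -> bool:
        if not isinstance(other, MappingTable):
            return NotImplemented
        a = self._frame.sort_values(list(MAPPING_COLUMNS), ignore_index=True)
        b = other._frame.sort_values(list(MAPPING_COLUMNS), ignore_index=True)
        return a.equals(b)
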