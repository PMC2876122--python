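"""Readers and writers for the on-disk formats.

Everything is plain text: FASTA for genomes (via Biopython), tab-separated
tables with a header row for probe tables, mapping tables, hit tables,
expression matrices, group/batch labels and masks.  Mask parameters and
derivation metadata travel in a JSON sidecar next to the mask TSV.  All
writers are deterministic for identical inputs.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .mapping import MAPPING_COLUMNS, MappingTable
from .match import HIT_COLUMNS
from .maskops import MaskSet
from .preprocess import ExpressionMatrix


def read_fasta(path) -> dict[str, str]:
    """FASTA records as {id: upper-case sequence}; id is the first header token."""
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate FASTA id {rec.id!r}")
        records[rec.id] = str(rec.seq).upper()
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(path, sequences: Mapping[str, str]) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def _read_tsv(path, required: tuple[str, ...]) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(required) - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return frame


def read_probes(path) -> pd.DataFrame:
    frame = _read_tsv(path, ("probe_id", "sequence"))
    if frame["probe_id"].duplicated().any():
        dupes = frame.loc[frame["probe_id"].duplicated(), "probe_id"].tolist()[:5]
        raise ValueError(f"duplicate probe ids, e.g. {dupes}")
    return frame


def write_probes(path, probes: pd.DataFrame) -> None:
    probes.loc[:, ["probe_id", "sequence"]].to_csv(path, sep="\t", index=False)


def read_mapping(path) -> MappingTable:
    return MappingTable(_read_tsv(path, MAPPING_COLUMNS))


def write_mapping(path, mapping: MappingTable) -> None:
    mapping.to_frame().to_csv(path, sep="\t", index=False)


def read_hits(path) -> pd.DataFrame:
    frame = _read_tsv(path, HIT_COLUMNS)
    frame["start"] = frame["start"].astype(int)
    frame["mismatches"] = frame["mismatches"].astype(int)
    return frame


def write_hits(path, hits: pd.DataFrame) -> None:
    hits.loc[:, list(HIT_COLUMNS)].to_csv(path, sep="\t", index=False)


def read_matrix(path, scale: str) -> ExpressionMatrix:
    """Expression matrix TSV: first column row id, header of sample ids.

    The scale ("linear" or "log2") is declared by the caller; bad cells
    are reported with their row/column coordinates.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & raw.notna()
    if bad.to_numpy().any():
        r, c = next(zip(*bad.to_numpy().nonzero()))
        raise ValueError(
            f"{path}: non-numeric value at row {raw.index[r]!r}, "
            f"column {raw.columns[c]!r}: {raw.iat[r, c]!r}"
        )
    if numeric.isna().to_numpy().any():
        raise ValueError(f"{path}: missing values in matrix")
    return ExpressionMatrix(numeric.astype(float), scale)


def write_matrix(path, m: ExpressionMatrix) -> None:
    out = m.values.copy()
    out.index.name = "row_id"
    out.to_csv(path, sep="\t")


def read_groups(path) -> dict[str, str]:
    """Sample -> group labels from a TSV with columns sample_id, group."""
    frame = _read_tsv(path, ("sample_id", "group"))
    return dict(zip(frame["sample_id"], frame["group"]))


def write_groups(path, groups: Mapping[str, str]) -> None:
    pd.DataFrame(
        {"sample_id": list(groups), "group": [groups[s] for s in groups]}
    ).to_csv(path, sep="\t", index=False)


def _sidecar(path) -> Path:
    return Path(str(path) + ".json")


def read_mask(path) -> MaskSet:
    frame = _read_tsv(path, ("cluster_id", "provenance"))
    params: dict = {}
    metadata: dict = {}
    provenance = frame["provenance"].iloc[0] if len(frame) else None
    sidecar = _sidecar(path)
    if sidecar.exists():
        doc = json.loads(sidecar.read_text())
        params = doc.get("params", {})
        metadata = doc.get("metadata", {})
        provenance = doc.get("provenance", provenance)
    if provenance is None:
        raise ValueError(f"{path}: empty mask file without a JSON sidecar")
    return MaskSet(frozenset(frame["cluster_id"].dropna()), provenance, params, metadata)


def write_mask(path, mask: MaskSet) -> None:
    pd.DataFrame({
        "cluster_id": sorted(mask.clusters),
        "provenance": mask.provenance,
    }).to_csv(path, sep="\t", index=False)
    _sidecar(path).write_text(json.dumps(
        {"provenance": mask.provenance, "params": dict(mask.params),
         "metadata": dict(mask.metadata)},
        indent=2, sort_keys=True, default=str,
    ))


def read_truth(path) -> frozenset[str]:
    """Contaminated-cluster ids from a TSV with columns cluster_id, contaminated."""
    frame = _read_tsv(path, ("cluster_id", "contaminated"))
    return frozenset(frame.loc[frame["contaminated"] == "yes", "cluster_id"])


def write_truth(path, cluster_ids, contaminated: frozenset[str]) -> None:
    pd.DataFrame({
        "cluster_id": sorted(cluster_ids),
        "contaminated": ["yes" if c in contaminated else "no"
                         for c in sorted(cluster_ids)],
    }).to_csv(path, sep="\t", index=False)
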