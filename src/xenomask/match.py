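"""Placement of short oligonucleotide probes on a host genome.

A probe "hits" the genome when some window on either strand matches it with
100% identity or with a single base substitution (ungapped; indels are not
considered).  Matching is done with a BLAT-style tile index (default tile
size 12, step 7) extended with exhaustive scans of the probe's two terminal
tiles, which makes the search provably complete for up to one mismatch:
the terminal tiles ``probe[0:t]`` and ``probe[L-t:L]`` are disjoint whenever
``L >= 2t`` (25-mers, 12-mer tiles), so a single mismatch can corrupt at
most one of them and the other is found by exact scan.

``brute_force_hits`` is an independent exhaustive sliding-window matcher
used as the verification oracle for the seeded search.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_VALID_BASES = frozenset("ACGT")

HIT_COLUMNS = ("probe_id", "target_id", "start", "strand", "mismatches")


def reverse_complement(seq: str) -> str:
    """Reverse complement of an upper-case ACGT sequence."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MatchHit:
    """One placement of a probe on the genome.

    ``start`` is a 0-based offset on the + strand of ``target_id``; a
    - strand hit is reported at the + coordinates of the matched window.
    """

    probe_id: str
    target_id: str
    start: int
    strand: str
    mismatches: int

    def sort_key(self):
        return (self.target_id, self.start, self.strand)


def _as_genome(genome) -> dict[str, str]:
    if isinstance(genome, str):
        genome = {"genome": genome}
    return {tid: seq.upper() for tid, seq in genome.items()}


class SeedIndex:
    """Tile index over the + strand of a genome.

    Every genome offset ``p`` with ``p % step_size == 0`` and
    ``p + tile_size <= len(target)`` contributes one tile entry.
    """

    def __init__(self, genome: Mapping[str, str] | str, tile_size: int = 12,
                 step_size: int = 7):
        if tile_size < 1 or step_size < 1:
            raise ValueError("tile_size and step_size must be >= 1")
        self.genome = _as_genome(genome)
        if not self.genome or all(len(s) == 0 for s in self.genome.values()):
            raise ValueError("cannot index an empty genome")
        self.tile_size = tile_size
        self.step_size = step_size
        tiles: dict[str, list[tuple[str, int]]] = {}
        for tid, seq in self.genome.items():
            for p in range(0, len(seq) - tile_size + 1, step_size):
                tiles.setdefault(seq[p:p + tile_size], []).append((tid, p))
        self._tiles = tiles

    def lookup(self, tile: str) -> list[tuple[str, int]]:
        return self._tiles.get(tile, [])

    def __len__(self) -> int:
        return sum(len(v) for v in self._tiles.values())

    @property
    def tiles(self) -> Mapping[str, list[tuple[str, int]]]:
        return self._tiles


def build_seed_index(genome, tile_size: int = 12, step_size: int = 7) -> SeedIndex:
    """Build a :class:`SeedIndex` over ``genome`` (str or mapping id->seq)."""
    return SeedIndex(genome, tile_size=tile_size, step_size=step_size)


def _check_probe(probe: str, probe_id: str) -> str | None:
    probe = probe.upper()
    if not probe:
        raise ValueError("empty probe sequence")
    if set(probe) - _VALID_BASES:
        warnings.warn(
            f"probe {probe_id!r} contains non-ACGT characters; reported as zero hits",
            stacklevel=3,
        )
        return None
    return probe


def _hamming_at_most(query: str, target: str, start: int, cap: int) -> int | None:
    """Mismatch count of query vs target[start:start+len(query)], or None if > cap."""
    mm = 0
    for i, base in enumerate(query):
        if target[start + i] != base:
            mm += 1
            if mm > cap:
                return None
    return mm


def find_hits(probe: str, index: SeedIndex, probe_id: str = "probe",
              max_mismatches: int = 1) -> list[MatchHit]:
    """All placements of ``probe`` on both strands with <= max_mismatches.

    Candidates come from the stepped tile index (probe tiles at every
    offset) plus exhaustive scans for the two terminal tiles; every
    candidate window is then verified by direct Hamming comparison.
    Complete for ``max_mismatches <= 1`` when probe length >= 2*tile_size.
    """
    probe = _check_probe(probe, probe_id)
    if probe is None:
        return []
    L = len(probe)
    t = index.tile_size
    hits: set[MatchHit] = set()
    for strand, q in (("+", probe), ("-", reverse_complement(probe))):
        candidates: set[tuple[str, int]] = set()
        if t <= L:
            for off in range(0, L - t + 1):
                for tid, p in index.lookup(q[off:off + t]):
                    s = p - off
                    if 0 <= s <= len(index.genome[tid]) - L:
                        candidates.add((tid, s))
            # terminal-tile exhaustive scans: the completeness guarantee
            for off in {0, L - t}:
                tile = q[off:off + t]
                for tid, seq in index.genome.items():
                    p = seq.find(tile)
                    while p != -1:
                        s = p - off
                        if 0 <= s <= len(seq) - L:
                            candidates.add((tid, s))
                        p = seq.find(tile, p + 1)
        else:  # tiles longer than the probe: no seeds possible, scan all windows
            for tid, seq in index.genome.items():
                candidates.update((tid, s) for s in range(len(seq) - L + 1))
        for tid, s in candidates:
            mm = _hamming_at_most(q, index.genome[tid], s, max_mismatches)
            if mm is not None:
                hits.add(MatchHit(probe_id, tid, s, strand, mm))
    return sorted(hits, key=MatchHit.sort_key)


def brute_force_hits(probe: str, genome, probe_id: str = "probe",
                     max_mismatches: int = 1) -> list[MatchHit]:
    """Exhaustive sliding-window matcher; same output contract as find_hits.

    Independent of the seeded path: every window on both strands is
    compared by vectorised byte equality.
    """
    probe = _check_probe(probe, probe_id)
    if probe is None:
        return []
    targets = _as_genome(genome)
    L = len(probe)
    hits: list[MatchHit] = []
    for strand, q in (("+", probe), ("-", reverse_complement(probe))):
        q_arr = np.frombuffer(q.encode("ascii"), dtype=np.uint8)
        for tid in targets:
            seq = targets[tid]
            if len(seq) < L:
                continue
            s_arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
            windows = np.lib.stride_tricks.sliding_window_view(s_arr, L)
            mismatches = (windows != q_arr).sum(axis=1)
            for start in np.nonzero(mismatches <= max_mismatches)[0]:
                hits.append(MatchHit(probe_id, tid, int(start), strand,
                                     int(mismatches[start])))
    return sorted(hits, key=MatchHit.sort_key)


def match_probe_table(probes: pd.DataFrame, index: SeedIndex,
                      max_mismatches: int = 1) -> pd.DataFrame:
    """Run find_hits for every row of a probe table (probe_id, sequence).

    Returns a tidy hit table with columns probe_id, target_id, start,
    strand, mismatches.
    """
    if not {"probe_id", "sequence"} <= set(probes.columns):
        raise ValueError("probe table requires columns 'probe_id' and 'sequence'")
    rows = []
    for pid, seq in zip(probes["probe_id"], probes["sequence"]):
        for h in find_hits(seq, index, probe_id=pid, max_mismatches=max_mismatches):
            rows.append((h.probe_id, h.target_id, h.start, h.strand, h.mismatches))
    return pd.DataFrame(rows, columns=list(HIT_COLUMNS))


def hit_probe_ids(hits: pd.DataFrame | Iterable[MatchHit]) -> set[str]:
    """Distinct probe ids with at least one placement."""
    if isinstance(hits, pd.DataFrame):
        return set(hits["probe_id"]) if len(hits) else set()
    return {h.probe_id for h in hits}
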