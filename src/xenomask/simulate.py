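"""Synthetic mixed-species microarray world with known ground truth.

Emulates the study design used to characterise cross-species
hybridisation of host (mouse) RNA to a human expression array: a random
host genome, an array design in which a configurable fraction of
transcript clusters carry probes copied (exactly or with one substitution)
from host genome windows, and probe-level intensity matrices for graded
human/host cell mixtures (by default 100%, 95% and 90% human, in
triplicate) plus pure-host hybridisations (NES, f = 0).

The intensity model for a probe with human cluster signal h and host term
a (the configured cross-hybridisation affinity for planted probes, a low
background for all others) in a mixture with human fraction f is

    I = [ f * h + (1 - f) * a ] * 2**eps,   eps ~ N(0, noise_sd^2)

i.e. a linear mixing of the two species' contributions with multiplicative
log-normal noise.  Homologous-probe placement is rule-aware: in each
contaminated cluster at least half of the probesets consist entirely of
planted probes, so the cluster satisfies the in silico masking rule by
construction, while all remaining probes are rejection-sampled to have no
exact-or-1-mismatch placement on the genome.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .mapping import MAPPING_COLUMNS, MappingTable
from .match import build_seed_index, find_hits, reverse_complement
from .preprocess import ExpressionMatrix

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimulationConfig:
    """Study-design parameters of the synthetic mixed-species world.

    Counts give the array hierarchy (clusters > probesets > probes of
    probe_length bases); frac_homologous_clusters is the fraction of
    clusters planted with host-genome-derived probes, each carrying
    homolog_mismatches (0 or 1) substitutions; mixture_fractions are the
    human cell fractions f of the graded mixtures; noise_sd is the
    log2-scale standard deviation of the multiplicative noise.

    human_signal_log2_range bounds the per-cluster human signal (log2,
    drawn uniformly); host_affinity_fold scales the planted probes' host
    cross-hybridisation signal relative to the mean linear human signal;
    background_level is the linear host-side signal of non-planted probes.
    """

    n_clusters: int = 1000
    probesets_per_cluster: int = 4
    probes_per_probeset: int = 4
    probe_length: int = 25
    frac_homologous_clusters: float = 0.05
    homolog_mismatches: int = 1
    genome_length: int = 100_000
    mixture_fractions: tuple[float, ...] = (1.0, 0.95, 0.90)
    replicates_per_mixture: int = 3
    noise_sd: float = 0.2
    seed: int = 0
    human_signal_log2_range: tuple[float, float] = (6.0, 12.0)
    host_affinity_fold: float = 10.0
    background_level: float = 20.0

    def __post_init__(self):
        for name in ("n_clusters", "probesets_per_cluster", "probes_per_probeset",
                     "probe_length", "replicates_per_mixture"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.probe_length < 13:
            raise ValueError("probe_length must be >= 13 (seeding needs two tiles)")
        if not 0 <= self.frac_homologous_clusters <= 1:
            raise ValueError("frac_homologous_clusters must be in [0, 1]")
        if self.homolog_mismatches not in (0, 1):
            raise ValueError("homolog_mismatches must be 0 or 1")
        if self.genome_length < self.probe_length:
            raise ValueError("genome_length must be >= probe_length")
        if any(not 0 <= f <= 1 for f in self.mixture_fractions):
            raise ValueError("mixture_fractions must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.background_level <= 0 or self.host_affinity_fold <= 0:
            raise ValueError("background_level and host_affinity_fold must be > 0")
        lo, hi = self.human_signal_log2_range
        if not lo < hi:
            raise ValueError("human_signal_log2_range must be increasing")

    @property
    def mean_human_signal(self) -> float:
        """Mean linear-scale human cluster signal under the log2-uniform draw."""
        lo, hi = self.human_signal_log2_range
        return (2.0 ** hi - 2.0 ** lo) / ((hi - lo) * math.log(2.0))

    @property
    def host_affinity(self) -> float:
        """Linear host cross-hybridisation signal of a planted probe."""
        return self.host_affinity_fold * self.mean_human_signal

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruth:
    """Oracle labels of the synthetic design.

    contaminated_clusters: clusters whose probes were planted from the
        host genome (the set any correct mask should recover).
    host_affinity: per planted probe, its linear host signal; probes
        absent from the dict have no host homology.
    human_signal: per cluster, the linear human signal shared by its
        probes (plumbing for expression simulation).
    """

    contaminated_clusters: frozenset[str]
    host_affinity: dict[str, float] = field(default_factory=dict)
    human_signal: dict[str, float] = field(default_factory=dict)


def group_label(f: float) -> str:
    """Column-group label for a human fraction: ALL.<pct>, or NES at f=0."""
    if f == 0:
        return "NES"
    return f"ALL.{round(f * 100):d}"


def generate_host_genome(config: SimulationConfig) -> str:
    """Uniform random ACGT genome of config.genome_length bases (seeded)."""
    rng = np.random.default_rng([config.seed, 0])
    return _BASES[rng.integers(0, 4, config.genome_length)].tobytes().decode("ascii")


def _random_probe(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, length)].tobytes().decode("ascii")


def _mutate(rng: np.random.Generator, seq: str, n_subs: int) -> str:
    out = list(seq)
    for pos in rng.choice(len(seq), size=n_subs, replace=False):
        alternatives = [b for b in "ACGT" if b != out[pos]]
        out[pos] = alternatives[rng.integers(0, 3)]
    return "".join(out)


def generate_array_design(
    config: SimulationConfig, genome: str
) -> tuple[pd.DataFrame, MappingTable, GroundTruth]:
    """Array design with rule-aware planted host homologs.

    Returns (probe table with columns probe_id/sequence, mapping table,
    ground truth).  In each contaminated cluster ceil(probesets/2)
    probesets consist entirely of probes copied from genome windows (with
    homolog_mismatches substitutions, on a random strand); every other
    probe is rejection-sampled until it has no <=1-mismatch placement.
    """
    if len(genome) < config.probe_length:
        raise ValueError("genome shorter than probe length")
    rng = np.random.default_rng([config.seed, 1])
    index = build_seed_index(genome)
    L = config.probe_length
    n_cont = int(round(config.frac_homologous_clusters * config.n_clusters))
    contaminated = set()
    if n_cont:
        picked = rng.choice(config.n_clusters, size=n_cont, replace=False)
        contaminated = {f"TC{int(i):05d}" for i in picked}
    n_planted_ps = math.ceil(config.probesets_per_cluster / 2)

    probe_rows: list[tuple[str, str]] = []
    map_rows: list[tuple[str, str, str]] = []
    affinity: dict[str, float] = {}
    human_signal: dict[str, float] = {}
    lo, hi = config.human_signal_log2_range
    for ci in range(config.n_clusters):
        cluster = f"TC{ci:05d}"
        human_signal[cluster] = float(2.0 ** rng.uniform(lo, hi))
        for pj in range(config.probesets_per_cluster):
            probeset = f"PS{ci:05d}.{pj}"
            planted_set = cluster in contaminated and pj < n_planted_ps
            for pk in range(config.probes_per_probeset):
                probe = f"P{ci:05d}.{pj}.{pk}"
                if planted_set:
                    start = int(rng.integers(0, len(genome) - L + 1))
                    seq = genome[start:start + L]
                    if rng.random() < 0.5:
                        seq = reverse_complement(seq)
                    seq = _mutate(rng, seq, config.homolog_mismatches)
                    affinity[probe] = config.host_affinity
                else:
                    for _ in range(1000):
                        seq = _random_probe(rng, L)
                        if not find_hits(seq, index, probe_id=probe):
                            break
                    else:
                        raise RuntimeError(
                            "could not sample a genome-free probe after 1000 tries"
                        )
                probe_rows.append((probe, seq))
                map_rows.append((probe, probeset, cluster))

    probes = pd.DataFrame(probe_rows, columns=["probe_id", "sequence"])
    mapping = MappingTable(pd.DataFrame(map_rows, columns=list(MAPPING_COLUMNS)))
    truth = GroundTruth(frozenset(contaminated), affinity, human_signal)
    return probes, mapping, truth


def simulate_expression(probes: pd.DataFrame, mapping: MappingTable,
                        truth: GroundTruth, f: float, n_reps: int, seed: int,
                        config: SimulationConfig) -> ExpressionMatrix:
    """Probe-level linear intensities for a mixture with human fraction f.

    Expected intensity per probe is f*h + (1-f)*a (h the probe's cluster
    human signal, a its host affinity or the background level), with
    multiplicative log-normal noise of sd config.noise_sd on the log2
    scale.  Columns are named <group>_<replicate>.
    """
    if not 0 <= f <= 1:
        raise ValueError(f"human fraction must lie in [0, 1], got {f}")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng([seed, 2])
    human = np.empty(len(probes))
    host = np.empty(len(probes))
    for i, pid in enumerate(probes["probe_id"]):
        cluster = sorted(mapping.clusters_of_probe(pid))[0]
        human[i] = truth.human_signal[cluster]
        host[i] = truth.host_affinity.get(pid, config.background_level)
    expected = f * human + (1.0 - f) * host
    noise = rng.normal(0.0, config.noise_sd, size=(len(probes), n_reps)) \
        if config.noise_sd > 0 else np.zeros((len(probes), n_reps))
    values = expected[:, None] * 2.0 ** noise
    label = group_label(f)
    columns = [f"{label}_{i + 1}" for i in range(n_reps)]
    frame = pd.DataFrame(values, index=list(probes["probe_id"]), columns=columns)
    return ExpressionMatrix(frame, "linear")


@dataclass
class SimulatedStudy:
    """Full synthetic study: genome, design, truth and probe intensities."""

    config: SimulationConfig
    genome: str
    probes: pd.DataFrame
    mapping: MappingTable
    truth: GroundTruth
    probe_matrix: ExpressionMatrix  # all mixtures + NES, linear scale
    groups: dict[str, str]  # sample -> group label


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Generate the complete study: graded mixtures plus host-only arrays.

    One probe-level linear matrix holds replicates_per_mixture columns for
    every fraction in mixture_fractions and for the pure-host NES arrays
    (f = 0).  Fully determined by config.seed.
    """
    genome = generate_host_genome(config)
    probes, mapping, truth = generate_array_design(config, genome)
    fractions = list(config.mixture_fractions)
    if 0.0 not in fractions:
        fractions.append(0.0)  # host-only (NES) hybridisations
    blocks = []
    groups: dict[str, str] = {}
    for k, f in enumerate(fractions):
        em = simulate_expression(probes, mapping, truth, f,
                                 config.replicates_per_mixture,
                                 seed=config.seed * 1000 + k, config=config)
        blocks.append(em.values)
        groups.update({s: group_label(f) for s in em.values.columns})
    matrix = ExpressionMatrix(pd.concat(blocks, axis=1), "linear")
    return SimulatedStudy(config, genome, probes, mapping, truth, matrix, groups)
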