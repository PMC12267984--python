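"""Reproducible synthetic fixtures: genomes, read sets, training tables with a
planted RAM response, and abundance tables with planted core structure.

Every generator is a pure function of its seed and spec: rerunning with the
same arguments yields byte-identical output.  The planted truth is returned
alongside the data (and can be serialized to JSON) so recovery tests can
compare against it directly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

from .pipeline import TARGET_COLUMN, TrainingTable

__all__ = [
    "CommunitySpec",
    "PlantedTruth",
    "FastqRead",
    "simulate_genomes",
    "simulate_readset",
    "write_fastq",
    "synth_training_table",
    "synth_abundance_fixture",
]

_BASES = np.array(list("ACGT"))
_OTHER = {  # substitution targets per base
    "A": "CGT",
    "C": "AGT",
    "G": "ACT",
    "T": "ACG",
}


class FastqRead(NamedTuple):
    name: str
    sequence: str
    quality: str


@dataclass(frozen=True)
class CommunitySpec:
    """Parameters of a simulated community read set."""

    n_genomes: int = 5
    genome_length: int = 5000
    gc: float = 0.5
    read_length: int = 150
    n_reads: int = 1000
    error_rate: float = 0.0
    abundance: Optional[Sequence[float]] = None  # explicit weights
    lognormal_sigma: float = 1.0  # used when abundance is None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.gc <= 1.0:
            raise ValueError("gc must lie in [0, 1]")
        if not 0.0 <= self.error_rate <= 1.0:
            raise ValueError("error_rate must lie in [0, 1]")
        if self.genome_length < self.read_length:
            raise ValueError("genome_length must be >= read_length")


@dataclass
class PlantedTruth:
    """Ground truth planted in a synthetic fixture (serializable)."""

    kind: str  # "training_table" | "abundance"
    seed: int
    # training-table truth
    response: Optional[dict] = None  # {"intercept", "coefficients", "noise_sd"}
    # abundance-fixture truth
    global_species: list[str] = field(default_factory=list)
    regional_species: dict = field(default_factory=dict)  # region -> [species]
    background_rate: Optional[float] = None

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "PlantedTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def simulate_genomes(
    n: int, length: int, gc: float = 0.5, seed: int = 0
) -> list[str]:
    """i.i.d. random genomes with P(G) + P(C) = gc."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if length < 1:
        raise ValueError("length must be >= 1")
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return [
        "".join(rng.choice(_BASES, size=length, p=probs)) for _ in range(n)
    ]


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def simulate_readset(genomes: Sequence[str], spec: CommunitySpec) -> list[FastqRead]:
    """Draw reads from genomes under the community spec.

    Genome choice is proportional to the abundance weights (explicit, or
    lognormal draws under the spec seed), start positions uniform, strand
    uniform, substitutions independent per base at ``error_rate``.  The
    quality string is constant; quality is never consumed downstream.
    """
    if not genomes:
        raise ValueError("no genomes given")
    if any(len(g) < spec.read_length for g in genomes):
        raise ValueError("read_length exceeds a genome length")
    rng = np.random.default_rng(spec.seed)
    if spec.abundance is not None:
        weights = np.asarray(spec.abundance, dtype=float)
        if len(weights) != len(genomes):
            raise ValueError("abundance weights do not match genome count")
    else:
        weights = rng.lognormal(mean=0.0, sigma=spec.lognormal_sigma, size=len(genomes))
    probs = weights / weights.sum()
    quality = "I" * spec.read_length
    reads: list[FastqRead] = []
    for i in range(spec.n_reads):
        g = int(rng.choice(len(genomes), p=probs))
        genome = genomes[g]
        start = int(rng.integers(0, len(genome) - spec.read_length + 1))
        seq = genome[start : start + spec.read_length]
        if rng.random() < 0.5:
            seq = _revcomp(seq)
        if spec.error_rate > 0:
            chars = list(seq)
            errors = np.flatnonzero(rng.random(len(chars)) < spec.error_rate)
            for pos in errors:
                chars[pos] = _OTHER[chars[pos]][int(rng.integers(0, 3))]
            seq = "".join(chars)
        reads.append(FastqRead(name=f"read_{i}", sequence=seq, quality=quality))
    return reads


def write_fastq(reads: Sequence[FastqRead], path) -> None:
    with open(path, "w") as fh:
        for read in reads:
            fh.write(f"@{read.name}\n{read.sequence}\n+\n{read.quality}\n")


# --- training table ---------------------------------------------------------

#: default linear response: peak_ram_gb = b0 + b21 * distinct_21 + b71 * distinct_71
DEFAULT_RESPONSE = {
    "intercept": 4.0,
    "coefficients": {"distinct_kmers_21": 9.0e-7, "distinct_kmers_71": 6.0e-7},
    "noise_sd": 2.0,
}


def synth_training_table(
    n_datasets: int = 300,
    seed: int = 0,
    noise_sd: float = 2.0,
    mode: str = "default",
    response: Optional[dict] = None,
    via_reads: bool = False,
) -> tuple[TrainingTable, PlantedTruth]:
    """Training table whose peak-RAM response is linear in the distinct k-mer
    counts at k = 21 and k = 71 plus Gaussian noise.

    In the default (direct) mode, features are drawn from declared
    distributions: a latent community-complexity factor drives the k-mer
    features, while GC content and read lengths are independent noise
    columns that correlation screening should reject.  With ``via_reads``
    features are extracted from small simulated read sets instead (slow;
    intended for tiny n).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    truth_response = dict(response or DEFAULT_RESPONSE)
    truth_response["noise_sd"] = noise_sd
    rng = np.random.default_rng(seed)

    if via_reads:
        frame = _features_via_reads(n_datasets, rng)
    else:
        frame = _features_direct(n_datasets, rng)

    coeffs = truth_response["coefficients"]
    y = np.full(len(frame), float(truth_response["intercept"]))
    for name, coef in coeffs.items():
        y = y + coef * frame[name].to_numpy(dtype=float)
    y = y + rng.normal(0.0, noise_sd, size=len(frame))
    frame[TARGET_COLUMN] = np.maximum(y, 0.5)  # peak RAM is positive

    table = TrainingTable(frame=frame, mode=mode)
    truth = PlantedTruth(kind="training_table", seed=seed, response=truth_response)
    return table, truth


def _features_direct(n: int, rng: np.random.Generator) -> pd.DataFrame:
    complexity = rng.lognormal(mean=0.0, sigma=0.6, size=n)
    jitter = lambda scale: rng.normal(1.0, scale, size=n).clip(0.5, 1.5)  # noqa: E731
    distinct_21 = 2.0e7 * complexity * jitter(0.05)
    distinct_71 = 1.4e7 * complexity * jitter(0.05)
    total_21 = distinct_21 * rng.uniform(1.5, 2.5, size=n)
    total_71 = distinct_71 * rng.uniform(1.2, 2.0, size=n)
    frame = pd.DataFrame(
        {
            "gc_content": rng.uniform(0.3, 0.7, size=n),
            "total_reads": rng.uniform(1e6, 5e6, size=n),
            "min_read_length": rng.integers(35, 100, size=n).astype(float),
            "avg_read_length": rng.uniform(100, 250, size=n),
            "total_bases": rng.uniform(1e8, 9e8, size=n),
            "distinct_kmers_21": distinct_21,
            "distinct_kmers_71": distinct_71,
            "total_kmers_21": total_21,
            "total_kmers_71": total_71,
        },
        index=pd.Index([f"ds{i:04d}" for i in range(n)], name="dataset_id"),
    )
    return frame


def _features_via_reads(n: int, rng: np.random.Generator) -> pd.DataFrame:
    from .kmer import (
        assemble_feature_vector,
        compute_read_stats,
        count_canonical_kmers,
        spectrum_statistics,
    )

    ks = (13, 21, 71)
    rows = []
    ids = []
    for i in range(n):
        n_genomes = int(rng.integers(1, 8))
        genomes = simulate_genomes(
            n_genomes, length=2000, gc=float(rng.uniform(0.3, 0.7)),
            seed=int(rng.integers(0, 2**31)),
        )
        spec = CommunitySpec(
            n_genomes=n_genomes,
            genome_length=2000,
            read_length=100,
            n_reads=int(rng.integers(200, 600)),
            error_rate=0.005,
            seed=int(rng.integers(0, 2**31)),
        )
        reads = [r.sequence for r in simulate_readset(genomes, spec)]
        stats = compute_read_stats(reads)
        spectra = {
            k: spectrum_statistics(count_canonical_kmers(reads, k)) for k in ks
        }
        fv = assemble_feature_vector(f"ds{i:04d}", stats, spectra, ks=ks)
        rows.append(fv.values)
        ids.append(fv.dataset_id)
    return pd.DataFrame(rows, index=pd.Index(ids, name="dataset_id"))


# --- abundance fixture ------------------------------------------------------


def synth_abundance_fixture(
    regions: dict[str, Sequence[str]],
    samples_per_country: int = 10,
    seed: int = 0,
    n_global: int = 3,
    n_regional_per_region: int = 1,
    n_background: int = 10,
    background_rate: float = 0.10,
    offregion_rate: float = 0.10,
    passing_country_fraction: float = 0.80,
) -> tuple[pd.DataFrame, pd.DataFrame, PlantedTruth]:
    """Abundance table plus metadata with planted core structure.

    Planted global species are present in every sample; each region gets
    ``n_regional_per_region`` species present in all samples of a ceil(80%)
    subset of its countries and sparsely (``offregion_rate``) elsewhere;
    background species are present independently at ``background_rate``.
    Abundances of present species are lognormal.
    """
    if not regions or any(not countries for countries in regions.values()):
        raise ValueError("need >= 1 region with >= 1 country each")
    if not 0.0 <= background_rate <= 1.0:
        raise ValueError("background_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)

    samples: list[str] = []
    meta_rows = []
    for region, countries in regions.items():
        for country in countries:
            for s in range(samples_per_country):
                sid = f"{country}_{s:03d}"
                samples.append(sid)
                meta_rows.append(
                    {
                        "sample_id": sid,
                        "country": country,
                        "region": region,
                        "nonpareil_coverage_pct": float(rng.uniform(60, 95)),
                    }
                )
    metadata = pd.DataFrame(meta_rows)
    country_of = {row["sample_id"]: row["country"] for row in meta_rows}

    species: list[str] = []
    presence_rows: list[np.ndarray] = []
    truth = PlantedTruth(
        kind="abundance", seed=seed, background_rate=background_rate
    )

    def _lognormal_where(mask: np.ndarray) -> np.ndarray:
        values = np.zeros(len(samples))
        values[mask] = rng.lognormal(mean=1.0, sigma=1.0, size=int(mask.sum()))
        return values

    for g in range(n_global):
        name = f"global_sp{g}"
        species.append(name)
        truth.global_species.append(name)
        presence_rows.append(np.ones(len(samples), dtype=bool))

    for region, countries in regions.items():
        n_pass = max(1, math.ceil(passing_country_fraction * len(countries)))
        passing = set(list(countries)[:n_pass])
        for r in range(n_regional_per_region):
            name = f"{region}_core_sp{r}"
            species.append(name)
            truth.regional_species.setdefault(region, []).append(name)
            mask = np.zeros(len(samples), dtype=bool)
            for i, sid in enumerate(samples):
                if country_of[sid] in passing:
                    mask[i] = True
                else:
                    mask[i] = rng.random() < offregion_rate
            presence_rows.append(mask)

    for b in range(n_background):
        species.append(f"background_sp{b}")
        presence_rows.append(rng.random(len(samples)) < background_rate)

    table = pd.DataFrame(
        [_lognormal_where(mask) for mask in presence_rows],
        index=pd.Index(species, name="species"),
        columns=samples,
    )
    return table, metadata, truth
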