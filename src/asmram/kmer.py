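"""Read-set statistics, canonical k-mer counting, and spectrum features.

The k-mer *spectrum* of a read set is the histogram mapping an occurrence
frequency ``f`` to ``c_f``, the number of distinct canonical k-mers observed
exactly ``f`` times.  All downstream spectrum features are derived from the
per-bin k-mer mass ``v_f = f * c_f``.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "ReadSetStats",
    "KmerSpectrum",
    "SpectrumStats",
    "FeatureVector",
    "DEFAULT_KS",
    "READ_FEATURES",
    "SPECTRUM_FEATURES",
    "feature_names",
    "reverse_complement",
    "canonical",
    "compute_read_stats",
    "count_canonical_kmers",
    "spectrum_statistics",
    "read_kmc_histogram",
    "write_kmc_histogram",
    "assemble_feature_vector",
]

DEFAULT_KS: tuple[int, ...] = (13, 21, 71)

READ_FEATURES = (
    "gc_content",
    "total_reads",
    "min_read_length",
    "avg_read_length",
    "total_bases",
)
SPECTRUM_FEATURES = ("total_kmers", "distinct_kmers", "mean", "sd", "max", "q5", "q95")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_ACGT_RUN = re.compile("[ACGT]+")


def feature_names(ks: Sequence[int] = DEFAULT_KS, diversity: bool = True) -> list[str]:
    """Canonical ordering of candidate feature names for the given k sizes."""
    names = list(READ_FEATURES)
    for k in ks:
        names.extend(f"{stat}_{k}" for stat in SPECTRUM_FEATURES)
    if diversity:
        names.append("nonpareil_diversity")
    return names


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def canonical(kmer: str) -> str:
    """Lexicographic minimum of a k-mer and its reverse complement."""
    rc = reverse_complement(kmer)
    return kmer if kmer <= rc else rc


@dataclass(frozen=True)
class ReadSetStats:
    """Per-read summary statistics of a read set."""

    n_reads: int
    total_bases: int
    gc_fraction: float
    min_read_length: int
    avg_read_length: float

    def __post_init__(self) -> None:
        if self.n_reads < 1:
            raise ValueError("read set must contain at least one read")
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ValueError(f"gc_fraction outside [0, 1]: {self.gc_fraction}")
        if self.min_read_length > self.avg_read_length:
            raise ValueError("min_read_length exceeds avg_read_length")


@dataclass(frozen=True)
class KmerSpectrum:
    """Frequency histogram of canonical k-mer counts.

    ``histogram[f]`` is the number of distinct canonical k-mers seen exactly
    ``f`` times.  Zero-valued bins are never stored.
    """

    k: int
    histogram: Mapping[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")
        for f, c in self.histogram.items():
            if f < 1 or c < 1:
                raise ValueError(f"invalid histogram bin {f}: {c}")

    @property
    def distinct(self) -> int:
        return sum(self.histogram.values())

    @property
    def total(self) -> int:
        return sum(f * c for f, c in self.histogram.items())

    def is_empty(self) -> bool:
        return not self.histogram


@dataclass(frozen=True)
class SpectrumStats:
    """Summary features of one k-mer spectrum.

    ``mean/sd/max`` are taken over the multiset of per-bin masses
    ``v_f = f * c_f`` of occupied bins (population SD).  ``q5_sum`` is the
    mass of the longest low-frequency prefix of bins whose cumulative mass
    stays within 5% of the total; ``q95_sum`` the analogous high-frequency
    suffix.
    """

    total_kmers: int
    distinct_kmers: int
    mean_total_per_freq: float
    sd_total_per_freq: float
    max_total_per_freq: int
    q5_sum: int
    q95_sum: int

    def as_features(self, k: int) -> dict[str, float]:
        return {
            f"total_kmers_{k}": float(self.total_kmers),
            f"distinct_kmers_{k}": float(self.distinct_kmers),
            f"mean_{k}": self.mean_total_per_freq,
            f"sd_{k}": self.sd_total_per_freq,
            f"max_{k}": float(self.max_total_per_freq),
            f"q5_{k}": float(self.q5_sum),
            f"q95_{k}": float(self.q95_sum),
        }


@dataclass
class FeatureVector:
    """Named candidate features for one dataset.

    ``values`` maps feature name to value; features that could not be
    computed (currently only ``nonpareil_diversity``, which is supplied by
    an external tool) are listed in ``missing`` rather than stored as zero.
    """

    dataset_id: str
    values: dict[str, float]
    missing: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for name in ("total_reads", "total_bases", "min_read_length"):
            if name in self.values and self.values[name] < 0:
                raise ValueError(f"negative count for {name}")

    def __getitem__(self, name: str) -> float:
        return self.values[name]


def compute_read_stats(reads: Iterable[str]) -> ReadSetStats:
    """One-pass per-read tally of lengths and GC content.

    GC fraction is (#G + #C) / (#A + #C + #G + #T); ambiguous bases are
    excluded from both numerator and denominator but do count toward read
    lengths.
    """
    n_reads = 0
    total_bases = 0
    min_len: Optional[int] = None
    gc = 0
    acgt = 0
    for read in reads:
        seq = str(read).upper()
        n_reads += 1
        total_bases += len(seq)
        if min_len is None or len(seq) < min_len:
            min_len = len(seq)
        gc += seq.count("G") + seq.count("C")
        acgt += seq.count("A") + seq.count("T") + seq.count("G") + seq.count("C")
    if n_reads == 0 or min_len is None:
        raise ValueError("empty read set")
    if acgt == 0:
        raise ValueError("no unambiguous A/C/G/T bases; GC content undefined")
    return ReadSetStats(
        n_reads=n_reads,
        total_bases=total_bases,
        gc_fraction=gc / acgt,
        min_read_length=min_len,
        avg_read_length=total_bases / n_reads,
    )


def count_canonical_kmers(reads: Iterable[str], k: int) -> KmerSpectrum:
    """Count canonical k-mers over all reads and return the spectrum.

    Windows containing a non-ACGT symbol are skipped; reads shorter than
    ``k`` contribute nothing.  An empty spectrum is allowed (downstream
    statistics will then refuse to compute).
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    counts: Counter[str] = Counter()
    for read in reads:
        seq = str(read).upper()
        # splitting on non-ACGT runs skips exactly the windows that contain them
        for chunk in _ACGT_RUN.findall(seq):
            for i in range(len(chunk) - k + 1):
                counts[canonical(chunk[i : i + k])] += 1
    return KmerSpectrum(k=k, histogram=dict(Counter(counts.values())))


def spectrum_statistics(spectrum: KmerSpectrum) -> SpectrumStats:
    """Summary statistics over the occupied bins of a spectrum."""
    if spectrum.is_empty():
        raise ValueError("cannot compute statistics of an empty spectrum")
    freqs = sorted(spectrum.histogram)
    masses = [f * spectrum.histogram[f] for f in freqs]
    total = sum(masses)
    distinct = sum(spectrum.histogram.values())
    n_bins = len(masses)
    mean = total / n_bins
    sd = (sum((v - mean) ** 2 for v in masses) / n_bins) ** 0.5
    cap = 0.05 * total

    q5 = 0
    for v in masses:  # ascending frequency prefix
        if q5 + v > cap:
            break
        q5 += v
    q95 = 0
    for v in reversed(masses):  # descending frequency suffix
        if q95 + v > cap:
            break
        q95 += v

    return SpectrumStats(
        total_kmers=total,
        distinct_kmers=distinct,
        mean_total_per_freq=mean,
        sd_total_per_freq=sd,
        max_total_per_freq=max(masses),
        q5_sum=q5,
        q95_sum=q95,
    )


def read_kmc_histogram(path, k: int) -> KmerSpectrum:
    """Parse a KMC ``transform … histogram`` two-column text file.

    Each line holds a frequency and the count of distinct k-mers at that
    frequency, whitespace separated.  Zero-count lines are dropped.
    """
    histogram: dict[int, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns, got {len(fields)}")
            try:
                freq, count = int(fields[0]), int(fields[1])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer field: {line.strip()!r}") from exc
            if freq < 1 or count < 0:
                raise ValueError(f"{path}:{lineno}: negative or zero-frequency bin")
            if count > 0:
                histogram[freq] = histogram.get(freq, 0) + count
    return KmerSpectrum(k=k, histogram=histogram)


def write_kmc_histogram(spectrum: KmerSpectrum, path) -> None:
    """Write a spectrum in the KMC two-column histogram dialect."""
    with open(path, "w") as fh:
        for f in sorted(spectrum.histogram):
            fh.write(f"{f}\t{spectrum.histogram[f]}\n")


def assemble_feature_vector(
    dataset_id: str,
    stats: ReadSetStats,
    spectra: Mapping[int, SpectrumStats],
    ks: Sequence[int] = DEFAULT_KS,
    diversity: Optional[float] = None,
) -> FeatureVector:
    """Combine read-level and spectrum-level statistics into one vector.

    ``spectra`` must provide statistics for every configured ``k``; a missing
    Nonpareil diversity value is recorded as missing, never as zero.
    """
    if len(set(ks)) != len(ks):
        raise ValueError(f"duplicate k in configuration: {tuple(ks)}")
    values: dict[str, float] = {
        "gc_content": stats.gc_fraction,
        "total_reads": float(stats.n_reads),
        "min_read_length": float(stats.min_read_length),
        "avg_read_length": stats.avg_read_length,
        "total_bases": float(stats.total_bases),
    }
    for k in ks:
        if k not in spectra:
            raise ValueError(f"no spectrum statistics supplied for k={k}")
        values.update(spectra[k].as_features(k))
    missing: tuple[str, ...] = ()
    if diversity is None:
        missing = ("nonpareil_diversity",)
    else:
        values["nonpareil_diversity"] = float(diversity)
    return FeatureVector(dataset_id=dataset_id, values=values, missing=missing)
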