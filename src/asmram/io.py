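"""File input/output helpers: sequence files, feature tables, flavor catalogs."""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import IO, Iterator, Optional, Sequence, Union

import pandas as pd
import yaml
from Bio import SeqIO

from .kmer import FeatureVector, feature_names

PathLike = Union[str, Path]

GZIP_MAGIC = b"\x1f\x8b"


def open_text_auto(path: PathLike) -> IO[str]:
    """Open a text file, transparently decompressing gzip.

    Compression is detected from the two magic bytes, not the extension.
    """
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == GZIP_MAGIC:
        return gzip.open(path, "rt")
    return open(path, "rt")


def iter_reads(path: PathLike) -> Iterator[str]:
    """Yield read sequences from a FASTQ or FASTA file (optionally gzipped).

    The format is sniffed from the first record character ('@' FASTQ,
    '>' FASTA).
    """
    handle = open_text_auto(path)
    try:
        first = handle.read(1)
        handle.seek(0)
        if first == "@":
            fmt = "fastq"
        elif first == ">":
            fmt = "fasta"
        else:
            raise ValueError(f"{path}: not FASTA/FASTQ (starts with {first!r})")
        for record in SeqIO.parse(handle, fmt):
            yield str(record.seq)
    finally:
        handle.close()


def write_feature_table(vectors: Sequence[FeatureVector], path: PathLike) -> None:
    """Write feature vectors as a TSV with a stable column order."""
    rows = []
    for fv in vectors:
        row: dict[str, object] = {"dataset_id": fv.dataset_id}
        row.update(fv.values)
        rows.append(row)
    frame = pd.DataFrame(rows)
    ordered = ["dataset_id"] + [c for c in feature_names() if c in frame.columns]
    extras = [c for c in frame.columns if c not in ordered]
    frame[ordered + extras].to_csv(path, sep="\t", index=False)


def read_feature_table(path: PathLike) -> pd.DataFrame:
    """Read a TSV feature table into a frame indexed by dataset_id."""
    frame = pd.read_csv(path, sep="\t")
    if "dataset_id" not in frame.columns:
        raise ValueError(f"{path}: missing required column 'dataset_id'")
    return frame.set_index("dataset_id")


def read_gb_table(path: PathLike, value_column: Optional[str] = None) -> dict[str, float]:
    """Read a two-column TSV of dataset_id and a GB quantity (peaks/predictions)."""
    frame = pd.read_csv(path, sep="\t")
    if "dataset_id" not in frame.columns:
        raise ValueError(f"{path}: missing required column 'dataset_id'")
    if value_column is None:
        candidates = [c for c in frame.columns if c != "dataset_id"]
        if len(candidates) != 1:
            raise ValueError(f"{path}: ambiguous value column, pass one of {candidates}")
        value_column = candidates[0]
    return dict(zip(frame["dataset_id"].astype(str), frame[value_column].astype(float)))


def load_flavor_catalog(path: PathLike):
    """Load a flavor catalog from YAML: a list of {name, ram_gb[, cpus]}."""
    from .allocation import Flavor, FlavorCatalog

    with open(path) as fh:
        entries = yaml.safe_load(fh)
    if isinstance(entries, dict) and "flavors" in entries:
        entries = entries["flavors"]
    if not isinstance(entries, list):
        raise ValueError(f"{path}: expected a YAML list of flavors")
    flavors = [
        Flavor(name=str(e["name"]), ram_gb=float(e["ram_gb"]), cpus=e.get("cpus"))
        for e in entries
    ]
    return FlavorCatalog(flavors)


def read_abundance_table(path: PathLike) -> pd.DataFrame:
    """Read a species-by-sample abundance TSV (first column = species id)."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    if (frame.values < 0).any():
        raise ValueError(f"{path}: abundance table contains negative values")
    return frame


def read_sample_metadata(path: PathLike) -> pd.DataFrame:
    """Read sample metadata TSV (sample_id, country, region[, nonpareil_coverage_pct])."""
    frame = pd.read_csv(path, sep="\t")
    required = {"sample_id", "country", "region"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing metadata columns {sorted(missing)}")
    frame["sample_id"] = frame["sample_id"].astype(str)
    return frame
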