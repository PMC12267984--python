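"""Core-microbiome ubiquity analysis over a species-by-sample abundance table.

Rules implemented:

* sample filtering — drop samples whose genome-coverage percentage falls
  strictly below ``Q1 - 1.5 * IQR`` (quartiles by linear interpolation);
* ubiquity–abundance curves — per species, the percentage of samples whose
  abundance meets each threshold of an ascending grid;
* global core — species present (abundance > 0) in strictly more than 60%
  of all samples;
* regional core ("range-through") — species present in strictly more than
  90% of a country's samples, kept if that holds in at least 80% of the
  region's countries;
* top-abundance share — the percentage of samples a species wins as the
  unique abundance maximum.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CoreReport",
    "filter_samples_by_coverage",
    "default_threshold_grid",
    "ubiquity_abundance_curves",
    "global_core",
    "regional_core",
    "top_abundance_share",
    "plot_ubiquity_curves",
]


@dataclass
class CoreReport:
    """Regional core-membership table.

    ``frame`` has one row per (region, species) with the percentage of the
    region's countries in which the species passes the per-country rule and
    the resulting membership flag.
    """

    frame: pd.DataFrame  # columns: region, species, pct_countries, member
    per_country: float
    country_fraction: float

    def members(self, region: str) -> list[str]:
        sub = self.frame[(self.frame["region"] == region) & self.frame["member"]]
        return sub["species"].tolist()

    @property
    def regions(self) -> list[str]:
        return sorted(self.frame["region"].unique().tolist())


def filter_samples_by_coverage(
    metadata: pd.DataFrame,
    multiplier: float = 1.5,
    coverage_column: str = "nonpareil_coverage_pct",
) -> tuple[list[str], Optional[float]]:
    """Drop samples whose coverage falls strictly below ``Q1 - m * IQR``.

    Quartiles use linear interpolation.  With fewer than 4 coverage values,
    or no coverage column at all, no filtering is applied (a warning is
    emitted) and every sample is retained.

    Returns ``(retained sample ids, cutoff)``; cutoff is None when no
    filtering happened.
    """
    ids = metadata["sample_id"].astype(str)
    if coverage_column not in metadata.columns:
        warnings.warn(f"metadata lacks column {coverage_column!r}; no samples filtered")
        return ids.tolist(), None
    coverage = pd.to_numeric(metadata[coverage_column], errors="coerce")
    known = coverage.dropna()
    if len(known) < 4:
        warnings.warn(
            f"only {len(known)} coverage values available (< 4); no samples filtered"
        )
        return ids.tolist(), None
    q1 = float(np.quantile(known.to_numpy(), 0.25))  # linear interpolation
    q3 = float(np.quantile(known.to_numpy(), 0.75))
    cutoff = q1 - multiplier * (q3 - q1)
    keep = coverage.isna() | (coverage >= cutoff)
    return ids[keep].tolist(), cutoff


def default_threshold_grid(table: pd.DataFrame, n_steps: int = 50) -> np.ndarray:
    """Ascending log10-spaced abundance thresholds spanning the positive range."""
    positive = table.to_numpy()[table.to_numpy() > 0]
    if positive.size == 0:
        raise ValueError("abundance table has no positive entries")
    lo, hi = np.log10(positive.min()), np.log10(positive.max())
    if lo == hi:
        return np.array([positive.min()])
    return np.logspace(lo, hi, n_steps)


def ubiquity_abundance_curves(
    table: pd.DataFrame, thresholds: Sequence[float]
) -> pd.DataFrame:
    """Percent of samples at or above each abundance threshold, per species.

    Returns a species-by-threshold frame of percentages in [0, 100]; rows
    are non-increasing left to right because thresholds must ascend.
    """
    if table.empty:
        raise ValueError("empty abundance table")
    thresholds = np.asarray(list(thresholds), dtype=float)
    if thresholds.size == 0:
        raise ValueError("no thresholds given")
    if np.any(np.diff(thresholds) < 0):
        raise ValueError("thresholds must be ascending")
    values = table.to_numpy(dtype=float)
    n_samples = values.shape[1]
    curves = np.empty((values.shape[0], thresholds.size))
    for j, t in enumerate(thresholds):
        curves[:, j] = 100.0 * (values >= t).sum(axis=1) / n_samples
    return pd.DataFrame(curves, index=table.index, columns=thresholds)


def global_core(
    table: pd.DataFrame,
    min_ubiquity: float = 0.60,
    presence_threshold: float = 0.0,
) -> list[str]:
    """Species present in strictly more than ``min_ubiquity`` of all samples.

    Presence means abundance strictly greater than ``presence_threshold``
    (default 0).
    """
    if table.empty:
        raise ValueError("empty abundance table")
    present = table.to_numpy(dtype=float) > presence_threshold
    fraction = present.sum(axis=1) / table.shape[1]
    return table.index[fraction > min_ubiquity].tolist()


def regional_core(
    table: pd.DataFrame,
    metadata: pd.DataFrame,
    per_country: float = 0.90,
    country_fraction: float = 0.80,
    presence_threshold: float = 0.0,
) -> CoreReport:
    """Two-stage regional core extraction.

    Stage 1: per country, a species passes if present in strictly more than
    ``per_country`` of that country's samples.  Stage 2: per region, a
    species is a member if it passes stage 1 in at least ``country_fraction``
    of the region's countries (boundary inclusive).  The report carries the
    percentage of countries passing for every species with at least one
    passing country in the region.
    """
    if table.empty:
        raise ValueError("empty abundance table")
    meta = metadata.copy()
    meta["sample_id"] = meta["sample_id"].astype(str)
    unmapped = [s for s in table.columns if s not in set(meta["sample_id"])]
    if unmapped:
        raise ValueError(f"samples missing from metadata: {unmapped[:5]}")
    region_of_country = (
        meta.drop_duplicates("country").set_index("country")["region"].to_dict()
    )
    conflicting = meta.groupby("country")["region"].nunique()
    if (conflicting > 1).any():
        raise ValueError(
            f"countries mapped to multiple regions: "
            f"{conflicting.index[conflicting > 1].tolist()}"
        )

    present = table.to_numpy(dtype=float) > presence_threshold
    presence = pd.DataFrame(present, index=table.index, columns=table.columns)

    country_pass: dict[str, pd.Series] = {}
    for country, group in meta.groupby("country"):
        samples = [s for s in group["sample_id"] if s in table.columns]
        if not samples:
            warnings.warn(f"country {country!r} has no samples in the table; excluded")
            continue
        fraction = presence[samples].sum(axis=1) / len(samples)
        country_pass[country] = fraction > per_country

    records = []
    regions = sorted(set(region_of_country[c] for c in country_pass))
    for region in regions:
        countries = [c for c in country_pass if region_of_country[c] == region]
        n_countries = len(countries)
        pass_counts = sum(country_pass[c].astype(int) for c in countries)
        for species in table.index:
            n_pass = int(pass_counts.loc[species])
            if n_pass == 0:
                continue
            pct = 100.0 * n_pass / n_countries
            records.append(
                {
                    "region": region,
                    "species": species,
                    "pct_countries": pct,
                    "member": pct >= country_fraction * 100.0,
                }
            )
    frame = pd.DataFrame.from_records(
        records, columns=["region", "species", "pct_countries", "member"]
    )
    return CoreReport(frame=frame, per_country=per_country, country_fraction=country_fraction)


def top_abundance_share(
    table: pd.DataFrame, group: Optional[Sequence[str]] = None
) -> pd.Series:
    """Percentage of samples each species wins as the unique abundance maximum.

    Samples whose maximum is shared by several species credit nobody; such
    ties are logged.  Shares therefore sum to at most 100%.
    """
    samples = list(table.columns) if group is None else list(group)
    if not samples:
        raise ValueError("empty sample group")
    unknown = [s for s in samples if s not in table.columns]
    if unknown:
        raise KeyError(f"samples not in table: {unknown[:5]}")
    sub = table[samples].to_numpy(dtype=float)
    wins = pd.Series(0, index=table.index, dtype=float)
    n_ties = 0
    for j, sample in enumerate(samples):
        column = sub[:, j]
        top = column.max()
        winners = np.flatnonzero(column == top)
        if len(winners) == 1:
            wins.iloc[winners[0]] += 1
        else:
            n_ties += 1
            logger.info("sample %s: top abundance tied among %d species", sample, len(winners))
    if n_ties:
        warnings.warn(f"{n_ties} sample(s) had tied top abundances; credited to no species")
    return 100.0 * wins / len(samples)


def plot_ubiquity_curves(
    curves: pd.DataFrame,
    path,
    min_display_ubiquity: float = 50.0,
    highlight_ubiquity: float = 60.0,
) -> None:
    """Ubiquity–abundance plot; species below ``min_display_ubiquity`` at the
    smallest threshold are hidden, species above ``highlight_ubiquity`` are
    colored, the rest drawn in grey."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 5))
    thresholds = curves.columns.to_numpy(dtype=float)
    for species, row in curves.iterrows():
        start = row.iloc[0]
        if start < min_display_ubiquity:
            continue
        if start > highlight_ubiquity:
            ax.plot(np.log10(thresholds), row.to_numpy(), label=str(species))
        else:
            ax.plot(np.log10(thresholds), row.to_numpy(), color="lightgrey")
    ax.set_xlabel("Log10 abundance threshold")
    ax.set_ylabel("Percent ubiquity")
    ax.set_ylim(0, 105)
    if ax.get_legend_handles_labels()[0]:
        ax.legend(fontsize=7, loc="upper right")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
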