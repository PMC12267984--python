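"""VM flavor selection and out-of-memory failover accounting.

A dataset is assigned a starting flavor by some policy; if the flavor's RAM
is below the dataset's true peak the run fails and is retried on the next
larger flavor until it succeeds or the catalog is exhausted.  Cost of a
dataset is the summed RAM of every attempted flavor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import pandas as pd

__all__ = [
    "Flavor",
    "FlavorCatalog",
    "DEFAULT_CATALOG",
    "CatalogExhaustedError",
    "AttemptLog",
    "FleetSimulationResult",
    "FixedPolicy",
    "OptimumPolicy",
    "PredictedPolicy",
    "predict_required_ram",
    "select_flavor",
    "escalate",
    "simulate_fleet",
    "compare_policies",
    "plot_policy_totals",
]


class CatalogExhaustedError(RuntimeError):
    """Requested RAM exceeds the largest flavor in the catalog."""


@dataclass(frozen=True)
class Flavor:
    name: str
    ram_gb: float
    cpus: Optional[int] = None

    def __post_init__(self) -> None:
        if self.ram_gb <= 0:
            raise ValueError(f"flavor {self.name!r}: ram_gb must be > 0")


class FlavorCatalog:
    """An ordered catalog of flavors with strictly increasing RAM."""

    def __init__(self, flavors: Sequence[Flavor]):
        if not flavors:
            raise ValueError("flavor catalog must not be empty")
        names = [f.name for f in flavors]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate flavor names: {names}")
        rams = [f.ram_gb for f in flavors]
        if any(b <= a for a, b in zip(rams, rams[1:])):
            raise ValueError(f"flavor RAM sizes must be strictly increasing: {rams}")
        self.flavors: tuple[Flavor, ...] = tuple(flavors)

    def __len__(self) -> int:
        return len(self.flavors)

    def __iter__(self):
        return iter(self.flavors)

    def __getitem__(self, i: int) -> Flavor:
        return self.flavors[i]

    @property
    def largest(self) -> Flavor:
        return self.flavors[-1]

    def by_name(self, name: str) -> Flavor:
        for flavor in self.flavors:
            if flavor.name == name:
                return flavor
        raise KeyError(f"no flavor named {name!r} in catalog")

    def index_of(self, flavor: Flavor) -> int:
        try:
            return self.flavors.index(flavor)
        except ValueError:
            raise KeyError(f"flavor {flavor.name!r} not in catalog") from None


def _default_catalog() -> FlavorCatalog:
    return FlavorCatalog(
        [Flavor(f"{gb}GB", float(gb)) for gb in (14, 29, 58, 113)]
    )


DEFAULT_CATALOG = _default_catalog()


def predict_required_ram(bundle, features: pd.DataFrame) -> pd.Series:
    """Required RAM per dataset: ``max(0, point prediction) + bias_gb``."""
    required = bundle.predict_required(features)
    return pd.Series(required, index=features.index, name="required_gb")


def select_flavor(catalog: FlavorCatalog, required_gb: float) -> Flavor:
    """Smallest flavor whose RAM meets ``required_gb`` (boundary inclusive)."""
    if required_gb < 0:
        raise ValueError(f"required_gb must be >= 0, got {required_gb}")
    for flavor in catalog:
        if flavor.ram_gb >= required_gb:
            return flavor
    raise CatalogExhaustedError(
        f"required {required_gb} GB exceeds largest flavor "
        f"({catalog.largest.name}, {catalog.largest.ram_gb} GB)"
    )


def escalate(catalog: FlavorCatalog, current: Flavor) -> Flavor:
    """The flavor with the next-higher RAM; errors if already at the top."""
    idx = catalog.index_of(current)
    if idx + 1 >= len(catalog):
        raise CatalogExhaustedError(
            f"flavor {current.name!r} is the largest in the catalog"
        )
    return catalog[idx + 1]


@dataclass
class AttemptLog:
    """Escalation history of one dataset."""

    dataset_id: str
    attempts: list[Flavor] = field(default_factory=list)
    outcome: str = "success"  # "success" | "exhausted"

    @property
    def cost_gb(self) -> float:
        return sum(f.ram_gb for f in self.attempts)

    @property
    def n_attempts(self) -> int:
        return len(self.attempts)


@dataclass
class FleetSimulationResult:
    """Outcome of running one policy over a fleet of datasets."""

    policy: str
    logs: dict[str, AttemptLog]
    catalog: FlavorCatalog

    @property
    def total_cost_gb(self) -> float:
        """Summed attempt cost over successful datasets only."""
        return sum(log.cost_gb for log in self.logs.values() if log.outcome == "success")

    @property
    def n_exhausted(self) -> int:
        return sum(1 for log in self.logs.values() if log.outcome == "exhausted")

    @property
    def exhausted_ids(self) -> list[str]:
        return [i for i, log in self.logs.items() if log.outcome == "exhausted"]


@dataclass(frozen=True)
class FixedPolicy:
    """Start every dataset on one fixed flavor."""

    start: Flavor

    @property
    def label(self) -> str:
        return f"fixed_{self.start.ram_gb:g}"


@dataclass(frozen=True)
class OptimumPolicy:
    """Start every dataset on the smallest flavor that fits its true peak."""

    label: str = "optimum"


@dataclass(frozen=True)
class PredictedPolicy:
    """Start each dataset on the flavor selected for its predicted requirement."""

    required_gb: Mapping[str, float]
    label: str = "predicted"


Policy = Union[FixedPolicy, OptimumPolicy, PredictedPolicy]


def _start_flavor(
    policy: Policy, dataset_id: str, peak_gb: float, catalog: FlavorCatalog
) -> Optional[Flavor]:
    """Starting flavor for a dataset, or None if no flavor can ever fit."""
    if isinstance(policy, FixedPolicy):
        catalog.index_of(policy.start)  # validate membership
        return policy.start
    if isinstance(policy, OptimumPolicy):
        try:
            return select_flavor(catalog, peak_gb)
        except CatalogExhaustedError:
            return None
    if isinstance(policy, PredictedPolicy):
        if dataset_id not in policy.required_gb:
            raise KeyError(f"predicted policy has no requirement for dataset {dataset_id!r}")
        required = policy.required_gb[dataset_id]
        try:
            return select_flavor(catalog, required)
        except CatalogExhaustedError:
            # the largest flavor is the only remaining chance
            warnings.warn(
                f"dataset {dataset_id!r}: predicted requirement {required:.1f} GB "
                f"exceeds the catalog; starting on the largest flavor"
            )
            return catalog.largest
    raise TypeError(f"unknown policy {policy!r}")


def simulate_fleet(
    true_peaks: Mapping[str, float],
    policy: Policy,
    catalog: FlavorCatalog = DEFAULT_CATALOG,
) -> FleetSimulationResult:
    """Run one policy over a fleet, escalating on every OOM failure.

    An attempt on flavor ``f`` succeeds iff ``f.ram_gb >= true peak``.
    Datasets whose peak exceeds the largest flavor are reported exhausted
    and excluded from the cost total.
    """
    if not true_peaks:
        raise ValueError("empty fleet")
    logs: dict[str, AttemptLog] = {}
    for dataset_id, peak in true_peaks.items():
        if peak <= 0:
            raise ValueError(f"dataset {dataset_id!r}: peak must be > 0, got {peak}")
        log = AttemptLog(dataset_id=str(dataset_id))
        flavor = _start_flavor(policy, str(dataset_id), float(peak), catalog)
        if flavor is None:
            log.outcome = "exhausted"
            logs[str(dataset_id)] = log
            continue
        while True:
            log.attempts.append(flavor)
            if flavor.ram_gb >= peak:
                log.outcome = "success"
                break
            try:
                flavor = escalate(catalog, flavor)
            except CatalogExhaustedError:
                log.outcome = "exhausted"
                break
        logs[str(dataset_id)] = log
    label = policy.label if not isinstance(policy, FixedPolicy) else policy.label
    return FleetSimulationResult(policy=label, logs=logs, catalog=catalog)


def compare_policies(
    true_peaks: Mapping[str, float],
    predictions: Mapping[str, float],
    catalog: FlavorCatalog = DEFAULT_CATALOG,
    fixed_starts: Optional[Sequence[Flavor]] = None,
) -> tuple[dict[str, FleetSimulationResult], pd.DataFrame]:
    """Simulate fixed/optimum/predicted policies and tabulate RAM savings.

    ``savings_gb`` of a policy is ``total(policy) - total(predicted)``; the
    predicted policy saves against itself exactly 0.
    """
    if not true_peaks:
        raise ValueError("empty fleet")
    if fixed_starts is None:
        fixed_starts = list(catalog)
    policies: list[Policy] = [FixedPolicy(start=f) for f in fixed_starts]
    policies.append(OptimumPolicy())
    policies.append(PredictedPolicy(required_gb=dict(predictions)))
    results = {p.label: simulate_fleet(true_peaks, p, catalog) for p in policies}
    predicted_total = results["predicted"].total_cost_gb
    table = pd.DataFrame(
        {
            "total_gb": {name: r.total_cost_gb for name, r in results.items()},
            "n_exhausted": {name: r.n_exhausted for name, r in results.items()},
        }
    )
    table["savings_gb"] = table["total_gb"] - predicted_total
    return results, table


def plot_policy_totals(table: pd.DataFrame, path) -> None:
    """Bar chart of per-policy total RAM with the predicted total as a line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    ax.bar(table.index, table["total_gb"], color="steelblue")
    ax.axhline(table.loc["predicted", "total_gb"], color="red", linestyle="-")
    ax.set_ylabel("Total RAM over all attempts (GB)")
    ax.set_xlabel("Allocation policy")
    ax.tick_params(axis="x", rotation=45)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
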