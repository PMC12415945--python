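"""Sample QC, universal-site intersection and the stratified subset search.

Reduced-representation libraries cover different CpG sets in different
samples, while a penalised-regression clock needs a complete sites × samples
matrix.  Three tools mitigate this:

* :func:`sample_qc` discards samples with too few called CpGs;
* :func:`universal_sites` intersects the per-sample site sets;
* :func:`stratified_subset_search` randomly partitions samples into
  age-stratified groups, scores each group by its number of uniform
  (group-universal) sites, repeats for many iterations, and returns the
  single best group over the whole search — trading cohort size for a much
  larger common CpG panel when a full intersection is too small.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SubsetSearchConfig",
    "SubsetResult",
    "sample_qc",
    "universal_sites",
    "stratified_subset_search",
]

logger = logging.getLogger(__name__)


def sample_qc(site_counts: Mapping[str, int] | pd.Series, min_sites: float) -> list[str]:
    """Retain samples whose unique-CpG count is at least ``min_sites``.

    The boundary is inclusive: a sample with exactly ``min_sites`` CpGs
    survives.  Discarded sample ids are logged.
    """
    counts = pd.Series(site_counts)
    if (counts < 0).any():
        raise ValueError("site counts must be non-negative")
    keep = counts[counts >= min_sites].index.tolist()
    dropped = counts.index.difference(keep).tolist()
    if dropped:
        logger.info(
            "sample_qc: discarding %d/%d samples below %g CpGs: %s",
            len(dropped), len(counts), min_sites, dropped,
        )
    return keep


def universal_sites(site_sets: Mapping[str, set] | Sequence[set]) -> set:
    """Exact intersection of per-sample site-id sets.

    Raises ``ValueError`` on zero samples (the intersection is undefined).
    """
    sets = list(site_sets.values()) if isinstance(site_sets, Mapping) else list(site_sets)
    if not sets:
        raise ValueError("universal_sites requires at least one sample")
    out = set(sets[0])
    for s in sets[1:]:
        out &= set(s)
    return out


@dataclass(frozen=True)
class SubsetSearchConfig:
    """Parameters of the random age-stratified subset search."""

    n_groups: int = 4
    iterations: int = 500
    age_bins: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_groups < 1 or self.iterations < 1 or self.age_bins < 1:
            raise ValueError("n_groups, iterations and age_bins must be >= 1")


@dataclass(frozen=True)
class SubsetResult:
    """Outcome of a subset search.

    ``iteration``/``group`` locate the winner; ``groups`` and ``counts`` hold
    the winning iteration's full partition and per-group uniform-site counts;
    ``samples`` and ``sites`` are the selected group's members and their
    common site ids.  ``trace`` stores every iteration's partition and counts
    so the search is fully auditable.
    """

    iteration: int
    group: int
    groups: dict[int, list[str]]
    counts: dict[int, int]
    samples: list[str]
    sites: set
    trace: list[dict[int, list[str]]] = field(repr=False, default_factory=list)


def _stratified_partition(
    ordered_ids: list[str],
    age_bins: int,
    n_groups: int,
    rng: np.random.Generator,
) -> dict[int, list[str]]:
    """One age-stratified random partition into ``n_groups`` groups.

    Samples are pre-sorted by (age, id); quantile bins are the equal-size
    chunks of that ordering.  Each bin is shuffled and dealt round-robin,
    continuing the group counter across bins so group sizes stay balanced.
    """
    bins = np.array_split(np.asarray(ordered_ids, dtype=object), age_bins)
    groups: dict[int, list[str]] = {g: [] for g in range(n_groups)}
    counter = 0
    for chunk in bins:
        for sid in rng.permutation(chunk):
            groups[counter % n_groups].append(str(sid))
            counter += 1
    return groups


def stratified_subset_search(
    ages: Mapping[str, float] | pd.Series,
    site_sets: Mapping[str, set],
    config: SubsetSearchConfig = SubsetSearchConfig(),
) -> SubsetResult:
    """Search random age-stratified partitions for the group with the most
    uniform sites.

    Per iteration, samples are binned by age quantile (ties broken by sample
    id so the seed fully determines the output) and dealt at random into
    ``n_groups`` groups whose age distributions each approximate the whole;
    each group is scored by the size of the intersection of its members'
    site sets.  The single best (iteration, group) over the whole search is
    returned, ties broken by first occurrence (lower iteration, then lower
    group index).
    """
    ages = pd.Series(ages)
    if set(ages.index) != set(site_sets):
        raise ValueError("ages and site_sets must cover the same samples")
    n = len(ages)
    if config.n_groups > n:
        raise ValueError(f"n_groups={config.n_groups} exceeds n_samples={n}")
    # stable order: (age, sample id)
    ordered = sorted(ages.index, key=lambda s: (ages[s], s))
    rng = np.random.default_rng(config.seed)

    best: tuple[int, int] | None = None
    best_count = -1
    best_partition: dict[int, list[str]] = {}
    best_counts: dict[int, int] = {}
    trace: list[dict[int, list[str]]] = []
    for it in range(config.iterations):
        groups = _stratified_partition(ordered, config.age_bins, config.n_groups, rng)
        trace.append(groups)
        counts = {
            g: len(universal_sites([site_sets[s] for s in members]))
            for g, members in groups.items()
        }
        for g in sorted(counts):
            if counts[g] > best_count:
                best_count = counts[g]
                best = (it, g)
                best_partition = groups
                best_counts = counts
    assert best is not None
    it, g = best
    members = best_partition[g]
    logger.info(
        "subset search: best group %d of iteration %d with %d uniform sites "
        "over %d samples", g, it, best_count, len(members),
    )
    return SubsetResult(
        iteration=it,
        group=g,
        groups=best_partition,
        counts=best_counts,
        samples=list(members),
        sites=universal_sites([site_sets[s] for s in members]),
        trace=trace,
    )
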