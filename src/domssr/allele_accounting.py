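"""Band classification by group occupancy.

Presence sets per group, exclusive (private) bands, bands absent from a
focal group with source attribution, and tracing of source-exclusive bands
into a target group's individuals. "Exclusive" is a presence-set notion: a
single carrier suffices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import GroupNameError, SizeError
from .genotype_io import PRESENT, BinaryGenotypeMatrix, Partition


@dataclass
class AbsenceReport:
    focal_group: str
    absent_bands: list[str]
    #: band -> groups carrying it
    carriers: dict[str, list[str]]
    #: band -> the single carrying group, for bands exclusive to one group
    exclusive_source: dict[str, str]
    total_bands: int

    @property
    def count(self) -> int:
        return len(self.absent_bands)

    @property
    def pct_of_total(self) -> float:
        return 100.0 * self.count / self.total_bands

    def exclusive_counts_by_source(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for src in self.exclusive_source.values():
            counts[src] = counts.get(src, 0) + 1
        return counts


@dataclass
class AlleleLedger:
    total_bands: int
    presence: dict[str, set[str]]
    exclusive: dict[str, set[str]]
    exclusive_pct: dict[str, float]
    #: per group: share of its own bands also seen elsewhere (denominator =
    #: the group's own band count, not the panel total)
    shared_pct: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.shared_pct:
            self.shared_pct = {
                g: 100.0 * (len(p) - len(self.exclusive.get(g, set()))) / len(p)
                for g, p in self.presence.items()
                if p
            }


def group_presence(
    matrix: BinaryGenotypeMatrix, partition: Partition
) -> dict[str, set[str]]:
    """Band label sets with at least one present call per group."""
    partition.check_covers(matrix)
    labels = matrix.band_labels()
    presence: dict[str, set[str]] = {}
    for group in partition.groups:
        rows = matrix.individual_index(partition.members(group))
        hit = (matrix.values[rows] == PRESENT).any(axis=0)
        presence[group] = {labels[j] for j in np.flatnonzero(hit)}
    return presence


def exclusive_alleles(
    presence: dict[str, set[str]],
    total_bands: int | None = None,
    among: list[str] | None = None,
) -> tuple[dict[str, set[str]], dict[str, float]]:
    """Per-group exclusive band sets and their percentage of all bands.

    ``among`` restricts the comparison to a subset of groups (exclusivity
    "within the basic germplasm", say) while percentages keep the full
    panel band total as denominator.
    """
    groups = list(presence) if among is None else list(among)
    unknown = set(groups) - set(presence)
    if unknown:
        raise GroupNameError(f"unknown group(s): {sorted(unknown)}")
    if len(groups) < 2:
        raise SizeError("exclusivity needs at least two groups")
    if total_bands is None:
        total_bands = len(set().union(*presence.values()))
    exclusive: dict[str, set[str]] = {}
    for g in groups:
        others: set[str] = set()
        for h in groups:
            if h != g:
                others |= presence[h]
        exclusive[g] = presence[g] - others
    pct = {g: 100.0 * len(s) / total_bands for g, s in exclusive.items()}
    return exclusive, pct


def build_ledger(matrix: BinaryGenotypeMatrix, partition: Partition) -> AlleleLedger:
    presence = group_presence(matrix, partition)
    exclusive, pct = exclusive_alleles(presence, total_bands=matrix.n_bands)
    return AlleleLedger(
        total_bands=matrix.n_bands,
        presence=presence,
        exclusive=exclusive,
        exclusive_pct=pct,
    )


def absence_report(
    presence: dict[str, set[str]],
    focal_group: str,
    total_bands: int | None = None,
) -> AbsenceReport:
    """Bands absent from ``focal_group``, attributed to the groups carrying them."""
    if focal_group not in presence:
        raise GroupNameError(f"unknown group {focal_group!r}")
    all_bands = set().union(*presence.values())
    if total_bands is None:
        total_bands = len(all_bands)
    absent = sorted(all_bands - presence[focal_group])
    carriers = {
        band: [g for g in presence if g != focal_group and band in presence[g]]
        for band in absent
    }
    exclusive_source = {
        band: groups[0] for band, groups in carriers.items() if len(groups) == 1
    }
    return AbsenceReport(
        focal_group=focal_group,
        absent_bands=absent,
        carriers=carriers,
        exclusive_source=exclusive_source,
        total_bands=total_bands,
    )


def trace_exclusive(
    matrix: BinaryGenotypeMatrix,
    partition: Partition,
    source_group: str,
    target_group: str,
) -> dict[str, list[str]]:
    """Bands exclusive to ``source_group`` among the non-target groups,
    mapped to the ``target_group`` individuals that carry them.

    Exclusivity deliberately excludes the target group from the comparison:
    a band private to the source among the other groups may still occur in
    the target, and those occurrences are the tracing signal.
    """
    for g in (source_group, target_group):
        if g not in partition.groups:
            raise GroupNameError(f"unknown group {g!r}")
    if source_group == target_group:
        raise GroupNameError("source and target group must differ")
    presence = group_presence(matrix, partition)
    non_target = [g for g in partition.groups if g != target_group]
    if len(non_target) < 2:
        source_exclusive = set(presence[source_group])
    else:
        exclusive, _ = exclusive_alleles(
            presence, total_bands=matrix.n_bands, among=non_target
        )
        source_exclusive = exclusive[source_group]

    labels = matrix.band_labels()
    col = {lab: j for j, lab in enumerate(labels)}
    target_rows = matrix.individual_index(partition.members(target_group))
    out: dict[str, list[str]] = {}
    for band in sorted(source_exclusive):
        j = col[band]
        hits = [
            matrix.individuals[i]
            for i in target_rows
            if matrix.values[i, j] == PRESENT
        ]
        if hits:
            out[band] = hits
    return out
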