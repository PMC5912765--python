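"""Jaccard-complement dissimilarities and group-level summaries.

The pair dissimilarity is 1 - a/(a+b+c) over bands non-missing in both
individuals, where a counts shared presences and b, c one-sided presences;
joint absences carry no signal. Missing cells are handled by pairwise
deletion.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .errors import ContractError, SizeError, UndefinedPairError
from .genotype_io import MISSING, PRESENT, BinaryGenotypeMatrix, Partition


@dataclass
class DistanceMatrix:
    """Symmetric dissimilarities with zero diagonal.

    ``compared`` (optional) holds the per-pair count of jointly non-missing
    bands used for each value.
    """

    labels: list[str]
    values: np.ndarray
    compared: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ContractError(f"values shape {self.values.shape} != ({n}, {n})")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise ContractError("diagonal must be zero")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ContractError("matrix must be symmetric")

    def loc(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.values[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


@dataclass
class GroupDissimilaritySummary:
    """Within/between group means; ``within`` is None for singleton groups."""

    groups: list[str]
    within: dict[str, float | None]
    between: dict[tuple[str, str], float]
    min_pair: tuple[str, str, float]
    max_pair: tuple[str, str, float]

    def to_frame(self) -> pd.DataFrame:
        """Lower-triangle layout: within means on the diagonal."""
        g = self.groups
        out = pd.DataFrame(np.nan, index=g, columns=g)
        for name in g:
            if self.within[name] is not None:
                out.loc[name, name] = self.within[name]
        for (a, b), v in self.between.items():
            lo, hi = (a, b) if g.index(a) < g.index(b) else (b, a)
            out.loc[hi, lo] = v
        return out


def jaccard_pair(x: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    """(dissimilarity, compared-band count) for two coded band vectors."""
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise ContractError("band vectors must share the same band list")
    ok = (x != MISSING) & (y != MISSING)
    a = int(np.count_nonzero((x == PRESENT) & (y == PRESENT) & ok))
    b = int(np.count_nonzero((x == PRESENT) & (y != PRESENT) & ok))
    c = int(np.count_nonzero((x != PRESENT) & (y == PRESENT) & ok))
    if a + b + c == 0:
        raise UndefinedPairError("no shared or differing presences (a+b+c = 0)")
    return 1.0 - a / (a + b + c), int(np.count_nonzero(ok))


def pairwise_jaccard_arrays(values: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized all-pairs Jaccard complement on a coded value array.

    Returns (d, union, compared) where ``union`` is a+b+c per pair; entries
    with union == 0 get d = NaN (the caller decides whether that is an
    error). The diagonal of d is forced to zero.
    """
    p = (values == PRESENT).astype(np.float64)
    v = (values != MISSING).astype(np.float64)
    a = p @ p.T
    union = p @ v.T + v @ p.T - a
    compared = v @ v.T
    with np.errstate(invalid="ignore", divide="ignore"):
        d = 1.0 - np.where(union > 0, a / np.maximum(union, 1), np.nan)
    np.fill_diagonal(d, 0.0)
    return d, union, compared


def pairwise_matrix(matrix: BinaryGenotypeMatrix) -> DistanceMatrix:
    """Full Jaccard-complement distance matrix over all individuals."""
    if matrix.n_individuals < 2:
        raise SizeError("need at least two individuals")
    d, union, compared = pairwise_jaccard_arrays(matrix.values)
    off = ~np.eye(len(d), dtype=bool)
    if np.isnan(d[off]).any():
        i, j = np.argwhere(np.isnan(d) & off)[0]
        raise UndefinedPairError(
            f"pair ({matrix.individuals[i]}, {matrix.individuals[j]}) has no "
            "shared or differing presences"
        )
    return DistanceMatrix(
        labels=list(matrix.individuals), values=d, compared=compared.astype(int)
    )


def group_summary(dist: DistanceMatrix, partition: Partition) -> GroupDissimilaritySummary:
    """Within- and between-group mean dissimilarities plus extreme pairs."""
    idx = {lab: i for i, lab in enumerate(dist.labels)}
    unknown = set(partition.assignments) - set(idx)
    if unknown:
        raise ContractError(f"partition names unknown individuals: {sorted(unknown)}")
    members = {g: [idx[m] for m in partition.members(g)] for g in partition.groups}
    within: dict[str, float | None] = {}
    for g, rows in members.items():
        if len(rows) < 2:
            within[g] = None
        else:
            vals = [dist.values[i, j] for i, j in combinations(sorted(rows), 2)]
            within[g] = float(np.mean(vals))
    between: dict[tuple[str, str], float] = {}
    for g, h in combinations(partition.groups, 2):
        block = dist.values[np.ix_(members[g], members[h])]
        between[(g, h)] = float(block.mean())
    min_pair, max_pair = extreme_pairs(dist)
    return GroupDissimilaritySummary(
        groups=list(partition.groups),
        within=within,
        between=between,
        min_pair=min_pair,
        max_pair=max_pair,
    )


def accession_vs_group(
    dist: DistanceMatrix, partition: Partition, accession: str, group: str
) -> float:
    """Mean dissimilarity of one accession to the members of a group
    (excluding itself when it belongs to the group)."""
    if accession not in dist.labels:
        raise KeyError(f"unknown accession {accession!r}")
    i = dist.labels.index(accession)
    others = [
        dist.labels.index(m) for m in partition.members(group) if m != accession
    ]
    if not others:
        raise SizeError(f"no comparison individuals in group {group!r}")
    return float(np.mean([dist.values[i, j] for j in others]))


def extreme_pairs(
    dist: DistanceMatrix, within: list[str] | None = None
) -> tuple[tuple[str, str, float], tuple[str, str, float]]:
    """(min pair, max pair) over off-diagonal entries, ties broken by
    lexicographic label order; ``within`` optionally restricts to a label set."""
    labels = dist.labels if within is None else [l for l in dist.labels if l in set(within)]
    if len(labels) < 2:
        raise SizeError("need at least two eligible individuals")
    idx = [dist.labels.index(l) for l in labels]
    pairs = sorted(
        (tuple(sorted((labels[a], labels[b]))) for a, b in combinations(range(len(idx)), 2))
    )
    scored = [
        (a, b, float(dist.values[dist.labels.index(a), dist.labels.index(b)]))
        for a, b in pairs
    ]
    # scored is already in lexicographic pair order, so the first hit wins ties
    min_val = min(t[2] for t in scored)
    max_val = max(t[2] for t in scored)
    min_pair = next(t for t in scored if t[2] == min_val)
    max_pair = next(t for t in scored if t[2] == max_val)
    return min_pair, max_pair
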