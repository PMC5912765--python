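"""One-level analysis of molecular variance on binary band profiles.

Distances are squared Euclidean on 0/1 profiles, i.e. mismatch counts (the
standard choice for dominant/RFLP data); with missing cells the mismatch
count over compared bands is rescaled to the full band count. Variance
components follow the sums-of-squares decomposition over pairwise squared
distances, and significance comes from permuting individuals between groups
with group sizes fixed.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np

from .errors import ContractError, GroupNameError, SizeError, UndefinedPairError
from .genotype_io import MISSING, PRESENT, BinaryGenotypeMatrix, Partition

DEFAULT_PERMUTATIONS = 1023


@dataclass
class AmovaTable:
    groups: list[str]
    df_among: int
    df_within: int
    ss_among: float
    ss_within: float
    ss_total: float
    sigma2_among: float
    sigma2_within: float
    pct_among: float
    pct_within: float
    phi_st: float
    p_value: float
    n_permutations: int
    seed: int | None


def squared_distance(x: np.ndarray, y: np.ndarray, rescale_missing: bool = True) -> float:
    """Mismatch count between two coded band vectors.

    With missing cells, the raw mismatch count m over c compared bands is
    rescaled to L * m / c (L = total band count) unless ``rescale_missing``
    is off, in which case the raw count is returned.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise ContractError("band vectors must share the same band list")
    ok = (x != MISSING) & (y != MISSING)
    c = int(np.count_nonzero(ok))
    if c == 0:
        raise UndefinedPairError("no jointly called bands")
    m = int(np.count_nonzero((x[ok] == PRESENT) != (y[ok] == PRESENT)))
    if rescale_missing and c < x.size:
        return x.size * m / c
    return float(m)


def _pairwise_sq(values: np.ndarray, rescale_missing: bool) -> np.ndarray:
    """All-pairs squared distances, vectorized."""
    p = (values == PRESENT).astype(np.float64)
    v = (values != MISSING).astype(np.float64)
    # mismatches over jointly called bands: one-sided presences
    a = p @ p.T
    m = p @ v.T + v @ p.T - 2.0 * a
    c = v @ v.T
    if np.any((c == 0) & ~np.eye(len(c), dtype=bool)):
        raise UndefinedPairError("a pair has no jointly called bands")
    if rescale_missing:
        with np.errstate(divide="ignore", invalid="ignore"):
            m = values.shape[1] * m / np.maximum(c, 1)
    np.fill_diagonal(m, 0.0)
    return m


def _components(d2: np.ndarray, group_of: np.ndarray, sizes: np.ndarray):
    """(ss_among, ss_within, ss_total, sigma2_among, sigma2_within, phi)."""
    n = len(group_of)
    g = len(sizes)
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for k in range(g):
        idx = np.flatnonzero(group_of == k)
        ss_within += d2[np.ix_(idx, idx)].sum() / 2.0 / sizes[k]
    ss_among = ss_total - ss_within
    ms_among = ss_among / (g - 1)
    sigma2_within = ss_within / (n - g)
    n0 = (n - float(np.sum(sizes**2)) / n) / (g - 1)
    sigma2_among = (ms_among - sigma2_within) / n0
    total = sigma2_among + sigma2_within
    if total == 0:
        raise ContractError("total molecular variance is zero; Phi undefined")
    return ss_among, ss_within, ss_total, sigma2_among, sigma2_within, sigma2_among / total


def amova(
    matrix: BinaryGenotypeMatrix,
    partition: Partition,
    groups: list[str] | None = None,
    n_permutations: int = DEFAULT_PERMUTATIONS,
    seed: int | None = None,
    rescale_missing: bool = True,
) -> AmovaTable:
    """AMOVA over the named groups (all partition groups by default).

    Negative among-group components are reported as-is, so Phi may be
    slightly negative under the null. The permutation p-value carries the
    +1 correction: p = (1 + #{Phi_perm >= Phi_obs}) / (P + 1).
    """
    if groups is None:
        groups = list(partition.groups)
    unknown = set(groups) - set(partition.groups)
    if unknown:
        raise GroupNameError(f"unknown group(s): {sorted(unknown)}")
    if len(set(groups)) != len(groups):
        raise GroupNameError("duplicate group in contrast")
    if len(groups) < 2:
        raise SizeError("AMOVA needs at least two groups")
    if n_permutations < 99:
        raise SizeError("use at least 99 permutations")

    labels: list[str] = []
    group_of_list: list[int] = []
    for k, g in enumerate(groups):
        members = partition.members(g)
        if len(members) < 2:
            raise SizeError(f"group {g!r} has fewer than two individuals")
        labels.extend(members)
        group_of_list.extend([k] * len(members))
    rows = matrix.individual_index(labels)
    group_of = np.array(group_of_list)
    sizes = np.bincount(group_of)

    d2 = _pairwise_sq(matrix.values[rows], rescale_missing)
    ss_a, ss_w, ss_t, s2_a, s2_w, phi = _components(d2, group_of, sizes)

    rng = np.random.default_rng(seed)
    hits = 0
    perm = group_of.copy()
    for _ in range(n_permutations):
        rng.shuffle(perm)
        try:
            *_, phi_p = _components(d2, perm, sizes)
        except ContractError:
            phi_p = np.inf
        if phi_p >= phi - 1e-12:
            hits += 1
    p_value = (1 + hits) / (n_permutations + 1)

    total = s2_a + s2_w
    n = len(labels)
    return AmovaTable(
        groups=list(groups),
        df_among=len(groups) - 1,
        df_within=n - len(groups),
        ss_among=ss_a,
        ss_within=ss_w,
        ss_total=ss_t,
        sigma2_among=s2_a,
        sigma2_within=s2_w,
        pct_among=100.0 * s2_a / total,
        pct_within=100.0 * s2_w / total,
        phi_st=phi,
        p_value=p_value,
        n_permutations=n_permutations,
        seed=seed,
    )


def pairwise_group_amovas(
    matrix: BinaryGenotypeMatrix,
    partition: Partition,
    pairs: list[tuple[str, str]],
    n_permutations: int = DEFAULT_PERMUTATIONS,
    seed: int | None = None,
    rescale_missing: bool = True,
) -> list[AmovaTable]:
    """One two-group AMOVA per named contrast, other individuals excluded."""
    tables = []
    for i, (g1, g2) in enumerate(pairs):
        if g1 == g2:
            raise GroupNameError(f"contrast of group {g1!r} with itself")
        sub_seed = None if seed is None else seed + i
        tables.append(
            amova(
                matrix,
                partition,
                groups=[g1, g2],
                n_permutations=n_permutations,
                seed=sub_seed,
                rescale_missing=rescale_missing,
            )
        )
    return tables
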