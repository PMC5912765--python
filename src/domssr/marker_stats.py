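"""Per-primer informativeness indices and per-group gene diversity.

Band ("allele") frequencies for a primer are occurrence counts over the
total number of present calls at that primer, so they sum to one per primer.
PIC follows the Botstein form; the multiplex ratio counts bands per
individual at the primer; the effective multiplex ratio discounts by the
polymorphic fraction; the marker index is their product with PIC; resolving
power sums per-band informativeness 1 - 2|0.5 - M|.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ContractError, InsufficientDataError
from .genotype_io import MISSING, PRESENT, BinaryGenotypeMatrix, Partition


@dataclass
class PrimerStatsRow:
    primer: str
    n_bands: int
    pic: float
    multiplex_ratio: float  # n: mean present bands per complete individual
    beta: float  # fraction of polymorphic bands (0 < M < 1)
    effective_multiplex: float  # E = n * beta
    marker_index: float  # MI = PIC * E
    resolving_power: float  # Rp = sum of per-band Ib
    distinct_profiles: int
    profile_pct: float


@dataclass
class DiversityRow:
    group: str
    per_primer: dict[str, float]
    mean_diversity: float


def _subset_rows(matrix: BinaryGenotypeMatrix, subset) -> np.ndarray:
    if subset is None:
        return np.arange(matrix.n_individuals)
    idx = matrix.individual_index(subset)
    if idx.size == 0:
        raise InsufficientDataError("empty individual subset")
    return idx


def band_frequencies(
    matrix: BinaryGenotypeMatrix, primer: str, subset=None
) -> np.ndarray:
    """Occurrence frequency of each band at ``primer`` within ``subset``.

    p_b = (present calls for band b) / (all present calls at the primer);
    the result sums to one.
    """
    rows = _subset_rows(matrix, subset)
    cols = matrix.primer_columns(primer)
    block = matrix.values[np.ix_(rows, cols)]
    counts = (block == PRESENT).sum(axis=0).astype(float)
    total = counts.sum()
    if total == 0:
        raise InsufficientDataError(
            f"no present calls for primer {primer!r} in the given subset"
        )
    return counts / total


def pic(frequencies) -> float:
    """Polymorphism information content from band frequencies.

    PIC = 1 - sum_i p_i^2 - sum_{i<j} 2 p_i^2 p_j^2.
    """
    p = np.asarray(frequencies, dtype=float)
    if abs(p.sum() - 1.0) > 1e-9:
        raise ContractError(f"frequencies sum to {p.sum()!r}, expected 1")
    s2 = float(np.sum(p**2))
    s4 = float(np.sum(p**4))
    # sum_{i<j} 2 p_i^2 p_j^2 = (sum p^2)^2 - sum p^4
    return 1.0 - s2 - (s2**2 - s4)


def multiplex_and_effective(
    matrix: BinaryGenotypeMatrix, primer: str, subset=None
) -> tuple[float, float, float]:
    """(n, beta, E) for one primer.

    n averages present-band counts over individuals with complete data at
    the primer; beta counts bands with carrier proportion strictly between
    0 and 1; E = n * beta.
    """
    rows = _subset_rows(matrix, subset)
    cols = matrix.primer_columns(primer)
    block = matrix.values[np.ix_(rows, cols)]
    complete = ~(block == MISSING).any(axis=1)
    if not complete.any():
        raise InsufficientDataError(
            f"no individual with complete data at primer {primer!r}"
        )
    n = float((block[complete] == PRESENT).sum(axis=1).mean())
    m = _carrier_proportions(block)
    beta = float(np.count_nonzero((m > 0.0) & (m < 1.0))) / len(cols)
    return n, beta, n * beta


def _carrier_proportions(block: np.ndarray) -> np.ndarray:
    """Per-band proportion of carriers among non-missing calls."""
    present = (block == PRESENT).sum(axis=0).astype(float)
    called = (block != MISSING).sum(axis=0).astype(float)
    with np.errstate(invalid="ignore"):
        return np.where(called > 0, present / np.maximum(called, 1), np.nan)


def marker_index(pic_value: float, effective_multiplex: float) -> float:
    """MI = PIC * E (unrounded)."""
    if not (np.isfinite(pic_value) and np.isfinite(effective_multiplex)):
        raise ContractError("marker_index inputs must be finite")
    return float(pic_value) * float(effective_multiplex)


def resolving_power(
    matrix: BinaryGenotypeMatrix, primer: str, subset=None
) -> tuple[float, np.ndarray]:
    """(Rp, per-band Ib) with Ib = 1 - 2|0.5 - M|."""
    rows = _subset_rows(matrix, subset)
    cols = matrix.primer_columns(primer)
    block = matrix.values[np.ix_(rows, cols)]
    m = _carrier_proportions(block)
    ib = 1.0 - 2.0 * np.abs(0.5 - m)
    return float(np.nansum(ib)), ib


def profile_discrimination(
    matrix: BinaryGenotypeMatrix, primer: str, subset=None
) -> tuple[int, float]:
    """Distinct complete banding patterns at a primer, and their percentage.

    The percentage denominator is the full individual count of the matrix
    (or subset) even when some individuals are dropped for missing data.
    """
    rows = _subset_rows(matrix, subset)
    cols = matrix.primer_columns(primer)
    block = matrix.values[np.ix_(rows, cols)]
    complete = ~(block == MISSING).any(axis=1)
    if not complete.any():
        raise InsufficientDataError(
            f"no individual with complete data at primer {primer!r}"
        )
    distinct = int(np.unique(block[complete], axis=0).shape[0])
    return distinct, 100.0 * distinct / len(rows)


def gene_diversity(
    matrix: BinaryGenotypeMatrix, partition: Partition, group: str
) -> DiversityRow:
    """Within-group gene diversity D_i = 1 - sum_j p_ij^2, averaged over primers."""
    members = partition.members(group)
    per_primer: dict[str, float] = {}
    for primer in matrix.primers:
        try:
            p = band_frequencies(matrix, primer, subset=members)
        except InsufficientDataError:
            continue
        per_primer[primer] = 1.0 - float(np.sum(p**2))
    if not per_primer:
        raise InsufficientDataError(f"group {group!r} has no present calls")
    return DiversityRow(
        group=group,
        per_primer=per_primer,
        mean_diversity=float(np.mean(list(per_primer.values()))),
    )


def primer_stats(
    matrix: BinaryGenotypeMatrix, primer: str, subset=None
) -> PrimerStatsRow:
    freqs = band_frequencies(matrix, primer, subset)
    p = pic(freqs)
    n, beta, e = multiplex_and_effective(matrix, primer, subset)
    rp, _ = resolving_power(matrix, primer, subset)
    distinct, pct = profile_discrimination(matrix, primer, subset)
    return PrimerStatsRow(
        primer=primer,
        n_bands=len(matrix.primer_columns(primer)),
        pic=p,
        multiplex_ratio=n,
        beta=beta,
        effective_multiplex=e,
        marker_index=marker_index(p, e),
        resolving_power=rp,
        distinct_profiles=distinct,
        profile_pct=pct,
    )


def stats_table(
    matrix: BinaryGenotypeMatrix,
    partition: Partition | None = None,
    subsets: dict[str, list[str] | None] | None = None,
) -> pd.DataFrame:
    """Primer-by-subset index table with a Total/Mean footer per subset.

    ``subsets`` maps a subset name to a list of individuals (``None`` =
    everyone); the default is the single subset ``all``. The footer carries
    the band-count total and the means of N, PIC, E, MI and Rp.
    """
    if subsets is None:
        subsets = {"all": None}
    records = []
    for name, members in subsets.items():
        rows = [primer_stats(matrix, primer, members) for primer in matrix.primers]
        for r in rows:
            records.append(
                {
                    "subset": name,
                    "primer": r.primer,
                    "N": r.n_bands,
                    "PIC": r.pic,
                    "n": r.multiplex_ratio,
                    "beta": r.beta,
                    "E": r.effective_multiplex,
                    "MI": r.marker_index,
                    "Rp": r.resolving_power,
                    "distinct_profiles": r.distinct_profiles,
                    "profile_pct": r.profile_pct,
                }
            )
        records.append(
            {
                "subset": name,
                "primer": "Total",
                "N": sum(r.n_bands for r in rows),
            }
        )
        records.append(
            {
                "subset": name,
                "primer": "Mean",
                "N": float(np.mean([r.n_bands for r in rows])),
                "PIC": float(np.mean([r.pic for r in rows])),
                "E": float(np.mean([r.effective_multiplex for r in rows])),
                "MI": float(np.mean([r.marker_index for r in rows])),
                "Rp": float(np.mean([r.resolving_power for r in rows])),
            }
        )
    return pd.DataFrame.from_records(records)
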