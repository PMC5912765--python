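"""Reading and writing genotype tables, partitions and distance matrices.

The on-disk conventions are plain text: genotype tables are CSV/TSV with
individuals as rows and band labels (``PRIMER.SIZE``) as column headers;
group metadata is a two-column CSV; distance matrices are written either as
labelled square CSV or PHYLIP square format.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import BandFormatError, ContractError, CoverageError, LoadError

logger = logging.getLogger(__name__)

#: cell codes used in :class:`BinaryGenotypeMatrix.values`
PRESENT = 1
ABSENT = 0
MISSING = -1

#: tokens accepted for missing cells on input (first one used on output)
DEFAULT_MISSING_TOKEN = "NA"
MISSING_ALIASES = ("NA", "?")


@dataclass(frozen=True, order=True)
class BandID:
    """One amplified fragment size at one primer, e.g. ``SCB436.0186``."""

    primer: str
    size: int

    def __post_init__(self) -> None:
        if not self.primer or "." in self.primer:
            raise BandFormatError(f"invalid primer label {self.primer!r}")
        if self.size <= 0:
            raise BandFormatError(f"band size must be positive, got {self.size}")

    def __str__(self) -> str:
        return f"{self.primer}.{self.size:04d}"


def parse_band_id(text: str) -> BandID:
    """Parse a serialized ``PRIMER.SIZE`` band label.

    The size suffix may be zero-padded to any width; serialization always
    pads to four digits, so ``serialize(parse(x)) == x`` for canonical input.
    """
    if text.count(".") != 1:
        raise BandFormatError(
            f"band label {text!r} must contain exactly one '.' separator"
        )
    primer, suffix = text.split(".")
    if not primer:
        raise BandFormatError(f"band label {text!r} has an empty primer part")
    if not suffix.isdigit():
        raise BandFormatError(f"band label {text!r} has a non-numeric size {suffix!r}")
    return BandID(primer, int(suffix))


def serialize_band_id(band: BandID) -> str:
    return str(band)


@dataclass
class BinaryGenotypeMatrix:
    """Individuals x bands grid of dominant presence/absence calls.

    ``values`` holds ``PRESENT``/``ABSENT``/``MISSING`` codes (int8). Band
    columns that are never present are rejected: every retained band must
    have been observed at least once.
    """

    individuals: list[str]
    bands: list[BandID]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        n, m = len(self.individuals), len(self.bands)
        if self.values.shape != (n, m):
            raise ContractError(
                f"values shape {self.values.shape} != ({n}, {m})"
            )
        if len(set(self.individuals)) != n:
            raise LoadError("duplicate individual labels")
        if len(set(self.bands)) != m:
            raise LoadError("duplicate band labels")
        bad = set(np.unique(self.values)) - {PRESENT, ABSENT, MISSING}
        if bad:
            raise LoadError(f"non-ternary cell codes: {sorted(bad)}")
        never_present = np.flatnonzero((self.values == PRESENT).sum(axis=0) == 0)
        if never_present.size:
            names = ", ".join(str(self.bands[j]) for j in never_present[:5])
            raise LoadError(f"band(s) with no present call: {names}")

    # -- convenience accessors -------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_bands(self) -> int:
        return len(self.bands)

    @property
    def primers(self) -> list[str]:
        seen: dict[str, None] = {}
        for b in self.bands:
            seen.setdefault(b.primer, None)
        return list(seen)

    def band_labels(self) -> list[str]:
        return [str(b) for b in self.bands]

    def primer_columns(self, primer: str) -> np.ndarray:
        cols = np.array([j for j, b in enumerate(self.bands) if b.primer == primer])
        if cols.size == 0:
            raise KeyError(f"unknown primer {primer!r}")
        return cols

    def individual_index(self, labels) -> np.ndarray:
        pos = {ind: i for i, ind in enumerate(self.individuals)}
        try:
            return np.array([pos[x] for x in labels], dtype=int)
        except KeyError as exc:
            raise KeyError(f"unknown individual {exc.args[0]!r}") from exc

    def to_frame(self, missing_token: str = DEFAULT_MISSING_TOKEN) -> pd.DataFrame:
        df = pd.DataFrame(
            self.values, index=self.individuals, columns=self.band_labels()
        ).astype(object)
        return df.mask(df == MISSING, missing_token)


@dataclass
class Partition:
    """Assignment of every individual to exactly one named group."""

    assignments: dict[str, str]
    groups: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.groups:
            seen: dict[str, None] = {}
            for g in self.assignments.values():
                seen.setdefault(g, None)
            self.groups = list(seen)
        if not self.groups:
            raise CoverageError("partition has no groups")
        missing = set(self.assignments.values()) - set(self.groups)
        if missing:
            raise CoverageError(f"groups missing from group order: {sorted(missing)}")

    def members(self, group: str) -> list[str]:
        if group not in self.groups:
            raise KeyError(f"unknown group {group!r}")
        return [ind for ind, g in self.assignments.items() if g == group]

    def sizes(self) -> dict[str, int]:
        return {g: len(self.members(g)) for g in self.groups}

    def check_covers(self, matrix: BinaryGenotypeMatrix) -> None:
        have = set(self.assignments)
        want = set(matrix.individuals)
        extra, absent = sorted(have - want), sorted(want - have)
        if extra or absent:
            raise CoverageError(
                f"partition mismatch: unknown individuals {extra}, "
                f"uncovered individuals {absent}"
            )


# ---------------------------------------------------------------------------
# genotype tables


def _delimiter(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","


def read_genotype_table(
    path, missing_token: str = DEFAULT_MISSING_TOKEN
) -> BinaryGenotypeMatrix:
    """Load a delimited genotype table (individuals x band columns).

    Cells must be ``0``, ``1`` or a missing token (``missing_token`` or any
    of its aliases). Duplicate labels, non-ternary cells and all-absent band
    columns are load errors reported with their coordinates.
    """
    path = Path(path)
    df = pd.read_csv(
        path, sep=_delimiter(path), index_col=0, dtype=str, keep_default_na=False
    )
    individuals = [str(x) for x in df.index]
    if len(set(individuals)) != len(individuals):
        dupes = sorted({x for x in individuals if individuals.count(x) > 1})
        raise LoadError(f"duplicate individual labels: {dupes}")
    try:
        bands = [parse_band_id(c) for c in df.columns]
    except BandFormatError as exc:
        raise LoadError(f"bad band header in {path}: {exc}") from exc

    tokens = {missing_token, *MISSING_ALIASES}
    values = np.empty(df.shape, dtype=np.int8)
    raw = df.to_numpy(dtype=str)
    for i in range(raw.shape[0]):
        for j in range(raw.shape[1]):
            cell = raw[i, j].strip()
            if cell == "1":
                values[i, j] = PRESENT
            elif cell == "0":
                values[i, j] = ABSENT
            elif cell in tokens:
                values[i, j] = MISSING
            else:
                raise LoadError(
                    f"non-ternary cell {cell!r} at row {individuals[i]!r}, "
                    f"column {df.columns[j]!r}"
                )
    all_absent = np.flatnonzero((values == PRESENT).sum(axis=0) == 0)
    if all_absent.size:
        names = ", ".join(df.columns[j] for j in all_absent)
        raise LoadError(f"all-absent band column(s): {names}")

    matrix = BinaryGenotypeMatrix(individuals, bands, values)
    logger.info(
        "loaded %s: %d individuals, %d bands, %d primers, %d missing cells",
        path,
        matrix.n_individuals,
        matrix.n_bands,
        len(matrix.primers),
        int((values == MISSING).sum()),
    )
    return matrix


def write_genotype_table(
    matrix: BinaryGenotypeMatrix, path, missing_token: str = DEFAULT_MISSING_TOKEN
) -> None:
    path = Path(path)
    matrix.to_frame(missing_token).to_csv(path, sep=_delimiter(path))


# ---------------------------------------------------------------------------
# partitions


def read_partition(path, matrix: BinaryGenotypeMatrix) -> Partition:
    """Load a two-column (individual, group) table and check total coverage.

    A header row is tolerated: if the first row's first field is not a matrix
    individual it is treated as a header. Group order is first-appearance.
    """
    path = Path(path)
    df = pd.read_csv(
        path, sep=_delimiter(path), header=None, dtype=str, keep_default_na=False
    )
    if df.shape[1] < 2:
        raise LoadError(f"{path}: expected two columns (individual, group)")
    rows = list(zip(df.iloc[:, 0], df.iloc[:, 1]))
    known = set(matrix.individuals)
    if rows and rows[0][0] not in known:
        rows = rows[1:]
    assignments: dict[str, str] = {}
    for ind, group in rows:
        if ind in assignments:
            raise LoadError(f"{path}: duplicate assignment for {ind!r}")
        assignments[str(ind)] = str(group)
    part = Partition(assignments)
    part.check_covers(matrix)
    return part


def write_partition(partition: Partition, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("individual,group\n")
        for ind, group in partition.assignments.items():
            fh.write(f"{ind},{group}\n")


# ---------------------------------------------------------------------------
# distance matrices


def _check_square(labels, values) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    n = len(labels)
    if values.shape != (n, n):
        raise ContractError(f"distance matrix shape {values.shape} != ({n}, {n})")
    if not np.allclose(np.diag(values), 0.0, atol=1e-12):
        raise ContractError("distance matrix diagonal is not zero")
    if not np.allclose(values, values.T, atol=1e-12):
        i, j = np.unravel_index(np.argmax(np.abs(values - values.T)), values.shape)
        raise ContractError(
            f"distance matrix asymmetric at ({labels[i]}, {labels[j]})"
        )
    return values


def write_distance_matrix(dist, path, format: str = "square-csv") -> None:
    """Write a symmetric distance matrix as square CSV or PHYLIP square.

    ``dist`` is anything exposing ``labels`` and ``values`` (see
    :class:`domssr.dissimilarity.DistanceMatrix`).
    """
    labels = list(dist.labels)
    values = _check_square(labels, dist.values)
    path = Path(path)
    if format == "square-csv":
        pd.DataFrame(values, index=labels, columns=labels).to_csv(path)
    elif format == "phylip":
        with open(path, "w") as fh:
            fh.write(f"{len(labels)}\n")
            for label, row in zip(labels, values):
                fields = " ".join(f"{v:.6f}" for v in row)
                fh.write(f"{label}  {fields}\n")
    else:
        raise ValueError(f"unknown distance-matrix format {format!r}")


def read_distance_matrix(path):
    """Read a square CSV distance matrix back (labels in header and index)."""
    from .dissimilarity import DistanceMatrix  # local import avoids a cycle

    df = pd.read_csv(Path(path), index_col=0)
    labels = [str(x) for x in df.index]
    values = _check_square(labels, df.to_numpy(dtype=float))
    return DistanceMatrix(labels=labels, values=values)
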