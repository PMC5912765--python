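"""Synthetic dominant-marker panels with known group structure.

Panels are generated band-by-band: every band gets a baseline presence
frequency drawn from a Beta distribution, group-specific frequencies are
pulled towards group-private Bernoulli draws by ``divergence``, a fraction
of bands is made private to a single group, and optional admixed hybrid
individuals draw each band from a mixture of the group frequencies. The
"truth record" returned alongside the matrix stores every latent frequency
so downstream estimators can be tested against ground truth.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError
from .genotype_io import (
    MISSING,
    PRESENT,
    BandID,
    BinaryGenotypeMatrix,
    Partition,
)

HYBRID_GROUP = "hybrid"

# latent frequencies strictly inside (0,1) are clamped away from the edges
# so random panels do not go accidentally monomorphic; exact 0/1 (fixed or
# private bands) are left untouched
_FREQ_FLOOR = 0.02
_FREQ_CEIL = 0.98


@dataclass
class SimConfig:
    """Parameters for :func:`simulate_panel`."""

    n_groups: int = 4
    group_sizes: tuple[int, ...] = (81, 19, 26, 11)
    n_primers: int = 12
    bands_per_primer: tuple[int, int] = (10, 43)
    baseline_beta: tuple[float, float] = (1.2, 1.8)
    divergence: float = 0.3
    private_band_fraction: float = 0.1
    n_hybrids: int = 0
    hybrid_mixture: tuple[float, ...] | None = None
    missing_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_groups < 1:
            raise ConfigError("n_groups must be >= 1")
        if len(self.group_sizes) != self.n_groups:
            raise ConfigError("group_sizes length must equal n_groups")
        if any(s < 1 for s in self.group_sizes):
            raise ConfigError("group sizes must be positive")
        if self.n_primers < 1:
            raise ConfigError("n_primers must be >= 1")
        lo, hi = self.bands_per_primer
        if lo < 2 or hi < lo:
            raise ConfigError("bands_per_primer must satisfy 2 <= min <= max")
        if not (0.0 <= self.divergence <= 1.0):
            raise ConfigError("divergence must be in [0, 1]")
        if not (0.0 <= self.private_band_fraction <= 1.0):
            raise ConfigError("private_band_fraction must be in [0, 1]")
        if self.n_hybrids < 0:
            raise ConfigError("n_hybrids must be >= 0")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ConfigError("missing_rate must be in [0, 1)")
        if self.hybrid_mixture is not None:
            w = np.asarray(self.hybrid_mixture, dtype=float)
            if w.shape != (self.n_groups,) or (w < 0).any() or w.sum() <= 0:
                raise ConfigError("hybrid_mixture must be non-negative per-group weights")
        if any(a <= 0 for a in self.baseline_beta):
            raise ConfigError("baseline_beta shapes must be positive")


@dataclass
class PanelTruth:
    """Latent generating quantities for a simulated panel."""

    frequencies: pd.DataFrame  # groups x bands
    private_bands: dict[str, list[str]]
    hybrids: dict[str, list[float]]
    config: dict = field(default_factory=dict)


def _band_ids(rng: np.random.Generator, cfg: SimConfig) -> list[BandID]:
    lo, hi = cfg.bands_per_primer
    counts = rng.integers(lo, hi + 1, size=cfg.n_primers)
    bands = []
    for p, count in enumerate(counts, start=1):
        primer = f"P{p:02d}"
        for k in range(count):
            bands.append(BandID(primer, 100 + 2 * k))
    return bands


def simulate_panel(cfg: SimConfig) -> tuple[BinaryGenotypeMatrix, Partition, PanelTruth]:
    """Draw one reproducible panel from ``cfg``.

    Hybrids, when requested, are appended under the group label ``hybrid``.
    Bands that come out entirely non-present get one call forced to present
    in the highest-frequency group so the matrix invariant (every retained
    band observed at least once) holds.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    bands = _band_ids(rng, cfg)
    L = len(bands)
    G = cfg.n_groups
    group_names = [f"G{g + 1}" for g in range(G)]

    q = rng.beta(*cfg.baseline_beta, size=L)
    z = (rng.random((G, L)) < q).astype(float)
    f = (1.0 - cfg.divergence) * q[None, :] + cfg.divergence * z

    n_private = int(round(cfg.private_band_fraction * L))
    private_idx = rng.choice(L, size=n_private, replace=False) if n_private else np.array([], dtype=int)
    owners = rng.integers(0, G, size=n_private)
    for j, owner in zip(private_idx, owners):
        f[:, j] = 0.0
        f[owner, j] = rng.uniform(0.5, 0.95)

    interior = (f > 0.0) & (f < 1.0)
    f = np.where(interior, np.clip(f, _FREQ_FLOOR, _FREQ_CEIL), f)
    for j, owner in zip(private_idx, owners):  # private zeros stay exact
        f[np.arange(G) != owner, j] = 0.0

    individuals: list[str] = []
    assignments: dict[str, str] = {}
    rows: list[np.ndarray] = []
    for g, (name, size) in enumerate(zip(group_names, cfg.group_sizes)):
        draws = (rng.random((size, L)) < f[g]).astype(np.int8)
        for i in range(size):
            label = f"{name}_{i + 1:03d}"
            individuals.append(label)
            assignments[label] = name
        rows.append(draws)

    hybrids: dict[str, list[float]] = {}
    if cfg.n_hybrids:
        w = (
            np.asarray(cfg.hybrid_mixture, dtype=float)
            if cfg.hybrid_mixture is not None
            else np.ones(G)
        )
        w = w / w.sum()
        p_h = w @ f
        draws = (rng.random((cfg.n_hybrids, L)) < p_h).astype(np.int8)
        for i in range(cfg.n_hybrids):
            label = f"H_{i + 1:03d}"
            individuals.append(label)
            assignments[label] = HYBRID_GROUP
            hybrids[label] = [float(x) for x in w]
        rows.append(draws)

    values = np.vstack(rows)
    if cfg.missing_rate > 0:
        mask = rng.random(values.shape) < cfg.missing_rate
        values = np.where(mask, MISSING, values).astype(np.int8)

    empty = np.flatnonzero((values == PRESENT).sum(axis=0) == 0)
    group_starts = np.cumsum([0, *cfg.group_sizes])
    for j in empty:
        owner = int(np.argmax(f[:, j]))
        values[group_starts[owner], j] = PRESENT

    matrix = BinaryGenotypeMatrix(individuals, bands, values)
    order = group_names + ([HYBRID_GROUP] if cfg.n_hybrids else [])
    partition = Partition(assignments, groups=order)
    truth = PanelTruth(
        frequencies=pd.DataFrame(f, index=group_names, columns=[str(b) for b in bands]),
        private_bands={
            name: sorted(
                str(bands[j]) for j, o in zip(private_idx, owners) if group_names[o] == name
            )
            for name in group_names
        },
        hybrids=hybrids,
        config=asdict(cfg),
    )
    return matrix, partition, truth


def toy6() -> tuple[BinaryGenotypeMatrix, Partition]:
    """Fixed six-individual, two-primer, five-band worked example."""
    bands = [
        BandID("P1", 100),
        BandID("P1", 110),
        BandID("P1", 120),
        BandID("P2", 200),
        BandID("P2", 210),
    ]
    values = np.array(
        [
            [1, 1, 0, 1, 0],  # A1
            [1, 1, 0, 1, 0],  # A2
            [1, 0, 0, 1, 0],  # A3
            [0, 0, 1, 0, 1],  # B1
            [0, 1, 1, 0, 1],  # B2
            [0, 0, 1, 0, 1],  # B3
        ],
        dtype=np.int8,
    )
    individuals = ["A1", "A2", "A3", "B1", "B2", "B3"]
    matrix = BinaryGenotypeMatrix(individuals, bands, values)
    partition = Partition(
        {"A1": "A", "A2": "A", "A3": "A", "B1": "B", "B2": "B", "B3": "B"},
        groups=["A", "B"],
    )
    return matrix, partition


__all__ = [
    "HYBRID_GROUP",
    "PanelTruth",
    "SimConfig",
    "simulate_panel",
    "toy6",
]
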