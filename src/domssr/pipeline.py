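"""Full-analysis orchestration: one config in, one report bundle out.

A single global seed is fanned out to per-stage seeds (stable hash of the
stage name) so any stage can be rerun independently yet deterministically.
All tabular outputs are CSV with a leading ``#`` comment naming the stage
and its parameters; a manifest JSON records everything needed for replay.
"""

from __future__ import annotations

import hashlib
import json
import shutil
from dataclasses import dataclass, field
from importlib.metadata import version as _pkg_version
from pathlib import Path

import numpy as np
import pandas as pd

from . import allele_accounting, amova, dissimilarity, marker_stats
from . import marker_sufficiency, trees_ordination
from .errors import ConfigError
from .genotype_io import read_genotype_table, read_partition, write_distance_matrix


@dataclass
class AnalysisConfig:
    genotypes: str
    groups: str
    outdir: str
    seed: int
    subsets: dict[str, list[str] | None] = field(default_factory=lambda: {"all": None})
    contrasts: list[tuple[str, str]] = field(default_factory=list)
    focal_group: str | None = None
    amova_permutations: int = 1023
    tree_bootstraps: int = 1000
    pcoa_axes: int = 2
    sufficiency_start: int = 3
    sufficiency_step: int = 3
    sufficiency_reps: int = 1000
    sufficiency_threshold: float = 10.0

    @classmethod
    def from_mapping(cls, data: dict) -> "AnalysisConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        for key in ("genotypes", "groups", "outdir", "seed"):
            if key not in data:
                raise ConfigError(f"missing required config key {key!r}")
        cfg = cls(**data)
        cfg.contrasts = [tuple(c) for c in cfg.contrasts]
        return cfg


def derived_seed(seed: int, stage: str) -> int:
    """Stable per-stage seed derived from the global seed."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big")


def _write_csv(df: pd.DataFrame, path: Path, stage: str, params: str, index=False) -> None:
    with open(path, "w") as fh:
        fh.write(f"# domssr {stage} {params}\n")
        df.to_csv(fh, index=index)


def run_full_analysis(config: AnalysisConfig) -> dict[str, str]:
    """Run every stage and write the bundle; returns artifact name -> path.

    Any stage failure aborts the run and removes partial outputs.
    """
    matrix = read_genotype_table(config.genotypes)
    partition = read_partition(config.groups, matrix)

    # validate all referenced groups before any compute
    referenced = set()
    for members in config.subsets.values():
        if members is not None:
            referenced.update(members)
    for g1, g2 in config.contrasts:
        referenced.update((g1, g2))
    if config.focal_group:
        referenced.add(config.focal_group)
    unknown = referenced - set(partition.groups)
    if unknown:
        raise ConfigError(f"config references unknown group(s): {sorted(unknown)}")

    outdir = Path(config.outdir)
    tmpdir = outdir.with_name(outdir.name + ".partial")
    if tmpdir.exists():
        shutil.rmtree(tmpdir)
    tmpdir.mkdir(parents=True)
    artifacts: dict[str, str] = {}
    try:
        # --- marker stats -------------------------------------------------
        subset_members = {
            name: (None if groups is None else sum((partition.members(g) for g in groups), []))
            for name, groups in config.subsets.items()
        }
        stats = marker_stats.stats_table(matrix, partition, subset_members)
        _write_csv(stats, tmpdir / "stats.csv", "stats", f"subsets={list(config.subsets)}")
        artifacts["stats"] = "stats.csv"

        # --- allele accounting -------------------------------------------
        ledger = allele_accounting.build_ledger(matrix, partition)
        rows = []
        for g in partition.groups:
            rows.append(
                {
                    "group": g,
                    "n_present": len(ledger.presence[g]),
                    "n_exclusive": len(ledger.exclusive[g]),
                    "exclusive_pct": ledger.exclusive_pct[g],
                    "shared_pct": ledger.shared_pct.get(g, np.nan),
                    "exclusive_bands": ";".join(sorted(ledger.exclusive[g])),
                }
            )
        _write_csv(
            pd.DataFrame(rows), tmpdir / "allele_ledger.csv", "accounting",
            f"total_bands={ledger.total_bands}",
        )
        artifacts["allele_ledger"] = "allele_ledger.csv"
        if config.focal_group:
            presence = ledger.presence
            rep = allele_accounting.absence_report(presence, config.focal_group)
            absent_df = pd.DataFrame(
                {
                    "band": rep.absent_bands,
                    "carriers": [";".join(rep.carriers[b]) for b in rep.absent_bands],
                    "exclusive_source": [
                        rep.exclusive_source.get(b, "") for b in rep.absent_bands
                    ],
                }
            )
            _write_csv(
                absent_df, tmpdir / "absence_report.csv", "accounting",
                f"focal={config.focal_group} absent={rep.count} pct={rep.pct_of_total:.1f}",
            )
            artifacts["absence_report"] = "absence_report.csv"

        # --- dissimilarity ------------------------------------------------
        dist = dissimilarity.pairwise_matrix(matrix)
        write_distance_matrix(dist, tmpdir / "distance.csv", format="square-csv")
        artifacts["distance"] = "distance.csv"
        summary = dissimilarity.group_summary(dist, partition)
        _write_csv(
            summary.to_frame(), tmpdir / "group_summary.csv", "dist",
            f"min={summary.min_pair} max={summary.max_pair}", index=True,
        )
        artifacts["group_summary"] = "group_summary.csv"

        # --- AMOVA --------------------------------------------------------
        contrasts = config.contrasts or (
            [tuple(partition.groups[:2])] if len(partition.groups) >= 2 else []
        )
        amova_seed = derived_seed(config.seed, "amova")
        tables = amova.pairwise_group_amovas(
            matrix, partition, contrasts,
            n_permutations=config.amova_permutations, seed=amova_seed,
        )
        amova_df = pd.DataFrame(
            [
                {
                    "contrast": f"{t.groups[0]}:{t.groups[1]}",
                    "df_among": t.df_among,
                    "df_within": t.df_within,
                    "ss_among": t.ss_among,
                    "ss_within": t.ss_within,
                    "ss_total": t.ss_total,
                    "sigma2_among": t.sigma2_among,
                    "sigma2_within": t.sigma2_within,
                    "pct_among": t.pct_among,
                    "pct_within": t.pct_within,
                    "phi_st": t.phi_st,
                    "p_value": t.p_value,
                }
                for t in tables
            ]
        )
        _write_csv(
            amova_df, tmpdir / "amova.csv", "amova",
            f"perms={config.amova_permutations} seed={amova_seed}",
        )
        artifacts["amova"] = "amova.csv"

        # --- tree + PCoA --------------------------------------------------
        tree_seed = derived_seed(config.seed, "tree")
        tree = trees_ordination.bootstrap_tree(
            matrix, B=config.tree_bootstraps, seed=tree_seed
        )
        (tmpdir / "tree.nwk").write_text(tree.to_newick(with_support=True) + "\n")
        artifacts["tree"] = "tree.nwk"
        result = trees_ordination.pcoa(dist, n_axes=config.pcoa_axes)
        _write_csv(
            result.coordinates, tmpdir / "pcoa_coordinates.csv", "pcoa",
            f"axes={config.pcoa_axes} negative_eigenvalues={result.n_negative}",
            index=True,
        )
        eig = pd.DataFrame(
            {
                "eigenvalue": result.eigenvalues,
                "percent_explained": np.concatenate(
                    [
                        result.percent_explained,
                        np.full(
                            len(result.eigenvalues) - len(result.percent_explained),
                            np.nan,
                        ),
                    ]
                ),
            }
        )
        _write_csv(eig, tmpdir / "pcoa_eigenvalues.csv", "pcoa", "")
        artifacts["pcoa"] = "pcoa_coordinates.csv"

        # --- sufficiency --------------------------------------------------
        suff_seed = derived_seed(config.seed, "sufficiency")
        grid = marker_sufficiency.default_grid(
            matrix.n_bands, start=config.sufficiency_start, step=config.sufficiency_step
        )
        curve = marker_sufficiency.cv_curve(
            matrix, grid=grid, B=config.sufficiency_reps, seed=suff_seed
        )
        from .errors import FitError, NoCrossingError

        try:
            marker_sufficiency.fit_decay(curve)
            marker_sufficiency.markers_for_threshold(curve, config.sufficiency_threshold)
        except (FitError, NoCrossingError):
            pass  # a flat or degenerate curve is reportable without a fit
        fitted = (
            curve.fitted_cv
            if curve.fitted_cv is not None
            else np.full(curve.grid.size, np.nan)
        )
        suff_df = pd.DataFrame(
            {"m": curve.grid, "cv_pct": curve.cv, "fitted_cv_pct": fitted}
        )
        _write_csv(
            suff_df, tmpdir / "sufficiency.csv", "sufficiency",
            f"B={curve.B} seed={suff_seed} a={curve.a} b={curve.b} "
            f"threshold={config.sufficiency_threshold} m_star={curve.m_star}",
        )
        artifacts["sufficiency"] = "sufficiency.csv"

        # --- manifest -----------------------------------------------------
        manifest = {
            "package": "domssr",
            "version": _pkg_version("domssr"),
            "inputs": {"genotypes": str(config.genotypes), "groups": str(config.groups)},
            "seed": config.seed,
            "derived_seeds": {
                "amova": amova_seed,
                "tree": tree_seed,
                "sufficiency": suff_seed,
            },
            "parameters": {
                "subsets": {k: v for k, v in config.subsets.items()},
                "contrasts": [list(c) for c in contrasts],
                "focal_group": config.focal_group,
                "amova_permutations": config.amova_permutations,
                "tree_bootstraps": config.tree_bootstraps,
                "pcoa_axes": config.pcoa_axes,
                "sufficiency": {
                    "start": config.sufficiency_start,
                    "step": config.sufficiency_step,
                    "reps": config.sufficiency_reps,
                    "threshold": config.sufficiency_threshold,
                },
            },
            "artifacts": artifacts,
        }
        (tmpdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
        artifacts["manifest"] = "manifest.json"
    except Exception:
        shutil.rmtree(tmpdir, ignore_errors=True)
        raise

    if outdir.exists():
        shutil.rmtree(outdir)
    tmpdir.rename(outdir)
    return {name: str(outdir / rel) for name, rel in artifacts.items()}
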