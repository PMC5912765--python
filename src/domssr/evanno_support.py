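"""Evanno delta-K model selection from clustering-run log-likelihood tables.

Works on (K, run, lnP) records only; no Bayesian clustering is run here.
L(K) is the per-K mean, L'(K) the first difference, |L''(K)| the absolute
second difference of means, and delta-K = |L''(K)| / sd(lnP at K) using the
sample (n-1) standard deviation. Delta-K is defined only for interior K;
the best K is the argmax (ties to the smallest K).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ContractError, SizeError


@dataclass
class EvannoResult:
    table: pd.DataFrame  # K, reps, mean_lnp, sd_lnp, lprime, abs_lpp, delta_k
    best_k: int | None  # None when no interior K has a defined delta-K


def _validate(df: pd.DataFrame) -> pd.DataFrame:
    required = {"K", "lnP"}
    if not required.issubset(df.columns):
        raise ContractError(f"table needs columns {sorted(required)}")
    ks = np.sort(df["K"].unique())
    if ks.size < 3:
        raise SizeError("need at least three distinct K values")
    if not np.array_equal(ks, np.arange(ks[0], ks[-1] + 1)):
        raise ContractError(f"K grid has gaps: {list(ks)}")
    reps = df.groupby("K")["lnP"].count()
    if (reps < 2).any():
        bad = list(reps[reps < 2].index)
        raise SizeError(f"need at least two runs per K; offending K: {bad}")
    return df


def delta_k(table: pd.DataFrame) -> EvannoResult:
    """Evanno table and best-K selection from a (K, run, lnP) table.

    K values with zero run-to-run standard deviation get an undefined
    (NaN) delta-K and are flagged, not dropped.
    """
    df = _validate(pd.DataFrame(table))
    grouped = df.groupby("K")["lnP"]
    ks = np.sort(df["K"].unique())
    mean = grouped.mean().reindex(ks).to_numpy(dtype=float)
    sd = grouped.std(ddof=1).reindex(ks).to_numpy(dtype=float)
    reps = grouped.count().reindex(ks).to_numpy()

    lprime = np.full(ks.size, np.nan)
    lprime[1:] = mean[1:] - mean[:-1]
    abs_lpp = np.full(ks.size, np.nan)
    abs_lpp[1:-1] = np.abs(mean[2:] - 2.0 * mean[1:-1] + mean[:-2])
    with np.errstate(divide="ignore", invalid="ignore"):
        dk = np.where(sd > 0, abs_lpp / sd, np.nan)
    dk[[0, -1]] = np.nan  # endpoints are never interior

    out = pd.DataFrame(
        {
            "K": ks,
            "reps": reps,
            "mean_lnp": mean,
            "sd_lnp": sd,
            "lprime": lprime,
            "abs_lpp": abs_lpp,
            "delta_k": dk,
        }
    )
    interior = out["delta_k"].notna()
    if interior.any():
        best = out.loc[interior]
        best_k = int(best.loc[best["delta_k"].idxmax(), "K"])
        # ties to the smallest K
        top = best[np.isclose(best["delta_k"], best["delta_k"].max())]
        best_k = int(top["K"].min())
    else:
        best_k = None
    return EvannoResult(table=out, best_k=best_k)
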