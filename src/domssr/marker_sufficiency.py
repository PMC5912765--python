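"""Bootstrap marker-number sufficiency.

For a grid of marker counts m, band columns are resampled B times; each
resample yields a full pairwise Jaccard matrix, and for every individual
pair the coefficient of variation (100 * sd / mean) of its B sampled
dissimilarities is computed. The per-m summary is the median over pairs
(pairs with mean zero are excluded). A decay curve is fitted to the summary
and inverted for the smallest marker count meeting a CV threshold.

The default decay model is the power law CV(m) = a * m^b (log-log linear
least squares); simple sampling theory puts b near -1/2. An exponential
model a * exp(b*m) + c is available as an alternative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil

import numpy as np
from scipy.optimize import curve_fit

from .errors import FitError, InsufficientDataError, NoCrossingError, SizeError
from .dissimilarity import pairwise_jaccard_arrays
from .genotype_io import BinaryGenotypeMatrix


@dataclass
class SufficiencyCurve:
    grid: np.ndarray  # marker counts, strictly increasing
    cv: np.ndarray  # summary CV% per grid point
    B: int
    seed: int | None
    replace: bool = True
    pooled: bool = False
    model: str | None = None
    a: float | None = None
    b: float | None = None
    c: float | None = None
    fitted_cv: np.ndarray | None = None
    threshold: float | None = None
    m_star: int | None = None
    extra_params: dict = field(default_factory=dict)


def default_grid(n_bands: int, start: int = 3, step: int = 3) -> np.ndarray:
    """The arithmetic grid start, start+step, ... up to the band count."""
    return np.arange(start, n_bands + 1, step)


def cv_curve(
    matrix: BinaryGenotypeMatrix,
    grid=None,
    B: int = 1000,
    seed: int | None = None,
    replace: bool = True,
    pooled: bool = False,
) -> SufficiencyCurve:
    """Median (or pooled) CV% of pairwise dissimilarities per marker count.

    ``replace=False`` switches to no-replacement subsampling. ``pooled=True``
    computes one CV over the pooled vector of all pairwise dissimilarities
    per replicate set instead of the per-pair median.
    """
    if grid is None:
        grid = default_grid(matrix.n_bands)
    grid = np.asarray(grid, dtype=int)
    if grid.size == 0 or np.any(np.diff(grid) <= 0):
        raise SizeError("grid must be non-empty and strictly increasing")
    if grid.max() > matrix.n_bands:
        raise SizeError("grid exceeds the total band count")
    if B < 2:
        raise SizeError("need at least two bootstrap replicates")

    rng = np.random.default_rng(seed)
    n = matrix.n_individuals
    iu = np.triu_indices(n, 1)
    values = matrix.values
    cvs = np.empty(grid.size)
    for gi, m in enumerate(grid):
        s = np.zeros(iu[0].size)
        s2 = np.zeros(iu[0].size)
        cnt = np.zeros(iu[0].size)
        for _ in range(B):
            if replace:
                cols = rng.integers(0, matrix.n_bands, size=m)
            else:
                cols = rng.choice(matrix.n_bands, size=m, replace=False)
            d, union, _ = pairwise_jaccard_arrays(values[:, cols])
            dv = d[iu]
            ok = ~np.isnan(dv)
            s[ok] += dv[ok]
            s2[ok] += dv[ok] ** 2
            cnt[ok] += 1
        eligible = cnt >= 2
        mean = np.where(eligible, s / np.maximum(cnt, 1), np.nan)
        var = np.where(
            eligible,
            (s2 - cnt * mean**2) / np.maximum(cnt - 1, 1),
            np.nan,
        )
        sd = np.sqrt(np.maximum(var, 0.0))
        use = eligible & (mean > 0)
        if not use.any():
            raise InsufficientDataError(
                f"all pairs excluded at m={m} (no positive mean dissimilarity)"
            )
        if pooled:
            cvs[gi] = 100.0 * float(np.mean(sd[use])) / float(np.mean(mean[use]))
        else:
            cvs[gi] = float(np.median(100.0 * sd[use] / mean[use]))
    return SufficiencyCurve(
        grid=grid, cv=cvs, B=B, seed=seed, replace=replace, pooled=pooled
    )


def fit_decay(curve: SufficiencyCurve, model: str = "power") -> SufficiencyCurve:
    """Fit a decay model to the summary curve (in place, returned for chaining)."""
    usable = curve.cv > 0
    dropped = int((~usable).sum())
    if dropped:
        import warnings

        warnings.warn(f"{dropped} non-positive CV point(s) excluded from fit", stacklevel=2)
    m = curve.grid[usable].astype(float)
    cv = curve.cv[usable]
    if m.size < 3:
        raise FitError("need at least three positive-CV grid points")
    if model == "power":
        slope, intercept = np.polyfit(np.log(m), np.log(cv), 1)
        curve.a, curve.b, curve.c = float(np.exp(intercept)), float(slope), None
        curve.fitted_cv = curve.a * curve.grid.astype(float) ** curve.b
    elif model == "exponential":
        def f(x, a, b, c):
            return a * np.exp(b * x) + c

        p0 = (cv[0] - cv[-1], -1.0 / max(m[-1], 1.0), cv[-1])
        try:
            popt, _ = curve_fit(f, m, cv, p0=p0, maxfev=20000)
        except RuntimeError as exc:
            raise FitError(f"exponential fit failed: {exc}") from exc
        curve.a, curve.b, curve.c = (float(x) for x in popt)
        curve.fitted_cv = f(curve.grid.astype(float), *popt)
    else:
        raise ValueError(f"unknown decay model {model!r}")
    curve.model = model
    return curve


def markers_for_threshold(curve: SufficiencyCurve, threshold_pct: float) -> int:
    """Smallest integer m with fitted CV(m) <= threshold."""
    if curve.model is None:
        raise FitError("fit the curve before inverting it")
    if curve.b is None or curve.b >= -1e-9:
        raise NoCrossingError("fitted decay exponent/rate is not negative")
    if curve.model == "power":
        # a * m^b <= t  =>  m >= (t/a)^(1/b)  (b < 0)
        if curve.a <= threshold_pct:
            m_star = 1
        else:
            m_star = ceil((threshold_pct / curve.a) ** (1.0 / curve.b) - 1e-9)
    else:  # exponential a*exp(b*m) + c
        if curve.c is not None and curve.c >= threshold_pct:
            raise NoCrossingError("asymptote lies above the threshold")
        c = curve.c or 0.0
        if curve.a <= 0:
            m_star = 1
        else:
            m_star = max(1, ceil(np.log((threshold_pct - c) / curve.a) / curve.b - 1e-9))
    curve.threshold = float(threshold_pct)
    curve.m_star = int(max(1, m_star))
    return curve.m_star
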