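"""Rarefaction and extrapolation of species richness.

Individual-based rarefaction uses the classical hypergeometric
expectation

    E[S(m)] = S_obs − Σ_i C(n − n_i, m) / C(n, m),

evaluated in log-gamma arithmetic so large counts do not overflow.
Sample-based rarefaction applies the same form to incidence counts
(Mao's tau).  Extrapolation beyond the observed effort follows the
Bernoulli-product-model closed form with a Chao-type estimate of the
number of undetected species:

    f0 = f1² / (2 f2)                       (f2 > 0)
    f0 = f1 (f1 − 1) / 2                    (f2 = 0, bias-corrected)
    S(n + g) = S_obs + f0 · [1 − (1 − f1 / (n f0 + f1))^g]

with singletons/doubletons (f1, f2) for individuals and uniques /
duplicates (Q1, Q2, over R sample units) for samples.  Confidence
intervals come from a bootstrap over sample units (rows of the
abundance matrix), percentile method.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .io import AbundanceMatrix


def _log_choose(n: np.ndarray, k: float) -> np.ndarray:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def rarefy_individuals(abundances: np.ndarray, m: int) -> float:
    """Expected richness in a random subsample of m individuals."""
    counts = np.asarray(abundances, dtype=float)
    counts = counts[counts > 0]
    n = counts.sum()
    if not 1 <= m <= n:
        raise ValueError(f"m={m} outside [1, n={int(n)}]; use extrapolation beyond n")
    keep = counts <= n - m  # others cannot be absent from the subsample
    terms = np.exp(_log_choose(n - counts[keep], m) - _log_choose(np.array([n]), m))
    return float(counts.size - terms.sum())


def chao_unseen(f1: int, f2: int) -> float:
    """Chao1-type estimate of the number of undetected species."""
    if f1 < 0 or f2 < 0:
        raise ValueError("frequency counts must be non-negative")
    if f1 == 0:
        return 0.0
    if f2 > 0:
        return f1 * f1 / (2.0 * f2)
    return f1 * (f1 - 1) / 2.0


def extrapolate_individuals(abundances: np.ndarray, m_star: int) -> float:
    """Expected richness at m_star > n individuals (Bernoulli product model)."""
    counts = np.asarray(abundances, dtype=float)
    counts = counts[counts > 0]
    n = counts.sum()
    if m_star <= n:
        raise ValueError("m_star must exceed the observed number of individuals")
    s_obs = counts.size
    f1 = int(np.sum(counts == 1))
    f2 = int(np.sum(counts == 2))
    f0 = chao_unseen(f1, f2)
    if f1 == 0 or f0 == 0:
        return float(s_obs)
    g = m_star - n
    return float(s_obs + f0 * (1.0 - (1.0 - f1 / (n * f0 + f1)) ** g))


def rarefy_samples(incidences: np.ndarray, n_samples: int, t: int) -> float:
    """Expected richness among t of the R sample units (Mao's tau)."""
    r_i = np.asarray(incidences, dtype=float)
    r_i = r_i[r_i > 0]
    if not 1 <= t <= n_samples:
        raise ValueError(f"t={t} outside [1, R={n_samples}]")
    keep = r_i <= n_samples - t
    terms = np.exp(
        _log_choose(n_samples - r_i[keep], t) - _log_choose(np.array([float(n_samples)]), t)
    )
    return float(r_i.size - terms.sum())


def extrapolate_samples(incidences: np.ndarray, n_samples: int, t_star: int) -> float:
    """Expected richness at t_star > R sample units (Chao2-based)."""
    r_i = np.asarray(incidences, dtype=float)
    r_i = r_i[r_i > 0]
    if t_star <= n_samples:
        raise ValueError("t_star must exceed the observed number of samples")
    s_obs = r_i.size
    q1 = int(np.sum(r_i == 1))
    q2 = int(np.sum(r_i == 2))
    q0 = chao_unseen(q1, q2)
    if q1 == 0 or q0 == 0:
        return float(s_obs)
    g = t_star - n_samples
    return float(s_obs + q0 * (1.0 - (1.0 - q1 / (n_samples * q0 + q1)) ** g))


def richness_estimate(matrix_values: np.ndarray, mode: str, effort: int) -> float:
    """Rarefied or extrapolated richness at the given effort, dispatching
    on whether the effort is below or beyond the observed reference."""
    if mode == "individual":
        counts = matrix_values.sum(axis=0)
        n = int(counts.sum())
        if effort <= n:
            return rarefy_individuals(counts, effort)
        return extrapolate_individuals(counts, effort)
    if mode == "sample":
        r = matrix_values.shape[0]
        inc = (matrix_values > 0).sum(axis=0)
        if effort <= r:
            return rarefy_samples(inc, r, effort)
        return extrapolate_samples(inc, r, effort)
    raise ValueError(f"unknown mode {mode!r}")


@dataclass
class RarefactionCurve:
    mode: str
    reference_n: int
    f1: int
    f2: int
    points: pd.DataFrame  # effort, S_est, ci_lo, ci_hi, extrapolated

    @property
    def s_obs(self) -> int:
        return int(round(self.points.loc[self.points["effort"] == self.reference_n, "S_est"].iloc[0]))


def _effort_grid(reference: int, target: int, n_knots: int) -> np.ndarray:
    hi = max(reference, target)
    grid = np.unique(
        np.concatenate(
            [np.linspace(1, hi, n_knots).round().astype(int), [reference, target]]
        )
    )
    return grid[grid >= 1]


def curve_with_ci(
    matrix: AbundanceMatrix,
    mode: str,
    target_effort: int | None = None,
    n_boot: int = 200,
    seed: int = 0,
    n_knots: int = 30,
) -> RarefactionCurve:
    """Rarefaction/extrapolation curve with bootstrap 95% CIs.

    Point estimates are analytic; uncertainty comes from resampling the
    night replicates (matrix rows) with replacement.  ``target_effort``
    lets schedule-restricted matrices extend to the full-night effort so
    curves are compared at a common endpoint.
    """
    values = matrix.data.to_numpy()
    if values.shape[0] == 0 or values.sum() == 0:
        raise ValueError("empty matrix")
    if mode == "individual":
        reference = int(values.sum())
        f1 = int(np.sum(values.sum(axis=0) == 1))
        f2 = int(np.sum(values.sum(axis=0) == 2))
    else:
        reference = values.shape[0]
        inc = (values > 0).sum(axis=0)
        f1 = int(np.sum(inc == 1))
        f2 = int(np.sum(inc == 2))
    target = target_effort if target_effort is not None else reference
    grid = _effort_grid(reference, target, n_knots)
    est = np.array([richness_estimate(values, mode, int(m)) for m in grid])

    n_rows = values.shape[0]
    if n_rows < 2:
        warnings.warn("single sample unit: returning point estimates without CIs", stacklevel=2)
        ci_lo = np.full(grid.shape, np.nan)
        ci_hi = np.full(grid.shape, np.nan)
    else:
        rng = np.random.default_rng(seed)
        boots = np.empty((n_boot, grid.size))
        for b in range(n_boot):
            rows = rng.integers(0, n_rows, size=n_rows)
            vb = values[rows]
            for j, m in enumerate(grid):
                try:
                    boots[b, j] = richness_estimate(vb, mode, int(m))
                except ValueError:  # resample with fewer individuals than m
                    counts = vb.sum(axis=0) if mode == "individual" else (vb > 0).sum(axis=0)
                    nb = counts.sum() if mode == "individual" else vb.shape[0]
                    boots[b, j] = (
                        richness_estimate(vb, mode, int(nb)) if nb >= 1 else np.nan
                    )
        ci_lo, ci_hi = np.nanpercentile(boots, [2.5, 97.5], axis=0)
    points = pd.DataFrame(
        {
            "effort": grid,
            "S_est": est,
            "ci_lo": ci_lo,
            "ci_hi": ci_hi,
            "extrapolated": grid > reference,
        }
    )
    return RarefactionCurve(mode=mode, reference_n=reference, f1=f1, f2=f2, points=points)
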