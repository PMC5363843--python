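"""Compositional congruence between sampling schedules.

Night-replicate x species matrices are compared in ordination space:
Jaccard (presence/absence) or Bray–Curtis (counts) dissimilarities are
embedded by principal coordinates analysis (PCoA); the configuration of
a schedule-restricted matrix is superimposed on the full-night
configuration by Procrustes rotation.  With both configurations centred
and scaled to unit sum of squares, the residual sum of squares m² after
the optimal rotation/reflection/scaling lies in [0, 1] and

    r = sqrt(1 − m²)

measures concordance (1 = identical composition structure).
Significance is assessed by the PROTEST permutation test.  The
sample-area null model asks how well a *random* subset of k species —
keeping their full-night counts, hence no time-of-night bias — would
reproduce the full ordination; a schedule that falls below the matched-k
null distribution distorts composition beyond what losing species alone
explains.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio.stats.ordination import pcoa as _skbio_pcoa

from .io import AbundanceMatrix

METRICS = ("jaccard", "braycurtis")
_EIG_TOL = 1e-10


@dataclass
class DissimilarityResult:
    distances: np.ndarray  # square-form
    row_labels: list
    dropped_rows: list
    metric: str

    @property
    def degenerate(self) -> bool:
        return len(self.row_labels) < 3


def dissimilarity(matrix: AbundanceMatrix, metric: str) -> DissimilarityResult:
    """Pairwise dissimilarities among night replicates.

    All-zero rows carry no compositional information under either metric
    (distances to them are undefined/1) and are removed first; losing
    too many marks the matrix degenerate — the signature of a schedule
    that sampled too few captures to ordinate.
    """
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}")
    data = matrix.data
    nonzero = data.sum(axis=1) > 0
    dropped = list(data.index[~nonzero])
    kept = data.loc[nonzero]
    values = kept.to_numpy(dtype=float)
    if metric == "jaccard":
        d = pdist(values > 0, metric="jaccard")
    else:
        d = pdist(values, metric="braycurtis")
    return DissimilarityResult(
        distances=squareform(d),
        row_labels=list(kept.index),
        dropped_rows=dropped,
        metric=metric,
    )


@dataclass
class OrdinationResult:
    scores: np.ndarray
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray
    row_labels: list
    dropped_rows: list
    n_axes_used: int

    @property
    def degenerate(self) -> bool:
        return self.n_axes_used < 2 or len(self.row_labels) < 3


def pcoa(dissim: DissimilarityResult, n_axes: int = 5) -> OrdinationResult:
    """Principal coordinates of a dissimilarity matrix.

    Axes are eigenvectors of the double-centred matrix scaled by the
    square root of their eigenvalues; negative eigenvalues are dropped
    without correction.  When fewer positive axes exist than requested
    the ordination proceeds with what there is, with a warning.
    """
    n = len(dissim.row_labels)
    if n < 2:
        raise ValueError("need at least 2 rows to ordinate")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # skbio warns about negative eigenvalues
        ord_res = _skbio_pcoa(dissim.distances, method="eigh")
    eig = ord_res.eigvals.to_numpy()
    scale = max(eig.max(), 1.0)
    positive = eig > _EIG_TOL * scale
    n_pos = int(positive.sum())
    n_used = min(n_axes, n_pos)
    if n_used < n_axes:
        warnings.warn(
            f"only {n_pos} positive PCoA axes available (requested {n_axes})",
            stacklevel=2,
        )
    scores = ord_res.samples.to_numpy()[:, :n_used]
    total = eig[positive].sum()
    prop = eig[:n_used] / total if total > 0 else np.zeros(n_used)
    return OrdinationResult(
        scores=scores,
        eigenvalues=eig[:n_used],
        proportion_explained=prop,
        row_labels=dissim.row_labels,
        dropped_rows=dissim.dropped_rows,
        n_axes_used=n_used,
    )


def _standardize(conf: np.ndarray) -> np.ndarray:
    centred = conf - conf.mean(axis=0)
    norm = np.sqrt((centred**2).sum())
    if norm == 0:
        raise ValueError("configuration has zero variance")
    return centred / norm


def _pad_columns(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    width = max(a.shape[1], b.shape[1])
    pad = lambda m: np.pad(m, ((0, 0), (0, width - m.shape[1])))
    return pad(a), pad(b)


def procrustes_r(scores_ref: np.ndarray, scores_target: np.ndarray) -> tuple[float, float]:
    """Procrustes m² and r = sqrt(1 − m²) after optimal superimposition.

    Both configurations are centred and scaled to unit sum of squares
    (symmetric scaling); rotation with reflection is allowed.  With that
    normalisation m² = 1 − (Σ σ)², σ the singular values of Xᵀ Y.
    """
    x = np.asarray(scores_ref, dtype=float)
    y = np.asarray(scores_target, dtype=float)
    if x.shape[0] != y.shape[0]:
        raise ValueError("configurations must have the same number of rows")
    if x.shape[0] < 3:
        raise ValueError("need at least 3 shared rows")
    x, y = _pad_columns(x, y)
    xs, ys = _standardize(x), _standardize(y)
    trace = np.linalg.svd(xs.T @ ys, compute_uv=False).sum()
    trace = min(float(trace), 1.0)
    m2 = max(1.0 - trace**2, 0.0)
    return m2, float(np.sqrt(1.0 - m2))


def protest(
    scores_ref: np.ndarray,
    scores_target: np.ndarray,
    n_perm: int = 999,
    seed: int | np.random.Generator = 0,
) -> float:
    """Permutation p-value for the observed Procrustes r.

    Rows of the target configuration are permuted; p applies the +1
    correction: (1 + #{r_perm ≥ r_obs}) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x, y = _pad_columns(
        np.asarray(scores_ref, dtype=float), np.asarray(scores_target, dtype=float)
    )
    xs, ys = _standardize(x), _standardize(y)
    r_obs = min(float(np.linalg.svd(xs.T @ ys, compute_uv=False).sum()), 1.0)
    n = xs.shape[0]
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r_p = float(np.linalg.svd(xs.T @ ys[perm], compute_uv=False).sum())
        if r_p >= r_obs - 1e-12:
            count += 1
    return (1 + count) / (n_perm + 1)


@dataclass
class CongruenceResult:
    strategy: str
    metric: str
    m2: float
    r: float
    p: float
    n_rows_shared: int
    n_species_strategy: int
    degenerate: bool
    note: str | None = None


def strategy_congruence(
    full: AbundanceMatrix,
    strategy: AbundanceMatrix,
    metric: str,
    n_axes: int = 5,
    n_perm: int = 999,
    seed: int | np.random.Generator = 0,
    strategy_name: str | None = None,
) -> CongruenceResult:
    """Procrustes congruence of a schedule's ordination with the full night's.

    Each matrix is ordinated on its own non-empty rows; the score
    configurations are then restricted to the shared night replicates
    before superimposition.  A schedule whose restricted matrix leaves
    fewer than three usable rows or fewer than two positive axes is
    reported degenerate (r undefined) rather than scored.
    """
    name = strategy_name or strategy.schedule_name or "strategy"
    n_species = int((strategy.data.sum(axis=0) > 0).sum())

    def _degenerate(note: str) -> CongruenceResult:
        return CongruenceResult(
            strategy=name, metric=metric, m2=np.nan, r=np.nan, p=np.nan,
            n_rows_shared=0, n_species_strategy=n_species, degenerate=True, note=note,
        )

    d_full = dissimilarity(full, metric)
    d_strat = dissimilarity(strategy, metric)
    if d_full.degenerate or d_strat.degenerate:
        return _degenerate("too many all-zero rows")
    ord_full = pcoa(d_full, n_axes)
    ord_strat = pcoa(d_strat, n_axes)
    if ord_full.degenerate or ord_strat.degenerate:
        return _degenerate("fewer than two positive ordination axes")
    shared = [lab for lab in ord_full.row_labels if lab in set(ord_strat.row_labels)]
    if len(shared) < 3:
        return _degenerate("fewer than three shared rows")
    idx_full = [ord_full.row_labels.index(lab) for lab in shared]
    idx_strat = [ord_strat.row_labels.index(lab) for lab in shared]
    x = ord_full.scores[idx_full]
    y = ord_strat.scores[idx_strat]
    m2, r = procrustes_r(x, y)
    p = protest(x, y, n_perm=n_perm, seed=seed) if n_perm else np.nan
    return CongruenceResult(
        strategy=name, metric=metric, m2=m2, r=r, p=p,
        n_rows_shared=len(shared), n_species_strategy=n_species, degenerate=False,
    )


@dataclass
class NullCurve:
    mode: str  # "curve" or "matched-k"
    draws: pd.DataFrame  # columns k, r, failed
    n_draws: int
    seed: int

    def median_r(self, k: int | None = None) -> float:
        sub = self.draws if k is None else self.draws[self.draws["k"] == k]
        return float(sub.loc[~sub["failed"], "r"].median())

    def percentile_of(self, r: float, k: int | None = None) -> float:
        """Mid-rank percentile of an observed r within the null draws."""
        sub = self.draws if k is None else self.draws[self.draws["k"] == k]
        vals = sub.loc[~sub["failed"], "r"].to_numpy()
        if vals.size == 0:
            raise ValueError("no successful null draws to rank against")
        return float(np.mean(vals < r) + 0.5 * np.mean(vals == r))


def null_model(
    full: AbundanceMatrix,
    k_values: list[int] | int,
    n_draws: int = 1000,
    metric: str = "braycurtis",
    n_axes: int = 5,
    seed: int = 0,
) -> NullCurve:
    """Random-species-subset null model.

    Each draw picks k species uniformly without replacement, keeps their
    full-night counts over all night replicates, and scores the
    column-subset matrix against the full community exactly as a
    schedule would be.  With a list of k values the draws sweep the grid
    (curve mode); with a single k all draws probe that size (matched-k
    mode), giving the reference distribution for a schedule with k
    species.  Draws whose subset matrix cannot be ordinated are recorded
    as failed, not dropped.
    """
    rng = np.random.default_rng(seed)
    species = [sp for sp in full.data.columns if full.data[sp].sum() > 0]
    s_total = len(species)
    if isinstance(k_values, int):
        mode, grid = "matched-k", [k_values]
    else:
        mode, grid = "curve", list(k_values)
    for k in grid:
        if not 2 <= k <= s_total:
            raise ValueError(f"k={k} outside [2, {s_total}]")
    rows = []
    for i in range(n_draws):
        k = grid[i % len(grid)]
        chosen = list(rng.choice(species, size=k, replace=False))
        sub = AbundanceMatrix(full.data[chosen], schedule_name=f"null-k{k}")
        res = strategy_congruence(
            full, sub, metric=metric, n_axes=n_axes, n_perm=0, seed=rng,
            strategy_name=f"null-k{k}",
        )
        rows.append({"k": k, "r": res.r, "failed": res.degenerate})
    return NullCurve(mode=mode, draws=pd.DataFrame(rows), n_draws=n_draws, seed=seed)
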