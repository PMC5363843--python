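"""Threshold indicator taxa analysis along the nocturnal time gradient.

Sample units are (site, night, check-interval) cells; the gradient value
of a unit is its interval midpoint in minutes since 18:00.  For each
taxon, candidate change points are midpoints between consecutive
distinct capture times; each candidate splits the units into an early
(left) and late (right) group, scored with Dufrêne–Legendre indicator
values

    IndVal_g = 100 · A_g · B_g,
    A_g = mean abundance in g / (mean left + mean right),
    B_g = fraction of units in g with the taxon present.

Each candidate's IndVal is standardised against a permutation null
(gradient labels shuffled) and the candidate/side with the largest
z-score gives the observed change point and direction (left/early
maximum = "negative" responder, right/late = "positive"); raw-IndVal
maximisation is available via ``selection="indval"``.  The z-selection
is the reference default because raw IndVal is inflated for very small
splits.  Bootstrap resampling of units re-runs the whole selection,
yielding purity (fraction of resamples agreeing in direction) and
reliability (fraction with permutation p ≤ 0.05).  A taxon is
flagged significant when purity and reliability both reach 0.95.
Community-level thresholds are peaks of the cumulative sums of z-scores
of negative (z−) and positive (z+) responders along the gradient.

Species with few records carry no individual signal; below a minimum
record count (default 9) they are pooled into composite taxa keyed by
(guild, rarity class) before analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import AbundanceMatrix, CaptureRecord
from .schedules import DEFAULT_CHECK_INTERVAL, NIGHT_MINUTES

DEFAULT_MIN_SPLIT = 4
DEFAULT_MIN_RECORDS = 9


def gradient_samples(
    records: list[CaptureRecord],
    check_interval: int = DEFAULT_CHECK_INTERVAL,
    nights: list[tuple[str, str]] | None = None,
    species: list[str] | None = None,
) -> pd.DataFrame:
    """Unit x taxon count table; rows indexed (site, night, midpoint).

    Every check interval of every night is a unit, including those with
    zero captures — absence along the gradient is informative.
    """
    if nights is None:
        nights = sorted({(r.site_id, r.night_id) for r in records})
    if species is None:
        species = sorted({r.species_id for r in records})
    n_bins = NIGHT_MINUTES // check_interval
    midpoints = np.arange(n_bins) * check_interval + check_interval / 2
    index = pd.MultiIndex.from_tuples(
        [(s, n, m) for s, n in nights for m in midpoints],
        names=["site", "night", "gradient"],
    )
    table = pd.DataFrame(0, index=index, columns=species, dtype=int)
    for r in records:
        mid = r.time_min - r.time_min % check_interval + check_interval / 2
        table.loc[(r.site_id, r.night_id, mid), r.species_id] += r.count
    return table


def pool_sparse_taxa(
    table: pd.DataFrame,
    traits: pd.DataFrame,
    min_records: int = DEFAULT_MIN_RECORDS,
) -> pd.DataFrame:
    """Merge columns of species with < min_records into (guild, rarity)
    composite taxa named like ``FR_C``.  Pooled once, never re-pooled:
    a composite that still falls short is retained anyway.

    ``traits`` must index species and provide ``guild`` and
    ``rarity_class`` columns.
    """
    totals = table.sum(axis=0)
    sparse = [sp for sp in table.columns if totals[sp] < min_records]
    missing = [sp for sp in sparse if sp not in traits.index]
    if missing:
        raise ValueError(f"species lacking traits: {missing}")
    out = table[[sp for sp in table.columns if sp not in sparse]].copy()
    groups: dict[str, list[str]] = {}
    for sp in sparse:
        key = f"{traits.loc[sp, 'guild']}_{traits.loc[sp, 'rarity_class']}"
        groups.setdefault(key, []).append(sp)
    for key, members in sorted(groups.items()):
        out[key] = table[members].sum(axis=1)
    return out


def candidate_change_points(
    present_gradient: np.ndarray,
    all_gradient: np.ndarray,
    min_split: int = DEFAULT_MIN_SPLIT,
) -> np.ndarray:
    """Midpoints between consecutive distinct capture times, keeping only
    splits that leave at least ``min_split`` units on each side."""
    distinct = np.unique(np.asarray(present_gradient, dtype=float))
    if distinct.size < 2:
        return np.empty(0)
    mids = (distinct[:-1] + distinct[1:]) / 2
    g_sorted = np.sort(np.asarray(all_gradient, dtype=float))
    n = g_sorted.size
    left_counts = np.searchsorted(g_sorted, mids)
    ok = (left_counts >= min_split) & (n - left_counts >= min_split)
    return mids[ok]


def indval(x: np.ndarray, gradient: np.ndarray, split: float) -> tuple[float, float]:
    """Indicator values of the taxon for the units left and right of a split."""
    x = np.asarray(x, dtype=float)
    g = np.asarray(gradient, dtype=float)
    left = g < split
    if x.sum() == 0:
        raise ValueError("taxon absent from all units")
    mean_l, mean_r = x[left].mean(), x[~left].mean()
    denom = mean_l + mean_r
    if denom == 0:
        return 0.0, 0.0
    a_l, a_r = mean_l / denom, mean_r / denom
    b_l = float(np.mean(x[left] > 0))
    b_r = float(np.mean(x[~left] > 0))
    return 100.0 * a_l * b_l, 100.0 * a_r * b_r


def _indval_profile(
    xs: np.ndarray, left_counts: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """IndVal (left, right) at each candidate for gradient-sorted rows.

    ``xs`` is (n_rows, n_units) of abundances sorted by gradient;
    ``left_counts`` gives, per candidate, how many units fall left.
    Vectorised over rows (permutations / observed) and candidates.
    """
    n = xs.shape[1]
    cs = np.cumsum(xs, axis=1)
    cp = np.cumsum(xs > 0, axis=1)
    k = left_counts  # (n_cand,)
    sum_l = cs[:, k - 1]
    sum_r = cs[:, -1:] - sum_l
    occ_l = cp[:, k - 1]
    occ_r = cp[:, -1:] - occ_l
    mean_l = sum_l / k
    mean_r = sum_r / (n - k)
    denom = mean_l + mean_r
    with np.errstate(invalid="ignore", divide="ignore"):
        a_l = np.where(denom > 0, mean_l / denom, 0.0)
        a_r = np.where(denom > 0, mean_r / denom, 0.0)
    iv_l = 100.0 * a_l * (occ_l / k)
    iv_r = 100.0 * a_r * (occ_r / (n - k))
    return iv_l, iv_r


@dataclass
class _SplitStats:
    change_point: float
    direction: str
    indval: float
    z: float
    p: float
    degenerate_null: bool


def _split_stats(
    x_sorted: np.ndarray,
    g_sorted: np.ndarray,
    min_split: int,
    n_perm: int,
    rng: np.random.Generator,
    selection: str,
) -> _SplitStats | None:
    """Select the best candidate split and score it against a permutation null.

    ``selection="z"`` (default) picks the candidate/side with the largest
    permutation z-score of IndVal — the reference behaviour, which
    standardises away the inflated raw IndVal of very small splits.
    ``selection="indval"`` picks the largest raw IndVal.  The permutation
    p-value uses the distribution of the selection statistic maximised
    over candidates and sides, so candidate search is accounted for.
    """
    cands = candidate_change_points(g_sorted[x_sorted > 0], g_sorted, min_split)
    if cands.size == 0:
        return None
    k = np.searchsorted(g_sorted, cands)
    iv_l, iv_r = _indval_profile(x_sorted[None, :], k)
    iv_l, iv_r = iv_l[0], iv_r[0]
    perms = rng.permuted(np.tile(x_sorted, (n_perm, 1)), axis=1)
    piv_l, piv_r = _indval_profile(perms, k)

    if selection == "indval":
        obs_stat_l, obs_stat_r = iv_l, iv_r
        null_max = np.maximum(piv_l, piv_r).max(axis=1)
    elif selection == "z":
        mu_l, sd_l = piv_l.mean(axis=0), piv_l.std(axis=0, ddof=1)
        mu_r, sd_r = piv_r.mean(axis=0), piv_r.std(axis=0, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            obs_stat_l = np.where(sd_l > 0, (iv_l - mu_l) / sd_l, -np.inf)
            obs_stat_r = np.where(sd_r > 0, (iv_r - mu_r) / sd_r, -np.inf)
            pz_l = np.where(sd_l > 0, (piv_l - mu_l) / sd_l, -np.inf)
            pz_r = np.where(sd_r > 0, (piv_r - mu_r) / sd_r, -np.inf)
        null_max = np.maximum(pz_l, pz_r).max(axis=1)
    else:
        raise ValueError(f"unknown selection rule {selection!r}")

    best_l, best_r = obs_stat_l.max(), obs_stat_r.max()
    if not np.isfinite(max(best_l, best_r)):
        return _SplitStats(float(cands[0]), "negative", 0.0, np.nan, np.nan, True)
    if best_l >= best_r:
        j, direction = int(np.argmax(obs_stat_l)), "negative"
        obs_stat, obs_iv = float(best_l), float(iv_l[j])
    else:
        j, direction = int(np.argmax(obs_stat_r)), "positive"
        obs_stat, obs_iv = float(best_r), float(iv_r[j])

    finite = null_max[np.isfinite(null_max)]
    if finite.size < 2 or finite.std(ddof=1) == 0:
        return _SplitStats(float(cands[j]), direction, obs_iv, np.nan, np.nan, True)
    if selection == "indval":
        z = (obs_stat - float(finite.mean())) / float(finite.std(ddof=1))
    else:
        z = obs_stat
    p = float(np.mean(null_max >= obs_stat))
    return _SplitStats(float(cands[j]), direction, obs_iv, float(z), p, False)


@dataclass
class TaxonThreshold:
    taxon_id: str
    change_point: float | None
    direction: str | None
    indval: float
    z: float
    p_perm: float
    cp_lo: float
    cp_hi: float
    purity: float
    reliability: float
    n_records: int
    significant: bool
    flag: str | None = None


def taxon_titan(
    x: np.ndarray,
    gradient: np.ndarray,
    taxon_id: str = "taxon",
    n_perm: int = 250,
    n_boot: int = 500,
    min_split: int = DEFAULT_MIN_SPLIT,
    seed: int | np.random.Generator = 0,
    selection: str = "z",
) -> TaxonThreshold:
    """Change point, permutation z and bootstrap diagnostics for one taxon."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x = np.asarray(x, dtype=float)
    g = np.asarray(gradient, dtype=float)
    order = np.argsort(g, kind="stable")
    xs, gs = x[order], g[order]
    n = xs.size
    nan_result = dict(
        change_point=None, direction=None, indval=np.nan, z=np.nan, p_perm=np.nan,
        cp_lo=np.nan, cp_hi=np.nan, purity=0.0, reliability=0.0,
        n_records=int(x.sum()), significant=False,
    )
    obs = _split_stats(xs, gs, min_split, n_perm, rng, selection)
    if obs is None:
        return TaxonThreshold(taxon_id, **{**nan_result, "flag": "no candidates"})
    if obs.degenerate_null:
        return TaxonThreshold(
            taxon_id, **{
                **nan_result,
                "change_point": obs.change_point, "direction": obs.direction,
                "indval": obs.indval, "flag": "degenerate permutation null",
            },
        )
    cp, direction, iv_obs, z, p_perm = (
        obs.change_point, obs.direction, obs.indval, obs.z, obs.p,
    )
    flag = None

    boot_cps: list[float] = []
    n_match_dir = 0
    n_reliable = 0
    n_valid = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        xb, gb = xs[idx], gs[idx]
        sub = np.argsort(gb, kind="stable")
        xb, gb = xb[sub], gb[sub]
        best = _split_stats(xb, gb, min_split, n_perm, rng, selection)
        if best is None or best.degenerate_null:
            continue
        n_valid += 1
        boot_cps.append(best.change_point)
        if best.direction == direction:
            n_match_dir += 1
        if best.p <= 0.05:
            n_reliable += 1
    if n_valid:
        purity = n_match_dir / n_valid
        reliability = n_reliable / n_valid
        cp_lo, cp_hi = np.percentile(boot_cps, [5, 95])
    else:
        purity = reliability = 0.0
        cp_lo = cp_hi = np.nan
    significant = flag is None and purity >= 0.95 and reliability >= 0.95
    return TaxonThreshold(
        taxon_id=taxon_id, change_point=cp, direction=direction, indval=iv_obs,
        z=float(z), p_perm=p_perm, cp_lo=float(cp_lo), cp_hi=float(cp_hi),
        purity=purity, reliability=reliability, n_records=int(x.sum()),
        significant=significant, flag=flag,
    )


def titan(
    table: pd.DataFrame,
    n_perm: int = 250,
    n_boot: int = 500,
    min_split: int = DEFAULT_MIN_SPLIT,
    seed: int = 0,
    selection: str = "z",
) -> list[TaxonThreshold]:
    """Run the per-taxon analysis on every column of a unit x taxon table."""
    gradient = table.index.get_level_values("gradient").to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    results = []
    for taxon in table.columns:
        results.append(
            taxon_titan(
                table[taxon].to_numpy(),
                gradient,
                taxon_id=str(taxon),
                n_perm=n_perm,
                n_boot=n_boot,
                min_split=min_split,
                seed=rng,
                selection=selection,
            )
        )
    return results


@dataclass
class CommunityThresholds:
    gradient: np.ndarray
    sum_z_neg: np.ndarray
    sum_z_pos: np.ndarray
    peak_neg: float | None
    peak_pos: float | None
    flags: list[str] = field(default_factory=list)


def community_thresholds(
    results: list[TaxonThreshold],
    candidates: np.ndarray | None = None,
    filter_significant: bool = True,
) -> CommunityThresholds:
    """Cumulative z-score sums of negative / positive responders.

    At each candidate gradient value the z-scores of responders whose
    change point lies at or before it are summed; the curves are step
    functions and their argmax marks the community threshold.  A
    direction with no responders yields an all-zero curve and an
    undefined (flagged) peak.
    """
    if not results:
        raise ValueError("no taxon results")
    used = [
        r for r in results
        if r.change_point is not None and np.isfinite(r.z)
        and (r.significant or not filter_significant)
    ]
    if candidates is None:
        cps = sorted({r.change_point for r in used})
        candidates = np.asarray(cps if cps else [0.0], dtype=float)
    sum_neg = np.zeros_like(candidates, dtype=float)
    sum_pos = np.zeros_like(candidates, dtype=float)
    for r in used:
        contrib = np.where(candidates >= r.change_point, max(r.z, 0.0), 0.0)
        if r.direction == "negative":
            sum_neg += contrib
        else:
            sum_pos += contrib
    flags = []
    peak_neg = float(candidates[np.argmax(sum_neg)]) if sum_neg.any() else None
    peak_pos = float(candidates[np.argmax(sum_pos)]) if sum_pos.any() else None
    if peak_neg is None:
        flags.append("no negative responders")
    if peak_pos is None:
        flags.append("no positive responders")
    return CommunityThresholds(
        gradient=np.asarray(candidates, dtype=float),
        sum_z_neg=sum_neg,
        sum_z_pos=sum_pos,
        peak_neg=peak_neg,
        peak_pos=peak_pos,
        flags=flags,
    )


def results_table(results: list[TaxonThreshold]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])
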