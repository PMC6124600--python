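"""Gaussian-kernel window smoothing with bootstrap empirical null.

The shared window engine behind both the F_ST scan (50 kb windows) and the
ARR scans (100 kb windows).  For each focal SNP the per-SNP statistic is
averaged over loci within ``window_bp`` of the focal position, weighted by a
Gaussian kernel with sigma = window_bp / 6 (so the window edge sits at three
sigma).  Significance comes from an empirical null: per replicate, values
are resampled with replacement from the genome-wide value vector and
re-smoothed at the original coordinates; the upper-tail P-value uses the
add-one estimator (1 + #{replicate >= observed}) / (n_reps + 1), so P is
never zero.  Windows never span scaffolds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class WindowResult:
    """Smoothed statistic and empirical P for one focal SNP."""

    locus_id: str
    scaffold: str
    position: int
    smoothed: float
    n_contributing: int
    p_value: float


def kernel_sigma(window_bp: int) -> float:
    """Kernel bandwidth: the half-window equals three sigma."""
    return window_bp / 6.0


def gaussian_smooth(
    values: np.ndarray,
    positions: np.ndarray,
    focal_index: int,
    window_bp: int,
) -> tuple[float, int]:
    """Kernel-smoothed value at one focal SNP on a single scaffold.

    Loci with |position - focal| <= window_bp / 2 contribute with weight
    exp(-d^2 / (2 sigma^2)); NaN values are dropped.  Returns
    ``(smoothed, n_contributing)``; ``(nan, 0)`` if no value survives.
    """
    values = np.asarray(values, dtype=float)
    positions = np.asarray(positions, dtype=float)
    half = window_bp / 2.0
    d = np.abs(positions - positions[focal_index])
    in_win = (d <= half) & np.isfinite(values)
    if not in_win.any():
        return float("nan"), 0
    sig = kernel_sigma(window_bp)
    w = np.exp(-(d[in_win] ** 2) / (2 * sig**2))
    return float(np.sum(w * values[in_win]) / np.sum(w)), int(in_win.sum())


def _window_members(positions: np.ndarray, window_bp: int):
    """Per-focal-locus (neighbor index array, kernel weight array).

    ``positions`` must be sorted; all loci share one scaffold.
    """
    half = window_bp / 2.0
    sig = kernel_sigma(window_bp)
    lo = np.searchsorted(positions, positions - half, side="left")
    hi = np.searchsorted(positions, positions + half, side="right")
    out = []
    for i in range(len(positions)):
        idx = np.arange(lo[i], hi[i])
        d = positions[idx] - positions[i]
        out.append((idx, np.exp(-(d**2) / (2 * sig**2))))
    return out


def bootstrap_window_pvalues(
    values: np.ndarray,
    loci: pd.DataFrame,
    window_bp: int,
    n_reps: int,
    seed: int,
    pool: np.ndarray | None = None,
) -> pd.DataFrame:
    """Smoothed statistic and bootstrap empirical P for every focal SNP.

    Parameters
    ----------
    values : per-locus statistic, aligned with ``loci`` rows; NaN allowed
        (those loci contribute neither to windows nor to the resampling pool).
    loci : DataFrame with locus_id, scaffold, position (sorted).
    window_bp : total window width in bp.
    n_reps : bootstrap replicates (>= 1).
    seed : RNG seed.
    pool : optional value vector to resample from instead of ``values``
        (e.g. the genome-wide statistic when smoothing is restricted to a
        scaffold subset); NaNs are dropped.

    Replicate values are drawn i.i.d. with replacement from the genome-wide
    pool of non-missing values and re-smoothed with the original window
    weights, which is distributionally equivalent, window by window, to
    resampling one full genome-wide vector per replicate.

    Returns a DataFrame: locus_id, scaffold, position, observed_smoothed,
    n_contributing, empirical_P (NaN rows for loci with empty windows).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    values = np.asarray(values, dtype=float)
    if len(values) != len(loci):
        raise ValueError("values length does not match loci")
    loci = loci.reset_index(drop=True)
    pool = values if pool is None else np.asarray(pool, dtype=float)
    pool = pool[np.isfinite(pool)]
    if pool.size == 0:
        raise ValueError("no non-missing values to smooth")

    rng = np.random.default_rng(seed)
    observed = np.full(len(values), np.nan)
    n_contrib = np.zeros(len(values), dtype=int)
    exceed = np.zeros(len(values), dtype=int)

    for scaffold, grp in loci.groupby("scaffold", sort=False):
        gidx = grp.index.to_numpy()
        pos = grp["position"].to_numpy(dtype=float)
        vals = values[gidx]
        finite = np.isfinite(vals)
        # drop missing loci from the coordinate frame: the resampled vector
        # replaces observed values at observed coordinates
        sub = np.where(finite)[0]
        if sub.size == 0:
            continue
        pos_f = pos[sub]
        vals_f = vals[sub]
        members = _window_members(pos_f, window_bp)
        for j, (idx, w) in enumerate(members):
            gi = gidx[sub[j]]
            wsum = w.sum()
            obs = float(np.dot(w, vals_f[idx]) / wsum)
            observed[gi] = obs
            n_contrib[gi] = len(idx)
            draws = pool[rng.integers(0, pool.size, size=(n_reps, len(idx)))]
            rep = draws @ w / wsum
            # tolerance so exact ties (e.g. constant input) count as exceedances
            tol = 1e-9 * max(1.0, abs(obs))
            exceed[gi] = int(np.count_nonzero(rep >= obs - tol))

    with np.errstate(invalid="ignore"):
        pvals = np.where(
            np.isfinite(observed), (1.0 + exceed) / (n_reps + 1.0), np.nan
        )
    return pd.DataFrame(
        {
            "locus_id": loci["locus_id"].to_numpy(),
            "scaffold": loci["scaffold"].to_numpy(),
            "position": loci["position"].to_numpy(),
            "observed_smoothed": observed,
            "n_contributing": n_contrib,
            "empirical_P": pvals,
        }
    )


def significant_windows(
    results: list[pd.DataFrame] | pd.DataFrame, p_threshold: float
) -> set[str]:
    """Loci whose window P < threshold (strict) in at least one scan.

    ``results`` is one or several frames from
    :func:`bootstrap_window_pvalues`; the union over scans implements the
    "significant in at least one pairwise comparison" rule.
    """
    if isinstance(results, pd.DataFrame):
        results = [results]
    out: set[str] = set()
    for df in results:
        hit = df["empirical_P"] < p_threshold
        out.update(df.loc[hit.fillna(False), "locus_id"])
    return out
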