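"""Average relative rank (ARR) aggregation of replicate stochastic runs.

MCMC-based per-locus statistics (XtX, Bayes factors) vary from run to run;
ranking each run separately and averaging the ranks tames that Monte-Carlo
noise.  Within a run, the locus with the highest statistic gets relative
rank 1 and the lowest gets 1/N (N = loci with a non-missing score); ties
share the count-based rank #{score_j <= score_i} / N.  The ARR is the
per-locus mean rank across runs, reported with its standard deviation
(descriptive only -- selection uses the ARR alone).

Candidates are loci with ARR at or above the 95th percentile of the
genome-wide ARR distribution; the scan variant additionally requires the
kernel-smoothed ARR window centred on the locus to beat a permutation null
(both criteria must hold).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import smooth_boot
from .diff_scan import ScoreTable


@dataclass
class ARRTable:
    """Per-run relative ranks with their per-locus mean (ARR) and sd."""

    loci: pd.DataFrame
    ranks: np.ndarray  # (N_total, R); NaN where score missing
    arr: np.ndarray
    rank_sd: np.ndarray
    n_ranked: int  # N used in the 1/N..1 scale
    method: str = ""

    def to_frame(self) -> pd.DataFrame:
        df = self.loci[["locus_id", "scaffold", "position"]].copy()
        df["ARR"] = self.arr
        df["rank_sd"] = self.rank_sd
        return df


def relative_ranks(scores: np.ndarray) -> np.ndarray:
    """Relative rank #{j : score_j <= score_i} / N, NaN scores excluded.

    N counts non-missing scores only; the unique maximum maps to 1 and a
    unique minimum to 1/N.
    """
    scores = np.asarray(scores, dtype=float)
    finite = np.isfinite(scores)
    n = int(finite.sum())
    if n == 0:
        raise ValueError("all scores missing; nothing to rank")
    out = np.full(scores.shape, np.nan)
    vals = scores[finite]
    order = np.sort(vals)
    # count of values <= own == index past the last occurrence in sorted order
    out[finite] = np.searchsorted(order, vals, side="right") / n
    return out


def arr(score_table: ScoreTable) -> ARRTable:
    """Per-run relative ranks, their mean (ARR) and sample sd across runs.

    Runs whose scores are entirely missing are dropped with a warning;
    at least two usable runs are required.
    """
    if score_table.n_runs < 2:
        raise ValueError("ARR needs >= 2 replicate runs")
    cols = []
    for r in range(score_table.n_runs):
        col = score_table.scores[:, r]
        if not np.isfinite(col).any():
            import warnings

            warnings.warn(f"run {r} of {score_table.method} all-missing; dropped")
            continue
        cols.append(relative_ranks(col))
    if len(cols) < 2:
        raise ValueError("fewer than 2 usable runs after dropping all-missing columns")
    ranks = np.column_stack(cols)
    n_ranked = int(np.isfinite(ranks[:, 0]).sum())
    return ARRTable(
        loci=score_table.loci,
        ranks=ranks,
        arr=np.nanmean(ranks, axis=1),
        rank_sd=np.nanstd(ranks, axis=1, ddof=1),
        n_ranked=n_ranked,
        method=score_table.method,
    )


def percentile_threshold(arr_values: np.ndarray, percentile: float) -> float:
    """Linear-interpolation percentile of the non-missing ARR distribution."""
    if not 0 < percentile < 100:
        raise ValueError("percentile must lie in (0, 100)")
    vals = arr_values[np.isfinite(arr_values)]
    if vals.size == 0:
        raise ValueError("empty ARR table")
    return float(np.percentile(vals, percentile))


def select_candidates(arr_table: ARRTable, percentile: float = 95.0) -> set[str]:
    """Loci with ARR >= the given genome-wide percentile (inclusive)."""
    if arr_table.n_ranked < 20:
        import warnings

        warnings.warn("fewer than 20 ranked loci; percentile selection is coarse")
    thr = percentile_threshold(arr_table.arr, percentile)
    hit = arr_table.arr >= thr
    return set(arr_table.loci.loc[hit, "locus_id"])


def arr_scan(
    arr_table: ARRTable,
    window_bp: int = 100_000,
    n_reps: int = 10_000,
    p_threshold: float = 0.005,
    percentile: float = 95.0,
    seed: int = 0,
) -> tuple[set[str], pd.DataFrame]:
    """Joint percentile + smoothed-window criterion over the ARR.

    Smoothing and the permutation null are restricted to scaffolds that
    carry at least one locus in the ARR percentile (the genome-wide
    percentile is computed first); a locus is selected when it is itself in
    the percentile AND is centred in a window with empirical P below the
    threshold (strict).  Returns the selected locus set and the full
    per-locus window table (with ``in_95th`` and ``selected`` flags).
    """
    top = select_candidates(arr_table, percentile)
    loci = arr_table.loci
    top_scaffolds = set(loci.loc[loci["locus_id"].isin(top), "scaffold"])
    on_scf = loci["scaffold"].isin(top_scaffolds).to_numpy()

    out = loci[["locus_id", "scaffold", "position"]].copy()
    out["ARR"] = arr_table.arr
    out["rank_sd"] = arr_table.rank_sd
    out["in_95th"] = loci["locus_id"].isin(top)
    out["smoothed_ARR"] = np.nan
    out["window_P"] = np.nan

    if on_scf.any():
        win = smooth_boot.bootstrap_window_pvalues(
            values=arr_table.arr[on_scf],
            loci=loci.loc[on_scf],
            window_bp=window_bp,
            n_reps=n_reps,
            seed=seed,
            pool=arr_table.arr,  # permutation pool spans the entire dataset
        )
        out.loc[on_scf, "smoothed_ARR"] = win["observed_smoothed"].to_numpy()
        out.loc[on_scf, "window_P"] = win["empirical_P"].to_numpy()

    out["selected"] = out["in_95th"] & (out["window_P"] < p_threshold).fillna(False)
    return set(out.loc[out["selected"], "locus_id"]), out
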