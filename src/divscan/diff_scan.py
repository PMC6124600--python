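"""Per-locus and global pairwise F_ST (Weir & Cockerham 1984 theta).

Theta is computed from the a/b/c variance components (among populations,
among individuals within populations, within individuals), using observed
genotype counts only.  Negative per-locus estimates are retained; loci that
are monomorphic across the pair, or observed in fewer than two alleles in
either population, are left missing.  The global estimate is the
ratio-of-sums estimator sum(a) / sum(a+b+c).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix


@dataclass
class ScoreTable:
    """Per-locus values of one statistic, one column per replicate run.

    ``method`` is a label such as ``"fst_pair(A,B)"``, ``"xtx"`` or
    ``"env_bf(trait)"``.  F_ST tables have exactly one column; MCMC-based
    statistics carry one column per independent run.  Row order matches the
    source :class:`~divscan.genotype_io.GenotypeMatrix` locus order.
    ``components`` holds auxiliary per-locus arrays (e.g. the W&C variance
    components used by the ratio-of-sums global estimator).
    """

    loci: pd.DataFrame
    method: str
    scores: np.ndarray  # (n_loci, n_runs), NaN where undefined
    components: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.scores = np.atleast_2d(np.asarray(self.scores, dtype=float))
        if self.scores.shape[0] == 1 and len(self.loci) != 1:
            self.scores = self.scores.T
        if self.scores.shape[0] != len(self.loci):
            raise ValueError("scores row count does not match loci")
        if self.scores.shape[1] < 1:
            raise ValueError("ScoreTable needs >=1 run column")

    @property
    def n_runs(self) -> int:
        return self.scores.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = self.loci[["locus_id", "scaffold", "position"]].copy()
        for r in range(self.n_runs):
            df[f"{self.method}_run{r}" if self.n_runs > 1 else self.method] = (
                self.scores[:, r]
            )
        return df


def _wc_components(
    n_ind: np.ndarray, p: np.ndarray, het: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Weir & Cockerham (1984) a, b, c for r populations, vectorised over loci.

    Parameters are per-locus arrays of shape (L, r): sample sizes in diploid
    individuals, alt-allele frequencies, and observed heterozygote
    proportions.
    """
    r = n_ind.shape[1]
    nbar = n_ind.mean(axis=1)
    # squared-coefficient-of-variation correction term
    nc = (r * nbar - (n_ind**2).sum(axis=1) / (r * nbar)) / (r - 1)
    pbar = (n_ind * p).sum(axis=1) / (r * nbar)
    s2 = (n_ind * (p - pbar[:, None]) ** 2).sum(axis=1) / ((r - 1) * nbar)
    hbar = (n_ind * het).sum(axis=1) / (r * nbar)

    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    return a, b, c


def pairwise_fst(gm: GenotypeMatrix, pop_a: str, pop_b: str) -> ScoreTable:
    """Per-locus Weir & Cockerham theta between two populations.

    Loci monomorphic across the pair, or with fewer than two observed
    alleles (one genotyped individual) in either population, score NaN.
    The variance components a and a+b+c are stored in ``components`` for
    :func:`global_fst`.
    """
    if pop_a == pop_b:
        raise ValueError("pop_a and pop_b must differ")
    idx_a = gm.pop_sample_indices(pop_a)
    idx_b = gm.pop_sample_indices(pop_b)

    obs = gm.dosage != MISSING
    dos = gm.dosage.astype(float)

    def pop_stats(idx):
        o = obs[:, idx]
        d = np.where(o, dos[:, idx], 0.0)
        n_ind = o.sum(axis=1).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = d.sum(axis=1) / (2 * n_ind)
            het = np.where(o, dos[:, idx] == 1, False).sum(axis=1) / n_ind
        return n_ind, p, het

    na, pa, ha = pop_stats(idx_a)
    nb, pb, hb = pop_stats(idx_b)

    n_ind = np.stack([na, nb], axis=1)
    p = np.stack([pa, pb], axis=1)
    het = np.stack([ha, hb], axis=1)

    scorable = (na >= 1) & (nb >= 1) & (n_ind.mean(axis=1) > 1)
    pbar = np.where(scorable, (n_ind * p).sum(axis=1) / n_ind.sum(axis=1), np.nan)
    polymorphic = scorable & (pbar > 0) & (pbar < 1)

    a = np.full(gm.n_loci, np.nan)
    b = np.full(gm.n_loci, np.nan)
    c = np.full(gm.n_loci, np.nan)
    if polymorphic.any():
        sel = polymorphic
        a[sel], b[sel], c[sel] = _wc_components(n_ind[sel], p[sel], het[sel])

    with np.errstate(invalid="ignore", divide="ignore"):
        theta = a / (a + b + c)
    return ScoreTable(
        loci=gm.loci,
        method=f"fst_pair({pop_a},{pop_b})",
        scores=theta[:, None],
        components={"numerator": a, "denominator": a + b + c},
    )


def global_fst(score_table: ScoreTable) -> dict[str, float]:
    """Multilocus F_ST from a pairwise table.

    Returns the ratio-of-sums estimator (sum of a over sum of a+b+c across
    scorable loci) together with the simple mean of per-locus theta and the
    scorable locus count.
    """
    num = score_table.components.get("numerator")
    den = score_table.components.get("denominator")
    if num is None or den is None:
        raise ValueError("score table lacks variance components (not an F_ST table?)")
    ok = np.isfinite(num) & np.isfinite(den)
    if not ok.any():
        raise ValueError("no scorable loci for global F_ST")
    theta = score_table.scores[:, 0]
    return {
        "fst_ratio_of_sums": float(num[ok].sum() / den[ok].sum()),
        "fst_mean_per_locus": float(np.nanmean(theta)),
        "n_loci": int(ok.sum()),
    }


def all_pairwise_fst(gm: GenotypeMatrix) -> dict[tuple[str, str], ScoreTable]:
    """F_ST tables for every unordered population pair, in sorted label order."""
    pops = gm.pop_labels
    return {
        (a, b): pairwise_fst(gm, a, b)
        for i, a in enumerate(pops)
        for b in pops[i + 1 :]
    }
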