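"""Hierarchical population allele-frequency model: Omega, XtX and Bayes factors.

The model (the Coop et al. class of genotype--environment association
models): at locus i with ancestral frequency a_i, the standardized deviation
vector of population allele frequencies

    x_i ~ MVN(beta_i * env, Omega),      p_ik = a_i + sqrt(a_i (1 - a_i)) x_ik

with observed alternate-allele counts Binomial(n_ik, p_ik).  Omega is the
K x K covariance of standardized frequencies across populations, shared by
all loci; it absorbs shared drift/population history.  The differentiation
statistic XtX is the posterior mean of x' Omega^-1 x (large values flag loci
whose population frequencies deviate more than history explains; its null
expectation is around K).  With a standardized per-population covariate
``env``, the Bayes factor compares the linear-effect model (beta with a
zero-centred normal prior) against beta = 0, via the Savage--Dickey density
ratio with a Rao-Blackwellized posterior-density estimate.

Two numerical choices matter for unbiased covariance recovery:

* the latent x is *unbounded* and the frequency is censored into [0, 1]
  inside the binomial likelihood only (a Tobit-style device).  Truncating x
  itself would make the inverse-Wishart update ignore a truncation
  normalizer and visibly deflate Omega for loci near fixation;
* with a free per-locus ancestral frequency, the component of Omega along
  ones*ones' is a gauge freedom (a common shift of x trades off against
  a_i).  Estimates are therefore gauge-fixed to the minimal-off-diagonal
  representative of the equivalence class Omega + v 1' + 1 v'
  (:func:`canonicalize_omega`), which maps the projected estimate back to
  F I exactly when the populations are exchangeable and independent.

Sampling is Metropolis-within-Gibbs, vectorised across loci (loci are
conditionally independent given Omega): random-walk updates of x_ik and
a_i, conjugate Gibbs draws of beta_i, and -- when Omega itself is estimated
-- a conjugate inverse-Wishart draw of Omega.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .diff_scan import ScoreTable
from .genotype_io import GenotypeMatrix, allele_frequencies

logger = logging.getLogger(__name__)

_EPS_A = 1e-3  # bounds for the ancestral frequency
_EPS_P = 1e-6  # censoring bound for the binomial success probability


@dataclass
class CovarianceMatrix:
    """Population covariance Omega with estimation provenance."""

    omega: np.ndarray
    pops: list[str]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.omega = np.asarray(self.omega, dtype=float)
        K = len(self.pops)
        if self.omega.shape != (K, K):
            raise ValueError("Omega shape does not match population count")
        if not np.allclose(self.omega, self.omega.T, atol=1e-8):
            raise ValueError("Omega must be symmetric")
        if np.any(np.linalg.eigvalsh(self.omega) <= 0):
            raise ValueError("Omega must be positive definite")

    def to_text(self, path) -> None:
        """Whitespace-separated K x K matrix, no header (Bayenv dialect)."""
        np.savetxt(path, self.omega, fmt="%.10g")

    @classmethod
    def from_text(cls, path, pops: list[str]) -> "CovarianceMatrix":
        return cls(omega=np.loadtxt(path), pops=list(pops))


@dataclass
class StandardizedEnv:
    """A per-population covariate standardized to mean 0, sample sd 1."""

    trait: str
    values: np.ndarray  # aligned with a population-label order
    pops: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.pops):
            raise ValueError("env length does not match population count")
        if abs(self.values.mean()) > 1e-12 or abs(self.values.std(ddof=1) - 1) > 1e-12:
            raise ValueError("env not standardized to mean 0 / sample sd 1")


@dataclass
class LocusModelState:
    """Posterior summaries for one locus under one run."""

    abar: float
    x: np.ndarray
    xtx: float
    log10_bf: float | None


def standardize_env(trait_table, trait: str, pops: list[str]) -> StandardizedEnv:
    """Standardize one trait column: (v - mean) / sample (n-1) sd.

    ``trait_table`` is a population-indexed DataFrame
    (:func:`divscan.genotype_io.read_trait_table`); values are taken in the
    order of ``pops``.
    """
    v = np.asarray([float(trait_table.loc[p, trait]) for p in pops])
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValueError(f"trait {trait!r} has zero variance across populations")
    return StandardizedEnv(trait=trait, values=(v - v.mean()) / sd, pops=list(pops))


def nearest_positive_definite(m: np.ndarray, floor: float = 1e-8) -> np.ndarray:
    """Project a symmetric matrix to the PD cone by eigenvalue clipping."""
    m = (m + m.T) / 2
    w, v = np.linalg.eigh(m)
    w = np.maximum(w, floor * max(w.max(), 1.0))
    return (v * w) @ v.T


def canonicalize_omega(omega: np.ndarray) -> np.ndarray:
    """Gauge-fix Omega to the minimal-off-diagonal representative.

    With a free per-locus ancestral frequency the model identifies Omega
    only up to Omega + v 1' + 1 v'; this picks the class member minimizing
    the off-diagonal Frobenius norm (for K = 2 the symmetric member with a
    zero off-diagonal).
    """
    m = np.asarray(omega, dtype=float)
    K = m.shape[0]
    r = m.sum(axis=1) - m.diagonal()  # off-diagonal row sums
    if K == 2:
        v = np.full(2, -m[0, 1] / 2.0)
    else:
        S = -r.sum() / (2 * K - 2)
        v = -(r + S) / (K - 2)
    return m + v[:, None] + v[None, :]


def _counts(gm: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    freq, n_alleles = allele_frequencies(gm)
    alt = np.where(n_alleles > 0, np.round(freq * n_alleles), 0.0)
    return alt, n_alleles.astype(float)


class _Sampler:
    """Metropolis-within-Gibbs over (x, abar[, beta]), vectorised over loci.

    The latent x is unbounded; the binomial success probability is
    clip(abar + s * x, eps, 1 - eps).  Omega stays fixed within the sampler;
    callers estimating Omega alternate sweeps with conjugate
    inverse-Wishart draws via :meth:`set_omega`.
    """

    def __init__(self, alt, tot, omega, env=None, beta_prior_sd=1.0, seed=0):
        self.alt = np.asarray(alt, dtype=float)
        self.tot = np.asarray(tot, dtype=float)
        self.L, self.K = self.alt.shape
        self.rng = np.random.default_rng(seed)
        self.env = None if env is None else np.asarray(env, dtype=float)
        self.beta_sd = float(beta_prior_sd)

        self.set_omega(np.asarray(omega, dtype=float))

        pooled = (self.alt.sum(axis=1) + 1.0) / (self.tot.sum(axis=1) + 2.0)
        self.abar = np.clip(pooled, _EPS_A, 1 - _EPS_A)
        self.s = np.sqrt(self.abar * (1 - self.abar))
        with np.errstate(invalid="ignore", divide="ignore"):
            f_obs = (self.alt + 0.5) / np.maximum(self.tot + 1.0, 1.0)
        f_obs = np.where(self.tot > 0, f_obs, self.abar[:, None])
        self.x = (f_obs - self.abar[:, None]) / self.s[:, None]
        self.beta = np.zeros(self.L)

        self.step_x = np.full(self.K, 0.4)
        self.step_a = 0.05
        self._acc_x = np.zeros(self.K)
        self._acc_a = 0.0

    # -- helpers ----------------------------------------------------------
    def set_omega(self, omega):
        self.omega = omega
        self.lam = np.linalg.inv(omega)
        if self.env is not None and self.beta_sd > 0:
            elam = self.env @ self.lam
            self.beta_var = 1.0 / (1.0 / self.beta_sd**2 + elam @ self.env)
            self.elam = elam

    @property
    def e(self):
        """Residual deviations entering the Omega likelihood."""
        if self.env is None:
            return self.x
        return self.x - self.beta[:, None] * self.env[None, :]

    def _loglik_col(self, xcol, k, abar=None, s=None):
        abar = self.abar if abar is None else abar
        s = self.s if s is None else s
        p = np.clip(abar + s * xcol, _EPS_P, 1 - _EPS_P)
        return self.alt[:, k] * np.log(p) + (self.tot[:, k] - self.alt[:, k]) * np.log1p(-p)

    # -- updates ----------------------------------------------------------
    def _update_x(self):
        bshift = 0.0 if self.env is None else self.beta
        for k in range(self.K):
            prop = self.x[:, k] + self.rng.normal(0, self.step_x[k], self.L)
            d_lik = self._loglik_col(prop, k) - self._loglik_col(self.x[:, k], k)
            mean_k = bshift * self.env[k] if self.env is not None else 0.0
            ek_new = prop - mean_k
            ek = self.x[:, k] - mean_k
            e = self.e
            cross = e @ self.lam[:, k] - self.lam[k, k] * e[:, k]
            d_pri = -0.5 * self.lam[k, k] * (ek_new**2 - ek**2) - (ek_new - ek) * cross
            acc = np.log(self.rng.uniform(size=self.L)) < d_lik + d_pri
            self.x[acc, k] = prop[acc]
            self._acc_x[k] += acc.mean()

    def _update_abar(self):
        prop = self.abar + self.rng.normal(0, self.step_a, self.L)
        ok = (prop > _EPS_A) & (prop < 1 - _EPS_A)
        prop_c = np.clip(prop, _EPS_A, 1 - _EPS_A)
        s_new = np.sqrt(prop_c * (1 - prop_c))
        d_lik = np.zeros(self.L)
        for k in range(self.K):
            d_lik += self._loglik_col(self.x[:, k], k, prop_c, s_new)
            d_lik -= self._loglik_col(self.x[:, k], k)
        # Beta(1,1) prior is flat; x is the free parameter, so no Jacobian
        acc = ok & (np.log(self.rng.uniform(size=self.L)) < d_lik)
        self.abar[acc] = prop_c[acc]
        self.s[acc] = s_new[acc]
        self._acc_a += acc.mean()

    def _update_beta(self):
        m = self.beta_var * (self.x @ self.elam)
        self.beta = m + self.rng.normal(0, np.sqrt(self.beta_var), self.L)

    def _adapt(self, block: int):
        for k in range(self.K):
            rate = self._acc_x[k] / block
            self.step_x[k] = float(np.clip(self.step_x[k] * np.exp(rate - 0.3), 0.02, 2.0))
        rate_a = self._acc_a / block
        self.step_a = float(np.clip(self.step_a * np.exp(rate_a - 0.3), 0.005, 0.5))
        self._acc_x[:] = 0.0
        self._acc_a = 0.0

    def sweep(self):
        self._update_x()
        self._update_abar()
        if self.env is not None and self.beta_sd > 0:
            self._update_beta()


def score_loci(
    alt: np.ndarray,
    tot: np.ndarray,
    omega: CovarianceMatrix,
    env: StandardizedEnv | None = None,
    beta_prior_sd: float = 1.0,
    n_iter: int = 2000,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Posterior XtX (and log10 Bayes factors) for all loci under fixed Omega.

    ``alt``/``tot`` are (L, K) alternate and total observed allele counts in
    the population order of ``omega.pops``.  The first half of ``n_iter``
    sweeps is burn-in (with step-size adaptation); the second half is
    averaged.  With ``env``, log10 BF is returned alongside XtX; a
    zero-variance effect prior collapses the alternative onto the null, so
    BF = 1 exactly.
    """
    alt = np.atleast_2d(np.asarray(alt, dtype=float))
    tot = np.atleast_2d(np.asarray(tot, dtype=float))
    K = len(omega.pops)
    if alt.shape[1] != K or tot.shape != alt.shape:
        raise ValueError("count arrays do not match Omega dimension")
    if np.any((tot > 0).sum(axis=1) < 2):
        raise ValueError("every locus needs observed alleles in >=2 populations")

    degenerate_bf = env is not None and beta_prior_sd == 0
    smp = _Sampler(
        alt, tot, omega.omega,
        env=None if degenerate_bf else (env.values if env is not None else None),
        beta_prior_sd=beta_prior_sd, seed=seed,
    )
    burn = max(n_iter // 2, 1)
    keep = max(n_iter - burn, 1)
    xtx_acc = np.zeros(smp.L)
    abar_acc = np.zeros(smp.L)
    x_acc = np.zeros((smp.L, smp.K))
    dens0_acc = np.zeros(smp.L)
    for t in range(n_iter):
        smp.sweep()
        if t < burn:
            if (t + 1) % 50 == 0:
                smp._adapt(50)
            continue
        xtx_acc += np.einsum("ij,jk,ik->i", smp.x, smp.lam, smp.x)
        abar_acc += smp.abar
        x_acc += smp.x
        if smp.env is not None:
            m = smp.beta_var * (smp.x @ smp.elam)
            dens0_acc += stats.norm.pdf(0.0, loc=m, scale=np.sqrt(smp.beta_var))

    out = {
        "xtx": xtx_acc / keep,
        "abar": abar_acc / keep,
        "x_mean": x_acc / keep,
    }
    if env is not None:
        if degenerate_bf:
            out["log10_bf"] = np.zeros(smp.L)
        else:
            prior0 = stats.norm.pdf(0.0, scale=beta_prior_sd)
            post0 = np.maximum(dens0_acc / keep, 1e-300)
            out["log10_bf"] = np.log10(prior0 / post0)
    return out


def score_locus(
    counts_alt,
    counts_tot,
    omega: CovarianceMatrix,
    env: StandardizedEnv | None = None,
    beta_prior_sd: float = 1.0,
    mcmc_iterations: int = 4000,
    seed: int = 0,
) -> LocusModelState:
    """Single-locus surface over :func:`score_loci`."""
    res = score_loci(
        np.asarray(counts_alt, dtype=float)[None, :],
        np.asarray(counts_tot, dtype=float)[None, :],
        omega, env=env, beta_prior_sd=beta_prior_sd,
        n_iter=mcmc_iterations, seed=seed,
    )
    return LocusModelState(
        abar=float(res["abar"][0]),
        x=res["x_mean"][0],
        xtx=float(res["xtx"][0]),
        log10_bf=float(res["log10_bf"][0]) if env is not None else None,
    )


def estimate_covariance(
    gm: GenotypeMatrix,
    n_subsets: int = 10,
    subset_size: int = 5000,
    n_iter: int = 2000,
    seed: int = 0,
) -> CovarianceMatrix:
    """Estimate Omega by MCMC over random SNP subsets and average the runs.

    Each subset runs the full model with a conjugate inverse-Wishart update
    of Omega each sweep (prior IW(K+2, 0.01 I), washed out by the data).
    Kept draws are gauge-fixed with :func:`canonicalize_omega`; the
    per-subset posterior mean is recorded along with a convergence
    diagnostic (relative Frobenius change between the two halves of the
    kept sweeps) and the element-wise posterior standard deviation.  The
    final Omega is the element-wise mean across subsets, repaired to the
    nearest PD matrix if numerically indefinite.
    """
    pops = gm.pop_labels
    K = len(pops)
    alt_all, tot_all = _counts(gm)
    rng = np.random.default_rng(seed)
    if gm.n_loci < subset_size:
        logger.info(
            "estimate_covariance: only %d loci (< subset_size %d); using all",
            gm.n_loci, subset_size,
        )
        subset_size = gm.n_loci

    nu0 = K + 2
    psi0 = 0.01 * np.eye(K)
    omegas = []
    diags = []
    post_sds = []
    for s_i in range(n_subsets):
        idx = rng.choice(gm.n_loci, size=subset_size, replace=False)
        alt, tot = alt_all[idx], tot_all[idx]
        # moment initialisation from observed standardized deviations
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(tot > 0, alt / np.maximum(tot, 1), np.nan)
        ab = np.clip(np.nanmean(f, axis=1), _EPS_A, 1 - _EPS_A)
        x0 = (np.nan_to_num(f, nan=0.5) - ab[:, None]) / np.sqrt(ab * (1 - ab))[:, None]
        omega0 = nearest_positive_definite(np.cov(x0.T) + 0.01 * np.eye(K))

        smp = _Sampler(alt, tot, omega0, seed=int(rng.integers(2**31)))
        burn = max(n_iter // 2, 1)
        kept = []
        for t in range(n_iter):
            smp.sweep()
            scale = psi0 + smp.e.T @ smp.e
            omega_t = stats.invwishart.rvs(
                df=nu0 + smp.L, scale=scale, random_state=smp.rng
            )
            smp.set_omega(np.atleast_2d(omega_t))
            if t < burn:
                if (t + 1) % 50 == 0:
                    smp._adapt(50)
            else:
                kept.append(canonicalize_omega(omega_t))
        kept = np.asarray(kept)
        post_mean = kept.mean(axis=0)
        half = len(kept) // 2
        h1, h2 = kept[:half].mean(axis=0), kept[half:].mean(axis=0)
        diags.append(float(np.linalg.norm(h2 - h1) / np.linalg.norm(post_mean)))
        post_sds.append(kept.std(axis=0))
        omegas.append(post_mean)

    omega = np.mean(omegas, axis=0)
    omega = (omega + omega.T) / 2
    if np.any(np.linalg.eigvalsh(omega) <= 0):
        logger.warning("estimate_covariance: repairing non-PD Omega")
        omega = nearest_positive_definite(omega)
    return CovarianceMatrix(
        omega=omega,
        pops=pops,
        provenance={
            "n_subsets": n_subsets,
            "subset_size": subset_size,
            "n_iter": n_iter,
            "rel_frobenius_change": diags,
            "posterior_sd": np.mean(post_sds, axis=0),
            "between_subset_sd": np.std(omegas, axis=0),
        },
    )


def run_replicates(
    gm: GenotypeMatrix,
    omega: CovarianceMatrix,
    env: StandardizedEnv | None = None,
    n_runs: int = 20,
    n_iter: int = 2000,
    beta_prior_sd: float = 1.0,
    seed: int = 0,
) -> ScoreTable:
    """Independent replicate scoring runs: XtX (no env) or log10 BF columns.

    Run r uses seed ``seed + r``; replicate-to-replicate spread is what the
    rank-aggregation (ARR) stage averages over.  Loci should be pre-filtered
    to the minimum per-population sample size
    (:func:`divscan.genotype_io.apply_locus_filters`).
    """
    if n_runs < 2:
        raise ValueError("need >= 2 replicate runs for rank aggregation")
    alt, tot = _counts(gm)
    cols = []
    for r in range(n_runs):
        res = score_loci(
            alt, tot, omega, env=env, beta_prior_sd=beta_prior_sd,
            n_iter=n_iter, seed=seed + r,
        )
        cols.append(res["log10_bf"] if env is not None else res["xtx"])
    method = f"env_bf({env.trait})" if env is not None else "xtx"
    return ScoreTable(loci=gm.loci, method=method, scores=np.column_stack(cols))
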