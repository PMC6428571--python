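"""Tests of polygenic-score differentiation against the neutral-drift null.

Under neutral drift the vector of centered population scores is
multivariate normal with covariance proportional to ``F``, the
across-population covariance of standardized allele-frequency deviations.
On the allele-frequency scale used throughout this package
(``Z = Σ β p``, ``V_A = Σ β² p̄(1 − p̄)``, ``Var(p) = p̄(1 − p̄) F``) that
null is ``Z ~ MVN(0, V_A F)``.  The familiar ``2 V_A F`` form is the same
statistic written for diploid-coded scores (``Z = 2Σβp`` with
``V_A = 2Σβ²p̄(1 − p̄)``); the quadratic form is identical under the change
of scale, and only the frequency-scale form is internally consistent with
the drift model above — it is what makes Qx chi-square with M − 1 degrees
of freedom under the null.  The latitude statistic contrasts scores along
a latitude vector, ``YᵀZ ~ N(0, V_A YᵀFY)``.

``F`` is estimated from putatively neutral ("null") SNPs, never from the
trait-ascertained SNPs themselves.  An empirical null can also be formed by
re-ascertaining random (optionally frequency-matched) SNP sets and
recomputing Qx with the same effect-size routing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import FrequencyTable, QxResult, ScoreResult
from .scores import score_populations

logger = logging.getLogger(__name__)

RANK_TOL = 1e-9


def estimate_F(
    null_freqs: FrequencyTable,
    ancestral_freq: pd.Series | None = None,
    min_snps: int = 100,
) -> np.ndarray:
    """Estimate the drift covariance F̂ from null SNPs.

    Per SNP, the outer product of frequency deviations from ``p̄`` is scaled
    by ``p̄(1 − p̄)`` and averaged; the result is symmetrized and projected
    to the PSD cone (negative eigenvalues clipped at zero, clip magnitude
    logged).  ``p̄`` is the across-population mean unless ``ancestral_freq``
    supplies known ancestral frequencies — with the mean, the estimator
    recovers the mean-centered kernel T F Tᵀ, which is all the Qx and
    latitude statistics use; with the true ancestral frequencies it is
    unbiased for F itself.  Monomorphic SNPs (p̄ ∈ {0, 1}) are dropped.
    """
    p = null_freqs.freq.to_numpy(float)
    if ancestral_freq is None:
        p_bar = p.mean(axis=1)
    else:
        p_bar = ancestral_freq.reindex(null_freqs.freq.index).to_numpy(float)
    poly = (p_bar > 0) & (p_bar < 1)
    n_mono = int((~poly).sum())
    if n_mono:
        logger.info("%d monomorphic SNPs dropped from F estimation", n_mono)
    p, p_bar = p[poly], p_bar[poly]
    if len(p) == 0:
        raise ValueError("no polymorphic SNPs to estimate F from")
    if len(p) < min_snps:
        logger.warning("only %d null SNPs for F estimation (< %d recommended)",
                       len(p), min_snps)

    d = (p - p_bar[:, None]) / np.sqrt(p_bar * (1.0 - p_bar))[:, None]
    F = d.T @ d / len(p)
    F = (F + F.T) / 2.0
    evals, evecs = np.linalg.eigh(F)
    if evals.min() < 0:
        logger.info("PSD projection clipped eigenvalues by %.3g", -evals.min())
        F = (evecs * np.clip(evals, 0.0, None)) @ evecs.T
        F = (F + F.T) / 2.0
    return F


def _centered_kernel(F: np.ndarray) -> np.ndarray:
    M = F.shape[0]
    T = np.eye(M) - np.ones((M, M)) / M
    return T @ F @ T.T


def qx_test(scores: ScoreResult, F_hat: np.ndarray,
            v_a: float | None = None) -> QxResult:
    """Qx overdispersion statistic on the centered (M−1)-dim contrast space.

    ``Qx = Z̃ᵀ (V_A T F̂ Tᵀ)⁺ Z̃`` with ``Z̃`` the mean-centered scores and
    ``⁺`` the pseudo-inverse restricted to the kernel's numerical rank;
    P is the upper chi-square tail with dof equal to that rank (M − 1 for a
    full-rank F̂).
    """
    M = len(scores.populations)
    if M < 2:
        raise ValueError("Qx needs >= 2 populations")
    v_a = scores.v_a if v_a is None else v_a
    z = scores.z.to_numpy(float)
    z_t = z - z.mean()

    K = v_a * _centered_kernel(np.asarray(F_hat, float))
    evals, evecs = np.linalg.eigh(K)
    tol = RANK_TOL * max(evals.max(), 0.0) if evals.max() > 0 else np.inf
    keep = evals > tol
    rank = int(keep.sum())
    if rank == 0:
        raise ValueError("drift kernel has rank 0; Qx undefined")
    if rank < M - 1:
        logger.warning("drift kernel rank %d < M-1 = %d; dof reduced",
                       rank, M - 1)
    proj = evecs[:, keep].T @ z_t
    qx = float(proj @ (proj / evals[keep]))
    p_qx = float(stats.chi2.sf(qx, df=rank))
    return QxResult(qx=qx, dof=rank, p_qx=p_qx, v_a=v_a,
                    f_hat=np.asarray(F_hat, float))


def latitude_test(
    scores: ScoreResult, F_hat: np.ndarray, Y: np.ndarray,
    v_a: float | None = None,
) -> tuple[float, float]:
    """Latitude-cline statistic ``t = YᵀZ / √(V_A YᵀF̂Y)``, two-sided P.

    ``Y`` is mean-centered internally and must have ≥2 distinct values.
    """
    Y = np.asarray(Y, dtype=float)
    if len(np.unique(Y)) < 2:
        raise ValueError("latitudes must take >= 2 distinct values")
    v_a = scores.v_a if v_a is None else v_a
    yc = Y - Y.mean()
    z = scores.z.to_numpy(float)
    var = v_a * float(yc @ np.asarray(F_hat, float) @ yc)
    if var <= 0:
        raise ValueError("YᵀF̂Y <= 0: latitude variance non-positive")
    t = float(yc @ (z - z.mean())) / np.sqrt(var)
    p = float(2.0 * stats.norm.sf(abs(t)))
    return t, p


@dataclass
class EmpiricalNullResult:
    empirical_p: float
    null_qx: np.ndarray
    null_p: np.ndarray
    ks_stat: float
    ks_p: float


def empirical_qx_null(
    sumstats: pd.DataFrame,
    freqs: FrequencyTable,
    observed_qx: float,
    observed_ids=None,
    ascertainment_size: int | None = None,
    n_draws: int = 500,
    seed: int = 0,
    frequency_match: bool = False,
    F_hat: np.ndarray | None = None,
    n_strata: int = 10,
) -> EmpiricalNullResult:
    """Empirical Qx null by random SNP re-ascertainment.

    Draws ``n_draws`` random SNP sets from the pool (optionally matched to
    the observed set's mean-frequency deciles), recomputes Qx with the same
    effect sizes, and reports ``(1 + #{null ≥ observed}) / (1 + n_draws)``
    plus a KS check of the null chi-square P values against Uniform(0, 1) —
    a calibrated GWAS gives a uniform null, a stratified one does not.
    """
    betas = sumstats.set_index("snp")["beta"]
    pool = betas.index.intersection(freqs.snps.index)
    if observed_ids is not None:
        observed_ids = pd.Index(observed_ids)
        if ascertainment_size is None:
            ascertainment_size = len(observed_ids)
    if ascertainment_size is None:
        raise ValueError("give ascertainment_size or observed_ids")
    if len(pool) < 2 * ascertainment_size:
        raise ValueError("candidate pool not much larger than the draw size")
    if F_hat is None:
        F_hat = estimate_F(freqs.subset(pool))

    rng = np.random.default_rng(seed)
    p_bar_pool = freqs.freq.loc[pool].mean(axis=1)

    if frequency_match:
        if observed_ids is None:
            raise ValueError("frequency matching needs observed_ids")
        edges = np.quantile(p_bar_pool, np.linspace(0, 1, n_strata + 1))
        edges[0], edges[-1] = -np.inf, np.inf
        stratum_pool = np.digitize(p_bar_pool, edges[1:-1])
        stratum_obs = np.digitize(p_bar_pool.reindex(observed_ids), edges[1:-1])
        need = np.bincount(stratum_obs, minlength=n_strata)
        members = [np.flatnonzero(stratum_pool == s) for s in range(n_strata)]
        for s, k in enumerate(need):
            if k > 0 and len(members[s]) < k:
                raise ValueError(f"frequency-matching stratum {s} has "
                                 f"{len(members[s])} SNPs, need {k}")

    null_qx = np.empty(n_draws)
    null_p = np.empty(n_draws)
    pool_arr = pool.to_numpy()
    for d in range(n_draws):
        if frequency_match:
            take = np.concatenate([
                rng.choice(members[s], size=k, replace=False)
                for s, k in enumerate(need) if k > 0
            ])
        else:
            take = rng.choice(len(pool_arr), size=ascertainment_size,
                              replace=False)
        ids = pool_arr[take]
        res = score_populations(betas.loc[ids], freqs.subset(ids),
                                intervals=False)
        q = qx_test(res, F_hat)
        null_qx[d] = q.qx
        null_p[d] = q.p_qx

    emp_p = (1.0 + float((null_qx >= observed_qx).sum())) / (1.0 + n_draws)
    ks_stat, ks_p = stats.kstest(null_p, "uniform")
    return EmpiricalNullResult(empirical_p=emp_p, null_qx=null_qx,
                               null_p=null_p, ks_stat=float(ks_stat),
                               ks_p=float(ks_p))
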