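"""Synthetic populations, GWAS summary statistics, SDS-like scores, panels.

The generator reproduces the statistical structure that the drift-based
adaptation tests assume, plus the one failure mode under study: GWAS effect
estimates contaminated by a bias proportional to a frequency contrast along
an axis of population structure.

Model
-----
Allele frequencies drift from an ancestral frequency ``p̄_l`` as

    p_l· = p̄_l + ε,   ε ~ MVN(0, p̄_l (1 − p̄_l) F)

with ``F`` the M×M drift covariance (the same kernel the Qx null uses),
clipped to [0.001, 0.999].  Estimated effects are

    β̂_l = β_l + a·δ_l + N(0, se_l²),    δ_l = Σ_m axis_m p_lm

where ``axis`` sums to zero, so an unstructured GWAS has ``a = 0`` and a
stratified one has ``a > 0`` along a structure axis.  SDS-like scores carry
a frequency-cline confound ``c·δ_l`` and, optionally, a true-selection
component ``s·sign(β_l)`` on a designated SNP set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import FrequencyTable, GenotypePanel

logger = logging.getLogger(__name__)

FREQ_CLIP = (0.001, 0.999)
PSD_TOL = -1e-10
#: sentinel for a P value that underflows with se = 0 (documented in output)
P_UNDERFLOW = 1e-300


def _snp_ids(L: int) -> pd.Index:
    return pd.Index([f"rs{i + 1}" for i in range(L)], name="snp")


def _snp_meta(L: int, chrom: str = "1", spacing: int = 10_000) -> pd.DataFrame:
    """Default SNP metadata: one chromosome, evenly spaced, A/G alleles."""
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": np.arange(1, L + 1, dtype=np.int64) * spacing,
            "a1": "A",
            "a2": "G",
        },
        index=_snp_ids(L),
    )


@dataclass
class DriftSpec:
    """Ground truth for the multivariate-normal drift simulator.

    Parameters
    ----------
    M, L : number of populations and SNPs.
    F : M×M symmetric positive-semidefinite drift covariance (dimensionless).
    ancestral_freq_law : draws ancestral frequencies; callable ``(rng, L)``
        or a ``(low, high)`` uniform tuple.  Default Uniform(0.05, 0.95).
    Y : latitude per population, degrees.
    seed : integer seed; identical specs regenerate identical tables.
    """

    M: int
    L: int
    F: np.ndarray
    ancestral_freq_law: Callable | tuple[float, float] = (0.05, 0.95)
    Y: np.ndarray | None = None
    seed: int = 0
    populations: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.M < 1:
            raise ValueError("M must be >= 1")
        self.F = np.asarray(self.F, dtype=float)
        if self.F.shape != (self.M, self.M):
            raise ValueError(f"F must be {self.M}x{self.M}, got {self.F.shape}")
        if not np.allclose(self.F, self.F.T, atol=1e-12):
            raise ValueError("F must be symmetric")
        evals = np.linalg.eigvalsh(self.F)
        if evals.min() < PSD_TOL:
            raise ValueError(
                f"F is not positive semidefinite (min eigenvalue {evals.min():.3g})"
            )
        if self.Y is not None:
            self.Y = np.asarray(self.Y, dtype=float)
            if self.Y.shape != (self.M,):
                raise ValueError("Y must have one latitude per population")
        if not self.populations:
            self.populations = [f"pop{m + 1}" for m in range(self.M)]

    def draw_ancestral(self, rng: np.random.Generator) -> np.ndarray:
        if callable(self.ancestral_freq_law):
            p = np.asarray(self.ancestral_freq_law(rng, self.L), dtype=float)
        else:
            lo, hi = self.ancestral_freq_law
            p = rng.uniform(lo, hi, size=self.L)
        if p.min() <= 0 or p.max() >= 1:
            raise ValueError("ancestral frequencies must lie in (0, 1)")
        return p


@dataclass
class GwasSimSpec:
    """Specification of a (possibly stratified) synthetic GWAS.

    ``true_beta_law`` may be an array of per-SNP effects, a float standard
    deviation for N(0, sd²) effects, or a callable ``(rng, L)``.
    ``bias_coeff`` is in trait units per unit frequency contrast; the
    contrast is ``δ_l = Σ_m bias_axis_m p_lm`` with ``bias_axis`` summing
    to zero.  ``cohort_weights`` set the reported effect-allele frequency
    (default: the first population, a single-cohort GWAS).
    """

    true_beta_law: np.ndarray | float | Callable = 0.0
    se: np.ndarray | float = 0.0
    bias_coeff: float = 0.0
    bias_axis: np.ndarray | None = None
    selection_set: Sequence[str] | None = None
    cohort_weights: np.ndarray | None = None
    seed: int = 0

    def validate(self, M: int) -> None:
        se = np.asarray(self.se, dtype=float)
        if (se < 0).any():
            raise ValueError("se must be >= 0")
        if self.bias_axis is not None:
            axis = np.asarray(self.bias_axis, dtype=float)
            if axis.shape != (M,):
                raise ValueError("bias_axis must have one entry per population")
            if abs(axis.sum()) > 1e-8:
                raise ValueError("bias_axis must sum to 0")

    def draw_beta(self, rng: np.random.Generator, L: int) -> np.ndarray:
        law = self.true_beta_law
        if callable(law):
            return np.asarray(law(rng, L), dtype=float)
        arr = np.asarray(law, dtype=float)
        if arr.ndim == 0:
            sd = float(arr)
            return rng.normal(0.0, sd, size=L) if sd > 0 else np.zeros(L)
        if arr.shape != (L,):
            raise ValueError("true_beta_law array must have one effect per SNP")
        return arr.copy()


# ---------------------------------------------------------------------------
# frequency drift
# ---------------------------------------------------------------------------

def simulate_frequencies(
    spec: DriftSpec,
    n_haploid: int | Sequence[int] = 100,
    snp_meta: pd.DataFrame | None = None,
) -> tuple[FrequencyTable, pd.Series]:
    """Draw per-population frequencies under MVN drift around ``p̄``.

    Returns the frequency table (with binomial allele counts at ``n_haploid``
    haploid observations per population) and the recorded ancestral
    frequencies ``p̄_l`` — the simulator's ground truth.
    """
    rng = np.random.default_rng(spec.seed)
    p_bar = spec.draw_ancestral(rng)

    # MVN(0, p̄(1-p̄) F) via eigen square root (F may be singular)
    evals, evecs = np.linalg.eigh(spec.F)
    root = evecs * np.sqrt(np.clip(evals, 0.0, None))
    g = rng.standard_normal((spec.L, spec.M))
    eps = (g @ root.T) * np.sqrt(p_bar * (1.0 - p_bar))[:, None]
    p = np.clip(p_bar[:, None] + eps, *FREQ_CLIP)

    n = np.broadcast_to(np.asarray(n_haploid, dtype=np.int64), (spec.M,))
    x = rng.binomial(n[None, :], p)

    meta = _snp_meta(spec.L) if snp_meta is None else snp_meta
    cols = spec.populations
    freq = pd.DataFrame(p, index=meta.index, columns=cols)
    table = FrequencyTable(
        snps=meta,
        freq=freq,
        x=pd.DataFrame(x, index=meta.index, columns=cols),
        n=pd.DataFrame(np.broadcast_to(n, (spec.L, spec.M)).copy(),
                       index=meta.index, columns=cols),
    )
    return table, pd.Series(p_bar, index=meta.index, name="p_bar")


# ---------------------------------------------------------------------------
# GWAS summary statistics
# ---------------------------------------------------------------------------

def frequency_contrast_axis(freqs: FrequencyTable,
                            axis: np.ndarray) -> pd.Series:
    """Per-SNP frequency contrast ``δ_l = Σ_m axis_m p_lm``."""
    axis = np.asarray(axis, dtype=float)
    return pd.Series(freqs.freq.to_numpy() @ axis, index=freqs.freq.index,
                     name="delta")


def simulate_gwas(
    freqs: FrequencyTable, spec: GwasSimSpec
) -> tuple[pd.DataFrame, pd.Series]:
    """Simulate summary statistics ``β̂ = β + a·δ + noise`` over ``freqs``.

    Returns the canonical summary-statistics frame and the recorded true
    effects.  P values are two-sided normal from ``z = β̂/se``; with
    ``se = 0`` the P value is the documented underflow sentinel
    (``P_UNDERFLOW``) for nonzero ``β̂`` and 1 for ``β̂ = 0``.
    """
    L, M = freqs.n_snps, len(freqs.populations)
    spec.validate(M)
    rng = np.random.default_rng(spec.seed)

    beta_true = spec.draw_beta(rng, L)
    se = np.broadcast_to(np.asarray(spec.se, dtype=float), (L,)).copy()

    beta_hat = beta_true.copy()
    if spec.bias_coeff != 0.0:
        if spec.bias_axis is None:
            raise ValueError("bias_coeff != 0 requires a bias_axis")
        delta = frequency_contrast_axis(freqs, spec.bias_axis).to_numpy()
        beta_hat = beta_hat + spec.bias_coeff * delta
    noisy = se > 0
    beta_hat[noisy] += rng.normal(0.0, se[noisy])

    p = np.empty(L)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(noisy, beta_hat / np.where(noisy, se, 1.0), np.inf)
    p[noisy] = 2.0 * stats.norm.sf(np.abs(z[noisy]))
    p[~noisy] = np.where(beta_hat[~noisy] == 0.0, 1.0, P_UNDERFLOW)
    np.clip(p, P_UNDERFLOW, 1.0, out=p)

    w = spec.cohort_weights
    if w is None:
        freq_a1 = freqs.freq.iloc[:, 0].to_numpy()
    else:
        w = np.asarray(w, dtype=float)
        freq_a1 = freqs.freq.to_numpy() @ (w / w.sum())

    meta = freqs.snps
    sumstats = pd.DataFrame(
        {
            "snp": meta.index,
            "chrom": meta["chrom"].to_numpy(),
            "pos": meta["pos"].to_numpy(),
            "a1": meta["a1"].to_numpy(),
            "a2": meta["a2"].to_numpy(),
            "beta": beta_hat,
            "se": se,
            "p": p,
            "freq_a1": freq_a1,
        }
    ).reset_index(drop=True)
    return sumstats, pd.Series(beta_true, index=meta.index, name="beta_true")


# ---------------------------------------------------------------------------
# SDS-like scores
# ---------------------------------------------------------------------------

def simulate_sds(
    freqs: FrequencyTable,
    cline_coeff: float = 0.0,
    selection_coeff: float = 0.0,
    selection_set: Sequence[str] | None = None,
    noise_sd: float = 1.0,
    seed: int = 0,
    true_beta: pd.Series | None = None,
    cline_axis: np.ndarray | None = None,
) -> pd.DataFrame:
    """Simulate raw SDS-like scores with a frequency-cline confound.

    ``raw SDS_l = c·δ_l + s·1[l ∈ selection_set]·sign(β_l) + N(0, noise_sd²)``
    where the cline contrast δ defaults to the first-vs-last population axis
    (+1, 0, …, 0, −1).  Scores are reported with respect to the derived
    allele, which the simulator defines as the effect allele (A1); the
    derived-allele frequency is the across-population mean A1 frequency.
    """
    rng = np.random.default_rng(seed)
    M = len(freqs.populations)
    if cline_axis is None:
        cline_axis = np.zeros(M)
        cline_axis[0], cline_axis[-1] = 1.0, -1.0
        if M == 1:
            cline_axis[0] = 0.0
    delta = frequency_contrast_axis(freqs, cline_axis).to_numpy()

    sds = cline_coeff * delta + rng.normal(0.0, noise_sd, size=freqs.n_snps)
    if selection_coeff != 0.0 and selection_set is not None:
        sel = pd.Index(selection_set)
        unknown = sel.difference(freqs.snps.index)
        if len(unknown):
            raise ValueError(f"selection_set contains unknown SNP ids: "
                             f"{unknown.tolist()[:5]}")
        if true_beta is None:
            raise ValueError("selection requires the true effects")
        mask = freqs.snps.index.isin(sel)
        sds[mask] += selection_coeff * np.sign(
            true_beta.reindex(freqs.snps.index).to_numpy()[mask]
        )

    meta = freqs.snps
    return pd.DataFrame(
        {
            "chrom": meta["chrom"].to_numpy(),
            "pos": meta["pos"].to_numpy(),
            "id": meta.index,
            "aa": meta["a2"].to_numpy(),    # ancestral = other allele
            "da": meta["a1"].to_numpy(),    # derived = effect allele
            "daf": freqs.freq.mean(axis=1).to_numpy(),
            "sds": sds,
        }
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# genotype panels
# ---------------------------------------------------------------------------

def simulate_genotype_panel(
    freqs: FrequencyTable,
    n_per_pop: int | Sequence[int],
    sex_ratio: float = 0.5,
    seed: int = 0,
    latitudes: Sequence[float] | None = None,
    ld_block_size: int | None = None,
    ld_corr: float = 0.0,
) -> GenotypePanel:
    """Draw a diploid panel, counts ~ Binomial(2, p_lm) per population.

    With ``ld_block_size`` set, consecutive SNPs within a block share a
    latent per-haplotype uniform with probability ``ld_corr``, producing
    block LD sufficient to exercise clumping and pruning (not a coalescent
    model).
    """
    pops = freqs.populations
    M = len(pops)
    n_per_pop = np.broadcast_to(np.asarray(n_per_pop, dtype=int), (M,))
    if (n_per_pop < 1).any():
        raise ValueError("n_per_pop must be >= 1")
    rng = np.random.default_rng(seed)
    L = freqs.n_snps
    p_all = freqs.freq.to_numpy()

    blocks = None
    if ld_block_size is not None and ld_corr > 0:
        blocks = np.arange(L) // int(ld_block_size)

    counts_parts, meta_parts = [], []
    for m, pop in enumerate(pops):
        n = int(n_per_pop[m])
        p = p_all[:, m]
        if blocks is None:
            cnt = rng.binomial(2, p, size=(n, L))
        else:
            cnt = np.zeros((n, L), dtype=np.int64)
            for _hap in range(2):
                u_block = rng.uniform(size=(n, blocks.max() + 1))
                u_fresh = rng.uniform(size=(n, L))
                use_block = rng.uniform(size=(n, L)) < ld_corr
                u = np.where(use_block, u_block[:, blocks], u_fresh)
                cnt += (u < p[None, :]).astype(np.int64)
        sex = (rng.uniform(size=n) < sex_ratio).astype(int)
        lat = np.nan if latitudes is None else float(latitudes[m])
        meta_parts.append(pd.DataFrame(
            {"population": pop, "sex": sex, "latitude": lat},
            index=[f"{pop}_{i + 1}" for i in range(n)],
        ))
        counts_parts.append(cnt)

    individuals = pd.concat(meta_parts)
    individuals.index.name = "individual"
    counts = pd.DataFrame(np.vstack(counts_parts), index=individuals.index,
                          columns=freqs.snps.index)
    return GenotypePanel(counts=counts, individuals=individuals,
                         snps=freqs.snps.copy(), ploidy=2)
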