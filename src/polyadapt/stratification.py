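"""Population-stratification diagnostics.

A GWAS confounded by structure leaves a fingerprint: effect-size estimates
correlate with the SNP loadings of the principal components of population
structure, and with raw two-population frequency contrasts.  This module
computes PCA scores on a (filtered, optionally pruned) panel, per-SNP PC
loadings by regression (controlling for sex), loading–effect correlations
with block-jackknife errors and Bonferroni flags, signed frequency
contrasts of the trait-increasing allele, and two-population MAF-binned
heat maps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GenotypePanel
from .ldselect import prune

logger = logging.getLogger(__name__)


@dataclass
class PCLoadings:
    """PC scores per individual (zero mean) and variance explained."""

    scores: pd.DataFrame          # individuals × PCs
    explained_ratio: np.ndarray
    snp_ids: pd.Index             # SNPs the PCA was computed on

    @property
    def k(self) -> int:
        return self.scores.shape[1]


def _in_regions(snps: pd.DataFrame, regions) -> np.ndarray:
    """Mask of SNPs falling in any (chrom, start, end) 1-based interval."""
    mask = np.zeros(len(snps), dtype=bool)
    for chrom, lo, hi in regions or []:
        mask |= (
            (snps["chrom"].astype(str) == str(chrom))
            & (snps["pos"] >= lo) & (snps["pos"] <= hi)
        )
    return mask


def compute_pcs(
    panel: GenotypePanel,
    k: int,
    maf_min: float = 0.05,
    exclude_regions=None,
    prune_r2: float | None = None,
    prune_window: int = 1_000_000,
    standardize: bool = True,
) -> PCLoadings:
    """PCA of the individual × SNP allele-count matrix after filters.

    Filters: minor-allele frequency floor, exclusion intervals (e.g. MHC,
    inversions, long-LD regions), optional LD pruning.  Missing counts are
    mean-imputed (only here — frequency computations never impute).  Counts
    are centered and, by default, scaled by 1/√(2p(1−p)); PC scores are
    zero-mean with a deterministic sign (largest-|entry| positive).
    """
    counts = panel.counts.to_numpy(float)
    p = np.nanmean(counts, axis=0) / panel.ploidy
    maf = np.minimum(p, 1.0 - p)
    keep = maf > maf_min
    keep &= ~_in_regions(panel.snps, exclude_regions)

    ids = panel.snps.index[keep]
    if prune_r2 is not None:
        sub = GenotypePanel(
            counts=panel.counts[ids], individuals=panel.individuals,
            snps=panel.snps.loc[ids], ploidy=panel.ploidy,
        )
        ids = pd.Index(prune(sub, prune_r2, prune_window))
    if len(ids) == 0:
        raise ValueError("no SNPs survive the PCA filters")

    X = panel.counts[ids].to_numpy(float)
    col_mean = np.nanmean(X, axis=0)
    nan_i, nan_j = np.where(np.isnan(X))
    X[nan_i, nan_j] = col_mean[nan_j]
    X = X - col_mean
    if standardize:
        pf = col_mean / panel.ploidy
        X = X / np.sqrt(panel.ploidy * pf * (1.0 - pf))

    rank = np.linalg.matrix_rank(X)
    if k > rank:
        logger.warning("requested %d PCs but rank is %d; reduced", k, rank)
        k = rank
    U, S, _ = np.linalg.svd(X, full_matrices=False)
    scores = U[:, :k] * S[:k]
    # deterministic sign: largest-|score| entry positive per component
    flip = np.sign(scores[np.abs(scores).argmax(axis=0), np.arange(k)])
    scores = scores * flip
    explained = S**2 / (S**2).sum()

    return PCLoadings(
        scores=pd.DataFrame(scores, index=panel.counts.index,
                            columns=[f"PC{i + 1}" for i in range(k)]),
        explained_ratio=explained[:k],
        snp_ids=ids,
    )


def pc_loadings(
    pcs: PCLoadings,
    panel: GenotypePanel,
    sex: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-SNP PC loadings: allele-count coefficient in a least-squares fit
    of each PC score on (intercept, sex, count).

    Computable for all panel SNPs, including those outside the PCA input
    set.  Monomorphic SNPs get missing loadings.
    """
    if sex is None:
        sex = panel.individuals["sex"]
    sex = sex.reindex(pcs.scores.index).to_numpy(float)
    S = pcs.scores.to_numpy(float)
    G = panel.counts.reindex(pcs.scores.index).to_numpy(float)
    if np.isnan(G).any():
        # per-SNP regression on the non-missing individuals
        out = np.full((G.shape[1], S.shape[1]), np.nan)
        for j in range(G.shape[1]):
            g = G[:, j]
            ok = ~np.isnan(g)
            out[j] = _partial_coef(S[ok], sex[ok], g[ok])[0]
        load = out
    else:
        load = _partial_coef(S, sex, G)
    return pd.DataFrame(load, index=panel.snps.index,
                        columns=pcs.scores.columns)


def _partial_coef(S: np.ndarray, sex: np.ndarray, G: np.ndarray) -> np.ndarray:
    """Coefficient of G in lstsq of each column of S on (1, sex, G),
    via Frisch–Waugh: residualize S and G on (1, sex) first."""
    n = len(sex)
    D = np.column_stack([np.ones(n), sex])
    pinv = np.linalg.pinv(D)
    S_r = S - D @ (pinv @ S)
    G = G.reshape(n, -1)
    G_r = G - D @ (pinv @ G)
    denom = (G_r**2).sum(axis=0)
    # residual variance at round-off scale = monomorphic / sex-collinear SNP
    degenerate = denom <= 1e-12 * n * np.maximum((G**2).mean(axis=0), 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        coef = (G_r.T @ S_r) / denom[:, None]
    coef[degenerate] = np.nan
    return coef


# ---------------------------------------------------------------------------
# loading–effect correlations
# ---------------------------------------------------------------------------

def _jackknife_pearson(x: np.ndarray, y: np.ndarray,
                       n_blocks: int) -> tuple[float, float]:
    """(r, SE) of Pearson r by contiguous-block jackknife, via per-block
    sufficient statistics (O(n + B))."""
    n = len(x)
    bounds = np.linspace(0, n, n_blocks + 1).round().astype(int)
    sx = np.add.reduceat(x, bounds[:-1])
    sy = np.add.reduceat(y, bounds[:-1])
    sxx = np.add.reduceat(x * x, bounds[:-1])
    syy = np.add.reduceat(y * y, bounds[:-1])
    sxy = np.add.reduceat(x * y, bounds[:-1])
    cnt = np.diff(bounds)

    def r_from(sx_, sy_, sxx_, syy_, sxy_, n_):
        cov = sxy_ - sx_ * sy_ / n_
        vx = sxx_ - sx_**2 / n_
        vy = syy_ - sy_**2 / n_
        return cov / np.sqrt(vx * vy)

    r = float(r_from(sx.sum(), sy.sum(), sxx.sum(), syy.sum(), sxy.sum(), n))
    loo = r_from(sx.sum() - sx, sy.sum() - sy, sxx.sum() - sxx,
                 syy.sum() - syy, sxy.sum() - sxy, n - cnt)
    B = n_blocks
    se = float(np.sqrt((B - 1) / B * ((loo - loo.mean()) ** 2).sum()))
    return r, se


def loading_correlations(
    v: pd.Series,
    loadings: pd.DataFrame,
    n_jackknife: int = 1000,
    n_pcs: int = 20,
    alpha: float = 0.05,
    chrom: pd.Series | None = None,
    pos: pd.Series | None = None,
) -> pd.DataFrame:
    """Pearson correlation of a per-SNP vector (β̂ or SDS) with PC loadings.

    SE and P per PC from a contiguous-block jackknife in genomic order
    (B = ``n_jackknife``, reduced with a warning when SNPs are fewer);
    flags: ``nominal`` (P < alpha) and ``bonferroni`` (P < alpha / n_pcs).
    """
    ids = v.index.intersection(loadings.index)
    vv = v.loc[ids]
    ld = loadings.loc[ids]
    ok = vv.notna() & ld.notna().all(axis=1)
    vv, ld = vv[ok], ld[ok]
    if chrom is not None and pos is not None:
        order = np.lexsort((pos.loc[vv.index], chrom.loc[vv.index].astype(str)))
        vv, ld = vv.iloc[order], ld.iloc[order]
    n = len(vv)
    B = min(n_jackknife, n)
    if B < n_jackknife:
        logger.warning("fewer SNPs (%d) than jackknife blocks; B reduced", n)

    pcs = list(ld.columns)[:n_pcs]
    rows = []
    x = vv.to_numpy(float)
    for pc in pcs:
        r, se = _jackknife_pearson(x, ld[pc].to_numpy(float), B)
        p = float(2.0 * stats.norm.sf(abs(r) / se)) if se > 0 else np.nan
        rows.append({
            "pc": pc, "r": r, "se": se, "p": p,
            "nominal": bool(p < alpha),
            "bonferroni": bool(p < alpha / n_pcs),
        })
    return pd.DataFrame(rows).set_index("pc")


# ---------------------------------------------------------------------------
# frequency contrasts and heat maps
# ---------------------------------------------------------------------------

def freq_contrast(
    freqs_a: pd.Series, freqs_b: pd.Series, sumstats: pd.DataFrame
) -> pd.Series:
    """Per-SNP frequency difference of the trait-increasing allele,
    ``Δ = p_A − p_B`` computed for the allele with β > 0 (the A1 contrast
    negated when β < 0).  SNPs with β = 0 or missing from either
    population are dropped and tallied."""
    ss = sumstats.set_index("snp")
    ids = ss.index.intersection(freqs_a.index).intersection(freqs_b.index)
    n_missing = len(ss) - len(ids)
    beta = ss.loc[ids, "beta"]
    nz = beta != 0
    if n_missing or (~nz).any():
        logger.info("freq_contrast dropped %d missing and %d zero-beta SNPs",
                    n_missing, int((~nz).sum()))
    ids = ids[nz.to_numpy()]
    delta = np.sign(ss.loc[ids, "beta"]) * (
        freqs_a.loc[ids] - freqs_b.loc[ids]
    )
    return delta.rename("delta")


@dataclass
class BinnedHeatmap:
    """2-D grid of per-cell means over (MAF_A, MAF_B) bins with a mask for
    cells below the count threshold."""

    mean: np.ndarray
    count: np.ndarray
    mask: np.ndarray            # True = hidden (count < min_count)
    edges: np.ndarray
    min_count: int

    def to_frame(self) -> pd.DataFrame:
        shown = np.where(self.mask, np.nan, self.mean)
        labels = [f"[{a:.2f},{b:.2f})" for a, b in
                  zip(self.edges[:-1], self.edges[1:])]
        return pd.DataFrame(shown, index=labels, columns=labels)


def maf_bin_heatmap(
    values: pd.Series,
    freqs_a: pd.Series,
    freqs_b: pd.Series,
    bin_width: float = 0.05,
    min_count: int = 300,
) -> BinnedHeatmap:
    """Bin SNPs by minor-allele frequency in two populations; per-cell mean
    of ``values`` and count, masking cells with fewer than ``min_count``
    SNPs."""
    ids = values.index.intersection(freqs_a.index).intersection(freqs_b.index)
    if len(ids) == 0:
        raise ValueError("no SNPs shared between values and frequencies")
    v = values.loc[ids].to_numpy(float)
    maf_a = np.minimum(freqs_a.loc[ids], 1.0 - freqs_a.loc[ids]).to_numpy()
    maf_b = np.minimum(freqs_b.loc[ids], 1.0 - freqs_b.loc[ids]).to_numpy()

    n_bins = int(np.ceil(0.5 / bin_width))
    edges = np.arange(n_bins + 1) * bin_width
    ia = np.minimum((maf_a / bin_width).astype(int), n_bins - 1)
    ib = np.minimum((maf_b / bin_width).astype(int), n_bins - 1)

    count = np.zeros((n_bins, n_bins), dtype=int)
    total = np.zeros((n_bins, n_bins))
    np.add.at(count, (ia, ib), 1)
    np.add.at(total, (ia, ib), v)
    with np.errstate(invalid="ignore"):
        mean = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    mask = count < min_count
    return BinnedHeatmap(mean=mean, count=count, mask=mask, edges=edges,
                         min_count=min_count)
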