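"""Trait-aligned SDS (tSDS) analysis.

Raw singleton-density scores are normalized to mean 0, variance 1 within
each 1% derived-allele-frequency bin (after excluding the MHC region), then
sign-aligned to the trait-increasing allele: tSDS > 0 means the
trait-increasing allele carries the recent-selection-like signal.  The
trend of tSDS with GWAS significance is summarized by a Spearman
correlation with block-jackknife errors, by an un-binned regression slope,
and by a mean-shift test at genome-wide-significant SNPs (null: each
normalized tSDS ~ N(0, 1)).

Sign convention: ρ is computed between the score and the significance
order (ranks of −P), so positive ρ means higher scores at stronger
associations — selection-like.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: MHC exclusion bounds on chromosome 6 (bp, 1-based inclusive)
MHC_REGION = ("6", 25_000_000, 35_000_000)

SDS_COLUMNS = ["chrom", "pos", "id", "aa", "da", "daf", "sds"]
_SDS_FILE_COLUMNS = ["CHR", "POS", "ID", "AA", "DA", "DAF", "SDS"]


def read_sds(path) -> pd.DataFrame:
    """Read a pre-computed SDS table (CHR POS ID AA DA DAF SDS)."""
    df = pd.read_csv(path, sep=r"\s+")
    missing = [c for c in _SDS_FILE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"SDS file missing column(s): {missing}")
    df = df[_SDS_FILE_COLUMNS].copy()
    df.columns = SDS_COLUMNS
    df["chrom"] = df["chrom"].astype(str).str.removeprefix("chr")
    return df


def write_sds(table: pd.DataFrame, path) -> None:
    out = table[SDS_COLUMNS].copy()
    out.columns = _SDS_FILE_COLUMNS
    out.to_csv(path, sep="\t", index=False)


def normalize_sds(
    table: pd.DataFrame,
    mhc: tuple[str, int, int] = MHC_REGION,
    bin_width: float = 0.01,
) -> pd.DataFrame:
    """Normalize SDS within DAF bins; exclude the MHC first.

    Each bin [k·w, (k+1)·w) (the last closed at 1.0) is shifted to mean 0
    and scaled to unit sample variance (n − 1 denominator).  Bins with a
    single SNP are dropped with a warning.  Adds an ``sds_norm`` column.
    """
    chrom, lo, hi = mhc
    in_mhc = (
        (table["chrom"].astype(str) == str(chrom))
        & (table["pos"] >= lo) & (table["pos"] <= hi)
    )
    if in_mhc.any():
        logger.info("excluded %d SNPs in the MHC region", int(in_mhc.sum()))
    df = table[~in_mhc].copy()

    daf = df["daf"].to_numpy(float)
    if np.nanmin(daf) <= 0 or np.nanmax(daf) >= 1:
        raise ValueError("DAF must lie strictly in (0, 1)")
    n_bins = int(round(1.0 / bin_width))
    bins = np.minimum((daf / bin_width).astype(int), n_bins - 1)

    df["_bin"] = bins
    sizes = df.groupby("_bin")["sds"].transform("size")
    lonely = sizes < 2
    if lonely.any():
        logger.warning("dropped %d SNPs alone in their DAF bin "
                       "(SD undefined)", int(lonely.sum()))
        df = df[~lonely]
    grp = df.groupby("_bin")["sds"]
    df["sds_norm"] = (df["sds"] - grp.transform("mean")) / grp.transform(
        lambda s: s.std(ddof=1)
    )
    return df.drop(columns="_bin").reset_index(drop=True)


def align_tsds(
    normalized: pd.DataFrame, sumstats: pd.DataFrame
) -> tuple[pd.DataFrame, dict]:
    """Sign-align normalized SDS to trait-increasing alleles (tSDS).

    The derived allele is matched to the summary-statistics allele pair:
    tSDS = +SDS when the derived allele increases the trait (β for the
    derived allele > 0), −SDS otherwise.  SNPs whose derived allele matches
    neither allele, and SNPs with β exactly 0, are dropped and tallied.
    Joins GWAS ``beta`` and ``p`` onto the output.
    """
    ss = sumstats.set_index("snp")
    df = normalized.copy()
    report = {"kept": 0, "unmatched_dropped": 0, "allele_mismatch_dropped": 0,
              "zero_beta_dropped": 0}

    matched = df["id"].isin(ss.index)
    report["unmatched_dropped"] = int((~matched).sum())
    df = df[matched]
    sub = ss.loc[df["id"]]

    is_a1 = df["da"].to_numpy() == sub["a1"].to_numpy()
    is_a2 = df["da"].to_numpy() == sub["a2"].to_numpy()
    mismatch = ~(is_a1 | is_a2)
    report["allele_mismatch_dropped"] = int(mismatch.sum())

    beta_derived = np.where(is_a1, sub["beta"].to_numpy(),
                            -sub["beta"].to_numpy())
    zero = (beta_derived == 0) & ~mismatch
    report["zero_beta_dropped"] = int(zero.sum())

    keep = ~(mismatch | zero)
    df = df[keep].copy()
    df["beta_derived"] = beta_derived[keep]
    df["p"] = sub["p"].to_numpy()[keep]
    df["tsds"] = np.sign(df["beta_derived"]) * df["sds_norm"]
    report["kept"] = len(df)
    logger.info("align_tsds: %s", report)
    return df.reset_index(drop=True), report


# ---------------------------------------------------------------------------
# trend statistics
# ---------------------------------------------------------------------------

@dataclass
class TrendResult:
    """Spearman trend of a per-SNP score with GWAS significance."""

    rho: float
    jackknife_se: float
    jackknife_p: float
    slope: float
    slope_p: float
    n_snps: int
    n_blocks: int
    binned: pd.DataFrame    # bin, mean score, size, partial flag

    def to_dict(self) -> dict:
        return {
            "rho": self.rho, "jackknife_se": self.jackknife_se,
            "jackknife_p": self.jackknife_p, "slope": self.slope,
            "slope_p": self.slope_p, "n_snps": self.n_snps,
            "n_blocks": self.n_blocks,
        }


def _block_bounds(n: int, n_blocks: int) -> np.ndarray:
    """Split ``range(n)`` into ``n_blocks`` contiguous near-equal blocks."""
    return np.linspace(0, n, n_blocks + 1).round().astype(int)


def jackknife_blocks(values: np.ndarray, n_blocks: int,
                     statistic) -> tuple[float, float]:
    """Delete-one-block jackknife: returns (SE, mean of leave-one-out).

    SE = sqrt((B−1)/B · Σ (θ_i − θ̄)²) over B contiguous blocks in the
    given (genomic) order; on singleton blocks for the mean this equals the
    classical standard error of the mean.
    """
    n = len(values)
    bounds = _block_bounds(n, n_blocks)
    thetas = []
    for b in range(n_blocks):
        mask = np.ones(n, dtype=bool)
        mask[bounds[b]:bounds[b + 1]] = False
        thetas.append(statistic(values[mask]))
    thetas = np.asarray(thetas, dtype=float)
    B = n_blocks
    se = np.sqrt((B - 1) / B * ((thetas - thetas.mean()) ** 2).sum())
    return float(se), float(thetas.mean())


def trend(
    score: np.ndarray,
    p: np.ndarray,
    bin_size: int = 1000,
    n_jackknife_blocks: int = 100,
    chrom: np.ndarray | None = None,
    pos: np.ndarray | None = None,
) -> TrendResult:
    """Spearman trend of ``score`` with GWAS significance, jackknife errors.

    Inputs must be per-SNP aligned; if ``chrom``/``pos`` are given the data
    are put in genomic order first (jackknife blocks are contiguous in that
    order), otherwise the given order is assumed genomic.  The regression
    slope is of the score on the significance rank scaled to [0, 1], with
    its analytic P.  Binned means run from least to most significant; a
    final smaller bin is flagged ``partial``.
    """
    score = np.asarray(score, dtype=float)
    p = np.asarray(p, dtype=float)
    if score.shape != p.shape:
        raise ValueError("score and p must be aligned per SNP")
    n = len(score)
    if np.ptp(score) == 0 or np.ptp(p) == 0:
        raise ValueError("constant score or constant P: trend undefined")
    if chrom is not None and pos is not None:
        order = np.lexsort((pos, np.asarray(chrom, dtype=str)))
        score, p = score[order], p[order]

    sig = -p    # higher = more significant
    rho = float(stats.spearmanr(score, sig).statistic)

    B = min(n_jackknife_blocks, n)
    if B < n_jackknife_blocks:
        logger.warning("fewer SNPs than jackknife blocks; B reduced to %d", B)
    bounds = _block_bounds(n, B)
    thetas = np.empty(B)
    for b in range(B):
        mask = np.ones(n, dtype=bool)
        mask[bounds[b]:bounds[b + 1]] = False
        thetas[b] = stats.spearmanr(score[mask], sig[mask]).statistic
    se = float(np.sqrt((B - 1) / B * ((thetas - thetas.mean()) ** 2).sum()))
    jk_p = float(2.0 * stats.norm.sf(abs(rho) / se)) if se > 0 else np.nan

    ranks = stats.rankdata(sig)
    xs = (ranks - 1) / (n - 1)
    reg = stats.linregress(xs, score)

    order_sig = np.argsort(ranks, kind="stable")   # least significant first
    sorted_score = score[order_sig]
    rows = []
    for start in range(0, n, bin_size):
        chunk = sorted_score[start:start + bin_size]
        rows.append({"bin": start // bin_size, "mean_score": chunk.mean(),
                     "size": len(chunk), "partial": len(chunk) < bin_size})
    binned = pd.DataFrame(rows)

    return TrendResult(rho=rho, jackknife_se=se, jackknife_p=jk_p,
                       slope=float(reg.slope), slope_p=float(reg.pvalue),
                       n_snps=n, n_blocks=B, binned=binned)


def gw_sig_shift(tsds_values: np.ndarray) -> tuple[float, float, float]:
    """Mean-shift test at independent genome-wide-significant SNPs.

    Under the null each normalized tSDS ~ N(0, 1), so
    ``z = mean(tSDS)·√n``; returns (mean, z, two-sided P).
    """
    v = np.asarray(tsds_values, dtype=float)
    if len(v) == 0:
        raise ValueError("no genome-wide-significant SNPs supplied")
    mean = float(v.mean())
    z = mean * np.sqrt(len(v))
    p = float(2.0 * stats.norm.sf(abs(z)))
    return mean, float(z), p
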