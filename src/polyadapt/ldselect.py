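"""Ascertainment of independent trait-associated SNPs.

Three strategies: lowest-P SNP per pre-defined LD block, greedy clumping
(PLINK-style: index SNPs by ascending P absorb correlated neighbours within
a physical window), and sliding-window r² pruning.  LD is genotypic r² —
the squared Pearson correlation of 0/1/2 allele counts — so unphased panels
suffice.

Tie-breaks are everywhere (P, position, id) so runs are bit-reproducible.
Clumping absorbs at r² strictly above the threshold; pruning removes at
r² ≥ the threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import GenotypePanel

logger = logging.getLogger(__name__)


@dataclass
class ClumpSpec:
    """Clumping parameters: index threshold ``p1``, secondary threshold
    ``p2``, r² threshold, and physical window in bp (index-to-candidate)."""

    p1: float = 5e-8
    p2: float = 1.0
    r2: float = 0.1
    window: int = 1_000_000

    def __post_init__(self) -> None:
        if not (0 < self.p1 <= 1 and 0 < self.p2 <= 1):
            raise ValueError("p1 and p2 must be in (0, 1]")
        if not 0 <= self.r2 <= 1:
            raise ValueError("r2 must be in [0, 1]")
        if self.window <= 0:
            raise ValueError("window must be > 0")


# ---------------------------------------------------------------------------
# LD blocks
# ---------------------------------------------------------------------------

def read_ld_blocks(path) -> pd.DataFrame:
    """Read a BED-like block file (chrom, start, end; 0-based half-open).

    Intervals are kept 0-based half-open internally; a 1-based SNP position
    ``pos`` falls in a block iff ``start <= pos - 1 < end``.
    """
    blocks = pd.read_csv(path, sep=r"\s+", header=None, comment="#",
                         names=["chrom", "start", "end"],
                         dtype={"chrom": str})
    blocks["chrom"] = blocks["chrom"].str.removeprefix("chr")
    blocks = blocks.sort_values(["chrom", "start"]).reset_index(drop=True)
    for chrom, sub in blocks.groupby("chrom"):
        s, e = sub["start"].to_numpy(), sub["end"].to_numpy()
        if (e <= s).any() or (s[1:] < e[:-1]).any():
            raise ValueError(f"blocks overlap or are empty on chromosome {chrom}")
    return blocks


def assign_blocks(sumstats: pd.DataFrame, blocks: pd.DataFrame) -> pd.Series:
    """Block index per SNP (−1 when the SNP falls outside every block)."""
    out = np.full(len(sumstats), -1, dtype=np.int64)
    pos0 = sumstats["pos"].to_numpy(np.int64) - 1   # to 0-based
    chroms = sumstats["chrom"].astype(str).to_numpy()
    for chrom, sub in blocks.groupby("chrom"):
        mask = chroms == chrom
        if not mask.any():
            continue
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        i = np.searchsorted(starts, pos0[mask], side="right") - 1
        ok = (i >= 0) & (pos0[mask] < ends[np.clip(i, 0, None)])
        idx = sub.index.to_numpy()[np.clip(i, 0, None)]
        out[np.flatnonzero(mask)[ok]] = idx[ok]
    return pd.Series(out, index=sumstats.index, name="block")


def lowest_p_per_block(sumstats: pd.DataFrame,
                       blocks: pd.DataFrame) -> list[str]:
    """The lowest-P SNP in each block with ≥1 SNP (ties: position, then id)."""
    block = assign_blocks(sumstats, blocks)
    outside = int((block == -1).sum())
    if outside:
        logger.info("%d SNPs outside all LD blocks excluded", outside)
    df = sumstats.assign(_block=block)
    df = df[df["_block"] >= 0]
    df = df.sort_values(["p", "pos", "snp"], kind="mergesort")
    picked = df.groupby("_block", sort=True).head(1)
    return picked.sort_values(["chrom", "pos"])["snp"].tolist()


# ---------------------------------------------------------------------------
# genotypic r²
# ---------------------------------------------------------------------------

def genotypic_r2(panel: GenotypePanel, snp_i: str, snp_j: str) -> float:
    """Squared Pearson correlation of allele-count vectors.

    A monomorphic SNP has undefined correlation; treated as r² = 0 with a
    warning (it cannot tag anything).
    """
    gi = panel.counts[snp_i].to_numpy(float)
    gj = panel.counts[snp_j].to_numpy(float)
    ok = ~(np.isnan(gi) | np.isnan(gj))
    gi, gj = gi[ok] - gi[ok].mean(), gj[ok] - gj[ok].mean()
    vi, vj = gi @ gi, gj @ gj
    if vi == 0 or vj == 0:
        logger.warning("zero genotype variance at %s or %s; r2 treated as 0",
                       snp_i, snp_j)
        return 0.0
    return float((gi @ gj) ** 2 / (vi * vj))


def _r2_to_index(counts: np.ndarray, idx: int, others: np.ndarray) -> np.ndarray:
    """r² of column ``idx`` against each column in ``others`` (no NaN)."""
    x = counts[:, idx]
    Y = counts[:, others]
    xc = x - x.mean()
    Yc = Y - Y.mean(axis=0)
    vx = xc @ xc
    vy = (Yc ** 2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = (xc @ Yc) ** 2 / (vx * vy)
    r2[~np.isfinite(r2)] = 0.0
    return r2


# ---------------------------------------------------------------------------
# clumping
# ---------------------------------------------------------------------------

def clump(
    sumstats: pd.DataFrame,
    panel: GenotypePanel,
    spec: ClumpSpec,
    return_clumps: bool = False,
):
    """Greedy PLINK-style clumping; returns index SNP ids sorted by position.

    Index candidates are SNPs with P < p1, processed by ascending
    (P, position, id); each new index absorbs all still-unassigned SNPs with
    P < p2 on the same chromosome within ``window`` bp whose genotypic r²
    with the index exceeds ``spec.r2``.  Each SNP appears in at most one
    clump.
    """
    covered = sumstats["snp"].isin(panel.snp_ids)
    n_uncov = int((~covered).sum())
    if n_uncov:
        logger.info("%d sumstats SNPs not in panel excluded from clumping",
                    n_uncov)
    ss = sumstats[covered]
    ss = ss[ss["p"] < spec.p2]
    ss = ss.sort_values(["p", "pos", "snp"], kind="mergesort").reset_index(drop=True)
    if not (ss["p"] < spec.p1).any():
        logger.warning("no SNPs below index threshold p1=%g", spec.p1)
        return ([], {}) if return_clumps else []

    ids = ss["snp"].to_numpy()
    pos = ss["pos"].to_numpy(np.int64)
    chrom = ss["chrom"].astype(str).to_numpy()
    counts = panel.counts[ids].to_numpy(float)
    if np.isnan(counts).any():
        col_mean = np.nanmean(counts, axis=0)
        ii, jj = np.where(np.isnan(counts))
        counts[ii, jj] = col_mean[jj]

    assigned = np.zeros(len(ss), dtype=bool)
    indices: list[str] = []
    clumps: dict[str, list[str]] = {}
    n_index_candidates = int((ss["p"] < spec.p1).sum())
    for i in range(n_index_candidates):       # already sorted by ascending P
        if assigned[i]:
            continue
        assigned[i] = True
        cand = np.flatnonzero(
            ~assigned
            & (chrom == chrom[i])
            & (np.abs(pos - pos[i]) <= spec.window)
        )
        members: list[str] = []
        if len(cand):
            r2 = _r2_to_index(counts, i, cand)
            absorbed = cand[r2 > spec.r2]
            assigned[absorbed] = True
            members = [ids[j] for j in absorbed]
        indices.append(ids[i])
        clumps[ids[i]] = members

    order = {s: (c, p) for s, c, p in zip(ids, chrom, pos)}
    indices.sort(key=lambda s: order[s])
    return (indices, clumps) if return_clumps else indices


def clump_report(clumps: dict[str, list[str]]) -> pd.DataFrame:
    rows = [
        {"index_snp": k, "n_members": len(v), "members": ",".join(v)}
        for k, v in clumps.items()
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# pruning
# ---------------------------------------------------------------------------

def prune(panel: GenotypePanel, r2_threshold: float, window: int) -> list[str]:
    """Sliding-window greedy pruning, keeping the earlier-position SNP.

    Walks SNPs in (chromosome, position) order; a SNP is removed if any
    already-retained SNP on the same chromosome within ``window`` bp has
    genotypic r² ≥ ``r2_threshold``.
    """
    snps = panel.snps.sort_values(["chrom", "pos"])
    counts = panel.counts[snps.index].to_numpy(float)
    if np.isnan(counts).any():
        col_mean = np.nanmean(counts, axis=0)
        ii, jj = np.where(np.isnan(counts))
        counts[ii, jj] = col_mean[jj]
    pos = snps["pos"].to_numpy(np.int64)
    chrom = snps["chrom"].astype(str).to_numpy()
    ids = snps.index.to_numpy()

    kept: list[int] = []
    kept_by_chrom: dict[str, list[int]] = {}
    for i in range(len(ids)):
        near = [
            j for j in kept_by_chrom.get(chrom[i], [])
            if pos[i] - pos[j] <= window
        ]
        drop = False
        if near:
            r2 = _r2_to_index(counts, i, np.asarray(near))
            drop = bool((r2 >= r2_threshold).any())
        if not drop:
            kept.append(i)
            kept_by_chrom.setdefault(chrom[i], []).append(i)
    return [ids[i] for i in kept]
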