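"""Shared in-memory containers.

Summary statistics are plain :class:`pandas.DataFrame` objects with the
canonical columns ``snp, chrom, pos, a1, a2, beta, se, p, freq_a1`` (``beta``
is the effect of one copy of the A1 allele, in trait units).  Frequency
tables and genotype panels carry enough per-SNP allele metadata to be
harmonized against summary statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: canonical summary-statistics columns, in writing order
SUMSTATS_COLUMNS = ["snp", "chrom", "pos", "a1", "a2", "beta", "se", "p", "freq_a1"]

#: canonical per-SNP metadata columns for panels / frequency tables
SNP_META_COLUMNS = ["chrom", "pos", "a1", "a2"]


def _check_snp_meta(snps: pd.DataFrame) -> None:
    missing = [c for c in SNP_META_COLUMNS if c not in snps.columns]
    if missing:
        raise ValueError(f"SNP metadata missing columns: {missing}")
    if snps.index.duplicated().any():
        dups = snps.index[snps.index.duplicated()].unique().tolist()[:5]
        raise ValueError(f"duplicate SNP ids in metadata, e.g. {dups}")


@dataclass
class FrequencyTable:
    """Effect-allele (A1) frequencies for L SNPs across M populations.

    Attributes
    ----------
    snps : DataFrame indexed by SNP id with columns chrom, pos, a1, a2.
    freq : DataFrame (SNP × population) of A1 frequencies ``p``.
    x : optional DataFrame of A1 allele counts (same shape as ``freq``).
    n : optional DataFrame of haploid observation counts; ``p = x / n``
        whenever counts are present.
    """

    snps: pd.DataFrame
    freq: pd.DataFrame
    x: pd.DataFrame | None = None
    n: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        _check_snp_meta(self.snps)
        if not self.freq.index.equals(self.snps.index):
            self.freq = self.freq.reindex(self.snps.index)
        vals = self.freq.to_numpy(float)
        if np.nanmin(vals) < 0 or np.nanmax(vals) > 1:
            raise ValueError("frequencies outside [0, 1]")
        if (self.x is None) != (self.n is None):
            raise ValueError("x and n must be given together")
        if self.x is not None:
            xv = self.x.to_numpy(float)
            nv = self.n.to_numpy(float)
            if (xv < 0).any() or (xv > nv).any():
                raise ValueError("allele counts must satisfy 0 <= x <= n")

    @property
    def populations(self) -> list[str]:
        return list(self.freq.columns)

    @property
    def n_snps(self) -> int:
        return len(self.freq)

    def subset(self, ids) -> "FrequencyTable":
        ids = pd.Index(ids)
        return FrequencyTable(
            snps=self.snps.loc[ids],
            freq=self.freq.loc[ids],
            x=None if self.x is None else self.x.loc[ids],
            n=None if self.n is None else self.n.loc[ids],
        )

    def write_tsv(self, path) -> None:
        out = self.snps.copy()
        for pop in self.populations:
            out[f"freq_{pop}"] = self.freq[pop]
            if self.x is not None:
                out[f"x_{pop}"] = self.x[pop]
                out[f"n_{pop}"] = self.n[pop]
        out.index.name = "snp"
        out.to_csv(path, sep="\t")


@dataclass
class GenotypePanel:
    """Allele-count matrix (individuals × SNPs) with metadata.

    ``counts`` holds the number of A1 alleles per individual per SNP:
    0/1/2 for diploid data, 0/1 for pseudo-haploid data.  Missing calls are
    NaN.  ``individuals`` is indexed by individual id with columns
    ``population``, ``sex`` (0/1) and ``latitude``.
    """

    counts: pd.DataFrame
    individuals: pd.DataFrame
    snps: pd.DataFrame
    ploidy: int = 2

    def __post_init__(self) -> None:
        _check_snp_meta(self.snps)
        if not self.counts.columns.equals(self.snps.index):
            raise ValueError("counts columns must equal snps index")
        if not self.counts.index.equals(self.individuals.index):
            raise ValueError("counts index must equal individuals index")
        vals = self.counts.to_numpy(float)
        with np.errstate(invalid="ignore"):
            if np.nanmin(vals) < 0 or np.nanmax(vals) > self.ploidy:
                raise ValueError("allele counts outside ploidy bounds")
        for chrom, sub in self.snps.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            if (np.diff(pos) <= 0).any():
                raise ValueError(
                    f"positions not strictly increasing on chromosome {chrom}"
                )

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def snp_ids(self) -> pd.Index:
        return self.snps.index


@dataclass
class ScoreResult:
    """Population polygenic scores with centering and credible intervals.

    ``z`` is the raw score ``Z_m = Σ_l β_l p_lm`` in trait units; the
    standardized score is ``(Z_m − μ) / sqrt(V_A)`` with
    ``μ = Σ β_l p̄_l`` and additive variance ``V_A = Σ β_l² p̄_l (1 − p̄_l)``
    computed at the unweighted across-population mean frequency ``p̄``.
    """

    z: pd.Series
    standardized: pd.Series
    mu: float
    v_a: float
    p_bar: pd.Series
    n_snps: int
    v_z: pd.Series | None = None
    half_width: pd.Series | None = None           # raw trait units
    half_width_std: pd.Series | None = None       # divided by sqrt(V_A)

    @property
    def populations(self) -> list[str]:
        return list(self.z.index)

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"z": self.z, "standardized": self.standardized})
        if self.half_width is not None:
            out["half_width"] = self.half_width
            out["half_width_std"] = self.half_width_std
        out.index.name = "population"
        return out


@dataclass
class QxResult:
    """Overdispersion and latitude-cline test results."""

    qx: float
    dof: int
    p_qx: float
    v_a: float
    f_hat: np.ndarray
    latitude_stat: float | None = None
    p_lat: float | None = None
    empirical_p: float | None = None

    def to_dict(self) -> dict:
        out = {
            "qx": float(self.qx),
            "dof": int(self.dof),
            "p_qx": float(self.p_qx),
            "v_a": float(self.v_a),
        }
        if self.latitude_stat is not None:
            out["latitude_stat"] = float(self.latitude_stat)
            out["p_lat"] = float(self.p_lat)
        if self.empirical_p is not None:
            out["empirical_p"] = float(self.empirical_p)
        return out
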