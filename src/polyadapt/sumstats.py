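"""Reading, validation and allele harmonization of GWAS summary statistics,
plus genotype-panel utilities (pseudo-haploidization, allele frequencies).

Positions are 1-based inclusive throughout (VCF convention); BED-like block
files are 0-based half-open and converted at the boundary (see
:mod:`polyadapt.ldselect`).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import SUMSTATS_COLUMNS, FrequencyTable, GenotypePanel

logger = logging.getLogger(__name__)

VALID_ALLELES = {"A", "C", "G", "T"}
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: column-name dialects: canonical name -> file column name.
#: "giant" follows GIANT consortium releases (no chromosome/position);
#: "neale" follows Neale-lab UK Biobank releases joined to a variants table.
DIALECTS: dict[str, dict[str, str]] = {
    "canonical": {
        "snp": "SNP", "chrom": "CHR", "pos": "POS", "a1": "A1", "a2": "A2",
        "beta": "BETA", "se": "SE", "p": "P", "freq_a1": "FREQ_A1",
    },
    "giant": {
        "snp": "MarkerName", "a1": "Allele1", "a2": "Allele2",
        "beta": "b", "se": "SE", "p": "p",
        "freq_a1": "Freq.Allele1.HapMapCEU",
    },
    "neale": {
        "snp": "rsid", "chrom": "chr", "pos": "pos", "a1": "alt", "a2": "ref",
        "beta": "beta", "se": "se", "p": "pval", "freq_a1": "minor_AF",
    },
}

MANDATORY = ["snp", "a1", "a2", "beta", "se", "p"]


def read_sumstats(path, dialect: str | dict = "canonical") -> pd.DataFrame:
    """Read a whitespace/tab-delimited summary-statistics file.

    ``dialect`` names a documented column mapping (``canonical``, ``giant``,
    ``neale``) or is itself a canonical-name → file-column dict.  Rows with
    unparseable P values or invalid alleles are dropped with a warning;
    duplicate SNP keys are rejected.
    """
    mapping = DIALECTS[dialect] if isinstance(dialect, str) else dict(dialect)
    raw = pd.read_csv(path, sep=r"\s+", dtype=str)

    missing = [mapping[c] for c in MANDATORY if mapping.get(c) not in raw.columns]
    if missing:
        raise ValueError(f"missing mandatory column(s): {missing}")

    df = pd.DataFrame(index=raw.index)
    for canon, col in mapping.items():
        if col in raw.columns:
            df[canon] = raw[col]
    for canon in ("chrom", "pos", "freq_a1"):
        if canon not in df.columns:
            df[canon] = np.nan

    df["a1"] = df["a1"].str.upper()
    df["a2"] = df["a2"].str.upper()
    for col in ("beta", "se", "p", "freq_a1"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["pos"] = pd.to_numeric(df["pos"], errors="coerce").astype("Int64")
    df["chrom"] = df["chrom"].astype(str).str.replace(r"\.0$", "", regex=True)

    n0 = len(df)
    bad_allele = ~(df["a1"].isin(VALID_ALLELES) & df["a2"].isin(VALID_ALLELES))
    bad_p = df["p"].isna() | (df["p"] <= 0) | (df["p"] > 1)
    bad_num = df["beta"].isna() | df["se"].isna() | ~np.isfinite(df["beta"])
    bad = bad_allele | bad_p | bad_num
    if bad.any():
        logger.warning("dropped %d/%d malformed rows (%d bad alleles, "
                       "%d bad P, %d bad beta/se)", int(bad.sum()), n0,
                       int(bad_allele.sum()), int(bad_p.sum()),
                       int(bad_num.sum()))
        df = df[~bad]

    dup = df["snp"].duplicated(keep=False)
    if dup.any():
        raise ValueError("duplicate SNP keys: "
                         f"{sorted(df.loc[dup, 'snp'].unique())[:10]}")
    if df["pos"].notna().all() and df["chrom"].notna().all():
        pair = df[["a1", "a2"]].apply(frozenset, axis=1)
        key = list(zip(df["chrom"], df["pos"], pair))
        if pd.Index(key).duplicated().any():
            raise ValueError("duplicate (chromosome, position, allele-pair) keys")

    return df[SUMSTATS_COLUMNS].reset_index(drop=True)


def write_sumstats(table: pd.DataFrame, path) -> None:
    """Write the canonical tab-separated dialect (round-trips with
    :func:`read_sumstats`)."""
    out = table[SUMSTATS_COLUMNS].copy()
    out.columns = [DIALECTS["canonical"][c] for c in SUMSTATS_COLUMNS]
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# harmonization
# ---------------------------------------------------------------------------

def _is_palindromic(a1: pd.Series, a2: pd.Series) -> pd.Series:
    return a2 == a1.map(COMPLEMENT)


def harmonize(
    sumstats: pd.DataFrame,
    target: FrequencyTable | GenotypePanel,
) -> tuple[pd.DataFrame, dict]:
    """Align effect sizes to the target's counted allele.

    Joins on SNP id.  If the target counts the A2 allele, β is negated and
    the reported frequency mapped ``f → 1 − f``; strand-flipped matches
    (complement alleles) are resolved; palindromic A/T and C/G SNPs and
    incompatible or unmatched SNPs are dropped.  Returns the harmonized
    table (alleles relabelled to the target's) and a report of counts per
    action.  The operation is idempotent: harmonizing an already-harmonized
    table is the identity (minus nothing).
    """
    tsnps = target.snps
    ss = sumstats.set_index("snp", drop=False)

    report = {k: 0 for k in ("kept", "same", "swapped", "strand_flipped",
                             "strand_swapped", "palindromic_dropped",
                             "incompatible_dropped", "unmatched_dropped")}

    common = ss.index.intersection(tsnps.index)
    report["unmatched_dropped"] = len(ss) - len(common)
    ss = ss.loc[common]
    tg = tsnps.loc[common]

    pal = _is_palindromic(ss["a1"], ss["a2"])
    report["palindromic_dropped"] = int(pal.sum())
    ss, tg = ss[~pal], tg[~pal]

    c1 = ss["a1"].map(COMPLEMENT)
    c2 = ss["a2"].map(COMPLEMENT)
    same = (ss["a1"] == tg["a1"]) & (ss["a2"] == tg["a2"])
    swapped = (ss["a1"] == tg["a2"]) & (ss["a2"] == tg["a1"])
    flipped = (c1 == tg["a1"]) & (c2 == tg["a2"]) & ~same & ~swapped
    flipswap = (c1 == tg["a2"]) & (c2 == tg["a1"]) & ~same & ~swapped
    bad = ~(same | swapped | flipped | flipswap)

    report["same"] = int(same.sum())
    report["swapped"] = int(swapped.sum())
    report["strand_flipped"] = int(flipped.sum())
    report["strand_swapped"] = int(flipswap.sum())
    report["incompatible_dropped"] = int(bad.sum())

    ss = ss[~bad].copy()
    tg = tg[~bad]
    neg = (swapped | flipswap)[~bad]
    ss.loc[neg, "beta"] = -ss.loc[neg, "beta"]
    ss.loc[neg, "freq_a1"] = 1.0 - ss.loc[neg, "freq_a1"]
    ss["a1"] = tg["a1"]
    ss["a2"] = tg["a2"]
    ss["chrom"] = tg["chrom"].astype(str)
    ss["pos"] = tg["pos"]
    report["kept"] = len(ss)

    logger.info("harmonize: %s", report)
    return ss.reset_index(drop=True), report


# ---------------------------------------------------------------------------
# panels
# ---------------------------------------------------------------------------

def pseudo_haploidize(panel: GenotypePanel, seed: int = 0) -> GenotypePanel:
    """Sample one allele per individual per SNP (0→0, 2→1, 1→Bernoulli(½))."""
    if panel.ploidy == 1:
        logger.warning("panel already pseudo-haploid; returning unchanged")
        return panel
    rng = np.random.default_rng(seed)
    cnt = panel.counts.to_numpy(float)
    out = np.where(cnt == 1, rng.integers(0, 2, size=cnt.shape).astype(float),
                   cnt / 2.0)
    out[np.isnan(cnt)] = np.nan
    return GenotypePanel(
        counts=pd.DataFrame(out, index=panel.counts.index,
                            columns=panel.counts.columns),
        individuals=panel.individuals.copy(),
        snps=panel.snps.copy(),
        ploidy=1,
    )


def allele_freqs(
    panel: GenotypePanel, grouping: pd.Series | None = None
) -> FrequencyTable:
    """Per-population A1 frequencies ``p = Σ counts / (ploidy · n)``.

    ``grouping`` assigns each individual to exactly one population
    (default: the panel's population labels).  Missing genotypes are
    excluded from both x and n; they are never imputed here.
    """
    if grouping is None:
        grouping = panel.individuals["population"]
    grouping = grouping.reindex(panel.counts.index)
    if grouping.isna().any():
        raise ValueError("grouping must assign every individual")

    freq, xs, ns = {}, {}, {}
    for pop, idx in panel.counts.groupby(grouping, sort=False).groups.items():
        sub = panel.counts.loc[idx].to_numpy(float)
        if sub.shape[0] == 0:
            raise ValueError(f"empty population {pop!r}")
        x = np.nansum(sub, axis=0)
        n = panel.ploidy * np.sum(~np.isnan(sub), axis=0)
        if (n == 0).any():
            raise ValueError(f"population {pop!r} has SNPs with no calls")
        freq[pop] = x / n
        xs[pop] = x
        ns[pop] = n

    idx = panel.snps.index
    return FrequencyTable(
        snps=panel.snps.copy(),
        freq=pd.DataFrame(freq, index=idx),
        x=pd.DataFrame(xs, index=idx),
        n=pd.DataFrame(ns, index=idx),
    )
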