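"""Population polygenic scores, standardization, Beta-posterior intervals.

The population score is the effect-weighted sum of allele frequencies,
``Z_m = Σ_l β_l p_lm``.  Scores are reported in centered standardized form
``(Z_m − μ)/√V_A`` with ``μ = Σ β_l p̄_l`` and ``V_A = Σ β_l² p̄_l (1 − p̄_l)``,
where ``p̄_l`` is the *unweighted* mean frequency across the analyzed
populations (deliberately not sample-size weighted: ancient groups have very
different n).

95% credible intervals come from a per-locus Beta posterior: a Uniform
prior updated with allele counts x of n gives Beta(1 + x, 1 + n − x); the
score variance ``V_Z(m) = Σ_l β_l² Var_posterior`` treats loci and
populations as independent (no LD correction), and the half-width is
``1.96 √V_Z``.
"""

from __future__ import annotations

import json
import logging

import numpy as np
import pandas as pd

from .containers import FrequencyTable, ScoreResult

logger = logging.getLogger(__name__)

Z_CRIT = 1.96


def _aligned(betas: pd.Series, freqs: FrequencyTable):
    ids = betas.index.intersection(freqs.snps.index)
    dropped = len(betas) - len(ids)
    sub = freqs.freq.loc[ids]
    complete = ~sub.isna().any(axis=1)
    dropped += int((~complete).sum())
    ids = ids[complete.to_numpy()]
    if dropped:
        logger.info("%d SNPs dropped (missing from frequency table)", dropped)
    if len(ids) == 0:
        raise ValueError("no SNPs with frequencies in every population")
    return ids, dropped


def polygenic_score(betas: pd.Series, freqs: FrequencyTable) -> pd.Series:
    """Raw score ``Z_m = Σ_l β_l p_lm`` per population (trait units)."""
    ids, _ = _aligned(betas, freqs)
    b = betas.loc[ids].to_numpy()
    z = b @ freqs.freq.loc[ids].to_numpy()
    return pd.Series(z, index=freqs.populations, name="z")


def standardize(
    z: pd.Series, betas: pd.Series, freqs: FrequencyTable
) -> tuple[pd.Series, float, float, pd.Series]:
    """Centered standardized scores; returns (standardized, μ, V_A, p̄)."""
    if len(freqs.populations) < 2:
        raise ValueError("standardization needs >= 2 populations")
    ids, _ = _aligned(betas, freqs)
    b = betas.loc[ids].to_numpy()
    p_bar = freqs.freq.loc[ids].mean(axis=1)
    mu = float(b @ p_bar.to_numpy())
    v_a = float((b**2) @ (p_bar * (1.0 - p_bar)).to_numpy())
    if v_a <= 0:
        raise ValueError(
            "V_A = 0: all effects zero or all SNPs fixed at p̄ ∈ {0, 1}; "
            "standardized scores undefined"
        )
    std = (z - mu) / np.sqrt(v_a)
    return std.rename("standardized"), mu, v_a, p_bar.rename("p_bar")


def credible_interval(
    betas: pd.Series, freqs: FrequencyTable, v_a: float | None = None
) -> tuple[pd.Series, pd.Series, pd.Series | None]:
    """Per-population ``(V_Z, half-width)`` from Beta(1+x, 1+n−x) posteriors.

    Returns raw half-widths (trait units) and, when ``v_a`` is given,
    standardized half-widths (divided by √V_A).
    """
    if freqs.x is None:
        raise ValueError("credible intervals need allele counts (x, n)")
    ids, _ = _aligned(betas, freqs)
    n = freqs.n.loc[ids].to_numpy(float)
    if (n <= 0).any():
        bad = freqs.n.loc[ids].index[(n <= 0).any(axis=1)]
        raise ValueError(f"n = 0 at SNP(s) {bad.tolist()[:5]}")
    x = freqs.x.loc[ids].to_numpy(float)
    a, b_ = 1.0 + x, 1.0 + n - x
    var_post = a * b_ / ((a + b_) ** 2 * (a + b_ + 1.0))
    beta2 = betas.loc[ids].to_numpy() ** 2
    v_z = pd.Series(beta2 @ var_post, index=freqs.populations, name="v_z")
    half = Z_CRIT * np.sqrt(v_z)
    half_std = None if v_a is None else half / np.sqrt(v_a)
    return v_z, half.rename("half_width"), half_std


def posterior_mean_freqs(freqs: FrequencyTable) -> pd.DataFrame:
    """Posterior mean frequencies (x+1)/(n+2) under the Uniform prior."""
    if freqs.x is None:
        raise ValueError("posterior means need allele counts (x, n)")
    return (freqs.x + 1.0) / (freqs.n + 2.0)


def score_populations(
    betas: pd.Series, freqs: FrequencyTable, intervals: bool = True
) -> ScoreResult:
    """Full scoring pipeline: raw Z, standardized scores, credible bands."""
    ids, _ = _aligned(betas, freqs)
    z = polygenic_score(betas, freqs)
    std, mu, v_a, p_bar = standardize(z, betas, freqs)
    v_z = half = half_std = None
    if intervals and freqs.x is not None:
        v_z, half, half_std = credible_interval(betas, freqs, v_a)
    return ScoreResult(z=z, standardized=std, mu=mu, v_a=v_a, p_bar=p_bar,
                       n_snps=len(ids), v_z=v_z, half_width=half,
                       half_width_std=half_std)


def write_scores(result: ScoreResult, tsv_path, json_path=None) -> None:
    result.to_frame().to_csv(tsv_path, sep="\t")
    if json_path is not None:
        meta = {"mu": result.mu, "v_a": result.v_a, "n_snps": result.n_snps}
        with open(json_path, "w") as fh:
            json.dump(meta, fh, indent=2)
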