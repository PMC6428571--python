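"""Builders for small hand-specified containers used across tests."""

import numpy as np
import pandas as pd

from polyadapt.containers import FrequencyTable, GenotypePanel


def make_freq_table(p, populations=None, x=None, n=None, chrom="1",
                    pos=None, a1="A", a2="G", ids=None):
    """Build a FrequencyTable from an L×M array of A1 frequencies."""
    p = np.atleast_2d(np.asarray(p, dtype=float))
    L, M = p.shape
    populations = populations or [f"pop{m + 1}" for m in range(M)]
    ids = pd.Index(ids if ids is not None else [f"s{i + 1}" for i in range(L)],
                   name="snp")
    pos = np.asarray(pos if pos is not None else (np.arange(L) + 1) * 10_000)
    snps = pd.DataFrame({"chrom": chrom, "pos": pos, "a1": a1, "a2": a2},
                        index=ids)
    kw = {}
    if x is not None:
        kw["x"] = pd.DataFrame(np.atleast_2d(x), index=ids, columns=populations)
        kw["n"] = pd.DataFrame(np.atleast_2d(n), index=ids, columns=populations)
    return FrequencyTable(snps=snps,
                          freq=pd.DataFrame(p, index=ids, columns=populations),
                          **kw)


def make_panel(counts, chrom="1", pos=None, populations=None, sex=None,
               ploidy=2, ids=None, a1=None, a2=None):
    """Build a GenotypePanel from an individuals × SNPs count array."""
    counts = np.atleast_2d(np.asarray(counts, dtype=float))
    N, L = counts.shape
    ids = pd.Index(ids if ids is not None else [f"s{i + 1}" for i in range(L)],
                   name="snp")
    pos = np.asarray(pos if pos is not None else (np.arange(L) + 1) * 10_000)
    snps = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos,
            "a1": a1 if a1 is not None else "A",
            "a2": a2 if a2 is not None else "G",
        },
        index=ids,
    )
    individuals = pd.DataFrame(
        {
            "population": populations if populations is not None else "pop1",
            "sex": sex if sex is not None else np.zeros(N, dtype=int),
            "latitude": np.nan,
        },
        index=pd.Index([f"ind{i + 1}" for i in range(N)], name="individual"),
    )
    return GenotypePanel(
        counts=pd.DataFrame(counts, index=individuals.index, columns=ids),
        individuals=individuals, snps=snps, ploidy=ploidy,
    )
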