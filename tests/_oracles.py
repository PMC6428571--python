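"""Independent brute-force reference implementations used only in tests.

Kept deliberately naive (explicit loops, no shared code with the package)
so they can serve as oracles for the optimized implementations.
"""

import numpy as np


def naive_r2(g1, g2):
    g1 = np.asarray(g1, float)
    g2 = np.asarray(g2, float)
    if np.var(g1) == 0 or np.var(g2) == 0:
        return 0.0
    return float(np.corrcoef(g1, g2)[0, 1] ** 2)


def brute_clump(snps, r2, p1, p2, r2_thr, window):
    """Literal transcription of the greedy clumping definition.

    ``snps``: list of dicts with keys id, chrom, pos, p (pre-sorted not
    required); ``r2``: dict mapping frozenset({id_i, id_j}) -> r² value.
    Returns the index SNP ids sorted by (chrom, pos).
    """
    order = sorted(snps, key=lambda s: (s["p"], s["pos"], s["id"]))
    assigned = set()
    indices = []
    for s in order:
        if s["p"] >= p1:
            break
        if s["id"] in assigned:
            continue
        assigned.add(s["id"])
        indices.append(s)
        for t in order:
            if t["id"] in assigned or t["p"] >= p2:
                continue
            if t["chrom"] != s["chrom"]:
                continue
            if abs(t["pos"] - s["pos"]) > window:
                continue
            if r2[frozenset((s["id"], t["id"]))] > r2_thr:
                assigned.add(t["id"])
    return [s["id"] for s in sorted(indices,
                                    key=lambda s: (s["chrom"], s["pos"]))]


def brute_prune(snps, r2, r2_thr, window):
    """Greedy position-order pruning: keep a SNP unless a kept SNP within
    the window has r² ≥ threshold."""
    order = sorted(snps, key=lambda s: (s["chrom"], s["pos"]))
    kept = []
    for s in order:
        clash = any(
            k["chrom"] == s["chrom"]
            and abs(s["pos"] - k["pos"]) <= window
            and r2[frozenset((s["id"], k["id"]))] >= r2_thr
            for k in kept
        )
        if not clash:
            kept.append(s)
    return [s["id"] for s in kept]


def qx_two_pop_closed_form(z1, z2, v_a, f11, f22, f12):
    """Rank-one reduction of the Qx quadratic form at M = 2, on the
    allele-frequency scale (null Var(Z) = V_A·F)."""
    return (z1 - z2) ** 2 / (v_a * (f11 + f22 - 2.0 * f12))
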