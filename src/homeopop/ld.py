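"""Linkage-disequilibrium decay profiling.

Squared correlation r^2 between genotype vectors (selfing accessions are
haploid genotype vectors, so genotype r^2 equals haplotype r^2), binned
by pairwise distance into 50-bp bins with the mean and the central 50%
and 90% empirical quantile bands per bin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["LDBin", "genotype_r2", "ld_decay_profile"]


@dataclass
class LDBin:
    distance_lo: int
    distance_hi: int
    n_pairs: int
    mean_r2: float
    q25: float
    q75: float
    q05: float
    q95: float


def genotype_r2(g1, g2) -> float | None:
    """Squared Pearson correlation of two allele-count vectors.

    Pairs with a missing value (< 0) in either vector are dropped; returns
    None when fewer than two complete pairs remain or either site is
    monomorphic among them.
    """
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    keep = (g1 >= 0) & (g2 >= 0)
    x, y = g1[keep], g2[keep]
    if len(x) < 2:
        return None
    vx, vy = x.var(), y.var()
    if vx == 0 or vy == 0:
        return None
    cov = ((x - x.mean()) * (y - y.mean())).mean()
    return float(cov * cov / (vx * vy))


def ld_decay_profile(positions, genotypes, maf_min: float = 0.1,
                     max_dist: int = 50_000, bin_width: int = 50) -> list[LDBin]:
    """Binned r^2 decay over all intra-scaffold pairs within ``max_dist``.

    ``positions`` must be sorted; ``genotypes`` is (n_accessions, S) with
    missing = -1.  Sites with minor-allele frequency < ``maf_min`` among
    non-missing calls are excluded.
    """
    positions = np.asarray(positions)
    G = np.asarray(genotypes)
    if np.any(np.diff(positions) < 0):
        raise ValueError("positions must be sorted")
    keep = []
    for j in range(G.shape[1]):
        g = G[:, j]
        g = g[g >= 0]
        if len(g) == 0:
            continue
        p = g.mean()
        if min(p, 1 - p) >= maf_min:
            keep.append(j)
    pos = positions[keep]
    Gk = G[:, keep]
    n_bins = int(np.ceil(max_dist / bin_width))
    values: list[list[float]] = [[] for _ in range(n_bins)]
    S = len(pos)
    complete = S and np.all(Gk >= 0)
    if complete:
        X = Gk.astype(float)
        X = X - X.mean(axis=0)
        var = (X * X).mean(axis=0)
        for a in range(S):
            hi = int(np.searchsorted(pos, pos[a] + max_dist, side="left"))
            if hi <= a + 1:
                continue
            cov = X[:, a] @ X[:, a + 1:hi] / X.shape[0]
            with np.errstate(invalid="ignore", divide="ignore"):
                r2 = cov * cov / (var[a] * var[a + 1:hi])
            d = pos[a + 1:hi] - pos[a]
            for dist, val in zip(d, r2):
                if np.isfinite(val):
                    values[int(dist // bin_width)].append(float(val))
    else:
        for a in range(S):
            for b in range(a + 1, S):
                d = pos[b] - pos[a]
                if d >= max_dist:
                    break
                r2 = genotype_r2(Gk[:, a], Gk[:, b])
                if r2 is not None:
                    values[int(d // bin_width)].append(r2)
    out = []
    for bi, vals in enumerate(values):
        if not vals:
            continue
        v = np.asarray(vals)
        out.append(LDBin(bi * bin_width, (bi + 1) * bin_width, len(v),
                         float(v.mean()),
                         float(np.quantile(v, 0.25)),
                         float(np.quantile(v, 0.75)),
                         float(np.quantile(v, 0.05)),
                         float(np.quantile(v, 0.95))))
    return out
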