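"""Hudson coalescent with infinite-sites mutation.

A small single-locus coalescent simulator: exponential coalescence times at
rate C(k,2) (time in units of 2N generations, so theta = 4*N*mu per locus
gives E[S] = theta * a_{n-1}), Poisson mutations on branches at rate
theta/2 per unit branch length, and piecewise-constant population size
changes.  A "bottleneck" demography shrinks the ancestral population so
that surviving lineages coalesce almost instantly once they reach it,
producing star-like genealogies and an excess of rare variants (negative
Tajima's D), as expected for a recently founded selfing allopolyploid.

A structured variant with free recombination between blocks supports
LD-decay profiling: within a non-recombining block all sites share one
genealogy; blocks are separated by crossover events along the region, and
optional two-deme structure creates the nonzero long-range r^2 asymptote
seen in subdivided samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Demography",
    "CONSTANT",
    "BOTTLENECK",
    "Locus",
    "simulate_coalescent_sample",
    "simulate_locus",
    "simulate_structured_region",
]


@dataclass(frozen=True)
class Demography:
    """Piecewise-constant population sizes, backwards in time.

    ``epoch_times[i]`` is the start (pastward) of epoch i+1; ``sizes[0]``
    applies on [0, epoch_times[0]).  Sizes are relative to the present-day
    reference size used to scale theta.
    """

    epoch_times: tuple = ()
    sizes: tuple = (1.0,)

    def __post_init__(self):
        if len(self.sizes) != len(self.epoch_times) + 1:
            raise ValueError("need len(sizes) == len(epoch_times) + 1")
        if any(s <= 0 for s in self.sizes):
            raise ValueError("population sizes must be positive")


CONSTANT = Demography()
#: Recent normal-sized epoch over a tiny ancestral population: lineages that
#: survive to the ancestral epoch coalesce essentially at once, giving
#: star-like trees and a strong excess of rare variants.
BOTTLENECK = Demography(epoch_times=(0.4,), sizes=(1.0, 0.02))


@dataclass
class Locus:
    """One simulated locus: derived counts per site and carrier sets."""

    n: int
    derived_counts: np.ndarray          # (S,) derived-allele sample counts
    carriers: list = field(default_factory=list)  # per site: bool (n,) array
    total_branch_length: float = 0.0

    @property
    def S(self) -> int:
        return len(self.derived_counts)

    def haplotypes(self) -> np.ndarray:
        """(n, S) 0/1 haplotype matrix."""
        if self.S == 0:
            return np.zeros((self.n, 0), dtype=np.int8)
        return np.stack(self.carriers, axis=1).astype(np.int8)


def _coalescence_times(n: int, demography: Demography, rng) -> np.ndarray:
    """Waiting times between coalescences for k = n..2 lineages."""
    times = np.empty(n - 1)
    t = 0.0
    epoch = 0
    bounds = list(demography.epoch_times) + [np.inf]
    for idx, k in enumerate(range(n, 1, -1)):
        rate = k * (k - 1) / 2.0
        while True:
            lam = demography.sizes[epoch]
            w = rng.exponential(lam / rate)
            if t + w <= bounds[epoch]:
                t += w
                break
            t = bounds[epoch]
            epoch += 1
        times[idx] = t
    return times


def simulate_locus(n: int, theta: float, demography: Demography = CONSTANT,
                   rng=None, track_carriers: bool = True) -> Locus:
    """Simulate one locus under the Hudson coalescent.

    theta is the per-locus scaled mutation rate 4*N*mu.
    """
    if n < 2:
        raise ValueError("need at least 2 sampled sequences")
    if theta < 0:
        raise ValueError("theta must be >= 0")
    rng = np.random.default_rng(rng)
    node_times = _coalescence_times(n, demography, rng)

    # lineages: (birth_time, descendant boolean mask)
    lineages = [(0.0, np.eye(n, dtype=bool)[i]) for i in range(n)]
    per_branch = []  # (length, mask)
    for t_c in node_times:
        i, j = sorted(rng.choice(len(lineages), size=2, replace=False))
        tb_i, mask_i = lineages[i]
        tb_j, mask_j = lineages[j]
        per_branch.append((t_c - tb_i, mask_i))
        per_branch.append((t_c - tb_j, mask_j))
        lineages[i] = (t_c, mask_i | mask_j)
        del lineages[j]

    total_len = float(sum(length for length, _ in per_branch))
    locus = Locus(n=n, derived_counts=np.array([], dtype=int),
                  total_branch_length=total_len)
    if theta == 0:
        return locus
    counts: list[int] = []
    carriers: list[np.ndarray] = []
    lengths = np.array([b[0] for b in per_branch])
    n_mut = rng.poisson(theta / 2.0 * lengths)
    for (length, mask), m in zip(per_branch, n_mut):
        k = int(mask.sum())
        if k == 0 or k == n:
            continue
        for _ in range(int(m)):
            counts.append(k)
            if track_carriers:
                carriers.append(mask)
    locus.derived_counts = np.asarray(counts, dtype=int)
    locus.carriers = carriers
    return locus


def simulate_coalescent_sample(n: int, theta: float,
                               demography: Demography | str = CONSTANT,
                               n_loci: int = 1, rng=None,
                               track_carriers: bool = True) -> list[Locus]:
    """Simulate independent loci; ``demography`` may be 'constant'|'bottleneck'."""
    if isinstance(demography, str):
        try:
            demography = {"constant": CONSTANT, "bottleneck": BOTTLENECK}[demography]
        except KeyError:
            raise ValueError(f"unknown demography {demography!r}") from None
    rng = np.random.default_rng(rng)
    return [simulate_locus(n, theta, demography, rng, track_carriers)
            for _ in range(n_loci)]


_CLASS_FACTOR_CACHE: dict = {}


def expected_class_factors(n: int, demography: Demography,
                           n_loci: int = 8000) -> np.ndarray:
    """Per-class SFS distortion of a demography relative to constant size.

    Returns the raw ratios r_i = E_dem[S_i] / E_const[S_i] for unfolded
    classes i = 1..n-1 (a constant demography gives all ones) — the shared
    per-class multipliers that a nuisance-class DFE model absorbs.
    Estimated by simulation with an internal fixed seed and cached per
    (n, demography).
    """
    key = (n, demography.epoch_times, demography.sizes, n_loci)
    if key not in _CLASS_FACTOR_CACHE:
        if demography == CONSTANT:
            _CLASS_FACTOR_CACHE[key] = np.ones(n - 1)
        else:
            rng = np.random.default_rng(12345)
            counts = np.zeros(n - 1)
            for _ in range(n_loci):
                loc = simulate_locus(n, 10.0, demography, rng,
                                     track_carriers=False)
                if loc.S:
                    counts += np.bincount(loc.derived_counts,
                                          minlength=n)[1:n]
            neutral = 10.0 * n_loci / np.arange(1, n)
            _CLASS_FACTOR_CACHE[key] = counts / neutral
    return _CLASS_FACTOR_CACHE[key]


def simulate_structured_region(n: int, theta_per_site: float, length: int,
                               crossover_rate: float = 0.0, n_demes: int = 1,
                               split_time: float = 2.0, demography=CONSTANT,
                               rng=None):
    """Haplotypes over a region with free recombination between blocks.

    Crossover breakpoints are Poisson(crossover_rate * length) along the
    region; each non-recombining block draws its own genealogy, so r^2 is
    high within a block and decays with distance as pairs stop sharing
    blocks.  With ``n_demes`` == 2 the sample is split evenly and lineages
    may only coalesce within their deme until ``split_time``, after which
    all merge; the resulting allele-frequency differentiation is shared by
    every block and keeps long-range r^2 above zero.

    Returns (positions, haplotype matrix (n, S)).
    """
    rng = np.random.default_rng(rng)
    if n_demes not in (1, 2):
        raise ValueError("n_demes must be 1 or 2")
    n_breaks = rng.poisson(crossover_rate * length)
    breaks = np.sort(rng.uniform(0, length, n_breaks))
    edges = np.concatenate([[0.0], breaks, [length]])
    positions = []
    columns = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        block_len = hi - lo
        theta_block = theta_per_site * block_len
        if n_demes == 1:
            locus = simulate_locus(n, theta_block, demography, rng)
            hap = locus.haplotypes()
        else:
            hap = _two_deme_block(n, theta_block, split_time, rng)
        S = hap.shape[1]
        if S == 0:
            continue
        pos = np.sort(rng.uniform(lo, hi, S))
        positions.append(pos)
        columns.append(hap)
    if not positions:
        return np.array([]), np.zeros((n, 0), dtype=np.int8)
    return np.concatenate(positions), np.concatenate(columns, axis=1)


def _two_deme_block(n: int, theta: float, split_time: float, rng):
    """One block genealogy under a symmetric two-deme split model."""
    half = n // 2
    demes = [list(range(half)), list(range(half, n))]
    masks = {i: np.eye(n, dtype=bool)[i] for i in range(n)}
    births = {i: 0.0 for i in range(n)}
    next_id = n
    per_branch = []
    t = 0.0
    # phase 1: within-deme coalescence until split_time
    while True:
        k1, k2 = len(demes[0]), len(demes[1])
        rate = k1 * (k1 - 1) / 2.0 + k2 * (k2 - 1) / 2.0
        if rate == 0:
            break
        w = rng.exponential(1.0 / rate)
        if t + w > split_time:
            break
        t += w
        p1 = k1 * (k1 - 1) / 2.0 / rate
        d = 0 if rng.random() < p1 else 1
        i, j = rng.choice(len(demes[d]), 2, replace=False)
        id_i, id_j = demes[d][i], demes[d][j]
        per_branch.append((t - births[id_i], masks[id_i]))
        per_branch.append((t - births[id_j], masks[id_j]))
        masks[next_id] = masks[id_i] | masks[id_j]
        births[next_id] = t
        demes[d] = [x for x in demes[d] if x not in (id_i, id_j)]
        demes[d].append(next_id)
        next_id += 1
    # phase 2: merged panmictic coalescence
    t = max(t, split_time)
    pool = demes[0] + demes[1]
    while len(pool) > 1:
        k = len(pool)
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = rng.choice(k, 2, replace=False)
        id_i, id_j = pool[i], pool[j]
        per_branch.append((t - births[id_i], masks[id_i]))
        per_branch.append((t - births[id_j], masks[id_j]))
        masks[next_id] = masks[id_i] | masks[id_j]
        births[next_id] = t
        pool = [x for x in pool if x not in (id_i, id_j)]
        pool.append(next_id)
        next_id += 1
    cols = []
    for length, mask in per_branch:
        k = int(mask.sum())
        if k == 0 or k == n:
            continue
        for _ in range(int(rng.poisson(theta / 2.0 * length))):
            cols.append(mask.astype(np.int8))
    if not cols:
        return np.zeros((n, 0), dtype=np.int8)
    return np.stack(cols, axis=1)
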