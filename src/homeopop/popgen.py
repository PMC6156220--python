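"""Per-gene diversity and neutrality statistics.

Statistics computed from multi-accession CDS alignments (rows = accessions,
alphabet A/C/G/T plus N and '-' treated as missing, pairwise deletion):

* pi — average pairwise nucleotide differences per site
* theta_w — Watterson's estimator S / (a_{n-1} L)
* Tajima's D, Fay & Wu's unnormalised H, Fu & Li's D* and F*
* synonymous / nonsynonymous site partition (Nei-Gojobori-style
  enumeration of the 9 single-base changes per codon)
* folded / unfolded site-frequency spectra and hypergeometric projection
* Ne = pi / (4 mu)

All neutrality statistics follow the published variance constants
(Tajima 1989; Fu & Li 1993 with the Simonsen et al. 1995 corrections);
they return None when S = 0, where the statistics are undefined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import comb

from .codons import GENETIC_CODE, codon_site_counts, is_stop

__all__ = [
    "SiteFrequencySpectrum",
    "DiversityStats",
    "harmonic",
    "harmonic2",
    "alignment_array",
    "pairwise_pi",
    "watterson_theta",
    "tajimas_d",
    "fay_wu_h",
    "fu_li_star",
    "partition_sites",
    "build_sfs",
    "project_sfs",
    "effective_popsize",
    "gene_diversity",
    "window_diversity",
]

MISSING = (b"N", b"-")


def harmonic(n: int) -> float:
    """a_n = sum_{i=1..n} 1/i."""
    return float(np.sum(1.0 / np.arange(1, n + 1))) if n >= 1 else 0.0


def harmonic2(n: int) -> float:
    """b_n = sum_{i=1..n} 1/i^2."""
    return float(np.sum(1.0 / np.arange(1, n + 1) ** 2.0)) if n >= 1 else 0.0


def alignment_array(rows) -> np.ndarray:
    """Rows of equal-length sequences -> (n, L) byte array (upper-cased)."""
    if isinstance(rows, np.ndarray) and rows.dtype == "S1":
        return rows
    seqs = [str(r).upper() for r in rows]
    if len({len(s) for s in seqs}) > 1:
        raise ValueError("alignment rows differ in length")
    return np.frombuffer("".join(seqs).encode(), dtype="S1").reshape(
        len(seqs), -1).copy()


def _base_counts(aln: np.ndarray):
    """Per-site counts of A/C/G/T (4, L) and effective sample size (L,)."""
    counts = np.stack([(aln == b).sum(axis=0) for b in (b"A", b"C", b"G", b"T")])
    return counts, counts.sum(axis=0)


@dataclass
class SiteFrequencySpectrum:
    """Counts of segregating sites by allele-frequency class."""

    counts: np.ndarray
    n: int
    folded: bool
    site_class: str = "total"

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        want = self.n // 2 if self.folded else self.n - 1
        if len(self.counts) != want:
            raise ValueError(
                f"SFS with n={self.n} folded={self.folded} needs "
                f"{want} classes, got {len(self.counts)}")
        if np.any(self.counts < 0):
            raise ValueError("SFS counts must be >= 0")

    @property
    def S(self) -> float:
        return float(self.counts.sum())

    def fold(self) -> "SiteFrequencySpectrum":
        if self.folded:
            return self
        n = self.n
        folded = np.zeros(n // 2)
        for i, c in enumerate(self.counts, start=1):
            j = min(i, n - i)
            folded[j - 1] += c
        return SiteFrequencySpectrum(folded, n, True, self.site_class)


def pairwise_pi(alignment) -> tuple[float | None, int, float]:
    """Average pairwise diversity with per-site pairwise deletion.

    Returns (pi_per_site, n_sites_used, pi_locus) where pi_locus is the sum
    over usable sites of the per-site mean pairwise difference (the
    per-locus "mean number of pairwise differences" entering Tajima's D).
    Sites with fewer than two non-missing rows are excluded; an alignment
    with no usable site returns (None, 0, 0.0).
    """
    aln = alignment_array(alignment)
    if aln.shape[0] < 2:
        raise ValueError("need at least two sequences")
    counts, neff = _base_counts(aln)
    usable = neff >= 2
    if not usable.any():
        return None, 0, 0.0
    c = counts[:, usable].astype(float)
    m = neff[usable].astype(float)
    pairs = m * (m - 1) / 2.0
    same = (c * (c - 1) / 2.0).sum(axis=0)
    per_site = (pairs - same) / pairs
    pi_locus = float(per_site.sum())
    n_used = int(usable.sum())
    return pi_locus / n_used, n_used, pi_locus


def watterson_theta(S: int, n: int, L: float) -> float:
    """Watterson's per-site theta = S / (a_{n-1} * L)."""
    if L <= 0:
        raise ValueError("L must be > 0")
    if n < 2:
        raise ValueError("n must be >= 2")
    return S / (harmonic(n - 1) * L)


def tajimas_d(S: int, pi_locus: float, n: int) -> float | None:
    """Tajima's D from segregating sites and mean pairwise differences."""
    if n < 2:
        raise ValueError("n must be >= 2")
    if S == 0:
        return None
    a1 = harmonic(n - 1)
    a2 = harmonic2(n - 1)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return (pi_locus - S / a1) / np.sqrt(e1 * S + e2 * S * (S - 1))


def fay_wu_h(sfs: SiteFrequencySpectrum) -> float:
    """Unnormalised Fay & Wu's H = pi - theta_H from an unfolded SFS."""
    if sfs.folded:
        raise ValueError("Fay & Wu's H needs an unfolded (polarised) SFS")
    n = sfs.n
    i = np.arange(1, n)
    denom = n * (n - 1)
    pi = float((sfs.counts * 2.0 * i * (n - i) / denom).sum())
    theta_h = float((sfs.counts * 2.0 * i * i / denom).sum())
    return pi - theta_h


def _fu_li_constants(n: int):
    an = harmonic(n - 1)
    bn = harmonic2(n - 1)
    an1 = an + 1.0 / n  # a_{n+1} in Fu & Li's notation (sum to n)
    if n > 2:
        cn = 2.0 * (n * an - 2.0 * (n - 1)) / ((n - 1) * (n - 2))
    else:
        cn = 1.0
    dn = (cn + (n - 2) / (n - 1) ** 2.0
          + 2.0 / (n - 1) * (1.5 - (2 * an1 - 3) / (n - 2) - 1.0 / n))
    vd = ((n / (n - 1.0)) ** 2 * bn + an**2 * dn
          - 2.0 * n * an * (an + 1) / (n - 1.0) ** 2) / (an**2 + bn)
    ud = n / (n - 1.0) * (an - n / (n - 1.0)) - vd
    vf = (dn + 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
          - 2.0 / (n - 1) * (4.0 * bn - 6.0 + 8.0 / n)) / (an**2 + bn)
    uf = (n / (n - 1.0) + (n + 1) / (3.0 * (n - 1)) - 4.0 / (n * (n - 1))
          + 2.0 * (n + 1) / (n - 1.0) ** 2 * (an1 - 2.0 * n / (n + 1))) / an - vf
    return an, ud, vd, uf, vf


def fu_li_star(S: int, eta_s: int, n: int,
               pi_locus: float | None = None) -> tuple:
    """Fu & Li's D* and F* (within-sample singletons, no outgroup).

    eta_s is the number of singleton sites (minor-allele count 1).  F*
    additionally needs the per-locus mean pairwise differences; if
    ``pi_locus`` is None only D* is returned (F* as None).
    Returns (D*, F*); both None when S == 0.
    """
    if n < 4:
        raise ValueError("Fu & Li's starred statistics need n >= 4")
    if S == 0:
        return None, None
    an, ud, vd, uf, vf = _fu_li_constants(n)
    dstar = (n / (n - 1.0) * S - an * eta_s) / np.sqrt(ud * S + vd * S * S)
    fstar = None
    if pi_locus is not None:
        fstar = (pi_locus - (n - 1.0) / n * eta_s) / np.sqrt(uf * S + vf * S * S)
    return float(dstar), (None if fstar is None else float(fstar))


def partition_sites(alignment, frame: int = 0):
    """Synonymous/nonsynonymous site counts and per-site polymorphism class.

    The alignment must be in coding frame after dropping ``frame`` leading
    columns.  Per codon of the major (most frequent complete) haplotype,
    the 9 single-base changes are enumerated against the standard genetic
    code: the synonymous fraction per position accumulates into L_syn, the
    rest into L_nonsyn (changes creating a stop codon count as
    nonsynonymous).  Each segregating site inside a codon is classified by
    exchanging the two alleles in the context of the major codon.

    Returns a dict with keys L_syn, L_nonsyn, syn_sites, nonsyn_sites
    (column indices of classified polymorphic sites) and flagged (True if
    the major haplotype contains an internal stop).
    """
    aln = alignment_array(alignment)[:, frame:]
    L = aln.shape[1] - aln.shape[1] % 3
    aln = aln[:, :L]
    L_syn = 0.0
    L_nonsyn = 0.0
    syn_sites: list[int] = []
    nonsyn_sites: list[int] = []
    flagged = False
    n_codons = L // 3
    for ci in range(n_codons):
        block = aln[:, 3 * ci:3 * ci + 3]
        valid = ~np.isin(block, MISSING).any(axis=1)
        if not valid.any():
            continue
        codons = [bytes(row) for row in block[valid]]
        uniq, cnt = np.unique(codons, return_counts=True)
        major = sorted(uniq[cnt == cnt.max()])[0].decode()
        if is_stop(major) and ci < n_codons - 1:
            flagged = True
            continue
        if not is_stop(major):
            s, ns = codon_site_counts(major)
            L_syn += s
            L_nonsyn += ns
        # classify segregating positions in major-codon context
        for p in range(3):
            col = block[valid, p]
            bases = np.unique(col)
            bases = bases[~np.isin(bases, MISSING)]
            if len(bases) < 2:
                continue
            if len(bases) > 2:
                continue  # >2 alleles: excluded from syn/nonsyn classes
            b1, b2 = (b.decode() for b in bases)
            c1 = major[:p] + b1 + major[p + 1:]
            c2 = major[:p] + b2 + major[p + 1:]
            if is_stop(c1) or is_stop(c2):
                nonsyn_sites.append(3 * ci + p + frame)
            elif GENETIC_CODE[c1] == GENETIC_CODE[c2]:
                syn_sites.append(3 * ci + p + frame)
            else:
                nonsyn_sites.append(3 * ci + p + frame)
    return {"L_syn": L_syn, "L_nonsyn": L_nonsyn,
            "syn_sites": syn_sites, "nonsyn_sites": nonsyn_sites,
            "flagged": flagged}


def build_sfs(alignment, outgroup=None, fold: bool = False,
              site_class: str = "total", columns=None) -> SiteFrequencySpectrum:
    """Site-frequency spectrum from an alignment of complete columns.

    Only biallelic sites with no missing data are tabulated (incomplete
    sites can be rescued downstream with :func:`project_sfs`).  With an
    ``outgroup`` sequence the spectrum is polarised by the outgroup allele
    (sites where the outgroup matches neither ingroup allele are dropped);
    otherwise ``fold`` must be True.  ``columns`` optionally restricts to a
    set of column indices (e.g. the synonymous sites).
    """
    aln = alignment_array(alignment)
    n = aln.shape[0]
    if outgroup is None and not fold:
        raise ValueError("unfolded SFS requires an outgroup")
    out_row = None
    if outgroup is not None:
        out_row = alignment_array([outgroup])[0]
        if len(out_row) != aln.shape[1]:
            raise ValueError("outgroup length does not match alignment")
    counts, neff = _base_counts(aln)
    if columns is not None:
        keep = np.zeros(aln.shape[1], dtype=bool)
        keep[list(columns)] = True
    else:
        keep = np.ones(aln.shape[1], dtype=bool)
    spectrum = np.zeros(n // 2 if fold else n - 1)
    bases = np.array([b"A", b"C", b"G", b"T"])
    for j in np.nonzero(keep & (neff == n))[0]:
        col = counts[:, j]
        present = np.nonzero(col)[0]
        if len(present) != 2:
            continue
        if fold:
            mac = int(min(col[present]))
            spectrum[mac - 1 if mac <= n // 2 else n - mac - 1] += 1
        else:
            ob = out_row[j]
            alleles = bases[present]
            if ob not in alleles:
                continue
            derived = present[alleles != ob][0]
            d = int(col[derived])
            if 1 <= d <= n - 1:
                spectrum[d - 1] += 1
    return SiteFrequencySpectrum(spectrum, n, fold, site_class)


def project_sfs(sfs: SiteFrequencySpectrum, m: int) -> SiteFrequencySpectrum:
    """Project an unfolded SFS at n down to m by hypergeometric expectation."""
    if sfs.folded:
        raise ValueError("projection defined on unfolded spectra")
    n = sfs.n
    if m > n:
        raise ValueError("m must be <= n")
    if m < 2:
        raise ValueError("m must be >= 2")
    if m == n:
        return sfs
    out = np.zeros(m - 1)
    for i, c in enumerate(sfs.counts, start=1):
        if c == 0:
            continue
        j = np.arange(1, m)
        w = comb(i, j) * comb(n - i, m - j) / comb(n, m)
        out += c * w
    return SiteFrequencySpectrum(out, m, False, sfs.site_class)


def effective_popsize(pi: float, mu: float) -> float:
    """Ne = pi / (4 mu) at neutral equilibrium."""
    if mu <= 0:
        raise ValueError("mu must be > 0")
    return pi / (4.0 * mu)


@dataclass
class DiversityStats:
    """Per-gene summary mirroring the per-homeolog statistics table."""

    gene_id: str
    subgenome: str
    n: int
    L_used: int
    pi_total: float | None
    theta_w: float | None
    pi_syn: float | None
    pi_nonsyn: float | None
    theta_w_syn: float | None
    theta_w_nonsyn: float | None
    tajimas_d: float | None
    fay_wu_h: float | None
    fu_li_dstar: float | None
    fu_li_fstar: float | None
    S: int = 0


def _segregating(aln: np.ndarray):
    """(S, eta_singleton, per-site effective n) over biallelic+ sites."""
    counts, neff = _base_counts(aln)
    present = (counts > 0).sum(axis=0)
    seg = (present >= 2) & (neff >= 2)
    S = int(seg.sum())
    eta_s = 0
    for j in np.nonzero(seg)[0]:
        col = counts[:, j]
        nz = col[col > 0]
        if len(nz) == 2 and nz.min() == 1:
            eta_s += 1
    return S, eta_s, neff


def gene_diversity(alignment, gene_id: str = "", subgenome: str = "",
                   outgroup=None, frame: int = 0) -> DiversityStats:
    """All per-gene statistics for one CDS alignment (outgroup optional).

    Fay & Wu's H needs the outgroup (polarised spectrum) and is None
    without one.  Sample size for the variance constants is the number of
    alignment rows; sites are handled by pairwise deletion.
    """
    aln = alignment_array(alignment)
    n = aln.shape[0]
    pi_site, L_used, pi_locus = pairwise_pi(aln)
    S, eta_s, _ = _segregating(aln)
    if L_used == 0:
        return DiversityStats(gene_id, subgenome, n, 0, None, None, None,
                              None, None, None, None, None, None, None, 0)
    theta = watterson_theta(S, n, L_used)
    part = partition_sites(aln, frame=frame)
    pi_syn = pi_nonsyn = th_syn = th_nonsyn = None
    if part["L_syn"] > 0:
        counts, neffc = _base_counts(aln)
        pi_syn = _class_pi(aln, part["syn_sites"]) / part["L_syn"]
        th_syn = watterson_theta(len(part["syn_sites"]), n, part["L_syn"])
    if part["L_nonsyn"] > 0:
        pi_nonsyn = _class_pi(aln, part["nonsyn_sites"]) / part["L_nonsyn"]
        th_nonsyn = watterson_theta(len(part["nonsyn_sites"]), n,
                                    part["L_nonsyn"])
    D = tajimas_d(S, pi_locus, n)
    dstar, fstar = fu_li_star(S, eta_s, n, pi_locus) if S > 0 else (None, None)
    H = None
    if outgroup is not None and S > 0:
        H = fay_wu_h(build_sfs(aln, outgroup=outgroup, fold=False))
    return DiversityStats(gene_id, subgenome, n, L_used, pi_site, theta,
                          pi_syn, pi_nonsyn, th_syn, th_nonsyn, D, H,
                          dstar, fstar, S)


def _class_pi(aln: np.ndarray, cols) -> float:
    """Summed per-site pairwise diversity over the given columns."""
    if not len(cols):
        return 0.0
    sub = aln[:, list(cols)]
    _, _, pi_locus = pairwise_pi(sub)
    return pi_locus


def window_diversity(positions, genotypes, seq_length: int, width: int,
                     step: int | None = None) -> list[dict]:
    """Sliding-window pi and theta_w from haploid genotype vectors.

    ``positions`` are 0-based variant coordinates; ``genotypes`` is an
    (n_accessions, S) 0/1 matrix (missing = -1, dropped per site).
    Windows are half-open [start, start+width).
    """
    step = step or width
    positions = np.asarray(positions)
    G = np.asarray(genotypes)
    n_total = G.shape[0]
    out = []
    for start in range(0, max(seq_length - width + 1, 1), step):
        stop = start + width
        sel = (positions >= start) & (positions < stop)
        pi_sum = 0.0
        S = 0
        for j in np.nonzero(sel)[0]:
            g = G[:, j]
            g = g[g >= 0]
            m = len(g)
            c = int(g.sum())
            if m >= 2 and 0 < c < m:
                S += 1
                pi_sum += 2.0 * c * (m - c) / (m * (m - 1))
        a = harmonic(n_total - 1)
        out.append({"start": start, "end": stop, "S": S,
                    "pi": pi_sum / width, "theta_w": S / (a * width)})
    return out
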