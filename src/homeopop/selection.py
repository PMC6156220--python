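"""McDonald-Kreitman tests and the direction-of-selection statistic.

Per gene, polymorphic nonsynonymous (Pn) and synonymous (Ps) sites within
the ingroup are contrasted with fixed nonsynonymous (Dn) and synonymous
(Ds) differences from the outgroup in a 2x2 contingency table.  Departures
from neutrality are summarised by Fisher's exact test (two-sided,
probability-mass rule) and by

    DoS = Dn/(Dn+Ds) - Pn/(Pn+Ps)   in [-1, 1],

negative under purifying and positive under positive selection.  Sites
that are both polymorphic and divergent count as polymorphic only; sites
with more than two alleles are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .codons import GENETIC_CODE, is_stop
from .popgen import MISSING, alignment_array

__all__ = ["SelectionRecord", "mk_counts", "mk_fisher", "dos",
           "classify_selection"]


@dataclass
class SelectionRecord:
    gene_id: str
    subgenome: str
    Dn: int
    Ds: int
    Pn: int
    Ps: int
    fisher_p: float | None = None
    DoS: float | None = None
    label: str = "untested"


def mk_counts(rows, outgroup: str, frame: int = 0) -> tuple[int, int, int, int]:
    """(Dn, Ds, Pn, Ps) from an ingroup alignment plus outgroup row.

    Classification is per site in the context of the ingroup major codon:
    polymorphic sites exchange the two segregating alleles; fixed
    differences exchange the ingroup allele for the outgroup allele.
    Codons whose every row is missing, and sites with missing outgroup
    bases (for D) are skipped.
    """
    if outgroup is None:
        raise ValueError("MK counts need an outgroup")
    aln = alignment_array(rows)[:, frame:]
    og = alignment_array([outgroup])[0, frame:]
    L = aln.shape[1] - aln.shape[1] % 3
    Dn = Ds = Pn = Ps = 0
    for ci in range(L // 3):
        block = aln[:, 3 * ci:3 * ci + 3]
        valid = ~np.isin(block, MISSING).any(axis=1)
        if not valid.any():
            continue
        codons = [bytes(r) for r in block[valid]]
        uniq, cnt = np.unique(codons, return_counts=True)
        major = sorted(uniq[cnt == cnt.max()])[0].decode()
        if is_stop(major):
            continue
        for p in range(3):
            col = block[valid, p]
            bases = np.unique(col[~np.isin(col, MISSING)])
            if len(bases) == 0 or len(bases) > 2:
                continue
            if len(bases) == 2:
                b1, b2 = (b.decode() for b in bases)
                syn = _exchange_is_syn(major, p, b1, b2)
                if syn is None:
                    continue
                if syn:
                    Ps += 1
                else:
                    Pn += 1
                continue
            # monomorphic ingroup: fixed difference if outgroup differs
            ob = og[3 * ci + p]
            if ob in MISSING or ob == bases[0]:
                continue
            syn = _exchange_is_syn(major, p, bases[0].decode(), ob.decode())
            if syn is None:
                continue
            if syn:
                Ds += 1
            else:
                Dn += 1
    return Dn, Ds, Pn, Ps


def _exchange_is_syn(major: str, p: int, b1: str, b2: str) -> bool | None:
    c1 = major[:p] + b1 + major[p + 1:]
    c2 = major[:p] + b2 + major[p + 1:]
    if is_stop(c1) or is_stop(c2):
        return False
    return GENETIC_CODE[c1] == GENETIC_CODE[c2]


def mk_fisher(Dn: int, Ds: int, Pn: int, Ps: int) -> float | None:
    """Two-sided Fisher exact p for the 2x2 MK table (None if degenerate)."""
    if min(Dn + Ds, Pn + Ps, Dn + Pn, Ds + Ps) == 0:
        return None
    _, p = stats.fisher_exact([[Dn, Ds], [Pn, Ps]], alternative="two-sided")
    return float(p)


def dos(Dn: int, Ds: int, Pn: int, Ps: int) -> float | None:
    """DoS = Dn/(Dn+Ds) - Pn/(Pn+Ps); None when a denominator is zero."""
    if any(x < 0 for x in (Dn, Ds, Pn, Ps)):
        raise ValueError("counts must be >= 0")
    if Dn + Ds == 0 or Pn + Ps == 0:
        return None
    return Dn / (Dn + Ds) - Pn / (Pn + Ps)


def classify_selection(records: list[SelectionRecord], p_max: float = 0.05,
                       dos_eps: float = 0.01) -> list[SelectionRecord]:
    """Label genes purifying / positive / neutral / untested (marginal p).

    A gene is ``purifying`` when its MK test is significant and
    DoS < -dos_eps, ``positive`` when significant and DoS > +dos_eps;
    significant tests inside the DoS dead band and non-significant tests
    are ``neutral``; genes without a defined p or DoS stay ``untested``.
    No multiple-testing correction is applied.
    """
    for r in records:
        if r.fisher_p is None or r.DoS is None:
            r.label = "untested"
        elif r.fisher_p < p_max and r.DoS < -dos_eps:
            r.label = "purifying"
        elif r.fisher_p < p_max and r.DoS > dos_eps:
            r.label = "positive"
        else:
            r.label = "neutral"
    return records
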