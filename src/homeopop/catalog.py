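"""Homeolog pairing and per-gene multi-accession CDS alignments.

Homeologous pairs between the two subgenome CDS sets are found by
reciprocal best hits (best-to-best) under a banded global alignment score
(match +1, mismatch -1, gap open -2, extend -0.5); a pair is kept only if
each member is the other's best hit, the aligned length is >= 200 bp and
the score clears a floor (the desk-scale stand-in for a BLAST E-value
cutoff).  Genes duplicated within one subgenome (two near-identical
copies) are excluded from the catalog.

Accession CDS sequences are rebuilt from the reference CDS plus each
accession's filtered variants: SNP alleles substituted, deletions written
as '-' (coordinate-preserving; insertions are omitted), masked genotypes
written as 'N'.  The outgroup row is added by a profile-style global
alignment against the ingroup consensus that never alters ingroup
columns; outgroup-only insertions are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import Align

from .popgen import alignment_array

__all__ = [
    "HomeologPair",
    "GeneAlignment",
    "make_aligner",
    "reciprocal_best_hit",
    "apply_variants_to_cds",
    "add_outgroup",
    "consensus",
]


@dataclass(frozen=True)
class HomeologPair:
    gene_id_h: str
    gene_id_l: str
    pair_score: float
    outgroup_id: str | None = None


@dataclass
class GeneAlignment:
    gene_id: str
    subgenome: str
    rows: list                   # accession CDS strings, equal length
    accessions: list
    outgroup: str | None = None
    frame: int = 0

    def __post_init__(self):
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("rows differ in length")
        if self.outgroup is not None and self.rows and \
                len(self.outgroup) != len(self.rows[0]):
            raise ValueError("outgroup length mismatch")

    def matrix(self) -> np.ndarray:
        return alignment_array(self.rows)


def make_aligner(mode: str = "global") -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = 1.0
    a.mismatch_score = -1.0
    a.open_gap_score = -2.0
    a.extend_gap_score = -0.5
    return a


def reciprocal_best_hit(cds_h: dict, cds_l: dict, min_len: int = 200,
                        score_floor: float = 100.0) -> list[HomeologPair]:
    """Best-to-best pairs between the two CDS sets.

    The global alignment score is symmetric, so one all-vs-all score
    matrix serves both directions; best hits break ties by gene id.
    """
    if not cds_h or not cds_l:
        raise ValueError("empty CDS set")
    aligner = make_aligner()
    h_ids = sorted(cds_h)
    l_ids = sorted(cds_l)
    scores = np.empty((len(h_ids), len(l_ids)))
    for i, hid in enumerate(h_ids):
        for j, lid in enumerate(l_ids):
            scores[i, j] = aligner.score(cds_h[hid], cds_l[lid])
    pairs = []
    for i, hid in enumerate(h_ids):
        j = int(scores[i].argmax())
        if int(scores[:, j].argmax()) != i:
            continue
        score = scores[i, j]
        if score < score_floor:
            continue
        lid = l_ids[j]
        aln = aligner.align(cds_h[hid], cds_l[lid])[0]
        if aln.shape[1] < min_len:
            continue
        pairs.append(HomeologPair(hid, lid, float(score)))
    return sorted(pairs, key=lambda p: p.gene_id_h)


def apply_variants_to_cds(ref_cds: str, variants, masked=(),
                          low_coverage=()) -> str:
    """One accession's CDS from the reference CDS and its variant calls.

    ``variants`` is an iterable of (pos, ref_allele, alt_allele) with pos a
    0-based CDS coordinate; SNPs substitute the base, deletions (alt
    shorter than ref) replace the deleted bases with '-', insertions are
    ignored.  ``masked`` positions (failed genotype calls) and
    ``low_coverage`` positions become 'N'.  Positions absent everywhere
    keep the reference base.
    """
    seq = list(ref_cds)
    L = len(seq)
    for pos, ref, alt in variants:
        if pos < 0 or pos + len(ref) > L:
            raise ValueError(f"variant at {pos} ({ref}>{alt}) outside CDS "
                             f"of length {L}")
        if len(ref) == 1 and len(alt) == 1:
            seq[pos] = alt
        elif len(alt) < len(ref):
            # deletion: anchor base kept, deleted span becomes '-'
            for i in range(len(alt), len(ref)):
                seq[pos + i] = "-"
        # insertions (len(alt) > len(ref)) omitted to preserve coordinates
    for pos in masked:
        if 0 <= pos < L:
            seq[pos] = "N"
    for pos in low_coverage:
        if 0 <= pos < L:
            seq[pos] = "N"
    return "".join(seq)


def consensus(rows) -> str:
    """Majority base per column, ignoring N/-; ties lexicographic."""
    aln = alignment_array(rows)
    out = []
    for j in range(aln.shape[1]):
        col = aln[:, j]
        col = col[~np.isin(col, (b"N", b"-"))]
        if len(col) == 0:
            out.append("N")
            continue
        uniq, cnt = np.unique(col, return_counts=True)
        out.append(sorted(uniq[cnt == cnt.max()])[0].decode())
    return "".join(out)


def add_outgroup(alignment: GeneAlignment, outgroup_cds: str,
                 score_floor: float = 0.0) -> GeneAlignment:
    """Attach the outgroup row without touching ingroup columns.

    The outgroup is globally aligned to the ingroup consensus; columns
    where the consensus is gapped in that pairwise alignment (outgroup
    insertions) are discarded, and consensus positions unmatched by the
    outgroup become '-' in the outgroup row.  If the alignment score is
    below ``score_floor`` the gene is flagged by raising ValueError
    ("no outgroup").
    """
    cons = consensus(alignment.rows)
    aligner = make_aligner()
    aln = aligner.align(cons, outgroup_cds)
    if aln.score < score_floor:
        raise ValueError(f"no outgroup for {alignment.gene_id}: score "
                         f"{aln.score:.1f} < {score_floor:.1f}")
    best = aln[0]
    row = ["-"] * len(cons)
    for (t_blk, q_blk) in zip(*best.aligned):
        t0, t1 = t_blk
        q0, q1 = q_blk
        for off in range(t1 - t0):
            row[t0 + off] = outgroup_cds[q0 + off]
    return GeneAlignment(alignment.gene_id, alignment.subgenome,
                         alignment.rows, alignment.accessions,
                         outgroup="".join(row), frame=alignment.frame)
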