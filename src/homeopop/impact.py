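"""High-impact (putative loss-of-function) variant annotation.

Classifies variant consequences on single-CDS gene models against the
standard genetic code: frameshift (CDS indel with length % 3 != 0),
stop_gained (SNP creating an in-frame stop), stop_lost (destroying the
terminal stop), start_lost (altering the initiator ATG), plus the
lower-impact classes missense, synonymous and inframe_indel.  High
impact = the four disruptive types only.  Compound codons (two SNPs in
one codon in one accession) are evaluated jointly at codon level.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

from .codons import GENETIC_CODE, is_stop
from .genome import GeneModel

__all__ = ["ImpactCall", "HIGH_IMPACT", "annotate_effects",
           "impact_frequency_spectrum", "dual_disruption"]

HIGH_IMPACT = frozenset(
    {"frameshift", "stop_gained", "stop_lost", "start_lost"})


@dataclass(frozen=True)
class ImpactCall:
    gene_id: str
    subgenome: str
    accession: str
    type: str
    pos: int                  # 0-based scaffold coordinate of the variant


def annotate_effects(gene: GeneModel, cds_ref: str, variants,
                     subgenome: str = "") -> tuple[list[ImpactCall], int]:
    """Consequence calls for one gene; variants outside the CDS are counted.

    ``variants`` is an iterable of (accession, pos, ref, alt) with ``pos``
    a 0-based scaffold coordinate.  Reverse-strand genes are handled by
    mapping to CDS coordinates first.  Returns (calls, n_outside).
    """
    calls: list[ImpactCall] = []
    n_outside = 0
    L = len(cds_ref)
    by_acc: dict[str, list] = defaultdict(list)
    for acc, pos, ref, alt in variants:
        if not (gene.start <= pos < gene.end):
            n_outside += 1
            continue
        by_acc[acc].append((pos, ref, alt))
    for acc, accvars in by_acc.items():
        snps_by_codon: dict[int, list] = defaultdict(list)
        for pos, ref, alt in accvars:
            if gene.strand == "+":
                cpos = pos - gene.start
            else:
                cpos = gene.end - 1 - pos
                ref, alt = _rc(ref), _rc(alt)
            if len(ref) != len(alt):
                indel_len = abs(len(ref) - len(alt))
                typ = "frameshift" if indel_len % 3 else "inframe_indel"
                calls.append(ImpactCall(gene.gene_id, subgenome, acc, typ,
                                        pos))
                continue
            if len(ref) == 1:
                snps_by_codon[cpos // 3].append((cpos, alt))
        for ci, muts in snps_by_codon.items():
            cstart = 3 * ci
            codon = list(cds_ref[cstart:cstart + 3])
            for cpos, alt in muts:
                codon[cpos - cstart] = alt
            mutated = "".join(codon)
            original = cds_ref[cstart:cstart + 3]
            pos0 = (gene.start + cstart if gene.strand == "+"
                    else gene.end - cstart - 3)
            if ci == 0 and mutated != "ATG":
                typ = "start_lost"
            elif ci == L // 3 - 1 and is_stop(original) \
                    and not is_stop(mutated):
                typ = "stop_lost"
            elif is_stop(mutated) and not is_stop(original):
                typ = "stop_gained"
            elif not is_stop(mutated) and \
                    GENETIC_CODE.get(mutated) == GENETIC_CODE.get(original):
                typ = "synonymous"
            else:
                typ = "missense"
            calls.append(ImpactCall(gene.gene_id, subgenome, acc, typ, pos0))
    return calls, n_outside


def _rc(seq: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    return "".join(comp[b] for b in reversed(seq))


def impact_frequency_spectrum(calls: list[ImpactCall],
                              n_accessions: int = 25) -> dict:
    """Per-type counts of genes by carrier count (1..n_accessions).

    A gene is counted once per mutation type per carrier-count bin, where
    the carrier count is the number of accessions with >= 1 variant of
    that type in the gene.
    """
    carriers: dict[tuple, set] = defaultdict(set)
    for c in calls:
        if c.type in HIGH_IMPACT:
            carriers[(c.gene_id, c.type)].add(c.accession)
    spectrum: dict[str, dict[int, int]] = {
        t: defaultdict(int) for t in sorted(HIGH_IMPACT)}
    for (gene, typ), accs in carriers.items():
        k = len(accs)
        if 1 <= k <= n_accessions:
            spectrum[typ][k] += 1
    return {t: dict(bins) for t, bins in spectrum.items()}


def dual_disruption(calls: list[ImpactCall], pairs) -> list[tuple]:
    """Homeolog pairs with high-impact calls in both copies, same accession.

    ``pairs`` is an iterable with attributes gene_id_h / gene_id_l (or
    (h, l) tuples).  Returns sorted (gene_id_h, gene_id_l, accession) rows.
    """
    hit: dict[str, set] = defaultdict(set)
    for c in calls:
        if c.type in HIGH_IMPACT:
            hit[c.gene_id].add(c.accession)
    out = []
    for p in pairs:
        h, l = (p.gene_id_h, p.gene_id_l) if hasattr(p, "gene_id_h") else p
        for acc in sorted(hit.get(h, set()) & hit.get(l, set())):
            out.append((h, l, acc))
    return sorted(out)
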