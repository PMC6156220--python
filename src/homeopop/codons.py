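"""Standard genetic code helpers used across the package."""

from __future__ import annotations

from Bio.Data.CodonTable import standard_dna_table

BASES = "ACGT"

GENETIC_CODE: dict[str, str] = dict(standard_dna_table.forward_table)
STOP_CODONS = frozenset(standard_dna_table.stop_codons)
for _stop in STOP_CODONS:
    GENETIC_CODE[_stop] = "*"

#: sense codons only (used when generating stop-free CDS interiors)
SENSE_CODONS = tuple(sorted(c for c in GENETIC_CODE if c not in STOP_CODONS))


def is_stop(codon: str) -> bool:
    return codon in STOP_CODONS


def translate(cds: str) -> str:
    """Translate an in-frame CDS (no ambiguity handling)."""
    return "".join(GENETIC_CODE[cds[i:i + 3]] for i in range(0, len(cds) - len(cds) % 3, 3))


def codon_site_counts(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one sense codon.

    Each position contributes the fraction of its three possible base
    changes that preserve the amino acid; changes creating a stop codon
    count as nonsynonymous.  The three positions sum to 3 sites.
    """
    if is_stop(codon):
        raise ValueError("site counts undefined for stop codons")
    syn = 0.0
    aa = GENETIC_CODE[codon]
    for p in range(3):
        for b in BASES:
            if b == codon[p]:
                continue
            mut = codon[:p] + b + codon[p + 1:]
            if not is_stop(mut) and GENETIC_CODE[mut] == aa:
                syn += 1.0 / 3.0
    return syn, 3.0 - syn
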