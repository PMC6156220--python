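"""Gene models, coordinate conventions and light file I/O.

Internal coordinates are 0-based half-open throughout the package; the
GFF3 and VCF writers/readers are the only crossing points to the 1-based
conventions of those formats.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = ["GeneModel", "write_fasta", "read_fasta", "write_gff3",
           "read_gff3", "revcomp"]

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class GeneModel:
    """A single-CDS gene on a scaffold; [start, end) half-open, frame 0."""

    gene_id: str
    scaffold: str
    start: int
    end: int
    strand: str = "+"

    @property
    def length(self) -> int:
        return self.end - self.start

    def cds(self, scaffold_seq: str) -> str:
        s = scaffold_seq[self.start:self.end]
        return s if self.strand == "+" else revcomp(s)


def write_fasta(path, sequences: dict[str, str], width: int = 80) -> None:
    records = [SeqRecord(Seq(s), id=name, description="")
               for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


def write_gff3(path, genes: list[GeneModel]) -> None:
    """Write gene + CDS features (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id}"
            row = [g.scaffold, "homeopop", "gene", str(g.start + 1),
                   str(g.end), ".", g.strand, ".", attrs]
            fh.write("\t".join(row) + "\n")
            row[2] = "CDS"
            row[7] = "0"
            row[8] = f"ID={g.gene_id}.cds;Parent={g.gene_id}"
            fh.write("\t".join(row) + "\n")


def read_gff3(path) -> list[GeneModel]:
    """Read gene features back into models (CDS rows are redundant here)."""
    cols = ["scaffold", "source", "type", "start", "end", "score", "strand",
            "phase", "attributes"]
    df = pd.read_csv(path, sep="\t", comment="#", names=cols)
    genes = []
    for _, r in df[df["type"] == "gene"].iterrows():
        gid = dict(kv.split("=") for kv in r["attributes"].split(";"))["ID"]
        genes.append(GeneModel(gid, r["scaffold"], int(r["start"]) - 1,
                               int(r["end"]), r["strand"]))
    return genes
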