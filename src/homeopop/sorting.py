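"""Subgenome read sorting by mismatch comparison to both parents.

Reads from an allopolyploid are placed (ungapped, seeded by exact k-mers)
against both parental references; each read is classified by comparing its
best mismatch count on the two references:

* fewer mismatches on H -> ``H_origin``; on L -> ``L_origin``;
* equal mismatch counts (including 0/0) -> ``common`` — the read aligns
  equally well to both parents;
* no placement on either, or best mismatch *rate* above ``max_rate``
  -> ``unclassified``.

An iterative polishing scheme then substitutes well-supported variant
alleles into working copies of the references (coverage between 20% and
200% of the library average, Phred-scaled variant quality >= 30) over 10
cycles — origin reads only for cycles 1-5, origin plus common reads for
cycles 6-10 — so that accession-specific alleles stop inflating mismatch
counts.  The modified references are used for sorting only.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import stats

from .genome import revcomp

__all__ = [
    "ReadPlacement",
    "KmerIndex",
    "index_reference",
    "place_read",
    "classify_read",
    "update_reference",
    "sort_reads",
    "concordance_report",
    "CLASSES",
]

CLASSES = ("H_origin", "L_origin", "common", "unclassified")


@dataclass(frozen=True)
class ReadPlacement:
    read_id: str
    reference_label: str
    position: int               # 0-based offset on the reference
    mismatches: int
    aligned_length: int
    reverse: bool = False

    def __post_init__(self):
        if self.mismatches > self.aligned_length:
            raise ValueError("mismatches cannot exceed aligned length")


class KmerIndex:
    """Exact k-mer -> offsets lookup over one reference sequence."""

    def __init__(self, sequence: str, k: int, label: str = ""):
        if not 11 <= k <= 31:
            raise ValueError("k must be in [11, 31]")
        if not sequence:
            raise ValueError("empty reference")
        self.k = k
        self.label = label
        self.sequence = sequence.upper()
        self._arr = np.frombuffer(self.sequence.encode(), dtype=np.uint8)
        self._index: dict[str, list[int]] = {}
        for off in range(len(self.sequence) - k + 1):
            self._index.setdefault(self.sequence[off:off + k], []).append(off)

    def lookup(self, kmer: str) -> list[int]:
        return self._index.get(kmer.upper(), [])

    def __len__(self):
        return len(self._index)


def index_reference(sequence: str, k: int, label: str = "") -> KmerIndex:
    return KmerIndex(sequence, k, label)


def _count_mismatches(ref_arr: np.ndarray, read_arr: np.ndarray,
                      offset: int) -> int:
    return int((ref_arr[offset:offset + len(read_arr)] != read_arr).sum())


def place_read(read: str, index: KmerIndex, read_id: str = "",
               try_reverse: bool = True) -> ReadPlacement | None:
    """Best ungapped placement of a read by seeded mismatch counting.

    Seeds are taken at the read's start, middle and end; candidate offsets
    come from exact seed hits.  Among full-length candidates the placement
    with the fewest mismatches wins; ties break to the smallest offset
    (forward orientation preferred).  No seed hit -> None.
    """
    k = index.k
    if len(read) < k:
        raise ValueError("read shorter than k")
    best = None
    for rc in ((False, True) if try_reverse else (False,)):
        seq = revcomp(read) if rc else read.upper()
        arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
        L = len(seq)
        candidates = set()
        for soff in {0, (L - k) // 2, L - k}:
            for hit in index.lookup(seq[soff:soff + k]):
                start = hit - soff
                if 0 <= start <= len(index.sequence) - L:
                    candidates.add(start)
        for start in sorted(candidates):
            mm = _count_mismatches(index._arr, arr, start)
            key = (mm, rc, start)
            if best is None or key < (best.mismatches, best.reverse,
                                      best.position):
                best = ReadPlacement(read_id, index.label, start, mm, L, rc)
    return best


def classify_read(placement_h: ReadPlacement | None,
                  placement_l: ReadPlacement | None,
                  max_rate: float = 0.10) -> str:
    """H_origin / L_origin / common / unclassified for one read."""
    if max_rate < 0:
        raise ValueError("max_rate must be >= 0")

    def ok(p):
        return p is not None and p.mismatches <= max_rate * p.aligned_length

    h, l = ok(placement_h), ok(placement_l)
    if not h and not l:
        return "unclassified"
    if h and not l:
        return "H_origin"
    if l and not h:
        return "L_origin"
    if placement_h.mismatches < placement_l.mismatches:
        return "H_origin"
    if placement_h.mismatches > placement_l.mismatches:
        return "L_origin"
    return "common"


def _variant_quality(alt_count: int, coverage: int, error_rate: float) -> float:
    """Phred-scaled probability that >= alt_count errors occur by chance."""
    p = stats.binom.sf(alt_count - 1, coverage, error_rate / 3.0)
    if p <= 0:
        return 1000.0
    return float(-10.0 * np.log10(p))


def update_reference(reference: str, placements, reads: dict,
                     avg_coverage: float, error_rate: float = 0.01,
                     min_qual: float = 30.0) -> str:
    """One polishing cycle: substitute well-supported variant alleles.

    ``placements`` is an iterable of ReadPlacement onto this reference;
    ``reads`` maps read_id -> read sequence.  A position is substituted by
    the majority non-reference base only if its coverage is >= 20% and
    <= 200% of ``avg_coverage`` and the Phred-scaled binomial variant
    quality is >= ``min_qual``.  Returns the modified reference.
    """
    if avg_coverage <= 0:
        raise ValueError("avg_coverage must be > 0")
    L = len(reference)
    ref_arr = np.frombuffer(reference.upper().encode(), dtype=np.uint8)
    cov = np.zeros(L, dtype=np.int32)
    base_counts = {b: np.zeros(L, dtype=np.int32) for b in b"ACGT"}
    for p in placements:
        seq = reads[p.read_id]
        if p.reverse:
            seq = revcomp(seq)
        arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
        sl = slice(p.position, p.position + len(arr))
        cov[sl] += 1
        for b in b"ACGT":
            base_counts[b][sl] += arr == b
    out = bytearray(reference.upper().encode())
    counts = np.stack([base_counts[b] for b in b"ACGT"])
    order = b"ACGT"
    candidate = (cov >= 0.2 * avg_coverage) & (cov <= 2.0 * avg_coverage) \
        & (cov > 0)
    for pos in np.nonzero(candidate)[0]:
        col = counts[:, pos]
        top = int(col.argmax())
        base = order[top]
        if base == ref_arr[pos]:
            continue
        alt_count = int(col[top])
        if 2 * alt_count <= int(cov[pos]):
            continue  # require a strict alt majority
        if _variant_quality(alt_count, int(cov[pos]), error_rate) >= min_qual:
            out[pos] = base
    return out.decode()


def sort_reads(ref_h: str, ref_l: str, reads: dict, k: int = 21,
               max_rate: float = 0.10, cycles: int = 10,
               error_rate: float = 0.01, polish: bool = True):
    """Full sorting pipeline with iterative reference polishing.

    ``reads`` maps read_id -> sequence.  Returns (classes, placements)
    where ``classes`` maps read_id -> class using the final cycle's
    modified references; ``placements`` maps read_id -> (place_H, place_L).
    """
    if not 1 <= cycles <= 10:
        raise ValueError("cycles must be in 1..10")
    work_h, work_l = ref_h, ref_l
    avg_cov = max(
        sum(len(r) for r in reads.values()) / max(len(ref_h), len(ref_l)),
        1e-9)
    classes = {}
    placements = {}
    for cycle in range(1, cycles + 1):
        idx_h = KmerIndex(work_h, k, "H")
        idx_l = KmerIndex(work_l, k, "L")
        classes = {}
        placements = {}
        for rid, seq in reads.items():
            ph = place_read(seq, idx_h, rid)
            pl = place_read(seq, idx_l, rid)
            placements[rid] = (ph, pl)
            classes[rid] = classify_read(ph, pl, max_rate)
        if not polish or cycle == cycles:
            break
        use = {"H_origin", "L_origin"} if cycle <= 5 else \
            {"H_origin", "L_origin", "common"}
        ph_use = [placements[r][0] for r, c in classes.items()
                  if c in use and c != "L_origin" and placements[r][0]]
        pl_use = [placements[r][1] for r, c in classes.items()
                  if c in use and c != "H_origin" and placements[r][1]]
        work_h = update_reference(work_h, ph_use, reads, avg_cov, error_rate)
        work_l = update_reference(work_l, pl_use, reads, avg_cov, error_rate)
    return classes, placements


def concordance_report(n_discordant: int, n_total: int) -> float:
    """Validation discordance as a percentage, one decimal, half-up."""
    if n_total <= 0:
        raise ValueError("n_total must be > 0")
    if not 0 <= n_discordant <= n_total:
        raise ValueError("need 0 <= n_discordant <= n_total")
    pct = Decimal(100 * n_discordant) / Decimal(n_total)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))
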