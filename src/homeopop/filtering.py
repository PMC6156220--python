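"""Hard filters for per-subgenome variant calls.

Site level (VCF INFO): fail when QD < 2, MQ < 30 or MQRankSum < -15; an
absent annotation never fails its test (only the listed filters are
applied — no strand or read-position filters).  An additional excess-
coverage filter flags records whose summed depth exceeds mean + 5 sd of
the genome-wide per-position depth-sum distribution, and a blacklist of
positions callable from pure parental reads marks read-sorting artefacts.

Genotype level (FORMAT): a call is masked to missing ('N' downstream)
when heterozygous, GQ < 20, DP < 2 or DP > 250.

Reason codes: QD, MQ, MQRankSum, EXCESS_DP, BLACKLIST (site);
HET, LOW_GQ, LOW_DP, HIGH_DP (genotype).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FilterConfig",
    "VcfRecord",
    "read_vcf",
    "site_filter",
    "genotype_mask",
    "excess_coverage_threshold",
    "spurious_blacklist",
    "apply_filters",
]


@dataclass(frozen=True)
class FilterConfig:
    qd_min: float = 2.0
    mq_min: float = 30.0
    mqranksum_min: float = -15.0
    gq_min: float = 20.0
    geno_cov_min: int = 2
    geno_cov_max: int = 250
    coverage_sd_mult: float = 5.0

    def __post_init__(self):
        if self.geno_cov_min >= self.geno_cov_max:
            raise ValueError("genotype coverage min must be < max")


@dataclass
class VcfRecord:
    """One VCF line in memory (POS converted to 0-based internally)."""

    chrom: str
    pos: int                    # 0-based
    ref: str
    alt: str
    info: dict
    genotypes: list             # per sample: dict(gt=(a,b)|None, dp, gq)
    filters: list = field(default_factory=list)
    masks: list = field(default_factory=list)   # per sample: list of codes

    @property
    def is_snp(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def key(self):
        return (self.chrom, self.pos)


def read_vcf(path) -> tuple[list[VcfRecord], list[str]]:
    """Read an (uncompressed or bgzipped) VCF into records + sample names."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    records = []
    for v in vcf:
        info = {}
        for k in ("QD", "MQ", "MQRankSum", "DP"):
            val = v.INFO.get(k)
            if val is not None:
                info[k] = float(val)
        gts = []
        dps = v.format("DP")
        gqs = v.format("GQ")
        for si in range(len(samples)):
            a = v.genotypes[si]
            gt = None if a[0] < 0 else (a[0], a[1])
            dp = None if dps is None else int(dps[si][0])
            gq = None if gqs is None else int(gqs[si][0])
            gts.append({"gt": gt, "dp": dp, "gq": gq})
        alt = v.ALT[0] if v.ALT else "."
        records.append(VcfRecord(v.CHROM, v.POS - 1, v.REF, alt, info, gts))
    return records, samples


def site_filter(records: list[VcfRecord], config: FilterConfig = FilterConfig(),
                excess_threshold: float | None = None,
                blacklist: set | None = None) -> list[VcfRecord]:
    """Populate per-record failure reason codes; returns the same records."""
    for rec in records:
        codes = []
        qd = rec.info.get("QD")
        mq = rec.info.get("MQ")
        mqrs = rec.info.get("MQRankSum")
        if qd is not None and qd < config.qd_min:
            codes.append("QD")
        if mq is not None and mq < config.mq_min:
            codes.append("MQ")
        if mqrs is not None and mqrs < config.mqranksum_min:
            codes.append("MQRankSum")
        if excess_threshold is not None:
            dp = rec.info.get("DP")
            if dp is not None and dp > excess_threshold:
                codes.append("EXCESS_DP")
        if blacklist and rec.key in blacklist:
            codes.append("BLACKLIST")
        rec.filters = codes
    return records


def genotype_mask(records: list[VcfRecord],
                  config: FilterConfig = FilterConfig()) -> list[VcfRecord]:
    """Per-genotype mask codes (heterozygous, GQ, DP bounds)."""
    for rec in records:
        masks = []
        for g in rec.genotypes:
            codes = []
            gt, dp, gq = g["gt"], g["dp"], g["gq"]
            if gt is not None and gt[0] != gt[1]:
                codes.append("HET")
            if gq is not None and gq < config.gq_min:
                codes.append("LOW_GQ")
            if dp is not None:
                if dp < config.geno_cov_min:
                    codes.append("LOW_DP")
                elif dp > config.geno_cov_max:
                    codes.append("HIGH_DP")
            masks.append(codes)
        rec.masks = masks
    return records


def excess_coverage_threshold(depth_sums,
                              config: FilterConfig = FilterConfig()) -> float:
    """mean + 5 sd of per-position summed depths (MQ>=20 reads upstream)."""
    d = np.asarray(depth_sums, dtype=float)
    if d.size < 2:
        raise ValueError("need at least two positions")
    return float(d.mean() + config.coverage_sd_mult * d.std(ddof=0))


def spurious_blacklist(parental_reads: dict, ref_h: str, ref_l: str,
                       k: int = 21, error_rate: float = 0.0,
                       min_qual: float = 30.0) -> set:
    """Variant positions callable from pure, perfectly-labelled parental reads.

    Runs the parental read mixture through the same sorting + pileup
    machinery used for polishing; any position where a non-reference
    majority allele reaches the quality gate on either reference is a
    read-sorting / repeat artefact and its (scaffold-label, position) key
    joins the blacklist ("H"/"L" labels).
    """
    from . import sorting

    idx_h = sorting.KmerIndex(ref_h, k, "H")
    idx_l = sorting.KmerIndex(ref_l, k, "L")
    out = set()
    total_bases = sum(len(s) for s in parental_reads.values())
    for label, idx, ref in (("H", idx_h, ref_h), ("L", idx_l, ref_l)):
        placements = []
        for rid, seq in parental_reads.items():
            ph = sorting.place_read(seq, idx_h, rid)
            pl = sorting.place_read(seq, idx_l, rid)
            cls = sorting.classify_read(ph, pl)
            if cls == f"{label}_origin" or cls == "common":
                p = ph if label == "H" else pl
                if p is not None:
                    placements.append(p)
        avg_cov = max(total_bases / len(ref), 1e-9)
        polished = sorting.update_reference(
            ref, placements, parental_reads, avg_cov,
            error_rate=max(error_rate, 1e-3), min_qual=min_qual)
        for pos, (a, b) in enumerate(zip(ref.upper(), polished)):
            if a != b:
                out.add((label, pos))
    return out


def apply_filters(records: list[VcfRecord],
                  config: FilterConfig = FilterConfig(),
                  depth_sums=None, blacklist: set | None = None):
    """Site filter + genotype mask in one pass; returns (records, report).

    ``report`` maps reason code -> count, with PASS counting records with
    no site-level failure.
    """
    thr = None
    if depth_sums is not None:
        thr = excess_coverage_threshold(depth_sums, config)
    site_filter(records, config, excess_threshold=thr, blacklist=blacklist)
    genotype_mask(records, config)
    report: dict[str, int] = {"PASS": 0}
    for rec in records:
        if not rec.filters:
            report["PASS"] += 1
        for c in rec.filters:
            report[c] = report.get(c, 0) + 1
    return records, report
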