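"""Synthetic allotetraploid study generator.

Builds a complete desk-scale allopolyploid resequencing study with known
truth: two diverged parental reference genomes with single-CDS gene models,
an outgroup CDS set, a bottlenecked selfing allotetraploid sample of
accessions with disomic inheritance (one haplotype per subgenome per
accession), paired-end reads, per-subgenome VCFs with injectable
filter-failing records, an expression table, and injected high-impact
(loss-of-function) mutations concentrated at single carriers.

Statistical structure emulated:

* parental CDS pairs diverge by Jukes-Cantor substitutions at
  ``parental_divergence`` per site (stop codons avoided inside CDS);
* synonymous polymorphism from a per-gene Hudson coalescent (bottleneck
  demography by default, giving the excess of rare variants / negative
  Tajima's D expected for a recently founded selfer);
* nonsynonymous polymorphism from the Poisson-random-field expected SFS
  under a per-gene selection strength drawn from a gamma DFE --
  independently for the two homeologs of a pair, which decorrelates
  homeolog diversity statistics while leaving the marginal distributions
  identical;
* a fraction ``alpha_true`` of nonsynonymous fixed differences injected as
  adaptive substitutions concentrated in a flagged subset of genes.

All randomness flows from one seed; sub-streams are keyed by module name
so adding one component never reshuffles another.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import coalescent, prf
from .codons import BASES, GENETIC_CODE, SENSE_CODONS, is_stop
from .genome import GeneModel, revcomp, write_fasta, write_gff3

__all__ = [
    "SimulationConfig",
    "ParentalGenomes",
    "SelectedCounts",
    "StudyData",
    "simulate_parental_genomes",
    "simulate_selected_counts",
    "simulate_reads",
    "inject_impact_mutations",
    "emit_vcf",
    "simulate_study",
    "substream",
]

SUBGENOMES = ("H", "L")
IMPACT_TYPES = ("frameshift", "stop_gained", "stop_lost", "start_lost")


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, reproducible child RNG of the study seed."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(name.encode())]))


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of the synthetic allotetraploid experiment.

    Defaults follow the resequencing design being emulated: 25 selfing
    accessions, 100-bp paired-end reads with 200-500 bp inserts at ~12x
    per subgenome, ~3% parental divergence, synonymous per-site diversity
    around 0.005, a leptokurtic gamma DFE (shape 0.3, mean Ne*s 100), and
    a quarter of nonsynonymous divergence adaptive.
    """

    seed: int = 0
    n_accessions: int = 25
    n_genes: int = 40
    gene_length_bp: int = 900
    intergenic_bp: int = 400
    parental_divergence: float = 0.03
    outgroup_divergence_factor: float = 3.0
    theta_syn: float = 0.005
    dfe_shape: float = 0.3
    dfe_mean: float = 100.0
    alpha_true: float = 0.25
    adaptive_gene_fraction: float = 0.1
    demography: str = "bottleneck"
    read_length: int = 100
    insert_mean: float = 350.0
    insert_sd: float = 50.0
    coverage: float = 12.0
    error_rate: float = 0.01
    impact_rate: float = 0.2
    impact_singleton_prob: float = 0.85
    het_rate: float = 0.0
    qd_violation_rate: float = 0.0
    mq_violation_rate: float = 0.0
    mqranksum_violation_rate: float = 0.0
    gq_violation_rate: float = 0.0
    dp_violation_rate: float = 0.0
    excess_dp_rate: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.alpha_true <= 1.0:
            raise ValueError("alpha_true must be in [0, 1]")
        if self.gene_length_bp % 3 != 0:
            raise ValueError("gene_length_bp must be a multiple of 3")
        if not 0.0 < self.parental_divergence <= 0.2:
            if self.parental_divergence != 0.0:
                raise ValueError("parental_divergence must be in (0, 0.2] "
                                 "(or exactly 0 for identical parents)")
        if not 0.0 <= self.impact_rate <= 1.0:
            raise ValueError("impact_rate must be in [0, 1]")


# ---------------------------------------------------------------------------
# parental genomes


@dataclass
class ParentalGenomes:
    references: dict            # subgenome -> scaffold sequence (str)
    genes: dict                 # subgenome -> list[GeneModel]
    outgroup_cds: dict          # base gene id -> CDS string
    ancestral_cds: dict         # base gene id -> CDS string
    scaffold_names: dict = field(default_factory=dict)

    def cds_set(self, sub: str) -> dict:
        seq = self.references[sub]
        return {g.gene_id: g.cds(seq) for g in self.genes[sub]}


def _random_cds(length: int, rng) -> str:
    n_codons = length // 3
    body = rng.choice(len(SENSE_CODONS), size=n_codons - 2)
    return "ATG" + "".join(SENSE_CODONS[i] for i in body) + "TAA"


def _mutate_lineage(seq: list, cds_ranges, rate: float, rng,
                    avoid_stops: bool = True) -> list[int]:
    """Apply Jukes-Cantor substitutions in place; returns mutated positions.

    Substitutions that would create an internal stop codon inside a CDS are
    redrawn (stop-free CDS invariant); the terminal stop codon and the ATG
    may drift only to another stop / start-compatible state -- we simply
    protect the first and last codons entirely.
    """
    L = len(seq)
    n_mut = rng.binomial(L, rate)
    positions = rng.choice(L, size=n_mut, replace=False)
    mutated = []
    for p in positions:
        in_cds = None
        for (s, e) in cds_ranges:
            if s <= p < e:
                in_cds = (s, e)
                break
        if in_cds is not None:
            s, e = in_cds
            if p < s + 3 or p >= e - 3:
                continue  # protect start and stop codons
        old = seq[p]
        choices = [b for b in BASES if b != old]
        rng.shuffle(choices)
        ok = False
        for b in choices:
            if in_cds is None:
                seq[p] = b
                ok = True
                break
            s, e = in_cds
            cstart = s + ((p - s) // 3) * 3
            codon = "".join(seq[cstart:cstart + 3])
            mut = codon[:(p - cstart)] + b + codon[(p - cstart) + 1:]
            if avoid_stops and is_stop(mut):
                continue
            seq[p] = b
            ok = True
            break
        if ok:
            mutated.append(int(p))
    return mutated


def simulate_parental_genomes(config: SimulationConfig,
                              rng=None) -> ParentalGenomes:
    """Two diverged parental scaffolds + gene models + outgroup CDS.

    Gene-by-gene orthologous coordinates: gene i occupies the same slot on
    both parental scaffolds, so the homeolog truth pairing is positional.
    """
    d = config.parental_divergence
    if not (d == 0.0 or 0.0 < d <= 0.2):
        raise ValueError("parental_divergence outside (0, 0.2]")
    rng = rng or substream(config.seed, "parental_genomes")
    gl, ig = config.gene_length_bp, config.intergenic_bp
    ancestral = []
    genes_proto = []
    pos = 0
    for gi in range(config.n_genes):
        pos += ig
        ancestral.append(("intergenic", "".join(rng.choice(list(BASES), ig))))
        cds = _random_cds(gl, rng)
        genes_proto.append((f"g{gi:04d}", pos, pos + gl))
        ancestral.append(("cds", cds))
        pos += gl
    ancestral.append(("intergenic", "".join(rng.choice(list(BASES), ig))))
    anc_seq = "".join(s for _, s in ancestral)
    cds_ranges = [(s, e) for (_, s, e) in genes_proto]

    refs, genes = {}, {}
    for sub in SUBGENOMES:
        seq = list(anc_seq)
        if d > 0:
            _mutate_lineage(seq, cds_ranges, d / 2.0, rng)
        refs[sub] = "".join(seq)
        genes[sub] = [GeneModel(f"{gid}_{sub}", f"scf{sub}_1", s, e)
                      for gid, s, e in genes_proto]
    out_rng = rng
    outgroup_cds = {}
    ancestral_cds = {}
    d_out = config.outgroup_divergence_factor * d
    for gid, s, e in genes_proto:
        anc = anc_seq[s:e]
        ancestral_cds[gid] = anc
        og = list(anc)
        if d_out > 0:
            _mutate_lineage(og, [(0, e - s)], d_out, out_rng)
        outgroup_cds[gid] = "".join(og)
    return ParentalGenomes(refs, genes, outgroup_cds, ancestral_cds,
                           {s: f"scf{s}_1" for s in SUBGENOMES})


# ---------------------------------------------------------------------------
# selected site-frequency spectra + divergence (PRF)


@dataclass
class SelectedCounts:
    """Simulated nonsynonymous + matching neutral SFS and divergence."""

    n: int
    sfs_nonsyn: np.ndarray      # unfolded counts, classes 1..n-1
    sfs_syn: np.ndarray
    Dn: int
    Ds: int
    Dn_adaptive: int
    Ln: float
    Ls: float
    expected_nonsyn: np.ndarray
    expected_syn: np.ndarray


def simulate_selected_counts(theta_ns: float, n: int, dfe_shape: float,
                             dfe_mean: float, alpha_true: float,
                             Ls: float, Ln: float, theta_syn: float | None = None,
                             divergence_scale: float = 10.0, rng=None,
                             quad: prf.DFEQuadrature | None = None) -> SelectedCounts:
    """Poisson-sample a nonsynonymous SFS under a gamma DFE plus divergence.

    ``theta_ns``/``theta_syn`` are per-site scaled mutation rates (neutral
    expectation theta*L/i per unfolded class).  Nonadaptive nonsynonymous
    divergence scales the neutral divergence ``divergence_scale * theta * L``
    by the DFE-average relative fixation rate; adaptive divergence is added
    so its expected fraction of total nonsynonymous divergence equals
    ``alpha_true``.
    """
    if n < 4:
        raise ValueError("need n >= 4")
    if not 0 <= alpha_true < 1:
        raise ValueError("alpha_true must be in [0, 1)")
    theta_syn = theta_ns if theta_syn is None else theta_syn
    rng = np.random.default_rng(rng)
    quad = quad or prf.DFEQuadrature(n)
    i = np.arange(1, n)
    exp_syn = theta_syn * Ls / i
    if dfe_mean == 0:
        class_means = 1.0 / i
        fix = 1.0
    else:
        class_means = quad.class_means(dfe_shape, dfe_mean)
        fix = quad.mean_fixation_rate(dfe_shape, dfe_mean)
    exp_ns = theta_ns * Ln * class_means
    sfs_ns = rng.poisson(exp_ns)
    sfs_s = rng.poisson(exp_syn)
    e_ds = divergence_scale * theta_syn * Ls
    e_dn_na = divergence_scale * theta_ns * Ln * fix
    e_dn_ad = alpha_true / (1.0 - alpha_true) * e_dn_na
    Ds = int(rng.poisson(e_ds))
    Dn_na = int(rng.poisson(e_dn_na))
    Dn_ad = int(rng.poisson(e_dn_ad))
    return SelectedCounts(n, sfs_ns, sfs_s, Dn_na + Dn_ad, Ds, Dn_ad,
                          Ln, Ls, exp_ns, exp_syn)


# ---------------------------------------------------------------------------
# accession haplotypes (polymorphism placement)


@dataclass
class Variant:
    subgenome: str
    scaffold: str
    pos: int                      # 0-based scaffold coordinate
    ref: str
    alt: str
    vclass: str                   # syn | nonsyn | impact
    gene_id: str | None
    carriers: np.ndarray          # bool (n_accessions,)
    impact_type: str | None = None

    @property
    def derived_count(self) -> int:
        return int(self.carriers.sum())


def _pick_site(rng, cds: str, want_syn: bool, used: set):
    """Rejection-sample (cds position, alt base) of the wanted class."""
    L = len(cds)
    for _ in range(500):
        p = int(rng.integers(3, L - 3))  # keep start/stop codons intact
        if p in used:
            continue
        cstart = (p // 3) * 3
        codon = cds[cstart:cstart + 3]
        alts = [b for b in BASES if b != cds[p]]
        rng.shuffle(alts)
        for b in alts:
            mut = codon[:p - cstart] + b + codon[p - cstart + 1:]
            if is_stop(mut):
                continue
            syn = GENETIC_CODE[mut] == GENETIC_CODE[codon]
            if syn == want_syn:
                return p, b
    return None


def _gene_polymorphism(sub: str, gene: GeneModel, cds: str, gamma: float,
                       config: SimulationConfig, quad: prf.DFEQuadrature,
                       rng) -> list[Variant]:
    """Syn sites from a coalescent tree; nonsyn sites from the PRF SFS."""
    from .codons import codon_site_counts
    n = config.n_accessions
    L = len(cds)
    n_codons = L // 3
    Ls = Ln = 0.0
    for ci in range(1, n_codons - 1):
        s, ns = codon_site_counts(cds[3 * ci:3 * ci + 3])
        Ls += s
        Ln += ns
    used: set[int] = set()
    variants: list[Variant] = []
    demog = coalescent.BOTTLENECK if config.demography == "bottleneck" \
        else coalescent.CONSTANT
    # synonymous: one genealogy per gene
    locus = coalescent.simulate_locus(n, config.theta_syn * Ls, demog, rng)
    for mask in locus.carriers:
        site = _pick_site(rng, cds, want_syn=True, used=used)
        if site is None:
            continue
        p, b = site
        used.add(p)
        variants.append(Variant(sub, gene.scaffold, gene.start + p, cds[p],
                                b, "syn", gene.gene_id, mask.copy()))
    # nonsynonymous: independent sites from the PRF expected SFS, with the
    # demography's per-class distortion applied so syn and nonsyn spectra
    # share the same demographic shape (the nuisance-class device)
    if gamma == 0:
        class_means = 1.0 / np.arange(1, n)
    else:
        class_means = prf.sampling_kernel(gamma, n)[:, 0]
    dem_r = coalescent.expected_class_factors(n, demog)
    exp_ns = config.theta_syn * Ln * class_means * dem_r
    counts = rng.poisson(exp_ns)
    for i, c in enumerate(counts, start=1):
        for _ in range(int(c)):
            site = _pick_site(rng, cds, want_syn=False, used=used)
            if site is None:
                continue
            p, b = site
            used.add(p)
            mask = np.zeros(n, dtype=bool)
            mask[rng.choice(n, size=i, replace=False)] = True
            variants.append(Variant(sub, gene.scaffold, gene.start + p,
                                    cds[p], b, "nonsyn", gene.gene_id, mask))
    return variants


# ---------------------------------------------------------------------------
# impact mutations


def inject_impact_mutations(genes: list[GeneModel], reference: str,
                            config: SimulationConfig, rng=None,
                            subgenome: str = "H") -> list[Variant]:
    """Low-frequency loss-of-function variants (truth-typed).

    Each gene receives a high-impact variant with probability
    ``impact_rate``; the type is uniform over frameshift / stop_gained /
    stop_lost / start_lost and the carrier count is 1 with probability
    ``impact_singleton_prob`` (else uniform on 2..5), emulating spectra
    concentrated at single carriers.
    """
    rng = rng or substream(config.seed, f"impact_{subgenome}")
    n = config.n_accessions
    out: list[Variant] = []
    for g in genes:
        if rng.random() >= config.impact_rate:
            continue
        cds = g.cds(reference)
        typ = IMPACT_TYPES[rng.integers(len(IMPACT_TYPES))]
        var = _make_impact_variant(g, cds, typ, rng)
        if var is None:
            continue
        pos_cds, ref, alt = var
        k = 1 if rng.random() < config.impact_singleton_prob \
            else int(rng.integers(2, 6))
        mask = np.zeros(n, dtype=bool)
        mask[rng.choice(n, size=k, replace=False)] = True
        out.append(Variant(subgenome, g.scaffold, g.start + pos_cds, ref,
                           alt, "impact", g.gene_id, mask, impact_type=typ))
    return out


def _make_impact_variant(g: GeneModel, cds: str, typ: str, rng):
    L = len(cds)
    if typ == "frameshift":
        p = int(rng.integers(3, L - 4))
        return p - 1, cds[p - 1:p + 1], cds[p - 1]   # 1-bp deletion
    if typ == "stop_gained":
        for _ in range(200):
            p = int(rng.integers(3, L - 3))
            cstart = (p // 3) * 3
            codon = cds[cstart:cstart + 3]
            for b in "ACGT":
                if b == cds[p]:
                    continue
                mut = codon[:p - cstart] + b + codon[p - cstart + 1:]
                if is_stop(mut):
                    return p, cds[p], b
        return None
    if typ == "stop_lost":
        stop = cds[-3:]
        for _ in range(50):
            off = int(rng.integers(3))
            for b in "ACGT":
                if b == stop[off]:
                    continue
                mut = stop[:off] + b + stop[off + 1:]
                if not is_stop(mut):
                    return L - 3 + off, stop[off], b
        return None
    if typ == "start_lost":
        off = int(rng.integers(3))
        b = rng.choice([x for x in "ACGT" if x != "ATG"[off]])
        return off, "ATG"[off], str(b)
    raise ValueError(typ)


# ---------------------------------------------------------------------------
# reads


def simulate_reads(genome: str, config: SimulationConfig, rng=None,
                   source_label: str = "H", accession: str = "acc00",
                   id_prefix: str = "r"):
    """Paired-end reads (FR orientation) with uniform fragment starts.

    Returns (reads, truth, n_skipped): ``reads`` is a list of
    (read_id, seq1, seq2); ``truth`` a DataFrame with source subgenome and
    0-based fragment coordinates.  Fragments longer than the template are
    skipped and counted.
    """
    if config.coverage <= 0:
        raise ValueError("coverage must be > 0")
    rng = np.random.default_rng(rng) if rng is not None else \
        substream(config.seed, f"reads_{source_label}_{accession}")
    L = len(genome)
    rl = config.read_length
    n_pairs = int(round(config.coverage * L / (2.0 * rl)))
    reads = []
    truth = []
    n_skipped = 0
    for k in range(n_pairs):
        ins = int(round(rng.normal(config.insert_mean, config.insert_sd)))
        ins = max(ins, rl)
        if ins > L:
            n_skipped += 1
            continue
        start = int(rng.integers(0, L - ins + 1))
        frag = genome[start:start + ins]
        r1 = _with_errors(frag[:rl], config.error_rate, rng)
        r2 = _with_errors(revcomp(frag[-rl:]), config.error_rate, rng)
        rid = f"{id_prefix}_{source_label}_{accession}_{k}"
        reads.append((rid, r1, r2))
        truth.append((rid, source_label, accession, start, start + ins))
    truth_df = pd.DataFrame(
        truth, columns=["read_id", "origin", "accession", "start", "end"])
    return reads, truth_df, n_skipped


def _with_errors(seq: str, error_rate: float, rng) -> str:
    if error_rate <= 0:
        return seq
    arr = list(seq)
    n_err = rng.binomial(len(arr), error_rate)
    for p in rng.choice(len(arr), size=n_err, replace=False):
        arr[p] = rng.choice([b for b in BASES if b != arr[p]])
    return "".join(arr)


def write_fastq(path, reads, mate: int) -> None:
    with open(path, "w") as fh:
        for rid, r1, r2 in reads:
            seq = r1 if mate == 1 else r2
            fh.write(f"@{rid}/{mate}\n{seq}\n+\n{'I' * len(seq)}\n")


# ---------------------------------------------------------------------------
# VCF emission


def emit_vcf(variants: list[Variant], reference: str, scaffold: str,
             config: SimulationConfig, rng=None,
             accession_names: list[str] | None = None):
    """VCF v4.2 text + genotype/filter truth tables.

    Emits one record per variant (1-based POS) with DP/GQ genotype fields
    and QD/MQ/MQRankSum/DP info fields.  Filter violations and
    heterozygous genotypes are injected at the configured rates and
    recorded in the returned truth DataFrames.
    """
    rng = rng or substream(config.seed, f"vcf_{scaffold}")
    n = config.n_accessions
    accs = accession_names or [f"acc{i:02d}" for i in range(n)]
    mean_dp_sum = config.coverage * n * 2
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={scaffold},length={len(reference)}>",
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="Total depth">',
        '##INFO=<ID=QD,Number=1,Type=Float,Description="Quality by depth">',
        '##INFO=<ID=MQ,Number=1,Type=Float,Description="Mapping quality">',
        '##INFO=<ID=MQRankSum,Number=1,Type=Float,Description="MQ rank sum">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">',
        '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(accs),
    ]
    site_truth = []
    geno_truth = []
    for v in sorted(variants, key=lambda x: x.pos):
        qd = float(rng.uniform(15, 35))
        mq = float(rng.uniform(50, 60))
        mqrs = float(np.clip(rng.normal(0, 2), -10, 10))
        dp_sum = int(rng.poisson(mean_dp_sum))
        viol = []
        if rng.random() < config.qd_violation_rate:
            qd = float(rng.uniform(0, 1.95))
            viol.append("QD")
        if rng.random() < config.mq_violation_rate:
            mq = float(rng.uniform(10, 29.5))
            viol.append("MQ")
        if rng.random() < config.mqranksum_violation_rate:
            mqrs = float(rng.uniform(-25, -15.5))
            viol.append("MQRankSum")
        if rng.random() < config.excess_dp_rate:
            dp_sum = int(mean_dp_sum * 8)
            viol.append("EXCESS_DP")
        gts = []
        for ai in range(n):
            alt_carrier = bool(v.carriers[ai])
            gt = "1/1" if alt_carrier else "0/0"
            dp = int(rng.poisson(config.coverage))
            gq = int(np.clip(rng.normal(90, 8), 21, 99))
            gviol = []
            if rng.random() < config.het_rate:
                gt = "0/1"
                gviol.append("HET")
            if rng.random() < config.gq_violation_rate:
                gq = int(rng.integers(0, 20))
                gviol.append("LOW_GQ")
            if rng.random() < config.dp_violation_rate:
                dp = int(rng.integers(0, 2)) if rng.random() < 0.5 else \
                    int(rng.integers(251, 400))
            # record depth-bound violations whether injected or natural
            if dp < 2:
                gviol.append("LOW_DP")
            elif dp > 250:
                gviol.append("HIGH_DP")
            if gviol:
                geno_truth.append((v.scaffold, v.pos + 1, accs[ai],
                                   ",".join(sorted(gviol))))
            gts.append(f"{gt}:{dp}:{gq}")
        info = (f"DP={dp_sum};QD={qd:.2f};MQ={mq:.2f};"
                f"MQRankSum={mqrs:.2f}")
        lines.append("\t".join([
            v.scaffold, str(v.pos + 1), ".", v.ref, v.alt, "100", ".",
            info, "GT:DP:GQ", *gts]))
        site_truth.append((v.scaffold, v.pos + 1, v.ref, v.alt, v.vclass,
                           v.gene_id or "", v.impact_type or "",
                           v.derived_count, ",".join(sorted(viol))))
    site_df = pd.DataFrame(site_truth, columns=[
        "scaffold", "pos", "ref", "alt", "vclass", "gene_id", "impact_type",
        "derived_count", "violations"])
    geno_df = pd.DataFrame(geno_truth, columns=[
        "scaffold", "pos", "accession", "violations"])
    return "\n".join(lines) + "\n", site_df, geno_df


# ---------------------------------------------------------------------------
# full study


@dataclass
class StudyData:
    config: SimulationConfig
    parents: ParentalGenomes
    variants: dict                  # subgenome -> list[Variant]
    gene_truth: pd.DataFrame        # per (gene, subgenome): gamma, adaptive...
    divergence: dict                # (base_gid, sub) -> dict Dn/Ds/adaptive
    expression: pd.DataFrame
    accessions: list

    def accession_haplotype(self, sub: str, accession_idx: int) -> str:
        """Scaffold sequence of one accession's subgenome (SNPs only)."""
        seq = list(self.parents.references[sub])
        for v in self.variants[sub]:
            if len(v.ref) != 1 or len(v.alt) != 1:
                continue  # indels are not applied at the sequence level
            if v.carriers[accession_idx]:
                seq[v.pos] = v.alt
        return "".join(seq)

    def gene_alignment_truth(self, sub: str, gene_id: str) -> list[str]:
        """True accession CDS sequences for one gene (SNPs only)."""
        gm = next(g for g in self.parents.genes[sub] if g.gene_id == gene_id)
        ref_cds = gm.cds(self.parents.references[sub])
        rows = []
        gene_vars = [v for v in self.variants[sub]
                     if v.gene_id == gene_id
                     and len(v.ref) == 1 and len(v.alt) == 1]
        for ai in range(self.config.n_accessions):
            row = list(ref_cds)
            for v in gene_vars:
                if v.carriers[ai]:
                    row[v.pos - gm.start] = v.alt
            rows.append("".join(row))
        return rows

    def write(self, outdir) -> None:
        """Write the full study to disk (FASTA/GFF3/FASTQ/VCF/TSV)."""
        import pathlib

        out = pathlib.Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        cfg = self.config
        for sub in SUBGENOMES:
            scf = self.parents.scaffold_names[sub]
            write_fasta(out / f"reference_{sub}.fa",
                        {scf: self.parents.references[sub]})
            write_gff3(out / f"genes_{sub}.gff3", self.parents.genes[sub])
            write_fasta(out / f"cds_{sub}.fa", self.parents.cds_set(sub))
            vcf, site_df, geno_df = emit_vcf(
                self.variants[sub], self.parents.references[sub], scf, cfg,
                accession_names=self.accessions)
            (out / f"variants_{sub}.vcf").write_text(vcf)
            site_df.to_csv(out / f"truth_sites_{sub}.tsv", sep="\t",
                           index=False)
            geno_df.to_csv(out / f"truth_genotypes_{sub}.tsv", sep="\t",
                           index=False)
        write_fasta(out / "outgroup_cds.fa", self.parents.outgroup_cds)
        self.gene_truth.to_csv(out / "truth_genes.tsv", sep="\t", index=False)
        self.expression.to_csv(out / "expression.tsv", sep="\t", index=False)


def simulate_study(config: SimulationConfig) -> StudyData:
    """Generate the complete synthetic study (no file output)."""
    parents = simulate_parental_genomes(config)
    quad = prf.DFEQuadrature(config.n_accessions)
    rng_gamma = substream(config.seed, "dfe_draws")
    rng_adapt = substream(config.seed, "adaptive")
    variants = {s: [] for s in SUBGENOMES}
    gene_rows = []
    divergence = {}

    # per-gene selection strengths, independent between homeologs
    scale = config.dfe_mean / config.dfe_shape if config.dfe_mean > 0 else 0.0
    for sub in SUBGENOMES:
        for gm in parents.genes[sub]:
            base = gm.gene_id.rsplit("_", 1)[0]
            gamma = float(rng_gamma.gamma(config.dfe_shape, scale)) \
                if scale > 0 else 0.0
            adaptive = bool(rng_adapt.random()
                            < config.adaptive_gene_fraction)
            gene_rows.append((base, gm.gene_id, sub, gamma, adaptive))
    gene_truth = pd.DataFrame(gene_rows, columns=[
        "base_id", "gene_id", "subgenome", "gamma", "adaptive"])

    # adaptive divergence first (it edits the references), so polymorphism
    # is placed on the final parental sequences
    rng_div = substream(config.seed, "divergence")
    _inject_adaptive_divergence(parents, gene_truth, config, rng_div,
                                divergence)

    gamma_of = {r[1]: r[3] for r in gene_rows}
    for sub in SUBGENOMES:
        rng_poly = substream(config.seed, f"polymorphism_{sub}")
        ref = parents.references[sub]
        for gm in parents.genes[sub]:
            variants[sub].extend(_gene_polymorphism(
                sub, gm, gm.cds(ref), gamma_of[gm.gene_id], config, quad,
                rng_poly))
        variants[sub].extend(inject_impact_mutations(
            parents.genes[sub], ref, config, subgenome=sub))

    rng_expr = substream(config.seed, "expression")
    expr_rows = []
    for base in sorted({r[0] for r in gene_rows}):
        for sub in SUBGENOMES:
            expr_rows.append((f"{base}_{sub}", sub,
                              float(rng_expr.lognormal(2.0, 1.5)),
                              float(rng_expr.lognormal(2.0, 1.5))))
    expression = pd.DataFrame(expr_rows, columns=[
        "gene_id", "subgenome", "RPKM_leaf", "RPKM_root"])
    accessions = [f"acc{i:02d}" for i in range(config.n_accessions)]
    return StudyData(config, parents, variants, gene_truth, divergence,
                     expression, accessions)


def _count_fixed_classes(cds_in: str, cds_out: str):
    """(Dn, Ds) between one ingroup CDS and the outgroup CDS (same length)."""
    Dn = Ds = 0
    for ci in range(1, len(cds_in) // 3 - 1):
        a = cds_in[3 * ci:3 * ci + 3]
        b = cds_out[3 * ci:3 * ci + 3]
        for p in range(3):
            if a[p] == b[p]:
                continue
            m = a[:p] + b[p] + a[p + 1:]
            if is_stop(m) or is_stop(a):
                Dn += 1
            elif GENETIC_CODE[m] == GENETIC_CODE[a]:
                Ds += 1
            else:
                Dn += 1
    return Dn, Ds


def _inject_adaptive_divergence(parents: ParentalGenomes,
                                gene_truth: pd.DataFrame,
                                config: SimulationConfig, rng,
                                divergence: dict) -> None:
    """Mutate parental references at nonsyn sites of adaptive-flagged genes.

    The number of injected adaptive substitutions makes the expected
    adaptive fraction of nonsynonymous divergence equal alpha_true.
    """
    for sub in SUBGENOMES:
        # baseline counts per gene
        ref = parents.references[sub]
        base_counts = {}
        for gm in parents.genes[sub]:
            base = gm.gene_id.rsplit("_", 1)[0]
            Dn, Ds = _count_fixed_classes(gm.cds(ref),
                                          parents.outgroup_cds[base])
            base_counts[gm.gene_id] = [Dn, Ds, 0]
        total_dn = sum(v[0] for v in base_counts.values())
        flagged = gene_truth[(gene_truth.subgenome == sub)
                             & gene_truth.adaptive]["gene_id"].tolist()
        a = config.alpha_true
        n_extra = int(round(a / (1 - a) * total_dn)) if a > 0 else 0
        if flagged and n_extra > 0:
            seq = list(ref)
            targets = rng.choice(len(flagged), size=n_extra)
            per_gene = np.bincount(targets, minlength=len(flagged))
            for gid, k in zip(flagged, per_gene):
                gm = next(g for g in parents.genes[sub] if g.gene_id == gid)
                cds = gm.cds("".join(seq))
                used: set[int] = set()
                added = 0
                for _ in range(int(k)):
                    site = _pick_site(rng, cds, want_syn=False, used=used)
                    if site is None:
                        continue
                    p, b = site
                    used.add(p)
                    seq[gm.start + p] = b
                    cds = cds[:p] + b + cds[p + 1:]
                    added += 1
                base_counts[gid][2] = added
            parents.references[sub] = "".join(seq)
            ref = parents.references[sub]
        # final divergence truth
        for gm in parents.genes[sub]:
            base = gm.gene_id.rsplit("_", 1)[0]
            Dn, Ds = _count_fixed_classes(gm.cds(ref),
                                          parents.outgroup_cds[base])
            divergence[(base, sub)] = {
                "Dn": Dn, "Ds": Ds,
                "Dn_adaptive": base_counts[gm.gene_id][2]}
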