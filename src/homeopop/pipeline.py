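"""End-to-end glue: run the analysis pipeline on a synthetic study.

Each function performs one stage of the homeolog-resolved analysis on a
:class:`~homeopop.simulate.StudyData` object — emitting and re-reading the
standard file formats where the real pipeline would — and returns plain
DataFrames/objects that the analysis drivers, the tests and the acceptance
script all share.
"""

from __future__ import annotations

import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

from . import catalog, dfe, filtering, popgen, prf, selection, simulate, sorting

__all__ = [
    "default_study_config",
    "classify_study_reads",
    "filtered_records",
    "build_gene_alignments",
    "per_gene_diversity",
    "per_gene_selection",
    "pooled_folded_sfs",
    "fit_study_dfe",
]


def default_study_config(seed: int = 1, **overrides) -> simulate.SimulationConfig:
    """The study conditions shared by the numbered analysis drivers:
    a 60-gene desk-scale genome under the default resequencing design."""
    kw = dict(seed=seed, n_genes=60, gene_length_bp=900)
    kw.update(overrides)
    return simulate.SimulationConfig(**kw)


def classify_study_reads(study: simulate.StudyData, accession_idx: int = 0,
                         k: int = 21, max_rate: float = 0.10,
                         rng=None):
    """Simulate one accession's tetraploid read set and sort it.

    Returns (table, accuracy) where ``table`` has read_id, truth origin,
    assigned class and mismatch counts, and ``accuracy`` is the fraction
    of origin-classified (non-common, non-unclassified) reads whose label
    matches the truth.
    """
    cfg = study.config
    reads: dict[str, str] = {}
    origin: dict[str, str] = {}
    for sub in simulate.SUBGENOMES:
        hap = study.accession_haplotype(sub, accession_idx)
        rd, _, _ = simulate.simulate_reads(
            hap, cfg, rng=rng, source_label=sub,
            accession=study.accessions[accession_idx])
        for rid, r1, r2 in rd:
            reads[rid + "/1"] = r1
            reads[rid + "/2"] = r2
            origin[rid + "/1"] = sub
            origin[rid + "/2"] = sub
    idx_h = sorting.KmerIndex(study.parents.references["H"], k, "H")
    idx_l = sorting.KmerIndex(study.parents.references["L"], k, "L")
    rows = []
    n_ok = n_cls = 0
    for rid, seq in reads.items():
        ph = sorting.place_read(seq, idx_h, rid)
        pl = sorting.place_read(seq, idx_l, rid)
        c = sorting.classify_read(ph, pl, max_rate)
        rows.append((rid, origin[rid], c,
                     None if ph is None else ph.mismatches,
                     None if pl is None else pl.mismatches))
        if c in ("H_origin", "L_origin"):
            n_cls += 1
            n_ok += c[0] == origin[rid]
    table = pd.DataFrame(rows, columns=["read_id", "origin", "class",
                                        "mm_H", "mm_L"])
    return table, (n_ok / n_cls if n_cls else float("nan"))


def filtered_records(study: simulate.StudyData, sub: str,
                     config: filtering.FilterConfig | None = None,
                     depth_sums=None, blacklist=None, workdir=None):
    """Emit the subgenome VCF, re-read it, and apply all filters."""
    cfg = study.config
    scf = study.parents.scaffold_names[sub]
    vcf_text, site_df, geno_df = simulate.emit_vcf(
        study.variants[sub], study.parents.references[sub], scf, cfg,
        accession_names=study.accessions)
    with tempfile.TemporaryDirectory(dir=workdir) as td:
        path = Path(td) / f"{sub}.vcf"
        path.write_text(vcf_text)
        records, samples = filtering.read_vcf(path)
    records, report = filtering.apply_filters(
        records, config or filtering.FilterConfig(),
        depth_sums=depth_sums, blacklist=blacklist)
    return records, samples, site_df, geno_df, report


def build_gene_alignments(study: simulate.StudyData, sub: str,
                          records=None, with_outgroup: bool = True,
                          **kwargs) -> dict[str, catalog.GeneAlignment]:
    """Per-gene accession CDS alignments from filtered VCF records.

    Pass-failing sites are dropped; masked genotypes become N.  SNPs only
    feed the alignments (indels are the impact module's concern, and the
    injected frameshifts would otherwise shift coordinates).
    """
    if records is None:
        records, *_ = filtered_records(study, sub, **kwargs)
    by_gene: dict[str, list] = {}
    genes = {g.gene_id: g for g in study.parents.genes[sub]}
    for rec in records:
        if rec.filters or not rec.is_snp:
            continue
        for g in genes.values():
            if g.start <= rec.pos < g.end:
                by_gene.setdefault(g.gene_id, []).append(rec)
                break
    out = {}
    n_acc = study.config.n_accessions
    for gid, g in genes.items():
        ref_cds = g.cds(study.parents.references[sub])
        rows = []
        for ai in range(n_acc):
            variants = []
            masked = []
            for rec in by_gene.get(gid, []):
                cpos = rec.pos - g.start
                geno = rec.genotypes[ai]
                if rec.masks and rec.masks[ai]:
                    masked.append(cpos)
                elif geno["gt"] == (1, 1):
                    variants.append((cpos, rec.ref, rec.alt))
            rows.append(catalog.apply_variants_to_cds(ref_cds, variants,
                                                      masked=masked))
        ga = catalog.GeneAlignment(gid, sub, rows, list(study.accessions))
        if with_outgroup:
            base = gid.rsplit("_", 1)[0]
            ga = catalog.add_outgroup(ga, study.parents.outgroup_cds[base])
        out[gid] = ga
    return out


def per_gene_diversity(alignments: dict[str, catalog.GeneAlignment]
                       ) -> pd.DataFrame:
    """Per-gene diversity/neutrality statistics table (Table-2 layout)."""
    rows = []
    for gid, ga in alignments.items():
        st = popgen.gene_diversity(ga.rows, gid, ga.subgenome,
                                   outgroup=ga.outgroup, frame=ga.frame)
        rows.append({
            "gene_id": gid, "base_id": gid.rsplit("_", 1)[0],
            "subgenome": ga.subgenome, "n": st.n, "L": st.L_used, "S": st.S,
            "pi_total": st.pi_total, "theta_w": st.theta_w,
            "pi_syn": st.pi_syn, "pi_nonsyn": st.pi_nonsyn,
            "theta_w_syn": st.theta_w_syn,
            "theta_w_nonsyn": st.theta_w_nonsyn,
            "tajimas_d": st.tajimas_d, "fay_wu_h": st.fay_wu_h,
            "fu_li_dstar": st.fu_li_dstar, "fu_li_fstar": st.fu_li_fstar,
        })
    return pd.DataFrame(rows)


def per_gene_selection(alignments: dict[str, catalog.GeneAlignment],
                       p_max: float = 0.05, dos_eps: float = 0.01
                       ) -> pd.DataFrame:
    """Per-gene MK counts, Fisher p, DoS and selection label."""
    recs = []
    for gid, ga in alignments.items():
        if ga.outgroup is None:
            continue
        Dn, Ds, Pn, Ps = selection.mk_counts(ga.rows, ga.outgroup, ga.frame)
        rec = selection.SelectionRecord(
            gid, ga.subgenome, Dn, Ds, Pn, Ps,
            fisher_p=selection.mk_fisher(Dn, Ds, Pn, Ps),
            DoS=selection.dos(Dn, Ds, Pn, Ps))
        recs.append(rec)
    selection.classify_selection(recs, p_max, dos_eps)
    return pd.DataFrame([{
        "gene_id": r.gene_id, "base_id": r.gene_id.rsplit("_", 1)[0],
        "subgenome": r.subgenome, "Dn": r.Dn, "Ds": r.Ds, "Pn": r.Pn,
        "Ps": r.Ps, "fisher_p": r.fisher_p, "DoS": r.DoS, "label": r.label}
        for r in recs])


def pooled_folded_sfs(alignments: dict[str, catalog.GeneAlignment],
                      site_class: str) -> tuple[np.ndarray, float]:
    """(pooled folded SFS, total site count) for 'syn' or 'nonsyn' sites."""
    n = None
    pooled = None
    L_tot = 0.0
    for ga in alignments.values():
        part = popgen.partition_sites(ga.rows, frame=ga.frame)
        cols = part[f"{site_class}_sites"]
        L_tot += part[f"L_{site_class}"]
        sfs = popgen.build_sfs(ga.rows, fold=True, columns=cols,
                               site_class=site_class)
        if pooled is None:
            n = sfs.n
            pooled = sfs.counts.copy()
        else:
            pooled += sfs.counts
    return pooled, L_tot


def fit_study_dfe(sfs_syn, sfs_nonsyn, n: int, Dn: int, Ds: int,
                  Ln: float, Ls: float, reps: int = 100_000, seed: int = 0):
    """DFE + alpha for one pooled spectrum pair; returns (posterior,
    categories DataFrame, alpha dict)."""
    post = dfe.run_mcmc(sfs_syn, sfs_nonsyn, n, reps=reps, seed=seed,
                        site_ratio=Ln / Ls)
    cats = dfe.nes_categories(post)
    alpha = dfe.estimate_alpha(post, Dn, Ds, Ln, Ls)
    return post, cats, alpha
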