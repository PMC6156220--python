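"""Synthetic allotetraploid generator: construction invariants and oracles."""

import hashlib
import itertools

import numpy as np
import pytest
from scipy import integrate
from scipy.special import binom
from scipy.stats import gamma as gamma_dist

from homeopop import prf, simulate
from homeopop.codons import STOP_CODONS, translate
from homeopop.simulate import SimulationConfig


def no_internal_stops(cds: str) -> bool:
    aa = translate(cds)
    return "*" not in aa[:-1] and aa[-1] == "*"


class TestConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            SimulationConfig(gene_length_bp=601)
        with pytest.raises(ValueError):
            SimulationConfig(alpha_true=1.5)
        with pytest.raises(ValueError):
            SimulationConfig(parental_divergence=0.5)


class TestParentalGenomes:
    def test_zero_divergence_gives_identical_parents(self):
        cfg = SimulationConfig(seed=1, n_genes=5, gene_length_bp=300,
                               parental_divergence=0.0)
        g = simulate.simulate_parental_genomes(cfg)
        assert g.references["H"] == g.references["L"]

    def test_cds_construction_invariants(self):
        """10 orthologous CDS pairs, each 999 bp, stop-free interior."""
        cfg = SimulationConfig(seed=1, n_genes=10, gene_length_bp=999)
        g = simulate.simulate_parental_genomes(cfg)
        for sub in ("H", "L"):
            assert len(g.genes[sub]) == 10
            for gm in g.genes[sub]:
                cds = gm.cds(g.references[sub])
                assert len(cds) == 999
                assert cds.startswith("ATG")
                assert no_internal_stops(cds)
        # orthologous coordinates gene by gene
        for gh, gl in zip(g.genes["H"], g.genes["L"]):
            assert (gh.start, gh.end) == (gl.start, gl.end)

    def test_divergence_matches_binomial_oracle(self):
        """Realised per-site divergence within 3 sd of binomial(L, d)."""
        cfg = SimulationConfig(seed=7, n_genes=40, gene_length_bp=2502,
                               parental_divergence=0.03)
        g = simulate.simulate_parental_genomes(cfg)
        diffs = total = 0
        for gh in g.genes["H"]:
            a = gh.cds(g.references["H"])
            b = gh.cds(g.references["L"])
            diffs += sum(x != y for x, y in zip(a, b))
            total += len(a)
        assert total >= 1e5
        d = cfg.parental_divergence
        sd = np.sqrt(total * d * (1 - d))
        assert abs(diffs - total * d) < 3 * sd


class TestSelectedCounts:
    def test_neutral_limit_matches_harmonic(self, quad18):
        sc = simulate.simulate_selected_counts(
            0.01, 18, 0.3, 0.0, 0.0, Ls=1000, Ln=3000, rng=1, quad=quad18)
        i = np.arange(1, 18)
        assert np.allclose(sc.expected_nonsyn, 0.01 * 3000 / i)

    def test_strong_selection_kills_nonadaptive_divergence(self, quad18):
        sc = simulate.simulate_selected_counts(
            0.01, 18, 5.0, 1e5, 0.0, Ls=1000, Ln=3000,
            divergence_scale=10, rng=1, quad=quad18)
        # DFE with shape 5, mean 1e5: essentially all mass far above Nes=1
        assert sc.Dn < 0.01 * sc.Ds

    def test_expected_sfs_matches_independent_quadrature(self, quad18):
        """Frozen nested-quadrature oracle at (beta=0.3, mean=100, n=18)."""
        shape, mean = 0.3, 100.0
        scale = mean / shape
        sc = simulate.simulate_selected_counts(
            0.004, 18, shape, mean, 0.0, Ls=1.0, Ln=1.0, rng=1, quad=quad18)

        def kernel_oracle(g, i):
            def f(x):
                H = (np.exp(-2 * g * x) - np.exp(-2 * g)) / (
                    (1 - np.exp(-2 * g)) * x * (1 - x))
                return H * binom(18, i) * x ** i * (1 - x) ** (18 - i)
            pts = sorted({min(k / (2 * g), 0.99)
                          for k in (0.1, 1, 10, 100, 1000)}) if g > 1 else None
            return integrate.quad(f, 0, 1, limit=800, points=pts)[0]

        for i in (1, 5, 12, 17):
            def inner(g):
                return gamma_dist.pdf(g, shape, scale=scale) * \
                    kernel_oracle(g, i)
            total = gamma_dist.cdf(1e-12, shape, scale=scale) / i
            pts = np.logspace(-12, 7, 20)
            for a, b in zip(pts[:-1], pts[1:]):
                total += integrate.quad(inner, a, b, limit=300)[0]
            assert sc.expected_nonsyn[i - 1] == \
                pytest.approx(0.004 * total, rel=1e-8)

    def test_adaptive_fraction_targets_alpha(self, quad18):
        rng = np.random.default_rng(0)
        tot = ad = 0
        for k in range(40):
            sc = simulate.simulate_selected_counts(
                0.005, 18, 0.3, 100.0, 0.25, Ls=3e4, Ln=1e5, rng=rng,
                quad=quad18)
            tot += sc.Dn
            ad += sc.Dn_adaptive
        assert ad / tot == pytest.approx(0.25, abs=0.02)


class TestReads:
    def test_error_free_reads_match_source(self):
        cfg = SimulationConfig(seed=3, error_rate=0.0, coverage=3.0)
        genome = "".join(np.random.default_rng(0).choice(list("ACGT"), 5000))
        reads, truth, _ = simulate.simulate_reads(genome, cfg, rng=5)
        from homeopop.genome import revcomp
        for (rid, r1, r2), (_, _, _, start, end) in zip(
                reads, truth.itertuples(index=False)):
            assert genome[start:start + 100] == r1
            assert revcomp(genome[end - 100:end]) == r2

    def test_pair_count_arithmetic(self):
        cfg = SimulationConfig(seed=3, coverage=12.0, read_length=100)
        genome = "A" * 100_000
        reads, truth, skipped = simulate.simulate_reads(genome, cfg, rng=5)
        assert len(reads) + skipped == round(12 * 100_000 / 200)

    def test_error_rate_binomial_oracle(self):
        cfg = SimulationConfig(seed=3, error_rate=0.01, coverage=11.0,
                               insert_mean=300, insert_sd=0)
        rng = np.random.default_rng(1)
        genome = "".join(rng.choice(list("ACGT"), 100_000))
        reads, truth, _ = simulate.simulate_reads(genome, cfg, rng=6)
        from homeopop.genome import revcomp
        mism = bases = 0
        for (rid, r1, r2), t in zip(reads, truth.itertuples(index=False)):
            src1 = genome[t.start:t.start + 100]
            src2 = revcomp(genome[t.end - 100:t.end])
            mism += sum(a != b for a, b in zip(r1, src1))
            mism += sum(a != b for a, b in zip(r2, src2))
            bases += 200
        assert bases >= 1e6
        sd = np.sqrt(bases * 0.01 * 0.99)
        assert abs(mism - bases * 0.01) < 3 * sd


class TestVcf:
    def test_clean_records_pass_all_filters(self, small_study):
        from homeopop import filtering, pipeline
        records, *_ , report = pipeline.filtered_records(small_study, "H")
        assert all(not r.filters for r in records)

    def test_injected_qd_violations_flagged_exactly(self, dirty_study):
        from homeopop import pipeline
        records, samples, site_df, _, _ = pipeline.filtered_records(
            dirty_study, "H")
        truth_qd = {(r.scaffold, r.pos - 1)
                    for r in site_df.itertuples()
                    if "QD" in r.violations.split(",")}
        got_qd = {r.key for r in records if "QD" in r.filters}
        assert got_qd == truth_qd

    def test_het_injection_binomial_oracle(self):
        cfg = SimulationConfig(seed=9, n_genes=20, gene_length_bp=900,
                               het_rate=0.05)
        study = simulate.simulate_study(cfg)
        vcf, site_df, geno_df = simulate.emit_vcf(
            study.variants["H"], study.parents.references["H"], "scfH_1",
            cfg, accession_names=study.accessions)
        n_calls = len(site_df) * cfg.n_accessions
        n_het = (geno_df["violations"].str.contains("HET")).sum()
        sd = np.sqrt(n_calls * 0.05 * 0.95)
        assert abs(n_het - 0.05 * n_calls) < 3 * sd


class TestImpactInjection:
    def test_zero_rate_injects_nothing(self):
        cfg = SimulationConfig(seed=1, n_genes=10, gene_length_bp=300,
                               impact_rate=0.0)
        study = simulate.simulate_study(cfg)
        assert not [v for s in ("H", "L") for v in study.variants[s]
                    if v.vclass == "impact"]

    def test_frameshift_truth_type(self):
        cfg = SimulationConfig(seed=1, n_genes=40, gene_length_bp=300,
                               impact_rate=1.0)
        parents = simulate.simulate_parental_genomes(cfg)
        vars_ = simulate.inject_impact_mutations(
            parents.genes["H"], parents.references["H"], cfg)
        fs = [v for v in vars_ if v.impact_type == "frameshift"]
        assert fs, "expected frameshift injections"
        for v in fs:
            assert len(v.ref) == 2 and len(v.alt) == 1  # 1-bp deletion

    def test_carrier_counts_concentrated_at_one(self):
        """>= 80% of many injected events have exactly one carrier."""
        cfg = SimulationConfig(seed=2, n_genes=500, gene_length_bp=300,
                               impact_rate=1.0)
        parents = simulate.simulate_parental_genomes(cfg)
        vars_ = simulate.inject_impact_mutations(
            parents.genes["H"], parents.references["H"], cfg)
        assert len(vars_) >= 400
        singletons = sum(v.derived_count == 1 for v in vars_)
        assert singletons / len(vars_) >= 0.8


class TestDeterminism:
    def test_identical_config_gives_identical_files(self, tmp_path):
        cfg = SimulationConfig(seed=11, n_genes=6, gene_length_bp=300)
        hashes = []
        for d in ("a", "b"):
            study = simulate.simulate_study(cfg)
            out = tmp_path / d
            study.write(out)
            digest = {}
            for f in sorted(out.iterdir()):
                digest[f.name] = hashlib.sha256(f.read_bytes()).hexdigest()
            hashes.append(digest)
        assert hashes[0] == hashes[1]

    def test_truth_tables_cover_all_variants(self, small_study):
        cfg = small_study.config
        vcf, site_df, _ = simulate.emit_vcf(
            small_study.variants["H"], small_study.parents.references["H"],
            "scfH_1", cfg, accession_names=small_study.accessions)
        n_records = sum(1 for line in vcf.splitlines()
                        if line and not line.startswith("#"))
        assert n_records == len(site_df) == len(small_study.variants["H"])
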