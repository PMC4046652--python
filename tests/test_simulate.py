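"""Generator contracts: determinism, planted truth, read and intensity models."""

import numpy as np
import pytest

from allosnp import (
    GoldenGateConfig,
    SimulationConfig,
    generate_panel,
    generate_reference,
    simulate_goldengate,
    simulate_reads,
)
from allosnp import _seq
from allosnp.config import ConfigError
from allosnp.genes import translate
from allosnp.goldengate import theta_transform
from allosnp.simulate import _channel_signal, generate_gene_models


def _cfg(**kw):
    base = dict(
        seed=5, n_accessions=6, chrom_plan=[("A", 20_000), ("C", 20_000)],
        repeat_families=[], snp_rate=3e-4, n_genes=0,
        per_accession_depth=[8.0] * 6, minor_count_spectrum=[0.4, 0.3, 0.3],
    )
    base.update(kw)
    return SimulationConfig(**base)


class TestReference:
    def test_zero_divergence_identity_outside_repeats(self):
        ref, truth = generate_reference(_cfg(homoeolog_divergence=0.0))
        assert len(truth.homoeolog_sites) == 0
        np.testing.assert_array_equal(ref.seqs["A01"], ref.seqs["C01"])

    def test_divergent_site_count_within_binomial_bounds(self):
        cfg = _cfg(chrom_plan=[("A", 100_000), ("C", 100_000)],
                   homoeolog_divergence=0.03)
        _, truth = generate_reference(cfg)
        n, p = 100_000, 0.03
        sd = np.sqrt(n * p * (1 - p))
        assert abs(len(truth.homoeolog_sites) - n * p) < 3 * sd

    def test_same_seed_is_byte_identical(self, tmp_path):
        from allosnp.io import write_fasta

        for i in (1, 2):
            ref, _ = generate_reference(_cfg(repeat_families=[(100, 4)]))
            write_fasta(ref, tmp_path / f"r{i}.fa")
        assert (tmp_path / "r1.fa").read_bytes() == (tmp_path / "r2.fa").read_bytes()

    def test_short_chromosome_rejected(self):
        with pytest.raises(ConfigError):
            _cfg(chrom_plan=[("A", 500)])

    def test_repeats_recorded_and_exact(self):
        ref, truth = generate_reference(_cfg(repeat_families=[(120, 5)]))
        # 5 copies per subgenome planted
        assert len(truth.repeat_intervals) == 10
        units = [
            _seq.decode(ref.seqs[c][s:e]) for c, s, e in truth.repeat_intervals
        ]
        assert len(set(units)) == 1  # exact copies


class TestPanel:
    def test_snp_rate_zero_plants_nothing(self):
        ref, truth = generate_reference(_cfg())
        panel = generate_panel(ref, truth, _cfg(snp_rate=0.0))
        assert len(panel.sites) == 0

    def test_all_genotypes_homozygous_and_outside_repeats(self, tiny_world):
        truth = tiny_world["truth"]
        repeat = set()
        for c, s, e in truth.repeat_intervals:
            repeat.update((c, p) for p in range(s, e))
        for r in truth.simple_snps.itertuples():
            assert (r.chrom, r.pos) not in repeat
            # inbred: one homozygous base letter per accession
            assert set(r.genotypes) <= set(r.alleles)

    def test_fixed_spectrum_gives_maf_half(self):
        cfg = _cfg(minor_count_spectrum=[0.0, 0.0, 1.0])  # always k = 3 of 6
        ref, truth = generate_reference(cfg)
        panel = generate_panel(ref, truth, cfg)
        assert len(panel.sites) > 0
        for r in panel.sites.itertuples():
            if len(r.alleles) == 2:
                assert r.minor_count == 3  # frequency 0.5

    def test_planted_density_within_binomial_bounds(self):
        cfg = _cfg(chrom_plan=[("A", 100_000), ("C", 100_000)], snp_rate=1e-3)
        ref, truth = generate_reference(cfg)
        panel = generate_panel(ref, truth, cfg)
        usable = sum(
            (~truth.repeat_mask_for(c, ref.seqs[c].size)).sum() - 200
            for c in ref.names
        )
        expect = usable * 1e-3
        sd = np.sqrt(expect)
        assert abs(len(panel.sites) - expect) < 3.3 * sd  # 99% bound


class TestReads:
    def test_error_free_reads_match_origin(self):
        cfg = _cfg(base_error_rate=0.0)
        ref, truth = generate_reference(cfg)
        panel = generate_panel(ref, truth, cfg)
        readsets = simulate_reads(ref, panel, cfg)
        rs = readsets[0]
        personal = {}
        for ci, chrom in enumerate(rs.chrom_names):
            p = ref.seqs[chrom].copy()
            pos, alleles = panel.variants_for(0, chrom)
            p[pos] = alleles
            personal[ci] = p
        for i in range(0, rs.n_reads, 97):
            origin = personal[rs.chrom[i]][rs.start[i]:rs.start[i] + rs.read_length]
            got = rs.seq[i]
            if rs.strand[i]:
                got = _seq.revcomp(got)
            np.testing.assert_array_equal(got, origin)

    def test_coverage_arithmetic(self):
        # 10.7x over 1 Mb with 100 bp reads -> 107,000 reads exactly
        cfg = SimulationConfig(
            seed=1, n_accessions=2, chrom_plan=[("A", 1_000_000)],
            repeat_families=[], snp_rate=0.0, n_genes=0,
            per_accession_depth=[10.7, 10.7], minor_count_spectrum=[1.0],
        )
        ref, truth = generate_reference(cfg)
        panel = generate_panel(ref, truth, cfg)
        readsets = simulate_reads(ref, panel, cfg)
        assert readsets[0].n_reads == 107_000

    def test_invalid_depth_rejected(self):
        with pytest.raises(ConfigError):
            _cfg(per_accession_depth=[8.0] * 5 + [0.0])


class TestGeneModels:
    def test_cds_construction_invariants(self, tiny_world):
        ref, models = tiny_world["reference"], tiny_world["models"]
        assert models, "generator placed no genes"
        strands = set()
        for m in models:
            cds = m.cds_sequence(ref.seqs[m.chrom])
            assert len(cds) % 3 == 0
            assert cds.startswith("ATG")
            protein = translate(cds)
            assert protein.endswith("*")
            assert "*" not in protein[:-1]
            strands.add(m.strand)
        assert strands == {"+", "-"}

    def test_go_terms_assigned(self, tiny_world):
        go_map = tiny_world["go_map"]
        assert all(1 <= len(v) <= 5 for v in go_map.values())

    def test_overflow_warns_and_truncates(self):
        cfg = _cfg(n_genes=500, chrom_plan=[("A", 20_000), ("C", 20_000)])
        ref, truth = generate_reference(cfg)
        with pytest.warns(UserWarning, match="could only place"):
            models, _ = generate_gene_models(ref, truth, cfg)
        assert 0 < len(models) < 500


class TestGoldenGateSimulation:
    def test_noise_free_thetas(self):
        gg = GoldenGateConfig(sd=0.0)
        for genotype, expected in (("AA", 0.0), ("AB", 0.5), ("BB", 1.0)):
            cy3, cy5 = _channel_signal({"AA": 1.0, "AB": 0.5, "BB": 0.0}[genotype],
                                       GoldenGateConfig(sd=0.0, mu_off=0.0))
            theta, _ = theta_transform(cy3, cy5)
            assert theta == pytest.approx(expected, abs=1e-12)
        # with a nonzero off-channel background theta is near but not at 0/1
        cy3, cy5 = _channel_signal(1.0, gg)
        theta, _ = theta_transform(cy3, cy5)
        assert 0 < theta < 0.1

    def test_hemi_assay_pooled_theta_groups(self):
        # noise-free enumeration: locus1 genotypes x population-fixed locus2
        gg = GoldenGateConfig(sd=0.0)
        thetas = set()
        for pop, second in (("DH", "AA"), ("F2", "BB")):
            genos = ("AA", "BB") if pop == "DH" else ("AA", "AB", "BB")
            for g in genos:
                c3a, c5a = _channel_signal({"AA": 1, "AB": .5, "BB": 0}[g], gg)
                c3b, c5b = _channel_signal({"AA": 1, "AB": .5, "BB": 0}[second], gg)
                theta, _ = theta_transform(c3a + c3b, c5a + c5b)
                thetas.add(round(theta, 6))
        assert len(thetas) >= 4

    def test_simulated_table_shape_and_replicates(self):
        cfg = _cfg()
        data = simulate_goldengate(None, cfg)
        df = data.intensities
        gg = cfg.goldengate
        n_samples = gg.n_dh + gg.n_f2 + 4 + (gg.n_replicates - 1)
        assert len(df) == n_samples * gg.n_assays
        reps = df[df["replicate_of"] != ""]
        assert reps["sample"].nunique() == gg.n_replicates - 1
        assert (df[["Cy3", "Cy5"]] >= 0).all().all()

    def test_hemi_assays_recorded_in_truth(self, tiny_world):
        cfg, truth = tiny_world["config"], tiny_world["truth"]
        data = simulate_goldengate(truth, cfg)
        expected = int(round(cfg.goldengate.hemi_fraction * cfg.goldengate.n_assays))
        assert len(truth.hemi_assays) == expected
        assert set(truth.hemi_assays) == set(
            data.assays.loc[data.assays["hemi"], "assay"]
        )
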