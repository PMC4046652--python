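"""Substitution classes, AS-PCR rule, coding effects, density, pairwise counts."""

import numpy as np
import pytest

from allosnp import (
    classify_substitution,
    coding_effect,
    density_per_100kb,
    density_table,
    pairwise_snp_matrix,
    summarize_pairwise,
    tstv_ratio_from_shares,
)
from allosnp import _seq
from allosnp.annotate import aspcr_suitable
from allosnp.genes import GeneModel, translate
from allosnp.snp_filter import GenotypeCall, SnpSite
from allosnp.simulate import ReferenceSet


class TestSubstitution:
    @pytest.mark.parametrize("a,b,expected", [
        ("A", "G", "transition"), ("G", "A", "transition"),
        ("C", "T", "transition"), ("C", "A", "transversion"),
        ("A", "T", "transversion"), ("G", "C", "transversion"),
        ("G", "T", "transversion"), ("T", "A", "transversion"),
    ])
    def test_classes(self, a, b, expected):
        assert classify_substitution(a, b) == expected

    def test_identical_alleles_rejected(self):
        with pytest.raises(ValueError):
            classify_substitution("A", "A")

    def test_ratio_from_printed_shares(self):
        assert tstv_ratio_from_shares(57.5, 42.5) == pytest.approx(1.3529, abs=1e-4)


class TestAsPcr:
    def test_rule_truth_table(self):
        at = ("A", "T")
        assert aspcr_suitable(at, "GAA", "GGG") is True    # -3 base G
        assert aspcr_suitable(at, "TAA", "GGG") is True    # -3 base T
        assert aspcr_suitable(at, "CAA", "CAT") is False   # -3 C, +3 T: neither
        assert aspcr_suitable(at, "CAA", "GGC") is True    # +3 base C
        assert aspcr_suitable(at, "CAA", "GGA") is True    # +3 base A
        assert aspcr_suitable(at, "CAA", "GGG") is False   # neither side
        assert aspcr_suitable(("C", "T"), "GAA", "GGA") is False  # not A/T type

    def test_truncated_flank_warns_false(self):
        with pytest.warns(UserWarning):
            assert aspcr_suitable(("A", "T"), "GA", "GGA") is False


def _single_gene_reference(cds: str, strand: str, pad: int = 30):
    rng = np.random.default_rng(0)
    codes = _seq.encode(cds)
    if strand == "-":
        codes = _seq.revcomp(codes)
    chrom = np.concatenate([
        _seq.random_seq(rng, pad), codes, _seq.random_seq(rng, pad)
    ])
    ref = ReferenceSet(["A01"], {"A01": chrom}, {"A01": "A"}, [])
    model = GeneModel("g1", "A01", strand, [(pad, pad + len(cds))])
    return ref, model


class TestCodingEffect:
    @pytest.mark.parametrize("codon,pos_in_codon,alt,expected_class,alt_aa", [
        ("TGG", 3, "A", "stop_gain", "*"),    # TGG -> TGA
        ("GAA", 3, "G", "synonymous", "E"),   # GAA -> GAG
        ("AAA", 1, "G", "nonsynonymous", "E"),  # AAA -> GAA
    ])
    def test_plus_strand_classes(self, codon, pos_in_codon, alt, expected_class,
                                 alt_aa):
        cds = "ATG" + codon + "TAA"
        ref, model = _single_gene_reference(cds, "+")
        pos = 30 + 3 + (pos_in_codon - 1)
        eff = coding_effect("A01", pos, codon[pos_in_codon - 1], alt,
                            [model], ref)
        assert eff.effect == expected_class
        assert eff.alt_aa == alt_aa
        assert eff.codon_index == 1
        assert eff.codon_position == pos_in_codon

    def test_stop_loss(self):
        cds = "ATGGAATAA"
        ref, model = _single_gene_reference(cds, "+")
        # TAA -> CAA at the stop codon's first base
        eff = coding_effect("A01", 30 + 6, "T", "C", [model], ref)
        assert (eff.effect, eff.ref_aa, eff.alt_aa) == ("stop_loss", "*", "Q")

    def test_minus_strand_complements_allele(self):
        cds = "ATGGAATAA"
        ref, model = _single_gene_reference(cds, "-")
        # genomic position of CDS index 5 (last base of codon GAA):
        # minus strand, so genomic index = pad + (len-1-5)
        gpos = 30 + (9 - 1 - 5)
        # genomic ref base is complement of 'A'; substituting genomic T->C
        # means CDS A->G: GAA -> GAG, synonymous
        eff = coding_effect("A01", gpos, "T", "C", [model], ref)
        assert (eff.effect, eff.ref_codon, eff.alt_codon) == (
            "synonymous", "GAA", "GAG")

    def test_noncoding_returns_none(self):
        ref, model = _single_gene_reference("ATGGAATAA", "+")
        assert coding_effect("A01", 2, "A", "C", [model], ref) is None


def test_coding_effect_agrees_with_whole_protein_retranslation(tiny_world):
    """Oracle: mutate the genome base, re-translate the full CDS, diff."""
    ref = tiny_world["reference"]
    models = tiny_world["models"]
    rng = np.random.default_rng(4)
    checked = 0
    for m in models:
        seq = ref.seqs[m.chrom]
        for s, e in m.exons:
            for _ in range(10):
                pos = int(rng.integers(s, e))
                ref_base = _seq.BASES[seq[pos]]
                alt_base = _seq.BASES[(seq[pos] + rng.integers(1, 4)) % 4]
                eff = coding_effect(m.chrom, pos, ref_base, alt_base, models, ref)
                assert eff is not None and eff.gene_id == m.gene_id
                before = translate(m.cds_sequence(seq))
                mutated = seq.copy()
                mutated[pos] = _seq.encode(alt_base)[0]
                after = translate(m.cds_sequence(mutated))
                diff = [
                    (i, x, y) for i, (x, y) in enumerate(zip(before, after))
                    if x != y
                ]
                if eff.effect == "synonymous":
                    assert diff == []
                else:
                    assert len(diff) == 1
                    i, x, y = diff[0]
                    assert i == eff.codon_index
                    assert (x, y) == (eff.ref_aa, eff.alt_aa)
                    if eff.effect == "stop_gain":
                        assert y == "*" != x
                    elif eff.effect == "stop_loss":
                        assert x == "*" != y
                checked += 1
    assert checked >= 50


class TestDensity:
    @pytest.mark.parametrize("count,length,expected", [
        (48_510, 23_750_921, 204),   # densest chromosome worked example
        (14_756, 32_828_344, 45),    # sparsest
        (10, 1_000_000, 1),
        (758_494, 635_365_519, 119),
    ])
    def test_rounding(self, count, length, expected):
        assert density_per_100kb(count, length) == expected

    def test_table_and_windows(self):
        sites = [_site("A01", p) for p in (5, 150_000, 150_001, 250_000)]
        table, windows = density_table(sites, {"A01": 300_000, "C01": 100_000})
        a01 = table[table["chrom"] == "A01"].iloc[0]
        assert a01["snps"] == 4
        assert a01["snp_per_100kb"] == 1
        per_chrom = windows.groupby("chrom")["snps"].sum()
        assert per_chrom["A01"] == 4 and per_chrom["C01"] == 0
        assert windows[windows["chrom"] == "A01"]["snps"].tolist() == [1, 2, 1]

    def test_unknown_chromosome_rejected(self):
        with pytest.raises(ValueError):
            density_table([_site("Z99", 5)], {"A01": 1000})


def _site(chrom, pos, genos=("A", "A", "G", "G")):
    calls = [
        GenotypeCall(f"acc{i:02d}", "called" if g else "missing_low_depth",
                     g or None, 10 if g else 0)
        for i, g in enumerate(genos)
    ]
    alleles = sorted({g for g in genos if g})
    return SnpSite(chrom, pos, "A", alleles,
                   [sum(1 for g in genos if g == a) for a in alleles],
                   calls, "biallelic" if len(alleles) == 2 else None,
                   "accepted", None)


class TestPairwise:
    def test_counts_require_both_called(self):
        accs = [f"acc{i:02d}" for i in range(4)]
        sites = [
            _site("A01", 1, ("A", "A", "G", "G")),
            _site("A01", 2, ("A", "G", "G", "G")),
            _site("A01", 3, ("A", "A", None, "G")),  # acc02 missing
        ]
        mat = pairwise_snp_matrix(sites, accs)
        assert mat.loc["acc00", "acc03"] == 3
        assert mat.loc["acc00", "acc01"] == 1
        assert mat.loc["acc02", "acc03"] == 0  # missing is not a difference
        assert mat.loc["acc01", "acc02"] == 1
        assert (mat.to_numpy() == mat.to_numpy().T).all()
        assert (np.diag(mat.to_numpy()) == 0).all()

    def test_identical_accessions_count_zero(self):
        sites = [_site("A01", p, ("A", "A", "G", "G")) for p in range(5)]
        mat = pairwise_snp_matrix(sites, [f"acc{i:02d}" for i in range(4)])
        assert mat.loc["acc00", "acc01"] == 0

    def test_summary_shares(self):
        sites = [_site("A01", p, ("A", "A", "G", "G")) for p in range(4)]
        mat = pairwise_snp_matrix(sites, [f"acc{i:02d}" for i in range(4)])
        out = summarize_pairwise(mat, total_snps=8)
        assert out["n_pairs"] == 6
        assert out["max_count"] == 4
        assert out["max_share_pct"] == 50.0
        assert out["min_count"] == 0
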