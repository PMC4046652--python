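"""Mapping contract: seed-and-extend vs exhaustive Hamming placement."""

import numpy as np
import pytest

from allosnp import (
    AlignmentParams,
    SimulationConfig,
    build_index,
    classify_counts,
    map_read,
    map_reads,
)
from allosnp import _seq
from allosnp.align import CAT_REPEAT, CAT_UNALIGNED, CAT_UNIQUE
from allosnp.simulate import ReferenceSet, generate_reference


def _ref_from(seqs: dict[str, str]) -> ReferenceSet:
    names = list(seqs)
    return ReferenceSet(
        names, {n: _seq.encode(s) for n, s in seqs.items()},
        {n: n[0] for n in names}, [],
    )


@pytest.fixture(scope="module")
def toy():
    rng = np.random.default_rng(42)
    seq = _seq.decode(_seq.random_seq(rng, 2000))
    ref = _ref_from({"A01": seq})
    return ref, build_index(ref), rng


class TestSeedIndex:
    def test_unique_sequence_single_locus_seeds(self, toy):
        ref, index, _ = toy
        s = _seq.decode(ref.seqs["A01"][100:132])
        assert index.n_seed_loci(s) == 1

    def test_duplicate_chromosome_doubles_loci(self, toy):
        ref, _, _ = toy
        dup = _ref_from({"A01": _seq.decode(ref.seqs["A01"]),
                         "A02": _seq.decode(ref.seqs["A01"])})
        index = build_index(dup)
        assert index.n_seed_loci(_seq.decode(ref.seqs["A01"][100:132])) == 2

    def test_all_n_chromosome_has_no_seeds(self):
        ref = _ref_from({"A01": "N" * 1000})
        index = build_index(ref)
        assert index.hash_sorted.size == 0


class TestMapRead:
    def test_exact_read_is_unique_zero_mismatches(self, toy):
        ref, index, _ = toy
        read = _seq.decode(ref.seqs["A01"][500:600])
        a = map_read(read, index)
        assert (a.category, a.chrom, a.pos, a.strand, a.mismatches) == (
            "unique", "A01", 500, "+", 0)

    def test_reverse_strand_read(self, toy):
        ref, index, _ = toy
        read = _seq.decode(_seq.revcomp(ref.seqs["A01"][500:600]))
        a = map_read(read, index)
        assert (a.category, a.pos, a.strand) == ("unique", 500, "-")

    def test_homoeolog_tie_is_repeat_but_better_score_wins(self, rng):
        base = _seq.random_seq(rng, 1000)
        variant = base.copy()
        variant[450] = (variant[450] + 1) % 4  # one fixed difference
        ref = _ref_from({"A01": _seq.decode(base), "C01": _seq.decode(variant)})
        index = build_index(ref)
        # read straddling the difference, matching A exactly: 0 vs 1 mismatches
        read = _seq.decode(base[400:500])
        a = map_read(read, index)
        assert (a.category, a.chrom, a.mismatches) == ("unique", "A01", 0)
        # read from an identical region ties -> repeat, never arbitrary
        a2 = map_read(_seq.decode(base[100:200]), index)
        assert a2.category == "repeat"

    def test_too_many_mismatches_unaligned(self, toy):
        ref, index, rng = toy
        read = ref.seqs["A01"][800:900].copy()
        # 6 > 5 mismatches at spread positions (leaves exact 32-mer seeds)
        for p in (0, 1, 2, 97, 98, 99):
            read[p] = (read[p] + 1) % 4
        assert map_read(read, index).category == "unaligned"
        read5 = ref.seqs["A01"][800:900].copy()
        for p in (0, 1, 2, 97, 98):
            read5[p] = (read5[p] + 1) % 4
        a = map_read(read5, index)
        assert (a.category, a.mismatches) == ("unique", 5)

    def test_short_read_unaligned_with_reason(self, toy):
        _, index, _ = toy
        a = map_read("ACGTACGT", index)
        assert a.category == "unaligned"
        assert "short" in a.reason

    def test_overhang_respects_min_align_length(self, toy):
        ref, index, _ = toy
        # 60 bases real sequence + 40 bases past the contig end
        read = np.concatenate([
            ref.seqs["A01"][1940:2000],
            _seq.random_seq(np.random.default_rng(7), 40),
        ])
        a40 = map_read(read, index, AlignmentParams(min_align_length=40))
        a80 = map_read(read, index, AlignmentParams(min_align_length=80))
        assert a40.category == "unique" and a40.pos == 1940
        assert a80.category == "unaligned"


class TestClassify:
    def test_tally_conservation(self, toy):
        ref, index, _ = toy
        rng = np.random.default_rng(1)
        starts = rng.integers(0, 1900, size=50)
        reads = np.stack([ref.seqs["A01"][s:s + 100] for s in starts])
        res = map_reads(reads, index)
        tally = classify_counts(res)
        assert tally["total"] == 50
        assert tally["unique"] + tally["repeat"] + tally["unaligned"] == 50
        assert tally["unique"] == 50  # error-free draws from unique sequence

    def test_reads_from_high_copy_repeat_all_repeat(self, rng):
        unit = _seq.random_seq(rng, 300)
        chrom = np.concatenate(
            [v for _ in range(20) for v in (unit, _seq.random_seq(rng, 50))]
        )
        ref = _ref_from({"A01": _seq.decode(chrom)})
        index = build_index(ref)
        reads = np.stack([unit[i:i + 100] for i in range(0, 200, 10)])
        res = map_reads(reads, index)
        assert (res.category == CAT_REPEAT).all()


def _brute_force(read, chrom_seqs, params):
    """All-positions ungapped Hamming oracle (interior placements)."""
    L = read.size
    best, n_best = None, 0
    for codes in chrom_seqs.values():
        win = np.lib.stride_tricks.sliding_window_view(codes, L)
        for oriented in (read, _seq.revcomp(read)):
            mm = (win != oriented).sum(axis=1)
            ok = mm <= params.max_mismatches
            for v in mm[ok]:
                if best is None or v < best:
                    best, n_best = int(v), 1
                elif v == best:
                    n_best += 1
    if best is None:
        return "unaligned", None
    return ("unique", best) if n_best == 1 else ("repeat", best)


def test_equivalence_with_brute_force_on_homoeologous_toy_genome():
    """Seed-and-extend matches the exhaustive aligner, placement by placement."""
    cfg = SimulationConfig(
        seed=21, n_accessions=2, chrom_plan=[("A", 20_000), ("C", 20_000)],
        repeat_families=[], snp_rate=0.0, n_genes=0, homoeolog_divergence=0.05,
        per_accession_depth=[1.0, 1.0], minor_count_spectrum=[1.0],
    )
    ref, _ = generate_reference(cfg)
    index = build_index(ref)
    params = AlignmentParams()
    rng = np.random.default_rng(8)
    reads = []
    for _ in range(250):
        chrom = ref.names[rng.integers(0, 2)]
        start = rng.integers(0, ref.seqs[chrom].size - 100)
        read = ref.seqs[chrom][start:start + 100].copy()
        n_err = rng.integers(0, 4)
        idx = rng.choice(100, size=n_err, replace=False)
        read = _seq.mutate_bases(rng, read, idx)
        if rng.random() < 0.5:
            read = _seq.revcomp(read)
        reads.append(read)
    res = map_reads(np.stack(reads), index, params)
    from allosnp.align import CATEGORY_NAMES

    for i, read in enumerate(reads):
        cat, mm = _brute_force(read, ref.seqs, params)
        assert CATEGORY_NAMES[res.category[i]] == cat, i
        if cat == "unique":
            assert res.mismatches[i] == mm, i


def test_no_cross_homoeolog_placement_with_clean_reads():
    """Divergent homoeologs never capture each other's error-free reads."""
    cfg = SimulationConfig(
        seed=13, n_accessions=2, chrom_plan=[("A", 30_000), ("C", 30_000)],
        repeat_families=[], snp_rate=0.0, n_genes=0, homoeolog_divergence=0.04,
        base_error_rate=0.0, per_accession_depth=[1.0, 1.0],
        minor_count_spectrum=[1.0],
    )
    ref, truth = generate_reference(cfg)
    index = build_index(ref)
    div = truth.homoeolog_sites["pos"].to_numpy()
    rng = np.random.default_rng(5)
    starts = []
    # reads whose span covers >= 2 divergent positions
    while len(starts) < 120:
        s = int(rng.integers(0, 30_000 - 100))
        if ((div >= s) & (div < s + 100)).sum() >= 2:
            starts.append(s)
    reads = np.stack([ref.seqs["A01"][s:s + 100] for s in starts])
    res = map_reads(reads, index)
    assert (res.category == CAT_UNIQUE).all()
    assert all(res.names[c] == "A01" for c in res.chrom)
    np.testing.assert_array_equal(res.pos, np.asarray(starts))


def test_order_independence():
    rng = np.random.default_rng(17)
    seq = _seq.random_seq(rng, 5000)
    ref = _ref_from({"A01": _seq.decode(seq)})
    index = build_index(ref)
    starts = rng.integers(0, 4900, size=80)
    reads = np.stack([seq[s:s + 100] for s in starts])
    perm = rng.permutation(80)
    res1 = map_reads(reads, index)
    res2 = map_reads(reads[perm], index)
    np.testing.assert_array_equal(res1.category[perm], res2.category)
    np.testing.assert_array_equal(res1.pos[perm], res2.pos)
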