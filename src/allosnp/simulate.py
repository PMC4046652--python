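"""Synthetic allotetraploid study generator.

Everything the discovery pipeline consumes is produced here from a single
seeded :class:`~allosnp.config.SimulationConfig`, together with a truth
table that records exactly what was planted: simple SNPs (allelic variants
segregating in the inbred panel), homoeolog-divergent positions (the A/C
subgenome differences that masquerade as SNPs in an allopolyploid), repeat
intervals, and which genotyping assays were planted as hemi-SNPs.

The genome model: each homoeologous chromosome pair descends from one
ancestral sequence; the C copy differs from the A copy at a configurable
per-base divergence.  Repeat family units are inserted as exact copies.
All accessions are fully inbred (homozygous everywhere), so any
heterozygous pileup downstream must come from homoeolog co-alignment or
sequencing error — the observation the filter cascade exploits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _seq, genes
from .config import ConfigError, GoldenGateConfig, SimulationConfig

_STAGES = {"reference": 0, "genes": 1, "panel": 2, "reads": 3, "goldengate": 4}


def stage_rng(config: SimulationConfig, stage: str) -> np.random.Generator:
    """Per-stage generator so each stage is independently reproducible."""
    ss = np.random.SeedSequence(config.seed, spawn_key=(_STAGES[stage],))
    return np.random.default_rng(ss)


# --------------------------------------------------------------------------
# containers


@dataclass
class ReferenceSet:
    names: list[str]
    seqs: dict[str, np.ndarray]             # uint8 codes
    subgenome: dict[str, str]               # chrom -> 'A' | 'C'
    pairs: list[tuple[str, str]]            # (A chrom, C chrom) homoeolog pairs

    def total_length(self) -> int:
        return sum(s.size for s in self.seqs.values())

    def chrom_lengths(self) -> dict[str, int]:
        return {n: self.seqs[n].size for n in self.names}

    def subset(self, names: list[str]) -> "ReferenceSet":
        keep = set(names)
        return ReferenceSet(
            names=[n for n in self.names if n in keep],
            seqs={n: self.seqs[n] for n in self.names if n in keep},
            subgenome={n: self.subgenome[n] for n in self.names if n in keep},
            pairs=[(a, c) for a, c in self.pairs if a in keep and c in keep],
        )


@dataclass
class TruthTable:
    simple_snps: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["chrom", "pos", "ref", "alleles", "genotypes", "minor_count",
                     "detectable"]
        )
    )
    homoeolog_sites: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["a_chrom", "c_chrom", "pos"])
    )
    repeat_intervals: list[tuple[str, int, int]] = field(default_factory=list)
    hemi_assays: list[str] = field(default_factory=list)

    def recompute_homoeolog_sites(self, reference: ReferenceSet) -> None:
        rows = []
        for a_name, c_name in reference.pairs:
            diff = np.nonzero(reference.seqs[a_name] != reference.seqs[c_name])[0]
            for p in diff:
                rows.append((a_name, c_name, int(p)))
        self.homoeolog_sites = pd.DataFrame(rows, columns=["a_chrom", "c_chrom", "pos"])

    def repeat_mask_for(self, chrom: str, length: int) -> np.ndarray:
        mask = np.zeros(length, dtype=bool)
        for c, s, e in self.repeat_intervals:
            if c == chrom:
                mask[s:e] = True
        return mask


# --------------------------------------------------------------------------
# reference


def generate_reference(config: SimulationConfig) -> tuple[ReferenceSet, TruthTable]:
    """Build the A+C reference and record repeats and divergent positions."""
    rng = stage_rng(config, "reference")
    a_plan = [(i, ln) for i, (sub, ln) in enumerate(config.chrom_plan) if sub == "A"]
    c_plan = [(i, ln) for i, (sub, ln) in enumerate(config.chrom_plan) if sub == "C"]

    names: list[str] = []
    seqs: dict[str, np.ndarray] = {}
    subgenome: dict[str, str] = {}
    pairs: list[tuple[str, str]] = []

    n_pairs = min(len(a_plan), len(c_plan))
    for k in range(n_pairs):
        (_, la), (_, lc) = a_plan[k], c_plan[k]
        if la != lc:
            raise ConfigError(
                f"homoeologous pair {k + 1}: A length {la} != C length {lc}"
            )
        ancestral = _seq.random_seq(rng, la)
        a_name, c_name = f"A{k + 1:02d}", f"C{k + 1:02d}"
        div_idx = np.nonzero(rng.random(la) < config.homoeolog_divergence)[0]
        c_copy = _seq.mutate_bases(rng, ancestral, div_idx)
        seqs[a_name] = ancestral.copy()
        seqs[c_name] = c_copy
        pairs.append((a_name, c_name))
        subgenome[a_name] = "A"
        subgenome[c_name] = "C"

    # unpaired leftovers have no homoeolog
    for sub, plan, used in (("A", a_plan, n_pairs), ("C", c_plan, n_pairs)):
        for j, (_, ln) in enumerate(plan[used:], start=used):
            name = f"{sub}{j + 1:02d}"
            seqs[name] = _seq.random_seq(rng, ln)
            subgenome[name] = sub

    # stable chromosome order: A first then C, numeric
    names = sorted(seqs, key=lambda n: (n[0], int(n[1:])))
    reference = ReferenceSet(names, seqs, subgenome, pairs)
    truth = TruthTable()

    # exact-copy repeat family units, copy_number per subgenome
    for fam_i, (unit_len, copies) in enumerate(config.repeat_families):
        unit = _seq.random_seq(rng, unit_len)
        for sub in ("A", "C"):
            chroms = [n for n in names if subgenome[n] == sub]
            if not chroms:
                continue
            lens = np.array([seqs[n].size for n in chroms], dtype=float)
            for _copy in range(copies):
                for _attempt in range(200):
                    cn = chroms[rng.choice(len(chroms), p=lens / lens.sum())]
                    seq = seqs[cn]
                    if seq.size <= unit_len + 2 * config.read_length:
                        continue
                    start = int(
                        rng.integers(config.read_length,
                                     seq.size - unit_len - config.read_length)
                    )
                    iv = (start, start + unit_len)
                    clash = any(
                        c == cn and s < iv[1] and iv[0] < e
                        for c, s, e in truth.repeat_intervals
                    )
                    if clash:
                        continue
                    seq[iv[0]:iv[1]] = unit
                    truth.repeat_intervals.append((cn, iv[0], iv[1]))
                    break
    truth.repeat_intervals.sort()
    truth.recompute_homoeolog_sites(reference)
    return reference, truth


def generate_gene_models(
    reference: ReferenceSet, truth: TruthTable, config: SimulationConfig
):
    """Plant gene models (mutates reference sequences; truth diff refreshed)."""
    rng = stage_rng(config, "genes")
    forbidden: dict[str, list[tuple[int, int]]] = {}
    for c, s, e in truth.repeat_intervals:
        forbidden.setdefault(c, []).append((s, e))
    models, go_map = genes.generate_gene_models(reference, config, rng, forbidden)
    truth.recompute_homoeolog_sites(reference)
    return models, go_map


# --------------------------------------------------------------------------
# panel


@dataclass
class PanelGenotypes:
    """Planted simple SNPs with one homozygous genotype per accession."""

    accessions: list[str]
    sites: pd.DataFrame          # chrom, pos, ref, alleles (tuple of codes)
    genotypes: np.ndarray        # (n_sites, n_accessions) uint8 base codes

    def variants_for(self, accession_idx: int, chrom: str):
        """(positions, base codes) carried by one accession on one chromosome."""
        sel = (self.sites["chrom"] == chrom).to_numpy(dtype=bool)
        pos = self.sites.loc[sel, "pos"].to_numpy(dtype=np.int64)
        alleles = self.genotypes[sel, accession_idx]
        return pos, alleles


def generate_panel(
    reference: ReferenceSet, truth: TruthTable, config: SimulationConfig
) -> PanelGenotypes:
    """Plant simple SNPs in non-repeat sequence; all accessions homozygous.

    Each site's minor allele is carried by ``k`` accessions drawn from the
    configured minor-count spectrum; ``k = 1`` singletons are legitimate
    variants that the downstream MAF step is expected to reject.  A
    configurable fraction of sites receives a third allele.
    """
    rng = stage_rng(config, "panel")
    n = config.n_accessions
    kmax = n // 2
    spectrum = np.asarray(config.minor_count_spectrum)

    rows = []
    gts = []
    for chrom in reference.names:
        seq = reference.seqs[chrom]
        usable = ~truth.repeat_mask_for(chrom, seq.size)
        # keep planted sites coverable: stay off the extreme chromosome ends
        usable[: config.read_length] = False
        usable[seq.size - config.read_length:] = False
        hit = np.nonzero((rng.random(seq.size) < config.snp_rate) & usable)[0]
        for pos in hit:
            ref_code = int(seq[pos])
            shift = int(rng.integers(1, 4))
            alt_code = (ref_code + shift) % 4
            k = 1 + int(rng.choice(kmax, p=spectrum))
            carriers = rng.choice(n, size=k, replace=False)
            gt = np.full(n, ref_code, dtype=np.uint8)
            gt[carriers] = alt_code
            alleles = [ref_code, alt_code]
            if rng.random() < config.triallelic_fraction:
                third = (ref_code + ((shift + int(rng.integers(1, 3)) - 1) % 3) + 1) % 4
                rest = np.setdiff1d(np.arange(n), carriers)
                k2 = 1 + int(rng.choice(kmax, p=spectrum))
                k2 = min(k2, rest.size - 1)
                if k2 >= 1:
                    carriers2 = rng.choice(rest, size=k2, replace=False)
                    gt[carriers2] = third
                    alleles.append(third)
            counts = np.array([(gt == a).sum() for a in alleles])
            detectable = bool((counts >= 2).all() and len(alleles) >= 2)
            rows.append(
                (chrom, int(pos), _seq.BASES[ref_code],
                 tuple(_seq.BASES[a] for a in alleles), int(counts.min()),
                 detectable)
            )
            gts.append(gt)

    sites = pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alleles", "minor_count", "detectable"]
    )
    genotypes = (
        np.asarray(gts, dtype=np.uint8) if gts else np.zeros((0, n), dtype=np.uint8)
    )
    panel = PanelGenotypes(config.accession_names, sites, genotypes)

    snp_truth = sites.copy()
    snp_truth["genotypes"] = [
        "".join(_seq.BASES[b] for b in gt) for gt in genotypes
    ]
    truth.simple_snps = snp_truth[
        ["chrom", "pos", "ref", "alleles", "genotypes", "minor_count", "detectable"]
    ]
    return panel


# --------------------------------------------------------------------------
# reads


@dataclass
class ReadSet:
    """Uniformly sampled error-bearing reads for one accession."""

    accession: str
    read_length: int
    chrom_names: list[str]
    seq: np.ndarray      # (n_reads, read_length) uint8, as-sequenced orientation
    chrom: np.ndarray    # (n_reads,) index into chrom_names
    start: np.ndarray    # (n_reads,) 0-based origin on the forward strand
    strand: np.ndarray   # (n_reads,) 0 = forward, 1 = reverse

    @property
    def n_reads(self) -> int:
        return self.seq.shape[0]

    def read_name(self, i: int) -> str:
        st = "-" if self.strand[i] else "+"
        return (
            f"{self.accession}:{self.chrom_names[self.chrom[i]]}:"
            f"{self.start[i]}:{st}:{i}"
        )


def simulate_reads(
    reference: ReferenceSet, panel: PanelGenotypes, config: SimulationConfig
) -> list[ReadSet]:
    """Draw reads from each accession's personalised genome.

    Reads are sampled uniformly (fully inside each chromosome), placed on
    either strand with equal probability, and each base is flipped to a
    random different base with the configured error rate.
    """
    rng = stage_rng(config, "reads")
    rl = config.read_length
    out = []
    for ai, acc in enumerate(config.accession_names):
        depth = config.per_accession_depth[ai]
        seq_chunks, chrom_idx, starts, strands = [], [], [], []
        for ci, chrom in enumerate(reference.names):
            ref = reference.seqs[chrom]
            pos, alleles = panel.variants_for(ai, chrom)
            personal = ref.copy()
            personal[pos] = alleles
            n_reads = int(round(depth * ref.size / rl))
            if n_reads == 0:
                continue
            st = rng.integers(0, ref.size - rl + 1, size=n_reads)
            reads = personal[st[:, None] + np.arange(rl)]
            rev = rng.integers(0, 2, size=n_reads).astype(np.uint8)
            reads[rev == 1] = _seq.revcomp(reads[rev == 1])
            err = rng.random(reads.shape) < config.base_error_rate
            if err.any():
                shift = rng.integers(1, 4, size=int(err.sum()), dtype=np.uint8)
                reads[err] = (reads[err] + shift) % 4
            seq_chunks.append(reads)
            chrom_idx.append(np.full(n_reads, ci, dtype=np.int32))
            starts.append(st.astype(np.int64))
            strands.append(rev)
        out.append(
            ReadSet(
                accession=acc,
                read_length=rl,
                chrom_names=list(reference.names),
                seq=np.concatenate(seq_chunks) if seq_chunks else
                    np.zeros((0, rl), dtype=np.uint8),
                chrom=np.concatenate(chrom_idx) if chrom_idx else
                    np.zeros(0, dtype=np.int32),
                start=np.concatenate(starts) if starts else np.zeros(0, dtype=np.int64),
                strand=np.concatenate(strands) if strands else
                    np.zeros(0, dtype=np.uint8),
            )
        )
    return out


# --------------------------------------------------------------------------
# GoldenGate two-channel intensities


def _channel_signal(dose_a: float, gg: GoldenGateConfig) -> tuple[float, float]:
    """Noise-free (Cy3, Cy5) for one locus given the allele-A dose in [0, 1]."""
    cy3 = gg.mu_off + (gg.mu_on - gg.mu_off) * dose_a
    cy5 = gg.mu_off + (gg.mu_on - gg.mu_off) * (1.0 - dose_a)
    return cy3, cy5


_DOSE = {"AA": 1.0, "AB": 0.5, "BB": 0.0}


@dataclass
class GoldenGateData:
    """Simulated intensity table plus the per-assay planted truth."""

    intensities: pd.DataFrame   # sample, population, assay, Cy3, Cy5, ...
    assays: pd.DataFrame        # assay, hemi, dh_polymorphic, f2_polymorphic
    designability: pd.DataFrame  # assay candidates with rank scores


def simulate_goldengate(
    truth: TruthTable | None, config: SimulationConfig
) -> GoldenGateData:
    """Simulate DH and F2 population intensities for a multiplexed assay pool.

    Simple assays read out a single locus: allele A drives Cy3, allele B
    drives Cy5, heterozygotes split the signal.  Hemi assays additionally
    amplify a second, population-fixed locus (homozygous A in the DH
    background, homozygous B in the F2 background), so pooling the two
    populations yields four or more theta groups — the hemi-SNP signature.
    Genotypes are independent Mendelian draws per assay: DH lines are
    AA/BB 1:1, F2 individuals AA/AB/BB 1:2:1.  One DH sample is emitted in
    replicate for the reproducibility check.
    """
    rng = stage_rng(config, "goldengate")
    gg = config.goldengate
    n_assays = gg.n_assays
    n_hemi = int(round(gg.hemi_fraction * n_assays))

    # parent genotypes per assay, preferring planted panel SNPs
    p_dh = np.zeros((n_assays, 2), dtype="U2")
    p_f2 = np.zeros((n_assays, 2), dtype="U2")
    assay_ids = [f"snp{i:03d}" for i in range(n_assays)]
    planted = None
    if truth is not None and len(truth.simple_snps):
        ok = truth.simple_snps[
            truth.simple_snps["detectable"]
            & (truth.simple_snps["alleles"].map(len) == 2)
        ]
        planted = ok.reset_index(drop=True)
    for i in range(n_assays):
        if planted is not None and i < len(planted):
            gtv = planted.loc[i, "genotypes"]  # one base letter per accession
            alleles = planted.loc[i, "alleles"]
            code = {alleles[0]: "AA", alleles[1]: "BB"}
            d1, d2 = gg.dh_parents
            f1, f2_ = gg.f2_parents
            p_dh[i] = (code.get(gtv[d1], "AA"), code.get(gtv[d2], "AA"))
            p_f2[i] = (code.get(gtv[f1], "AA"), code.get(gtv[f2_], "AA"))
        else:
            # virtual assay from the wider discovery set
            p_dh[i] = ("AA", "BB") if rng.random() < 0.5 else ("AA", "AA")
            p_f2[i] = ("AA", "BB") if rng.random() < 0.5 else ("BB", "BB")

    # hemi assays are planted polymorphic in both populations so the pooled
    # four-cluster signature is realisable
    hemi_idx = rng.choice(n_assays, size=n_hemi, replace=False) if n_hemi else []
    hemi_flags = np.zeros(n_assays, dtype=bool)
    for i in hemi_idx:
        hemi_flags[i] = True
        p_dh[i] = ("AA", "BB")
        p_f2[i] = ("AA", "BB")

    samples: list[tuple[str, str, bool, str]] = []  # id, population, parent, rep_of
    for p in range(2):
        samples.append((f"DH_P{p + 1}", "DH", True, ""))
    for s in range(gg.n_dh):
        samples.append((f"DH{s:03d}", "DH", False, ""))
    for r in range(1, gg.n_replicates):
        samples.append((f"DH000_rep{r}", "DH", False, "DH000"))
    for p in range(2):
        samples.append((f"F2_P{p + 1}", "F2", True, ""))
    for s in range(gg.n_f2):
        samples.append((f"F2{s:03d}", "F2", False, ""))

    # genotype draws; replicates copy their source sample's genotype
    geno: dict[tuple[str, str], str] = {}
    for i, aid in enumerate(assay_ids):
        for sid, pop, is_parent, rep_of in samples:
            if rep_of:
                geno[(sid, aid)] = geno[(rep_of, aid)]
                continue
            par = p_dh[i] if pop == "DH" else p_f2[i]
            if is_parent:
                g = par[0] if sid.endswith("P1") else par[1]
            elif par[0] == par[1]:
                g = par[0]
            elif pop == "DH":
                g = "AA" if rng.random() < 0.5 else "BB"
            else:
                u = rng.random()
                g = "AA" if u < 0.25 else ("AB" if u < 0.75 else "BB")
            geno[(sid, aid)] = g

    rows = []
    for i, aid in enumerate(assay_ids):
        for sid, pop, is_parent, rep_of in samples:
            g = geno[(sid, aid)]
            cy3, cy5 = _channel_signal(_DOSE[g], gg)
            if hemi_flags[i]:
                second = "AA" if pop == "DH" else "BB"
                c3b, c5b = _channel_signal(_DOSE[second], gg)
                cy3, cy5 = cy3 + c3b, cy5 + c5b
            cy3 = max(0.0, cy3 + rng.normal(0.0, gg.sd))
            cy5 = max(0.0, cy5 + rng.normal(0.0, gg.sd))
            rows.append((sid, pop, aid, cy3, cy5, is_parent, rep_of, g))

    intensities = pd.DataFrame(
        rows,
        columns=["sample", "population", "assay", "Cy3", "Cy5", "is_parent",
                 "replicate_of", "true_genotype"],
    )
    assays = pd.DataFrame(
        {
            "assay": assay_ids,
            "hemi": hemi_flags,
            "dh_polymorphic": [a != b for a, b in p_dh],
            "f2_polymorphic": [a != b for a, b in p_f2],
        }
    )
    if truth is not None:
        truth.hemi_assays = [assay_ids[i] for i in np.sort(hemi_idx)]

    # designability rank scores for a slightly larger candidate pool,
    # matching the observed 0.56-0.99 range
    n_cand = max(n_assays, int(round(n_assays * 110 / 96)))
    scores = 0.56 + 0.43 * rng.beta(5.0, 1.5, size=n_cand)
    designability = pd.DataFrame(
        {"assay": [f"cand{i:03d}" for i in range(n_cand)],
         "rank_score": np.round(scores, 2)}
    )
    return GoldenGateData(intensities, assays, designability)
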