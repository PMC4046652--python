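"""Per-accession pileups and the four-step simple-SNP filter cascade.

The cascade implements the discovery scheme for inbred allopolyploid
panels, applied in order:

(i)   only *uniquely aligned* reads contribute to pileups, to avoid
      paralogue/homoeolog interference;
(ii)  an accession's genotype at a site is only called from >= ``min_depth``
      reads (default 4); shallower lines are *missing*, never miscalled;
(iii) any line heterozygous at the site rejects the whole site — in a
      fully inbred panel heterozygosity can only come from homoeologous
      co-alignment (or coincident errors), never from allelic variation;
(iv)  the least common allele must be carried by >= ``min_minor_accessions``
      called lines (default 2), which discards singletons and most
      error-driven calls.

Surviving sites with exactly two or three alleles are accepted simple
SNPs.  Heterozygosity within a line is declared when the second most
common base has at least ``het_minor_reads`` reads *and* at least
``het_minor_fraction`` of the line's depth — thresholds chosen so that a
single sequencing error can never trigger heterozygosity at callable
depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _seq
from .align import CAT_UNIQUE, BatchAlignments
from .simulate import ReadSet


@dataclass
class FilterThresholds:
    min_depth: int = 4
    min_minor_accessions: int = 2
    het_minor_reads: int = 2
    het_minor_fraction: float = 0.1

    def __post_init__(self):
        if min(self.min_depth, self.min_minor_accessions,
               self.het_minor_reads) <= 0 or self.het_minor_fraction <= 0:
            raise ValueError("all filter thresholds must be positive")


@dataclass
class PileupColumn:
    chrom: str
    pos: int                    # 0-based
    ref: str
    counts: np.ndarray          # (n_accessions, 4) base counts A/C/G/T


@dataclass
class GenotypeCall:
    accession: str
    status: str                 # 'called' | 'heterozygous' | 'missing_low_depth'
    allele: str | None
    depth: int


@dataclass
class SnpSite:
    chrom: str
    pos: int                    # 0-based
    ref: str
    alleles: list[str]          # distinct called alleles, most common first
    allele_counts: list[int]    # accessions carrying each allele
    calls: list[GenotypeCall]
    allelism: str | None        # 'biallelic' | 'triallelic' | None
    status: str                 # 'accepted' | 'rejected'
    rejection_reason: str | None  # low_depth | heterozygous_line | maf |
                                  # monomorphic | excess_alleles

REASONS = ("heterozygous_line", "low_depth", "monomorphic", "excess_alleles", "maf")


@dataclass
class FilterReport:
    """Candidate-site bookkeeping: rejections per step plus accepted split."""

    candidates: int = 0
    rejected: dict = field(default_factory=lambda: {r: 0 for r in REASONS})
    accepted_biallelic: int = 0
    accepted_triallelic: int = 0

    @property
    def accepted(self) -> int:
        return self.accepted_biallelic + self.accepted_triallelic

    def conserved(self) -> bool:
        return self.candidates == self.accepted + sum(self.rejected.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [("candidate_sites", self.candidates)]
        rows += [(f"rejected_{r}", self.rejected[r]) for r in REASONS]
        rows += [
            ("accepted_biallelic", self.accepted_biallelic),
            ("accepted_triallelic", self.accepted_triallelic),
        ]
        return pd.DataFrame(rows, columns=["step", "sites"])


# --------------------------------------------------------------------------
# pileup


class PileupMatrix:
    """Dense per-accession base counts over the whole reference.

    Backed by one ``(n_accessions, 4, length)`` array per chromosome; the
    memory cost is what buys exact, vectorised candidate detection at desk
    scale.
    """

    def __init__(self, chrom_names: list[str], lengths: dict[str, int],
                 accessions: list[str]):
        self.chrom_names = list(chrom_names)
        self.accessions = list(accessions)
        self.counts = {
            c: np.zeros((len(accessions), 4, lengths[c]), dtype=np.uint16)
            for c in chrom_names
        }

    def add_reads(self, acc_idx: int, readset: ReadSet,
                  alignments: BatchAlignments) -> None:
        """Accumulate the uniquely aligned reads of one accession."""
        L = readset.read_length
        sel = alignments.category == CAT_UNIQUE
        if not sel.any():
            return
        seq = readset.seq[sel]
        rev = alignments.strand[sel] == 1
        # orient into reference coordinates
        seq = seq.copy()
        seq[rev] = _seq.revcomp(seq[rev])
        chrom = alignments.chrom[sel]
        pos = alignments.pos[sel]
        for ci, cname in enumerate(self.chrom_names):
            m = chrom == ci
            if not m.any():
                continue
            size = self.counts[cname].shape[2]
            cols = (pos[m][:, None] + np.arange(L)).ravel()
            bases = seq[m].ravel()
            # clip contributions overhanging the contig and drop N
            keep = (cols >= 0) & (cols < size) & (bases < 4)
            cols, bases = cols[keep], bases[keep]
            for b in range(4):
                bc = np.bincount(cols[bases == b], minlength=size)
                self.counts[cname][acc_idx, b, :] += bc.astype(np.uint16)

    def column(self, chrom: str, pos: int, ref_base: str) -> PileupColumn:
        return PileupColumn(chrom, pos, ref_base,
                            self.counts[chrom][:, :, pos].copy())

    def candidate_positions(self, chrom: str) -> np.ndarray:
        """Positions where >= 2 distinct bases are observed across the panel."""
        pooled = self.counts[chrom].sum(axis=0)  # (4, length)
        return np.nonzero((pooled > 0).sum(axis=0) >= 2)[0]


def pileup(
    readsets: list[ReadSet],
    alignments: list[BatchAlignments],
    reference,
    accessions: list[str] | None = None,
) -> PileupMatrix:
    """Build per-accession pileups from unique alignments only."""
    names = list(reference.names)
    lengths = {c: reference.seqs[c].size for c in names}
    accs = accessions or [rs.accession for rs in readsets]
    mat = PileupMatrix(names, lengths, accs)
    for i, (rs, al) in enumerate(zip(readsets, alignments)):
        mat.add_reads(i, rs, al)
    return mat


def iter_columns(mat: PileupMatrix, reference) -> "list[PileupColumn]":
    """Candidate pileup columns (>= 2 observed bases), in coordinate order."""
    cols = []
    for chrom in mat.chrom_names:
        seq = reference.seqs[chrom]
        for p in mat.candidate_positions(chrom):
            cols.append(mat.column(chrom, int(p), _seq.BASES[seq[p]]))
    return cols


# --------------------------------------------------------------------------
# genotype calling and site filtering (scalar contract)


def call_genotype(
    column: PileupColumn, accession_idx: int,
    thresholds: FilterThresholds | None = None,
) -> GenotypeCall:
    th = thresholds or FilterThresholds()
    counts = column.counts[accession_idx].astype(np.int64)  # signed: argsort(-x)
    depth = int(counts.sum())
    acc = f"acc{accession_idx:02d}"
    if depth < th.min_depth:
        return GenotypeCall(acc, "missing_low_depth", None, depth)
    order = np.argsort(-counts, kind="stable")  # ties -> lower base index
    top, second = int(counts[order[0]]), int(counts[order[1]])
    if second >= th.het_minor_reads and second >= th.het_minor_fraction * depth:
        return GenotypeCall(acc, "heterozygous", None, depth)
    return GenotypeCall(acc, "called", _seq.BASES[order[0]], depth)


def filter_site(
    column: PileupColumn, thresholds: FilterThresholds | None = None
) -> SnpSite:
    """Apply the homozygosity/depth/MAF rules to one candidate column."""
    th = thresholds or FilterThresholds()
    n_acc = column.counts.shape[0]
    calls = [call_genotype(column, i, th) for i in range(n_acc)]

    def rejected(reason, alleles=None, counts=None):
        return SnpSite(column.chrom, column.pos, column.ref, alleles or [],
                       counts or [], calls, None, "rejected", reason)

    if any(c.status == "heterozygous" for c in calls):
        return rejected("heterozygous_line")
    called = [c.allele for c in calls if c.status == "called"]
    if not called:
        return rejected("low_depth")
    alleles, counts = np.unique(called, return_counts=True)
    order = np.argsort(-counts, kind="stable")
    alleles, counts = list(alleles[order]), [int(x) for x in counts[order]]
    if len(alleles) < 2:
        return rejected("monomorphic", alleles, counts)
    if len(alleles) > 3:
        return rejected("excess_alleles", alleles, counts)
    if min(counts) < th.min_minor_accessions:
        return rejected("maf", alleles, counts)
    allelism = "biallelic" if len(alleles) == 2 else "triallelic"
    return SnpSite(column.chrom, column.pos, column.ref, alleles, counts,
                   calls, allelism, "accepted", None)


def run_cascade(
    columns, thresholds: FilterThresholds | None = None
) -> tuple[list[SnpSite], FilterReport]:
    """Filter candidate columns in cascade order; report per-step removals."""
    th = thresholds or FilterThresholds()
    report = FilterReport()
    accepted = []
    for col in columns:
        site = filter_site(col, th)
        report.candidates += 1
        if site.status == "accepted":
            if site.allelism == "biallelic":
                report.accepted_biallelic += 1
            else:
                report.accepted_triallelic += 1
            accepted.append(site)
        else:
            report.rejected[site.rejection_reason] += 1
    return accepted, report


# --------------------------------------------------------------------------
# vectorised cascade used by the pipeline (same contract as filter_site)


def run_cascade_matrix(
    mat: PileupMatrix, reference, thresholds: FilterThresholds | None = None,
) -> tuple[list[SnpSite], FilterReport]:
    th = thresholds or FilterThresholds()
    report = FilterReport()
    accepted: list[SnpSite] = []
    n_acc = len(mat.accessions)
    for chrom in mat.chrom_names:
        cand = mat.candidate_positions(chrom)
        if cand.size == 0:
            continue
        counts = mat.counts[chrom][:, :, cand].astype(np.int64)  # (n_acc, 4, m)
        depth = counts.sum(axis=1)                               # (n_acc, m)
        srt = np.sort(counts, axis=1)
        top, second = srt[:, 3, :], srt[:, 2, :]
        missing = depth < th.min_depth
        het = (~missing & (second >= th.het_minor_reads)
               & (second >= th.het_minor_fraction * depth))
        calledb = counts.argmax(axis=1)                          # (n_acc, m)
        ok = ~missing & ~het
        carriers = np.zeros((4, cand.size), dtype=np.int64)
        for b in range(4):
            carriers[b] = (ok & (calledb == b)).sum(axis=0)
        n_called = ok.sum(axis=0)
        distinct = (carriers > 0).sum(axis=0)
        minor = np.where(carriers > 0, carriers, np.iinfo(np.int64).max).min(axis=0)

        any_het = het.any(axis=0)
        reason = np.full(cand.size, "", dtype=object)
        reason[any_het] = "heterozygous_line"
        free = ~any_het
        reason[free & (n_called == 0)] = "low_depth"
        free &= n_called > 0
        reason[free & (distinct < 2)] = "monomorphic"
        free &= distinct >= 2
        reason[free & (distinct > 3)] = "excess_alleles"
        free &= distinct <= 3
        reason[free & (minor < th.min_minor_accessions)] = "maf"
        acc_mask = free & (minor >= th.min_minor_accessions)

        report.candidates += int(cand.size)
        for r in REASONS:
            report.rejected[r] += int((reason == r).sum())
        seq = reference.seqs[chrom]
        for j in np.nonzero(acc_mask)[0]:
            p = int(cand[j])
            site = filter_site(mat.column(chrom, p, _seq.BASES[seq[p]]), th)
            if site.status != "accepted":  # scalar contract is authoritative
                report.rejected[site.rejection_reason] += 1
                continue
            accepted.append(site)
            if site.allelism == "biallelic":
                report.accepted_biallelic += 1
            else:
                report.accepted_triallelic += 1
    return accepted, report


# --------------------------------------------------------------------------
# validation arithmetic


def validation_fpr(n_validated: int, n_matching: int) -> float:
    """False-positive rate implied by a sequencing-validation experiment."""
    if n_validated <= 0:
        raise ValueError("n_validated must be positive")
    if not 0 <= n_matching <= n_validated:
        raise ValueError("n_matching must lie in [0, n_validated]")
    return 1.0 - n_matching / n_validated
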