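"""Repeat identification and masking.

Repetitive sequence must be removed before alignment: in an allopolyploid,
reads from high-copy DNA cannot be assigned to a single locus and would
contaminate the pileups.  Two detectors are provided — a k-mer multiplicity
mask (any position covered only by k-mers occurring more than ``max_copies``
times genome-wide, strand-collapsed, is repetitive) and a library mask
(ungapped local matches to known repeat units).  The default
``max_copies=2`` deliberately tolerates the two legitimate homoeologous
copies of every locus; more than two implies a repeat.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import _seq
from .simulate import ReferenceSet

DEFAULT_K = 31
DEFAULT_MAX_COPIES = 2

Intervals = dict[str, list[tuple[int, int]]]


@dataclass
class MaskedReference:
    """A reference plus merged mask intervals (0-based half-open)."""

    reference: ReferenceSet
    intervals: Intervals = field(default_factory=dict)
    style: str = "lowercase"

    @property
    def names(self):
        return self.reference.names

    @property
    def seqs(self):
        return self.reference.seqs

    def mask_array(self, chrom: str) -> np.ndarray:
        out = np.zeros(self.reference.seqs[chrom].size, dtype=bool)
        for s, e in self.intervals.get(chrom, []):
            out[s:e] = True
        return out

    def masked_fraction(self) -> float:
        total = self.reference.total_length()
        masked = sum(e - s for ivs in self.intervals.values() for s, e in ivs)
        return masked / total if total else 0.0

    def visible_seq(self, chrom: str) -> np.ndarray:
        """Sequence with hard-masked positions replaced by N codes."""
        seq = self.reference.seqs[chrom]
        if self.style != "hard":
            return seq
        out = seq.copy()
        out[self.mask_array(chrom)] = _seq.N
        return out


def merge_intervals(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not ivs:
        return []
    ivs = sorted(ivs)
    out = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


# --------------------------------------------------------------------------
# k-mer hashing shared with the aligner


def kmer_hashes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """(start positions, 2-bit packed k-mer values) for windows without N.

    k <= 32 so a k-mer packs exactly into a uint64.
    """
    n = codes.size
    if n < k:
        return np.zeros(0, dtype=np.int64), np.zeros(0, dtype=np.uint64)
    win = np.lib.stride_tricks.sliding_window_view(codes, k)
    valid = (win < 4).all(axis=1)
    # split into <=16-base halves so int64 dot products cannot overflow
    h = np.zeros(win.shape[0], dtype=np.uint64)
    for off in range(0, k, 16):
        part = win[:, off:off + 16].astype(np.int64)
        width = part.shape[1]
        powers = 4 ** np.arange(width - 1, -1, -1, dtype=np.int64)
        h = (h << np.uint64(2 * width)) | (part @ powers).astype(np.uint64)
    pos = np.nonzero(valid)[0].astype(np.int64)
    return pos, h[valid]


def _revcomp_hash(h: np.ndarray, k: int) -> np.ndarray:
    """Hash of the reverse complement, computed arithmetically."""
    comp = ~h  # 2-bit complement: A<->T, C<->G
    out = np.zeros_like(h)
    for _ in range(k):
        out = (out << np.uint64(2)) | (comp & np.uint64(3))
        comp >>= np.uint64(2)
    return out


def canonical_hashes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    pos, fwd = kmer_hashes(codes, k)
    rev = _revcomp_hash(fwd, k)
    return pos, np.minimum(fwd, rev)


# --------------------------------------------------------------------------
# operations


def kmer_mask(
    reference: ReferenceSet, k: int = DEFAULT_K, max_copies: int = DEFAULT_MAX_COPIES
) -> Intervals:
    """Mask positions covered only by k-mers occurring > max_copies genome-wide."""
    if k < 11:
        raise ValueError("k must be >= 11")
    if k > 32:
        raise ValueError("k must be <= 32 (packed k-mer)")
    shortest = min(s.size for s in reference.seqs.values())
    if k > shortest:
        raise ValueError("k exceeds the shortest chromosome")

    per_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    all_hashes = []
    for chrom in reference.names:
        pos, h = canonical_hashes(reference.seqs[chrom], k)
        per_chrom[chrom] = (pos, h)
        all_hashes.append(h)
    pool = np.concatenate(all_hashes) if all_hashes else np.zeros(0, dtype=np.uint64)
    uniq, counts = np.unique(pool, return_counts=True)
    frequent = uniq[counts > max_copies]

    intervals: Intervals = {}
    for chrom in reference.names:
        pos, h = per_chrom[chrom]
        size = reference.seqs[chrom].size
        hot = np.isin(h, frequent)
        # a position is masked iff every k-mer window covering it is frequent
        cover = np.zeros(size + 1, dtype=np.int32)
        total = np.zeros(size + 1, dtype=np.int32)
        hp = pos[hot]
        np.add.at(cover, hp, 1)
        np.add.at(cover, np.minimum(hp + k, size), -1)
        np.add.at(total, pos, 1)
        np.add.at(total, np.minimum(pos + k, size), -1)
        cov = np.cumsum(cover[:-1])
        tot = np.cumsum(total[:-1])
        masked = (tot > 0) & (cov == tot)
        intervals[chrom] = _bool_to_intervals(masked)
    return intervals


def _bool_to_intervals(mask: np.ndarray) -> list[tuple[int, int]]:
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.nonzero(d == 1)[0] + 1)
    ends = list(np.nonzero(d == -1)[0] + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(mask.size)
    return [(int(s), int(e)) for s, e in zip(starts, ends)]


def library_mask(
    reference: ReferenceSet,
    library: dict[str, np.ndarray],
    min_identity: float = 0.9,
    min_length: int = 50,
    seed: int = 12,
) -> Intervals:
    """Mask ungapped local matches of library units on either strand.

    Candidate placements are found by exact ``seed``-mer seeding of each
    unit against the genome, extended ungapped over the full unit overlap;
    matches with identity >= min_identity over >= min_length bases mask
    the genomic interval.
    """
    if not library:
        warnings.warn("empty repeat library: nothing masked", stacklevel=2)
        return {c: [] for c in reference.names}

    intervals: Intervals = {c: [] for c in reference.names}
    for chrom in reference.names:
        gseq = reference.seqs[chrom]
        gpos, gh = kmer_hashes(gseq, seed)
        order = np.argsort(gh, kind="stable")
        gh_sorted, gpos_sorted = gh[order], gpos[order]
        for _name, unit in library.items():
            for strand_unit in (unit, _seq.revcomp(unit)):
                upos, uh = kmer_hashes(strand_unit, seed)
                if upos.size == 0:
                    continue
                lo = np.searchsorted(gh_sorted, uh, side="left")
                hi = np.searchsorted(gh_sorted, uh, side="right")
                diags = set()
                for j in range(upos.size):
                    for idx in range(lo[j], hi[j]):
                        diags.add(int(gpos_sorted[idx]) - int(upos[j]))
                for d in sorted(diags):
                    gs, ge = max(0, d), min(gseq.size, d + strand_unit.size)
                    if ge - gs < min_length:
                        continue
                    us, ue = gs - d, ge - d
                    ident = float(
                        (gseq[gs:ge] == strand_unit[us:ue]).mean()
                    )
                    if ident >= min_identity:
                        intervals[chrom].append((gs, ge))
    return {c: merge_intervals(ivs) for c, ivs in intervals.items()}


def apply_mask(
    reference: ReferenceSet, intervals: Intervals, style: str = "lowercase"
) -> MaskedReference:
    """Attach merged mask intervals to a reference.

    ``lowercase`` masking preserves the underlying bases (round-trips
    through softmasked FASTA); ``hard`` masking replaces them with N when
    the sequence is viewed through :meth:`MaskedReference.visible_seq`.
    """
    if style not in ("lowercase", "hard"):
        raise ValueError(f"unknown mask style {style!r}")
    merged = {
        c: merge_intervals([
            (max(0, s), min(reference.seqs[c].size, e))
            for s, e in intervals.get(c, [])
        ])
        for c in reference.names
    }
    return MaskedReference(reference, merged, style)


def union_mask(*interval_sets: Intervals) -> Intervals:
    chroms = {c for ivs in interval_sets for c in ivs}
    return {
        c: merge_intervals([iv for ivs in interval_sets for iv in ivs.get(c, [])])
        for c in chroms
    }


def write_bed(intervals: Intervals, path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(intervals):
            for s, e in intervals[chrom]:
                fh.write(f"{chrom}\t{s}\t{e}\n")


def read_bed(path) -> Intervals:
    out: Intervals = {}
    with open(path) as fh:
        for line in fh:
            if line.strip():
                chrom, s, e = line.split()[:3]
                out.setdefault(chrom, []).append((int(s), int(e)))
    return {c: merge_intervals(ivs) for c, ivs in out.items()}
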