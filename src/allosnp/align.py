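"""Seed-and-extend read mapping with unique/repeat/unaligned classification.

The mapping contract mirrors substitution-only short-read alignment as used
for allopolyploid SNP discovery: candidate loci are found through exact
seed hits (default seed 32 bp), each candidate is extended ungapped across
the full read, and placements with at most ``max_mismatches`` (default 5)
over at least ``min_align_length`` aligned bases (default 40; binding only
when a read overhangs a contig end) are retained.  A read with exactly one
best-scoring placement is *unique*; two or more placements tied at the
best score make it *repeat* (never an arbitrary choice); no placement
means *unaligned*.  Only unique reads feed the SNP pileups — in an
allotetraploid this is what keeps homoeologous and paralogous copies from
contaminating each other, because a read whose two homoeologous placements
differ in score is still assigned to the strictly better one, while a read
that cannot tell the copies apart is discarded.

Reads whose best placement lies more than half inside masked sequence are
classified as repeat as well: masking exists to restrict analysis to
low-copy DNA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _seq
from .mask import MaskedReference, kmer_hashes
from .simulate import ReferenceSet

_SPACER = 256  # N gap between concatenated chromosomes; >= read length

CAT_UNIQUE, CAT_REPEAT, CAT_UNALIGNED = 0, 1, 2
CATEGORY_NAMES = ("unique", "repeat", "unaligned")


@dataclass
class AlignmentParams:
    max_mismatches: int = 5
    seed_length: int = 32
    min_align_length: int = 40
    max_masked_fraction: float = 0.5  # best placement more masked -> repeat


@dataclass
class ReadAlignment:
    """Classification of a single read."""

    read_id: str | int
    category: str  # 'unique' | 'repeat' | 'unaligned'
    chrom: str | None = None
    pos: int | None = None  # 0-based leftmost reference position
    strand: str | None = None  # '+' | '-'
    mismatches: int | None = None
    reason: str | None = None


class SeedIndex:
    """Exact seed-length-mer index over a (masked) reference.

    Chromosomes are concatenated with N spacers; seeds containing N and
    seeds lying entirely in masked sequence are not indexed.
    """

    def __init__(self, reference: MaskedReference | ReferenceSet,
                 seed_length: int = 32):
        if isinstance(reference, ReferenceSet):
            reference = MaskedReference(reference, {c: [] for c in reference.names})
        self.masked = reference
        self.seed_length = seed_length
        names = reference.names
        self.names = list(names)

        chunks, mask_chunks, offsets = [], [], []
        pos = 0
        for chrom in names:
            seq = reference.seqs[chrom]
            offsets.append(pos)
            chunks.append(seq)
            mask_chunks.append(reference.mask_array(chrom))
            pos += seq.size
            chunks.append(np.full(_SPACER, _seq.N, dtype=np.uint8))
            mask_chunks.append(np.zeros(_SPACER, dtype=bool))
            pos += _SPACER
        self.concat = np.concatenate(chunks) if chunks else np.zeros(0, np.uint8)
        self.concat_mask = (
            np.concatenate(mask_chunks) if mask_chunks else np.zeros(0, bool)
        )
        self.offsets = np.asarray(offsets, dtype=np.int64)
        self.lengths = np.asarray(
            [reference.seqs[c].size for c in names], dtype=np.int64
        )

        gpos, gh = kmer_hashes(self.concat, seed_length)
        # drop seeds entirely inside masked sequence
        cm = np.concatenate(([0], np.cumsum(self.concat_mask.astype(np.int64))))
        fully_masked = (cm[gpos + seed_length] - cm[gpos]) == seed_length
        gpos, gh = gpos[~fully_masked], gh[~fully_masked]
        order = np.argsort(gh, kind="stable")
        self.hash_sorted = gh[order]
        self.pos_sorted = gpos[order]

    @property
    def total_concat(self) -> int:
        return self.concat.size

    def locate(self, concat_pos: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map concatenated coordinates to (chrom index, position)."""
        ci = np.searchsorted(self.offsets, concat_pos, side="right") - 1
        return ci, concat_pos - self.offsets[ci]

    def n_seed_loci(self, seq: str) -> int:
        """Occurrence count of one exact seed (testing/debug helper)."""
        h = kmer_hashes(_seq.encode(seq), self.seed_length)[1]
        if h.size == 0:
            return 0
        lo = np.searchsorted(self.hash_sorted, h[0], side="left")
        hi = np.searchsorted(self.hash_sorted, h[0], side="right")
        return int(hi - lo)


def build_index(reference, seed_length: int = 32) -> SeedIndex:
    return SeedIndex(reference, seed_length)


def _batch_hashes(reads: np.ndarray, k: int) -> np.ndarray:
    """2-bit packed k-mer values for every window of every read (n, W)."""
    win = np.lib.stride_tricks.sliding_window_view(reads, k, axis=1)
    h = np.zeros(win.shape[:2], dtype=np.uint64)
    for off in range(0, k, 16):
        part = win[..., off:off + 16].astype(np.int64)
        width = part.shape[-1]
        powers = 4 ** np.arange(width - 1, -1, -1, dtype=np.int64)
        h = (h << np.uint64(2 * width)) | (part @ powers).astype(np.uint64)
    return h


@dataclass
class BatchAlignments:
    """Vectorised alignment results for one read set."""

    names: list[str]
    category: np.ndarray    # (n,) uint8: 0 unique, 1 repeat, 2 unaligned
    chrom: np.ndarray       # (n,) chrom index (unique reads only)
    pos: np.ndarray         # (n,) 0-based position within chromosome
    strand: np.ndarray      # (n,) 0 forward, 1 reverse
    mismatches: np.ndarray  # (n,)

    @property
    def n_reads(self) -> int:
        return self.category.size


def map_reads(
    reads: np.ndarray, index: SeedIndex, params: AlignmentParams | None = None,
    batch_size: int = 2000,
) -> BatchAlignments:
    """Classify a matrix of equal-length reads against the index."""
    params = params or AlignmentParams()
    n, L = reads.shape
    k = index.seed_length
    if L < k:
        return BatchAlignments(
            index.names,
            np.full(n, CAT_UNALIGNED, np.uint8),
            np.zeros(n, np.int32), np.zeros(n, np.int64),
            np.zeros(n, np.uint8), np.zeros(n, np.int32),
        )
    category = np.full(n, CAT_UNALIGNED, dtype=np.uint8)
    chrom = np.zeros(n, dtype=np.int32)
    pos = np.zeros(n, dtype=np.int64)
    strand = np.zeros(n, dtype=np.uint8)
    mism = np.zeros(n, dtype=np.int32)

    for b0 in range(0, n, batch_size):
        b1 = min(n, b0 + batch_size)
        _map_batch(reads[b0:b1], index, params, b0,
                   category, chrom, pos, strand, mism)
    return BatchAlignments(index.names, category, chrom, pos, strand, mism)


def _map_batch(reads, index, params, base, category, chrom, pos, strand, mism):
    nb, L = reads.shape
    k = index.seed_length
    Gc = index.total_concat
    rc = _seq.revcomp(reads)
    offs = np.arange(L - k + 1, dtype=np.int64)

    cand_read, cand_strand, cand_diag = [], [], []
    for st, oriented in ((0, reads), (1, rc)):
        qh = _batch_hashes(oriented, k)  # (nb, W)
        flat = qh.ravel()
        lo = np.searchsorted(index.hash_sorted, flat, side="left")
        hi = np.searchsorted(index.hash_sorted, flat, side="right")
        counts = hi - lo
        total = int(counts.sum())
        if total == 0:
            continue
        rep_lo = np.repeat(lo, counts)
        cc = counts[counts > 0]
        intra = np.arange(total) - np.repeat(np.cumsum(cc) - cc, cc)
        gidx = rep_lo + intra
        gpos = index.pos_sorted[gidx]
        W = qh.shape[1]
        ridx = np.repeat(np.arange(nb * W) // W, counts)
        woff = np.repeat(np.tile(offs, nb), counts)
        diag = gpos - woff
        cand_read.append(ridx)
        cand_strand.append(np.full(total, st, dtype=np.uint8))
        cand_diag.append(diag)
    if not cand_read:
        return
    ridx = np.concatenate(cand_read)
    cstr = np.concatenate(cand_strand)
    diag = np.concatenate(cand_diag)
    key = (ridx.astype(np.int64) * 2 + cstr) * np.int64(Gc + L) + (diag + L)
    uniq_key = np.unique(key)
    u_diag = uniq_key % np.int64(Gc + L) - L
    rest = uniq_key // np.int64(Gc + L)
    u_strand = (rest % 2).astype(np.uint8)
    u_read = (rest // 2).astype(np.int64)

    # ungapped extension over the full read, clipped at contig bounds
    m = u_read.size
    best_read, best_mm, best_diag, best_strand, best_alen, best_maskc = (
        [], [], [], [], [], []
    )
    chunk = 200_000
    concat = index.concat
    cmask = index.concat_mask
    for c0 in range(0, m, chunk):
        c1 = min(m, c0 + chunk)
        d = u_diag[c0:c1]
        cols = d[:, None] + np.arange(L)
        safe = np.clip(cols, 0, Gc - 1)
        g = concat[safe]
        outside = (g == _seq.N) | (cols < 0) | (cols >= Gc)
        rrows = np.where(
            (u_strand[c0:c1] == 0)[:, None], reads[u_read[c0:c1]], rc[u_read[c0:c1]]
        )
        mmv = ((g != rrows) & ~outside).sum(axis=1).astype(np.int32)
        alen = (L - outside.sum(axis=1)).astype(np.int32)
        maskc = (cmask[safe] & ~outside).sum(axis=1).astype(np.int32)
        ok = (mmv <= params.max_mismatches) & (
            alen >= min(params.min_align_length, L)
        )
        best_read.append(u_read[c0:c1][ok])
        best_mm.append(mmv[ok])
        best_diag.append(d[ok])
        best_strand.append(u_strand[c0:c1][ok])
        best_alen.append(alen[ok])
        best_maskc.append(maskc[ok])
    if not best_read:
        return
    v_read = np.concatenate(best_read)
    if v_read.size == 0:
        return
    v_mm = np.concatenate(best_mm)
    v_diag = np.concatenate(best_diag)
    v_strand = np.concatenate(best_strand)
    v_alen = np.concatenate(best_alen)
    v_maskc = np.concatenate(best_maskc)

    order = np.lexsort((v_diag, v_strand, v_mm, v_read))
    v_read, v_mm, v_diag, v_strand, v_alen, v_maskc = (
        a[order] for a in (v_read, v_mm, v_diag, v_strand, v_alen, v_maskc)
    )
    first = np.nonzero(np.diff(v_read, prepend=-1))[0]
    counts = np.diff(np.append(first, v_read.size))
    tied = np.zeros(first.size, dtype=bool)
    has_second = counts >= 2
    tied[has_second] = v_mm[first[has_second] + 1] == v_mm[first[has_second]]

    r = v_read[first]
    g_pos = v_diag[first]
    ci, cpos = index.locate(np.maximum(g_pos, 0))
    too_masked = v_maskc[first] > params.max_masked_fraction * v_alen[first]
    cat = np.where(tied | too_masked, CAT_REPEAT, CAT_UNIQUE).astype(np.uint8)
    category[base + r] = cat
    uniq = cat == CAT_UNIQUE
    chrom[base + r[uniq]] = ci[uniq]
    pos[base + r[uniq]] = cpos[uniq]
    strand[base + r[uniq]] = v_strand[first][uniq]
    mism[base + r[uniq]] = v_mm[first][uniq]


def map_read(
    read, index: SeedIndex, params: AlignmentParams | None = None,
    read_id: str | int = 0,
) -> ReadAlignment:
    """Classify a single read (string or code array)."""
    params = params or AlignmentParams()
    codes = _seq.encode(read) if isinstance(read, str) else np.asarray(read)
    if codes.size < index.seed_length:
        return ReadAlignment(read_id, "unaligned", reason="read shorter than seed")
    res = map_reads(codes[None, :], index, params)
    cat = CATEGORY_NAMES[res.category[0]]
    if cat != "unique":
        return ReadAlignment(read_id, cat)
    return ReadAlignment(
        read_id, "unique",
        chrom=index.names[res.chrom[0]],
        pos=int(res.pos[0]),
        strand="-" if res.strand[0] else "+",
        mismatches=int(res.mismatches[0]),
    )


def classify_counts(alignments: BatchAlignments | list[ReadAlignment]) -> dict:
    """Tally {unique, repeat, unaligned} and the unique fraction."""
    if isinstance(alignments, BatchAlignments):
        cats = alignments.category
        tally = {
            name: int((cats == code).sum())
            for code, name in enumerate(CATEGORY_NAMES)
        }
    else:
        tally = {name: 0 for name in CATEGORY_NAMES}
        for a in alignments:
            tally[a.category] += 1
    total = sum(tally.values())
    tally["total"] = total
    tally["unique_fraction"] = tally["unique"] / total if total else 0.0
    return tally
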