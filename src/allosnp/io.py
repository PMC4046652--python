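"""File-format boundaries: FASTA, FASTQ, SAM, VCF, TSV.

Internal coordinates are 0-based half-open; VCF and GFF3 are written
1-based per their standards.  FASTA goes through Biopython, SAM and VCF
through pysam; FASTQ records are written directly (constant quality, four
lines per read) and read back through ``pysam.FastxFile``.
"""

from __future__ import annotations

import numpy as np
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import _seq
from .align import CAT_UNIQUE, CAT_REPEAT, BatchAlignments
from .mask import MaskedReference
from .simulate import ReadSet, ReferenceSet

# --------------------------------------------------------------------------
# FASTA


def write_fasta(reference: ReferenceSet | MaskedReference, path) -> None:
    """Write a reference; masked references are written softmasked/hard."""
    records = []
    if isinstance(reference, MaskedReference):
        for chrom in reference.names:
            seq = _seq.decode(reference.reference.seqs[chrom])
            marr = reference.mask_array(chrom)
            if reference.style == "hard":
                chars = np.frombuffer(seq.encode(), dtype="S1").copy()
                chars[marr] = b"N"
                seq = b"".join(chars).decode()
            else:
                chars = np.array(list(seq))
                lower = np.char.lower(chars[marr])
                chars[marr] = lower
                seq = "".join(chars)
            records.append(SeqRecord(Seq(seq), id=chrom, description=""))
    else:
        for chrom in reference.names:
            records.append(
                SeqRecord(Seq(_seq.decode(reference.seqs[chrom])), id=chrom,
                          description="")
            )
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path, subgenome_of=None) -> ReferenceSet:
    """Read a FASTA into a ReferenceSet (lowercase recorded as unmasked base).

    Subgenome is inferred from the first character of each name unless a
    mapping is given; pairing follows name order (i-th A with i-th C).
    """
    names, seqs, sub = [], {}, {}
    for rec in SeqIO.parse(str(path), "fasta"):
        names.append(rec.id)
        seqs[rec.id] = _seq.encode(str(rec.seq))
        sub[rec.id] = (subgenome_of or {}).get(rec.id, rec.id[:1].upper())
    a = [n for n in names if sub[n] == "A"]
    c = [n for n in names if sub[n] == "C"]
    pairs = [
        (an, cn) for an, cn in zip(a, c)
        if seqs[an].size == seqs[cn].size
    ]
    return ReferenceSet(names, seqs, sub, pairs)


def read_fasta_mask(path) -> dict[str, list[tuple[int, int]]]:
    """Recover softmask intervals (lowercase runs) from a FASTA."""
    out = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        s = str(rec.seq)
        low = np.frombuffer(s.encode(), dtype=np.uint8)
        ivs, start = [], None
        lower = (low >= 97) & (low <= 122)
        for i, flag in enumerate(lower):
            if flag and start is None:
                start = i
            elif not flag and start is not None:
                ivs.append((start, i))
                start = None
        if start is not None:
            ivs.append((start, len(s)))
        out[rec.id] = ivs
    return out


# --------------------------------------------------------------------------
# FASTQ


def write_fastq(readset: ReadSet, path, quality_char: str = "I") -> None:
    qual = quality_char * readset.read_length
    with open(path, "w") as fh:
        for i in range(readset.n_reads):
            fh.write(
                f"@{readset.read_name(i)}\n"
                f"{_seq.decode(readset.seq[i])}\n+\n{qual}\n"
            )


def read_fastq(path, accession: str = "sample", chrom_names=None) -> ReadSet:
    seqs, chroms, starts, strands = [], [], [], []
    chrom_names = list(chrom_names or [])
    lookup = {c: i for i, c in enumerate(chrom_names)}
    with pysam.FastxFile(str(path)) as fh:
        for entry in fh:
            seqs.append(_seq.encode(entry.sequence))
            parts = entry.name.split(":")
            if len(parts) >= 5:  # provenance-encoded name
                _, chrom, start, strand = parts[:4]
                if chrom not in lookup:
                    lookup[chrom] = len(chrom_names)
                    chrom_names.append(chrom)
                chroms.append(lookup[chrom])
                starts.append(int(start))
                strands.append(1 if strand == "-" else 0)
            else:
                chroms.append(-1)
                starts.append(-1)
                strands.append(0)
    n = len(seqs)
    rl = seqs[0].size if n else 0
    return ReadSet(
        accession, rl, chrom_names,
        np.vstack(seqs) if n else np.zeros((0, 0), np.uint8),
        np.asarray(chroms, np.int32), np.asarray(starts, np.int64),
        np.asarray(strands, np.uint8),
    )


# --------------------------------------------------------------------------
# SAM


def write_sam(
    readset: ReadSet, alignments: BatchAlignments, reference, path
) -> None:
    """Minimal SAM: unique reads mapped with NM, others flagged unmapped
    with the category in the XC tag (U/R/N)."""
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [
            {"SN": c, "LN": int(reference.seqs[c].size)} for c in reference.names
        ],
    }
    tags = {CAT_UNIQUE: "U", CAT_REPEAT: "R"}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for i in range(readset.n_reads):
            a = pysam.AlignedSegment(out.header)
            a.query_name = readset.read_name(i)
            cat = alignments.category[i]
            if cat == CAT_UNIQUE:
                rev = bool(alignments.strand[i])
                seq = readset.seq[i]
                if rev:
                    seq = _seq.revcomp(seq)
                a.query_sequence = _seq.decode(seq)
                a.flag = 16 if rev else 0
                a.reference_id = int(alignments.chrom[i])
                a.reference_start = int(alignments.pos[i])
                a.mapping_quality = 60
                a.cigarstring = f"{readset.read_length}M"
                a.set_tag("NM", int(alignments.mismatches[i]))
            else:
                a.query_sequence = _seq.decode(readset.seq[i])
                a.flag = 4
                a.reference_id = -1
                a.reference_start = -1
                a.mapping_quality = 0
            a.query_qualities = pysam.qualitystring_to_array(
                "I" * readset.read_length
            )
            a.set_tag("XC", tags.get(int(cat), "N"))
            out.write(a)


# --------------------------------------------------------------------------
# VCF


def write_vcf(
    sites, reference, accessions: list[str], path, include_rejected: bool = False
) -> None:
    """Accepted (and optionally rejected) sites as VCF 4.2.

    Rejected sites carry their rejection reason in FILTER; triallelic
    sites become multi-ALT records.  The reference base is emitted as REF
    even when no accession carries it; allele indices refer to the
    REF+ALT list as usual.
    """
    header = pysam.VariantHeader()
    header.add_line('##source=allosnp')
    for c in reference.names:
        header.contigs.add(c, length=int(reference.seqs[c].size))
    header.add_line(
        '##INFO=<ID=ALLELISM,Number=1,Type=String,Description='
        '"biallelic or triallelic">'
    )
    header.add_line(
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">'
    )
    header.add_line(
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">'
    )
    for reason in ("low_depth", "heterozygous_line", "maf", "monomorphic",
                   "excess_alleles"):
        header.add_line(
            f'##FILTER=<ID={reason},Description="Rejected: {reason}">'
        )
    for acc in accessions:
        header.add_sample(acc)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for s in sorted(sites, key=lambda s: (s.chrom, s.pos)):
            if s.status != "accepted" and not include_rejected:
                continue
            alts = [a for a in s.alleles if a != s.ref]
            if not alts:
                alts = ["."]
            rec = out.new_record(
                contig=s.chrom, start=s.pos, stop=s.pos + 1,
                alleles=tuple([s.ref] + [a for a in alts if a != "."]) or None,
            )
            if s.status == "accepted":
                rec.filter.add("PASS")
                rec.info["ALLELISM"] = s.allelism
            else:
                rec.filter.add(s.rejection_reason)
            allele_index = {al: i for i, al in enumerate(rec.alleles)}
            for acc, call in zip(accessions, s.calls):
                sample = rec.samples[acc]
                if call.status == "called" and call.allele in allele_index:
                    idx = allele_index[call.allele]
                    sample["GT"] = (idx, idx)  # inbred: homozygous
                else:
                    sample["GT"] = (None, None)
                sample["DP"] = call.depth
            out.write(rec)
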