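"""Annotation of accepted simple SNPs.

Covers substitution class (transition vs transversion), the allele-specific
PCR suitability rule for A/T SNPs (a G or T three bases upstream, or a C or
A three bases downstream, on the reference strand), codon-level coding
effects against gene models, per-chromosome density summaries, and the
pairwise between-accession SNP count matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _seq
from .genes import GeneModel, translate
from .snp_filter import SnpSite

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")


def classify_substitution(ref_allele: str, alt_allele: str) -> str:
    """'transition' (purine<->purine or pyrimidine<->pyrimidine) or 'transversion'."""
    a, b = ref_allele.upper(), alt_allele.upper()
    if a == b:
        raise ValueError("alleles must differ")
    if {a, b} <= PURINES or {a, b} <= PYRIMIDINES:
        return "transition"
    return "transversion"


def tstv_counts(sites: list[SnpSite]) -> tuple[int, int]:
    """(transitions, transversions) over accepted biallelic sites.

    Triallelic sites are excluded from the numerator and denominator; they
    are reported separately by the density/annotation tables.
    """
    ts = tv = 0
    for s in sites:
        if s.allelism != "biallelic":
            continue
        if classify_substitution(s.alleles[0], s.alleles[1]) == "transition":
            ts += 1
        else:
            tv += 1
    return ts, tv


def tstv_ratio_from_shares(ts_share: float, tv_share: float) -> float:
    """Transition/transversion ratio implied by printed class percentages."""
    if tv_share <= 0:
        raise ValueError("transversion share must be positive")
    return ts_share / tv_share


def aspcr_suitable(alleles, flank_up: str, flank_down: str) -> bool:
    """Allele-specific-PCR suitability of an A/T SNP.

    ``flank_up``/``flank_down`` are the reference-strand bases immediately
    before and after the SNP (nearest first in ``flank_down``, nearest LAST
    in ``flank_up``); at least 3 bases of flank are required on each side.
    True iff the alleles are {A, T} and the 3rd base upstream is G or T, or
    the 3rd base downstream is C or A.
    """
    if set(a.upper() for a in alleles) != {"A", "T"}:
        return False
    if len(flank_up) < 3 or len(flank_down) < 3:
        warnings.warn("flank truncated by contig end; AS-PCR rule undecidable",
                      stacklevel=2)
        return False
    return flank_up[-3].upper() in "GT" or flank_down[2].upper() in "CA"


def aspcr_suitable_at(site: SnpSite, reference) -> bool:
    seq = reference.seqs[site.chrom]
    p = site.pos
    up = _seq.decode(seq[max(0, p - 3):p])
    down = _seq.decode(seq[p + 1:p + 4])
    return aspcr_suitable(site.alleles, up, down)


# --------------------------------------------------------------------------
# coding effects


@dataclass
class CodingEffect:
    gene_id: str
    strand: str
    codon_index: int          # 0-based codon number in the CDS
    codon_position: int       # 1, 2 or 3 within the codon
    ref_codon: str
    alt_codon: str
    ref_aa: str
    alt_aa: str
    effect: str               # synonymous | nonsynonymous | stop_gain | stop_loss


def _effect_class(ref_aa: str, alt_aa: str) -> str:
    if ref_aa == alt_aa:
        return "synonymous"
    if ref_aa != "*" and alt_aa == "*":
        return "stop_gain"
    if ref_aa == "*" and alt_aa != "*":
        return "stop_loss"
    return "nonsynonymous"


def coding_effect(
    chrom: str, pos: int, ref_allele: str, alt_allele: str,
    gene_models: list[GeneModel], reference,
) -> CodingEffect | None:
    """Codon-level consequence of a substitution, or None if noncoding.

    The substitution is mapped into spliced CDS coordinates honouring
    strand (minus-strand genes complement the allele and reverse the
    position), the affected codon is re-translated with the standard
    genetic code, and the effect class follows from the amino acid change.
    """
    for m in gene_models:
        if m.chrom != chrom:
            continue
        cds_idx = m.genome_to_cds(pos)
        if cds_idx is None:
            continue
        cds = m.cds_codes(reference.seqs[chrom])
        ref_code = _seq.encode(ref_allele)[0]
        alt_code = _seq.encode(alt_allele)[0]
        if m.strand == "-":
            ref_code = _seq.complement(np.array([ref_code]))[0]
            alt_code = _seq.complement(np.array([alt_code]))[0]
        if cds[cds_idx] != ref_code:
            # reference-allele mismatch against the model: annotate against
            # what the CDS actually carries
            ref_code = cds[cds_idx]
        if _seq.N in (ref_code, alt_code) or (cds[cds_idx] >= 4):
            warnings.warn(f"codon containing N at {chrom}:{pos}; unannotated",
                          stacklevel=2)
            return None
        ci = cds_idx // 3
        ref_codon = cds[3 * ci:3 * ci + 3]
        alt_codon = ref_codon.copy()
        alt_codon[cds_idx % 3] = alt_code
        ref_str, alt_str = _seq.decode(ref_codon), _seq.decode(alt_codon)
        ref_aa, alt_aa = translate(ref_str), translate(alt_str)
        return CodingEffect(
            gene_id=m.gene_id, strand=m.strand, codon_index=ci,
            codon_position=cds_idx % 3 + 1,
            ref_codon=ref_str, alt_codon=alt_str,
            ref_aa=ref_aa, alt_aa=alt_aa,
            effect=_effect_class(ref_aa, alt_aa),
        )
    return None


def annotate_sites(
    sites: list[SnpSite], gene_models: list[GeneModel], reference
) -> pd.DataFrame:
    """Per-site annotation table (substitution class, AS-PCR, coding effect)."""
    rows = []
    for s in sites:
        sub = (classify_substitution(s.alleles[0], s.alleles[1])
               if s.allelism == "biallelic" else "multiallelic")
        at_type = s.allelism == "biallelic" and set(s.alleles) == {"A", "T"}
        aspcr = aspcr_suitable_at(s, reference) if at_type else False
        eff = None
        if s.allelism == "biallelic":
            eff = coding_effect(s.chrom, s.pos, s.alleles[0], s.alleles[1],
                                gene_models, reference)
        rows.append({
            "chrom": s.chrom, "pos": s.pos, "ref": s.ref,
            "alleles": "/".join(s.alleles), "substitution": sub,
            "at_type": at_type, "aspcr_suitable": aspcr,
            "gene": eff.gene_id if eff else None,
            "effect": eff.effect if eff else "noncoding",
        })
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alleles", "substitution",
                       "at_type", "aspcr_suitable", "gene", "effect"]
    )


# --------------------------------------------------------------------------
# density and pairwise summaries


def density_per_100kb(count: int, length: int) -> int:
    """SNPs per 100 kb, rounded to the nearest integer."""
    if length <= 0:
        raise ValueError("length must be positive")
    return int(round(count / length * 100_000))


def density_table(
    sites: list[SnpSite] | pd.DataFrame,
    chrom_lengths: dict[str, int],
    window: int = 100_000,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-chromosome density rows plus fixed-width window counts."""
    if isinstance(sites, pd.DataFrame):
        pos_by_chrom = {
            c: g["pos"].to_numpy() for c, g in sites.groupby("chrom")
        }
    else:
        pos_by_chrom = {}
        for s in sites:
            pos_by_chrom.setdefault(s.chrom, []).append(s.pos)
        pos_by_chrom = {c: np.asarray(v) for c, v in pos_by_chrom.items()}
    unknown = set(pos_by_chrom) - set(chrom_lengths)
    if unknown:
        raise ValueError(f"SNPs on unknown chromosomes: {sorted(unknown)}")

    rows, win_rows = [], []
    for chrom, length in chrom_lengths.items():
        pos = pos_by_chrom.get(chrom, np.zeros(0, dtype=int))
        rows.append({
            "chrom": chrom, "length": length, "snps": int(pos.size),
            "snp_per_100kb": density_per_100kb(int(pos.size), length),
        })
        n_win = int(np.ceil(length / window))
        counts = np.bincount(pos // window, minlength=n_win)
        for w in range(n_win):
            win_rows.append({
                "chrom": chrom, "window_start": w * window,
                "window_end": min((w + 1) * window, length),
                "snps": int(counts[w]),
            })
    table = pd.DataFrame(rows)
    total = {
        "chrom": "Total",
        "length": int(table["length"].sum()),
        "snps": int(table["snps"].sum()),
        "snp_per_100kb": density_per_100kb(
            int(table["snps"].sum()), int(table["length"].sum())
        ),
    }
    table = pd.concat([table, pd.DataFrame([total])], ignore_index=True)
    return table, pd.DataFrame(win_rows)


def pairwise_snp_matrix(
    sites: list[SnpSite], accessions: list[str]
) -> pd.DataFrame:
    """Symmetric matrix counting sites where two lines are called and differ."""
    n = len(accessions)
    if n < 2:
        raise ValueError("need at least two accessions")
    mat = np.zeros((n, n), dtype=np.int64)
    for s in sites:
        alleles = np.array([
            c.allele if c.status == "called" else None for c in s.calls
        ], dtype=object)
        for i in range(n):
            if alleles[i] is None:
                continue
            for j in range(i + 1, n):
                if alleles[j] is not None and alleles[i] != alleles[j]:
                    mat[i, j] += 1
                    mat[j, i] += 1
    return pd.DataFrame(mat, index=accessions, columns=accessions)


def summarize_pairwise(matrix: pd.DataFrame, total_snps: int | None = None) -> dict:
    """Mean/extreme pairwise counts; shares of the total when given."""
    names = list(matrix.index)
    vals, pairs = [], []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            vals.append(int(matrix.iloc[i, j]))
            pairs.append((names[i], names[j]))
    vals = np.asarray(vals)
    imax, imin = int(vals.argmax()), int(vals.argmin())
    out = {
        "n_pairs": len(vals),
        "mean": float(vals.mean()),
        "max_pair": pairs[imax], "max_count": int(vals[imax]),
        "min_pair": pairs[imin], "min_count": int(vals[imin]),
    }
    if total_snps:
        out["max_share_pct"] = round(vals[imax] / total_snps * 100, 1)
        out["min_share_pct"] = round(vals[imin] / total_snps * 100, 1)
    return out
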