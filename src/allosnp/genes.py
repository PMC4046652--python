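"""Gene models, GFF3 round-trip and the toy GO ontology.

A gene model is a strand-aware list of CDS exons on one chromosome.  The
spliced CDS always starts with ATG, contains no internal stop codon, and
ends with a stop codon — the generator constructs genes that way, and the
coding-effect annotator relies on it.  Coordinates are 0-based half-open
internally and 1-based inclusive in GFF3, per the format standard.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import Seq

from . import _seq

STOP_CODONS = ("TAA", "TAG", "TGA")


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    exons: list[tuple[int, int]]  # 0-based half-open, sorted by genomic start

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def cds_codes(self, chrom_seq: np.ndarray) -> np.ndarray:
        """Spliced CDS in translation orientation as a code array."""
        parts = [chrom_seq[s:e] for s, e in self.exons]
        cds = np.concatenate(parts)
        if self.strand == "-":
            cds = _seq.revcomp(cds)
        return cds

    def cds_sequence(self, chrom_seq: np.ndarray) -> str:
        return _seq.decode(self.cds_codes(chrom_seq))

    def genome_to_cds(self, pos: int) -> int | None:
        """Map a genomic position into spliced-CDS coordinates (or None)."""
        offset = 0
        for s, e in self.exons:
            if s <= pos < e:
                fwd = offset + (pos - s)
                if self.strand == "+":
                    return fwd
                return self.cds_length - 1 - fwd
            offset += e - s
        return None


def translate(cds: str) -> str:
    return str(Seq(cds).translate())


# --------------------------------------------------------------------------
# toy GO ontology: (term id, parent id or None, name, namespace)

ONTOLOGY: list[tuple[str, str | None, str, str]] = [
    ("GO:0003674", None, "molecular_function", "molecular_function"),
    ("GO:0005488", "GO:0003674", "binding", "molecular_function"),
    ("GO:0005515", "GO:0005488", "protein binding", "molecular_function"),
    ("GO:0003677", "GO:0005488", "DNA binding", "molecular_function"),
    ("GO:0005524", "GO:0005488", "ATP binding", "molecular_function"),
    ("GO:0003824", "GO:0003674", "catalytic activity", "molecular_function"),
    ("GO:0016787", "GO:0003824", "hydrolase activity", "molecular_function"),
    ("GO:0016740", "GO:0003824", "transferase activity", "molecular_function"),
    ("GO:0016301", "GO:0016740", "kinase activity", "molecular_function"),
    ("GO:0005215", "GO:0003674", "transporter activity", "molecular_function"),
    ("GO:0008150", None, "biological_process", "biological_process"),
    ("GO:0008152", "GO:0008150", "metabolic process", "biological_process"),
    ("GO:0006259", "GO:0008152", "DNA metabolic process", "biological_process"),
    ("GO:0006810", "GO:0008150", "transport", "biological_process"),
    ("GO:0006950", "GO:0008150", "response to stress", "biological_process"),
    ("GO:0009628", "GO:0006950", "response to abiotic stimulus", "biological_process"),
]

# terms the generator samples gene annotations from (non-root)
ANNOTATABLE_TERMS = [t for t, p, _, _ in ONTOLOGY if p is not None]


def ontology_parents() -> dict[str, list[str]]:
    """child -> list of is-a parents for the built-in toy ontology."""
    parents: dict[str, list[str]] = {}
    for term, parent, _, _ in ONTOLOGY:
        parents.setdefault(term, [])
        if parent is not None:
            parents[term].append(parent)
    return parents


# --------------------------------------------------------------------------
# generation


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + stop-free internal codons + one stop codon (n_codons total)."""
    bases = "ACGT"
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        c = "".join(bases[i] for i in rng.integers(0, 4, size=3))
        if c not in STOP_CODONS:
            codons.append(c)
    codons.append(STOP_CODONS[rng.integers(0, 3)])
    return "".join(codons)


def generate_gene_models(
    reference,
    config,
    rng: np.random.Generator,
    forbidden: dict[str, list[tuple[int, int]]] | None = None,
):
    """Plant non-overlapping protein-coding genes into the reference.

    The reference sequences are modified in place so that each emitted
    model's spliced CDS translates cleanly.  Returns ``(models, go_map)``
    where ``go_map`` maps gene id -> list of GO term ids.  If fewer than
    ``config.n_genes`` genes fit, generates as many as possible and warns.
    """
    forbidden = forbidden or {}
    lo, hi = config.gene_length_range
    margin = config.read_length
    occupied = {name: list(forbidden.get(name, [])) for name in reference.names}
    models: list[GeneModel] = []
    go_map: dict[str, list[str]] = {}
    lengths = np.array([reference.seqs[n].size for n in reference.names], dtype=float)
    weights = lengths / lengths.sum()

    for gi in range(config.n_genes):
        placed = False
        for _attempt in range(200):
            chrom = reference.names[rng.choice(len(reference.names), p=weights)]
            seq = reference.seqs[chrom]
            n_codons = int(rng.integers(lo // 3, hi // 3 + 1))
            cds_len = 3 * n_codons
            two_exon = rng.random() < 0.3
            intron = int(rng.integers(50, 120)) if two_exon else 0
            span = cds_len + intron
            if seq.size < span + 2 * margin:
                continue
            start = int(rng.integers(margin, seq.size - span - margin))
            iv = (start, start + span)
            if any(s < iv[1] and iv[0] < e for s, e in occupied[chrom]):
                continue
            strand = "+" if rng.random() < 0.5 else "-"
            cds = _random_cds(rng, n_codons)
            codes = _seq.encode(cds)
            if strand == "-":
                codes = _seq.revcomp(codes)
            if two_exon:
                # split the (genomic-orientation) CDS at an arbitrary point
                cut = int(rng.integers(3, cds_len - 3))
                exon1 = (start, start + cut)
                exon2 = (start + cut + intron, start + span)
                seq[exon1[0]:exon1[1]] = codes[:cut]
                seq[exon2[0]:exon2[1]] = codes[cut:]
                exons = [exon1, exon2]
            else:
                seq[start:start + cds_len] = codes
                exons = [(start, start + cds_len)]
            gene_id = f"gene{gi:04d}"
            model = GeneModel(gene_id, chrom, strand, exons)
            models.append(model)
            occupied[chrom].append(iv)
            n_terms = int(rng.integers(1, 6))
            terms = rng.choice(len(ANNOTATABLE_TERMS), size=n_terms, replace=False)
            go_map[gene_id] = sorted(ANNOTATABLE_TERMS[i] for i in terms)
            placed = True
            break
        if not placed:
            warnings.warn(
                f"could only place {len(models)} of {config.n_genes} genes",
                stacklevel=2,
            )
            break
    return models, go_map


# --------------------------------------------------------------------------
# GFF3 round-trip (gene/mRNA/CDS three-level layout, 1-based inclusive)


def write_gff3(models: list[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            gid = m.gene_id
            fh.write(
                f"{m.chrom}\tallosnp\tgene\t{m.start + 1}\t{m.end}\t.\t"
                f"{m.strand}\t.\tID={gid}\n"
            )
            fh.write(
                f"{m.chrom}\tallosnp\tmRNA\t{m.start + 1}\t{m.end}\t.\t"
                f"{m.strand}\t.\tID={gid}.1;Parent={gid}\n"
            )
            # phase bookkeeping in translation order
            exons = m.exons if m.strand == "+" else m.exons[::-1]
            done = 0
            for s, e in exons:
                phase = (3 - done % 3) % 3
                fh.write(
                    f"{m.chrom}\tallosnp\tCDS\t{s + 1}\t{e}\t.\t{m.strand}\t"
                    f"{phase}\tID={gid}.1.cds;Parent={gid}.1\n"
                )
                done += e - s


def read_gff3(path) -> list[GeneModel]:
    by_gene: dict[str, GeneModel] = {}
    order: list[str] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            chrom, _src, ftype, start, end, _score, strand, _phase, attrs = (
                line.rstrip("\n").split("\t")
            )
            if ftype != "CDS":
                continue
            fields = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            parent = fields.get("Parent", fields.get("ID", "unknown"))
            gid = parent.rsplit(".", 1)[0]
            if gid not in by_gene:
                by_gene[gid] = GeneModel(gid, chrom, strand, [])
                order.append(gid)
            by_gene[gid].exons.append((int(start) - 1, int(end)))
    for m in by_gene.values():
        m.exons.sort()
    return [by_gene[g] for g in order]


def write_go_map(go_map: dict[str, list[str]], path) -> None:
    with open(path, "w") as fh:
        for gene in sorted(go_map):
            for term in go_map[gene]:
                fh.write(f"{gene}\t{term}\n")


def read_go_map(path) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            if line.strip():
                gene, term = line.split()
                out.setdefault(gene, []).append(term)
    return out


def write_ontology(path, ontology=ONTOLOGY) -> None:
    with open(path, "w") as fh:
        fh.write("term\tparent\tname\tnamespace\n")
        for term, parent, name, ns in ontology:
            fh.write(f"{term}\t{parent or '.'}\t{name}\t{ns}\n")


def read_ontology(path) -> dict[str, list[str]]:
    """Read an ontology TSV into a child -> parents mapping."""
    parents: dict[str, list[str]] = {}
    with open(path) as fh:
        header = fh.readline()
        assert header.startswith("term")
        for line in fh:
            term, parent, _name, _ns = line.rstrip("\n").split("\t")
            parents.setdefault(term, [])
            if parent != ".":
                parents[term].append(parent)
    return parents
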