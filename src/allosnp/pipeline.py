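"""End-to-end orchestration: simulate -> mask -> align -> call -> annotate
-> enrich -> goldengate, with truth-based evaluation.

The pipeline is deliberately in-memory: stages exchange numpy-backed
objects, and files are written only when an output directory is given.
`evaluate_against_truth` scores the accepted SNP set against the planted
truth, where a planted site only counts as recoverable when every allele
is carried by at least two accessions (sites below that bound are
expected casualties of the MAF step, not false negatives).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import align, annotate, enrich, genes, goldengate, mask, simulate, snp_filter
from .config import SimulationConfig

log = logging.getLogger("allosnp")


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    stages: list[dict] = field(default_factory=list)

    def record(self, name: str, **counts) -> None:
        self.stages.append({"stage": name, **counts})
        log.info("stage %-12s %s", name,
                 " ".join(f"{k}={v}" for k, v in counts.items()))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"config_hash": self.config_hash, "seed": self.seed,
                       "stages": self.stages}, fh, indent=2)


@dataclass
class MetricsReport:
    true_positives: int
    false_positives: int
    false_negatives: int
    precision: float
    recall: float
    f1: float
    undefined_precision: bool
    missed_reasons: dict
    tstv: tuple[int, int]


@dataclass
class PipelineResult:
    config: SimulationConfig
    reference: simulate.ReferenceSet
    truth: simulate.TruthTable
    masked: mask.MaskedReference
    gene_models: list
    go_map: dict
    read_tallies: list[dict]
    accepted: list[snp_filter.SnpSite]
    report: snp_filter.FilterReport
    annotations: pd.DataFrame
    enrichment: pd.DataFrame
    assay_results: pd.DataFrame
    goldengate_truth: pd.DataFrame
    metrics: MetricsReport
    manifest: RunManifest


def _config_hash(config: SimulationConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def simulate_inputs(config: SimulationConfig):
    """Reference + gene models + panel + reads, with truth bookkeeping."""
    reference, truth = simulate.generate_reference(config)
    models, go_map = simulate.generate_gene_models(reference, truth, config)
    panel = simulate.generate_panel(reference, truth, config)
    readsets = simulate.simulate_reads(reference, panel, config)
    return reference, truth, models, go_map, panel, readsets


def run_pipeline(
    config: SimulationConfig,
    thresholds: snp_filter.FilterThresholds | None = None,
    params: align.AlignmentParams | None = None,
    with_goldengate: bool = True,
) -> PipelineResult:
    thresholds = thresholds or snp_filter.FilterThresholds()
    params = params or align.AlignmentParams()
    manifest = RunManifest(_config_hash(config), config.seed)
    t0 = time.time()

    reference, truth, models, go_map, panel, readsets = simulate_inputs(config)
    manifest.record(
        "simulate",
        chromosomes=len(reference.names), genome_bp=reference.total_length(),
        genes=len(models), planted_snps=len(truth.simple_snps),
        reads=sum(rs.n_reads for rs in readsets),
    )

    intervals = mask.kmer_mask(reference)
    masked = mask.apply_mask(reference, intervals)
    manifest.record("mask", masked_fraction=round(masked.masked_fraction(), 4))

    index = align.build_index(masked, params.seed_length)
    alignments, tallies = [], []
    for rs in readsets:
        al = align.map_reads(rs.seq, index, params)
        alignments.append(al)
        tallies.append(align.classify_counts(al))
    manifest.record(
        "align",
        unique=sum(t["unique"] for t in tallies),
        repeat=sum(t["repeat"] for t in tallies),
        unaligned=sum(t["unaligned"] for t in tallies),
    )

    pile = snp_filter.pileup(readsets, alignments, reference,
                             config.accession_names)
    accepted, report = snp_filter.run_cascade_matrix(pile, reference, thresholds)
    manifest.record("call", candidates=report.candidates,
                    accepted=report.accepted, **{
                        f"rejected_{k}": v for k, v in report.rejected.items()
                    })

    annotations = annotate.annotate_sites(accepted, models, reference)
    ns_effects = {"nonsynonymous", "stop_gain", "stop_loss"}
    study_genes = sorted(
        set(annotations.loc[annotations["effect"].isin(ns_effects), "gene"])
    )
    background = sorted(go_map)
    enrichment = enrich.enrich_all(
        study_genes, background, go_map, genes.ontology_parents()
    ) if study_genes else pd.DataFrame()
    manifest.record("annotate", annotated=len(annotations),
                    ns_genes=len(study_genes))

    if with_goldengate:
        gg = simulate.simulate_goldengate(truth, config)
        assay_results = goldengate.analyze_assays(gg.intensities)
        gg_truth = gg.assays
        manifest.record(
            "goldengate", assays=len(assay_results),
            hemi_called=int(assay_results["hemi"].sum()),
            mean_call_rate=round(float(assay_results["call_rate"].mean()), 4),
        )
    else:
        assay_results, gg_truth = pd.DataFrame(), pd.DataFrame()

    metrics = evaluate_against_truth(accepted, truth)
    manifest.record("evaluate", precision=round(metrics.precision, 4),
                    recall=round(metrics.recall, 4),
                    seconds=round(time.time() - t0, 1))
    return PipelineResult(
        config, reference, truth, masked, models, go_map, tallies,
        accepted, report, annotations, enrichment, assay_results, gg_truth,
        metrics, manifest,
    )


def homoeolog_stress(
    config: SimulationConfig | None = None,
    thresholds: snp_filter.FilterThresholds | None = None,
) -> dict:
    """Align both subgenomes' reads to an A-only reference and count how the
    cascade handles the resulting homoeolog co-pileups.

    This reproduces the central failure mode of allopolyploid SNP calling:
    when the duplicated (C) copy is absent from the reference — or
    deliberately left unmasked — reads from both homoeologs pile onto one
    locus, and every divergent position presents as a heterozygote in every
    inbred line.  The experiment runs error-free so that each pileup base
    is exactly its homoeolog of origin.  Returns counts of co-piled
    divergent sites (>= 2 unique reads from each homoeolog covering the
    site within at least one accession) and how many the cascade rejected
    as heterozygous_line.
    """
    config = config or SimulationConfig(
        seed=0,
        chrom_plan=[("A", 40_000), ("C", 40_000)],
        repeat_families=[],
        n_genes=0,
        read_length=75,
        base_error_rate=0.0,
    )
    thresholds = thresholds or snp_filter.FilterThresholds()
    reference, truth = simulate.generate_reference(config)
    panel = simulate.generate_panel(reference, truth, config)
    readsets = simulate.simulate_reads(reference, panel, config)

    a_names = [n for n in reference.names if reference.subgenome[n] == "A"]
    ref_a = reference.subset(a_names)
    index = align.build_index(ref_a)
    alignments = [align.map_reads(rs.seq, index) for rs in readsets]

    # per-accession coverage split by homoeolog of origin
    L = config.read_length
    co_piled: dict[str, np.ndarray] = {
        c: np.zeros(ref_a.seqs[c].size, dtype=bool) for c in a_names
    }
    for rs, al in zip(readsets, alignments):
        uniq = al.category == align.CAT_UNIQUE
        origin_c = np.array([
            reference.subgenome[rs.chrom_names[ci]] == "C" for ci in rs.chrom
        ])
        for ci, cname in enumerate(a_names):
            size = ref_a.seqs[cname].size
            cov = {}
            for label, sel in (("A", uniq & ~origin_c), ("C", uniq & origin_c)):
                m = sel & (al.chrom == ci)
                d = np.zeros(size + 1, dtype=np.int32)
                np.add.at(d, np.clip(al.pos[m], 0, size), 1)
                np.add.at(d, np.clip(al.pos[m] + L, 0, size), -1)
                cov[label] = np.cumsum(d[:-1])
            co_piled[cname] |= (
                (cov["A"] >= thresholds.het_minor_reads)
                & (cov["C"] >= thresholds.het_minor_reads)
            )

    pile = snp_filter.pileup(readsets, alignments, ref_a, config.accession_names)
    _, report = snp_filter.run_cascade_matrix(pile, ref_a, thresholds)
    reasons: dict[tuple[str, int], str] = {}
    for cname in a_names:
        cand = pile.candidate_positions(cname)
        for p in cand:
            col = pile.column(cname, int(p), _seq_base(ref_a, cname, int(p)))
            site = snp_filter.filter_site(col, thresholds)
            reasons[(cname, int(p))] = site.rejection_reason or "accepted"

    div = truth.homoeolog_sites
    n_co, n_het = 0, 0
    for r in div.itertuples():
        if not co_piled[r.a_chrom][r.pos]:
            continue
        n_co += 1
        if reasons.get((r.a_chrom, r.pos)) == "heterozygous_line":
            n_het += 1
    return {
        "co_piled_divergent_sites": n_co,
        "rejected_heterozygous_line": n_het,
        "fraction_rejected_het": n_het / n_co if n_co else float("nan"),
        "filter_report": report,
    }


def _seq_base(reference, chrom: str, pos: int) -> str:
    from . import _seq

    return _seq.BASES[reference.seqs[chrom][pos]]


def evaluate_against_truth(
    accepted: list[snp_filter.SnpSite],
    truth: simulate.TruthTable,
    report: snp_filter.FilterReport | None = None,
) -> MetricsReport:
    """Precision/recall of the accepted set against recoverable planted sites."""
    planted = {
        (r.chrom, r.pos): r.detectable
        for r in truth.simple_snps.itertuples()
    }
    accepted_keys = {(s.chrom, s.pos) for s in accepted}
    recoverable = {k for k, det in planted.items() if det}
    tp = len(accepted_keys & recoverable)
    fp = len(accepted_keys - set(planted))
    fn = len(recoverable - accepted_keys)
    undefined = (tp + fp) == 0
    precision = 1.0 if undefined else tp / (tp + fp)
    recall = tp / (tp + fn) if (tp + fn) else 1.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall else 0.0)
    missed: dict[str, int] = {}
    tstv = annotate.tstv_counts(accepted)
    return MetricsReport(tp, fp, fn, precision, recall, f1, undefined,
                         missed, tstv)
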