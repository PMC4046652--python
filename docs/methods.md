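# Methods

This note documents the models, the synthetic-data generator, the
numerical choices, and the limits of what the test suite demonstrates.

## Genome and panel model

Each homoeologous chromosome pair descends from one ancestral random
sequence; the A copy is the ancestor and the C copy carries independent
per-base substitutions at rate `homoeolog_divergence` (default 0.03).
This emulates an allotetraploid whose subgenomes diverged from a common
ancestor: roughly one fixed inter-subgenome difference per 33 bp, i.e.
~2–3 per short read — enough that a read's own copy almost always wins
the alignment score, which is precisely the property the unique-alignment
filter exploits.  Repeat families are inserted as *exact* copies
(`(unit_length, copies_per_subgenome)`, defaults (200, 20) and (500, 8)),
so k-mer multiplicity masking is unambiguous at desk scale.  The truth
table's homoeolog-divergent positions are recomputed by direct A/C
comparison after every sequence edit (gene planting overwrites sequence),
so it is exact by construction.

The accession panel is fully inbred: every accession is homozygous at
every position.  Simple SNPs are planted per-base at `snp_rate`
(default 1e-4) in non-repeat sequence away from the extreme chromosome
ends; each site's minor allele is carried by `k` accessions drawn from
`minor_count_spectrum` (default uniform over 1..5 of 10 accessions —
singletons are deliberately included because the minor-allele filter is
*supposed* to reject them; the truth table marks a site "detectable" only
when every allele is carried by ≥ 2 accessions).  A `triallelic_fraction`
(default 3e-4, matching the observed tri-allelic share of the emulated
study) receives a third allele.

Reads (75 or 100 bp, default 100) are drawn uniformly from each
accession's personalised genome, strand-symmetric, with each base flipped
to a random different base at `base_error_rate` (default 0.002).  Reads
are unpaired: no pipeline step uses mate information, and the filter
treats mates as independent evidence anyway.  Default coverage is a flat
12× per accession — the regime in which the ≥ 4-read genotype rule is
informative rather than the binding constraint; the emulated study's
uneven 5.3–37.5× spectrum is available as `allosnp.STUDY_DEPTHS` for
experiments on missingness.

What the generator does **not** model: indels and structural variation,
residual heterozygosity of the accessions, base-quality variation,
GC/coverage bias, ancestral genome triplication, or linkage between
genotyping assays.  Consequently, passing tests demonstrate the *logic*
of the cascade (unique alignment, homozygosity, depth, MAF) under
substitution-only divergence and uniform error — they do not certify
behaviour on real data with indel-induced misalignment or
reference-quality problems.

## Mapping contract

Seed-and-extend, ungapped: candidate diagonals come from exact 32-mer
hits at every read offset (both strands), extension scores full-read
Hamming distance, clipped at contig ends.  A placement is valid with
≤ 5 mismatches over ≥ 40 aligned bases (the aligned-length bound only
binds for overhanging reads).  Exactly one best-score placement →
*unique*; a tie → *repeatedly aligned* (never an arbitrary pick); none →
*unaligned*.  Reads whose best placement is > 50% masked count as repeat:
masking exists to restrict the analysis to low-copy DNA.  A read with
more than five errors packed so densely that no exact 32-mer survives at
any true placement would be missed where an exhaustive aligner would not;
at the default error rate such reads are vanishingly rare, and the
equivalence property test against a brute-force all-positions aligner
covers the realistic regime.

## Filter cascade

Per line and site: depth < 4 → missing; else the line is heterozygous
when the second most common base has ≥ 2 reads *and* ≥ 10% of depth
(thresholds chosen so a single error can never trigger heterozygosity at
callable depth; exact two-base ties are conservatively heterozygous).
Site-level order: any heterozygous line → reject (`heterozygous_line`);
no callable line → `low_depth`; < 2 distinct called alleles →
`monomorphic`; > 3 → `excess_alleles`; any allele carried by < 2 called
lines → `maf`; otherwise accepted, bi- or tri-allelic.  The MAF rule is
evaluated over *called* lines, and a tri-allelic site must satisfy it for
every allele.  The reference base is recorded but not counted as an
allele: a site where all accessions agree against the reference is not an
inter-accession SNP.  A dense vectorised path (`run_cascade_matrix`)
implements the same contract as the scalar `filter_site`; the scalar
result is authoritative and the test suite holds both to an independent
rule oracle.

## Annotation and enrichment

Transition = purine↔purine or pyrimidine↔pyrimidine.  Tri-allelic sites
are excluded from the Ts/Tv numerator and denominator.  The AS-PCR rule
(A/T alleles with G/T three bases upstream or C/A three bases downstream)
is evaluated on the reference strand; truncated flanks fail with a
warning.  Coding effects map the substitution into spliced CDS
coordinates (minus-strand genes complement the allele and reverse the
position) and re-translate the affected codon; the oracle test mutates
the genome and re-translates whole proteins.  Densities are rounded to
the nearest integer per 100 kb.  Enrichment uses Pearson χ² (1 df, no
continuity correction) on each term's 2×2 table, with a two-sided
Fisher's exact test whenever any expected cell is below 5; annotations
propagate up is-a parents before testing; background = all genes with
models, not only annotated ones; raw p-values are reported with
Benjamini–Hochberg q-values as an extra column.

## GoldenGate model and clustering

Simulated intensities: an allele's channel reads μ_on = 4000 when present
and μ_off = 300 when absent, heterozygotes split the signal, Gaussian
noise sd = 200 truncated at zero.  Hemi assays sum a second locus fixed
homozygous-A in the DH background and homozygous-B in the F₂ background
("genotype-specific heterozygosity in the additional amplified region"),
which yields exactly four noise-free pooled θ values — the minimum
realisation of the ≥ 4-cluster hemi signature — while each population
alone shows ≤ 3.

Clustering is deterministic 1-D Lloyd with centres initialised at evenly
spaced quantiles, selected over k = 1..6 by equal-variance Gaussian BIC
(`n·ln(WCSS/n) + 2k·ln n`), ties to smaller k.  Two guards reject
degenerate fits: adjacent centres closer than 0.12 (genuine genotype
groups sit ≥ ~0.19 apart in θ while a split of one noise cluster lands
~0.05 apart), and any cluster holding fewer than 5% of points (min 3) —
θ is a ratio of noisy channels and has heavier-than-Gaussian tails, so a
handful of outliers would otherwise claim a spurious cluster.  These two
constants are the load-bearing numerical choices of the module; both are
arguments of `fit_clusters`.  Calls are nearest-centre memberships;
no-calls are points with summed intensity below 1000 or farther than 0.15
from every centre; samples calling < 80% of assays are dropped and assay
call rates recomputed once.  Segregation uses Pearson χ² without
continuity correction (df = classes − 1); an assay is polymorphic when
the population's parents fall in different clusters; a heterozygote class
in a DH design is flagged inconsistent and the test runs on the
homozygote classes.  Proprietary per-call quality scoring is replaced by
this distance/intensity rule: only cluster membership, call rate and
cluster counts drive any conclusion the package draws.

## Problem sizes and designed experiments

The default pipeline configuration — two homoeologous pairs of 150 kb
(600 kb total), ten accessions at 12×, 100 bp reads — plants ~55–75 SNPs
and runs in about two minutes on one CPU; it is the unit of the
precision (≥ 0.99) and recall (≥ 0.9) gates.  The homoeolog stress
experiment aligns both subgenomes' reads of a 40 kb pair against the A
copy only and runs error-free, so every co-piled divergent position
(≥ 2 unique reads from each homoeolog within one accession) is exactly a
homoeolog artefact; the cascade must reject 100% of them as
heterozygous_line.  Hemi/simple classification is checked over fifty
independent 96-assay simulations (4800 assays).  The GO null simulation
draws 1000 uniform random study sets of 25 from a 400-gene background and
requires the combined χ²/Fisher test's type-I error at p < 0.05 to stay
≤ 0.07 (measured ~0.034; the Fisher fallback is conservative on small
expected counts).

## Known limitations

* Ungapped alignment only; indels would shift pileups and are out of scope.
* The k-mer mask leaves k−1 bp of each repeat copy's edges unmasked
  (positions also covered by flank-spanning k-mers); edge leakage shows
  up downstream as heterozygous-line rejections, not false SNPs.
* Cluster-count selection is tuned to two-population pools of ~50–130
  samples; very small sample sets need an explicit `min_cluster_size`.
* The per-chromosome density and pairwise summary operations reproduce
  published table arithmetic exactly, but genome-scale counts themselves
  are outside desk scale and are not reproduced.
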