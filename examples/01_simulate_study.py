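"""Generate a synthetic allotetraploid resequencing study.

Builds one homoeologous chromosome pair (A and C copies diverged at 3% per
base), plants repeat families and simple SNPs across a ten-accession inbred
panel, and prints what was planted.  Every downstream capability runs off
objects like these.
"""

from allosnp import SimulationConfig, generate_panel, generate_reference

config = SimulationConfig(
    seed=42,
    chrom_plan=[("A", 100_000), ("C", 100_000)],
    repeat_families=[(200, 12)],
    snp_rate=2e-4,
)

reference, truth = generate_reference(config)
panel = generate_panel(reference, truth, config)

print(f"chromosomes: {reference.names}, total {reference.total_length():,} bp")
print(f"homoeolog-divergent positions: {len(truth.homoeolog_sites):,} "
      f"(~3% of 100 kb: these are the false-SNP hazard in an allopolyploid)")
print(f"repeat copies planted: {len(truth.repeat_intervals)}")
print(f"simple SNPs planted: {len(panel.sites)}, of which "
      f"{int(truth.simple_snps['detectable'].sum())} have every allele in "
      f">= 2 accessions (recoverable after the MAF filter)")
print()
print(truth.simple_snps[["chrom", "pos", "ref", "alleles", "minor_count",
                         "detectable"]].head(8).to_string(index=False))
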