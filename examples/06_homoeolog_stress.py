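"""Why the homozygosity filter is the heart of allopolyploid SNP calling.

Aligns reads from both subgenomes against a reference containing only the
A copy — the situation a duplicated, unmasked locus creates.  Reads from
the missing C homoeolog co-pile onto A, and every divergent position
looks heterozygous in every (fully inbred) accession.  The cascade
rejects all of them with reason heterozygous_line.
"""

from allosnp.pipeline import homoeolog_stress

result = homoeolog_stress()

print(f"divergent positions with >= 2 reads from each homoeolog co-piled "
      f"in some accession: {result['co_piled_divergent_sites']}")
print(f"rejected as heterozygous_line: "
      f"{result['rejected_heterozygous_line']} "
      f"({result['fraction_rejected_het']:.1%})")
print()
print("cascade bookkeeping for the whole stress run:")
print(result["filter_report"].to_frame().to_string(index=False))
print()
print("in an inbred panel a heterozygous pileup cannot be allelic, so "
      "site-level heterozygosity cleanly identifies homoeolog confusion")
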