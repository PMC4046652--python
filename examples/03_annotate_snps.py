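"""Annotate an accepted SNP set: Ts/Tv, AS-PCR context, coding effects.

Also recomputes the published worked examples carried with the package:
pairwise summary arithmetic, per-chromosome densities, and the
transition/transversion ratio implied by the printed class shares.
"""

from allosnp import (
    SimulationConfig,
    density_per_100kb,
    run_pipeline,
    summarize_pairwise,
    tstv_ratio_from_shares,
)
from allosnp import studydata as sd

result = run_pipeline(
    SimulationConfig(seed=7, chrom_plan=[("A", 60_000), ("C", 60_000)],
                     repeat_families=[(200, 10)], snp_rate=3e-4, n_genes=15),
    with_goldengate=False,
)

ann = result.annotations
ts = int((ann["substitution"] == "transition").sum())
tv = int((ann["substitution"] == "transversion").sum())
print(f"accepted SNPs: {len(ann)}; transitions {ts}, transversions {tv}")
print("coding effects:", ann["effect"].value_counts().to_dict())
print("AS-PCR-suitable A/T SNPs:", int(ann["aspcr_suitable"].sum()))
print()

print("published worked examples (recomputed from the shipped tables):")
pw = summarize_pairwise(sd.pairwise_matrix(), total_snps=sd.BIALLELIC_TOTAL)
print(f"  mean pairwise SNPs over {pw['n_pairs']} pairs: {pw['mean']:.0f}")
print(f"  largest pair {pw['max_pair']}: {pw['max_count']:,} "
      f"({pw['max_share_pct']}% of bi-allelic total)")
print(f"  smallest pair {pw['min_pair']}: {pw['min_count']:,} "
      f"({pw['min_share_pct']}%)")
t = sd.CHROMOSOME_TABLE.set_index("chrom")
print(f"  A05 density: {density_per_100kb(int(t.loc['A05','snps']), int(t.loc['A05','length']))} SNPs/100kb; "
      f"C05: {density_per_100kb(int(t.loc['C05','snps']), int(t.loc['C05','length']))}")
print(f"  Ts/Tv ratio from printed shares "
      f"{sd.TRANSITION_SHARE_PCT}/{sd.TRANSVERSION_SHARE_PCT}: "
      f"{tstv_ratio_from_shares(sd.TRANSITION_SHARE_PCT, sd.TRANSVERSION_SHARE_PCT):.2f}")
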