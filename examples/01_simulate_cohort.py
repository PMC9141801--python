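"""Generate a synthetic 80-trio cohort and write VCF/PED/BED/truth files.

The generator emulates a targeted-sequencing trio study: blockwise-LD
haplotypes over two multi-megabase regions, a transmission-distorted risk
locus, rare variants, injected de novos, and read-level noise.
"""

from pathlib import Path

import triotdt as tt

cfg = tt.SimConfig(
    n_trios=80,
    regions=[tt.SimRegion("7", 32_652_669, 34_695_364, 300),
             tt.SimRegion("20", 54_797_058, 56_797_057, 300)],
    risk_loci=[tt.RiskLocus("bmp_locus", 1, tau=0.85, risk_maf=0.3)],
    n_denovo=5,
    missing_rate=0.02,
    seed=42,
)
geno, trios, truth = tt.simulate_trios(cfg)
out = Path("scratch/example_cohort")
paths = tt.write_cohort(geno, trios, truth, out)

print(f"cohort: {len(trios)} trios ({trios.n_samples} samples), "
      f"{geno.n_variants} variants over {len(cfg.regions)} regions")
print(f"risk locus: {truth.risk_loci.iloc[0].locus_id} at "
      f"{truth.risk_loci.iloc[0].chrom}:{truth.risk_loci.iloc[0].pos} "
      f"(tau = {truth.risk_loci.iloc[0].tau})")
print(f"injected de novos: {len(truth.denovo)}")
for name, p in paths.items():
    print(f"  {name}: {p}")
# tau = 0.85 means a heterozygous parent passes the risk allele 85% of the
# time; the TDT's expected odds ratio at that variant is 0.85/0.15 = 5.67.
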