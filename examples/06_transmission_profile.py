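"""Genotype-frequency profiles: children versus parents at associated
variants.

When the *major* allele is over-transmitted (a protective minor allele),
affected children become enriched for the homozygous-major genotype
relative to their parents — visible as a shift between the two pooled
genotype spectra.
"""

import triotdt as tt
from triotdt.profile import genotype_frequencies, transmission_direction

cfg = tt.SimConfig(
    n_trios=80,
    regions=[tt.SimRegion("20", 55_000_001, 55_300_000, 60)],
    risk_loci=[tt.RiskLocus("bmp7", 0, tau=0.1, risk_maf=0.4)],  # protective minor
    missing_rate=0.0,
    seed=15,
)
geno, trios, truth = tt.simulate_trios(cfg)
clean, _, _ = tt.qc_pipeline(geno, trios, mendel_policy=tt.MendelPolicy())
table = tt.run_tdt(clean, trios)

sig = transmission_direction(table, p_max=1e-3)
print(f"{len(sig)} variants with p < 1e-3; directions:")
print(sig["direction"].value_counts().to_string())

ids = list(sig["id"])
kids = genotype_frequencies(clean, trios, ids, "children")
parents = genotype_frequencies(clean, trios, ids, "parents")
print("\npooled genotype fractions (hom-major, het, hom-minor):")
print(f"  children: {kids.hom_major:.3f}, {kids.het:.3f}, {kids.hom_minor:.3f}")
print(f"  parents:  {parents.hom_major:.3f}, {parents.het:.3f}, "
      f"{parents.hom_minor:.3f}")
# With tau = 0.1 the minor allele is transmitted only 10% of the time, so
# children pile up in the homozygous-major class relative to their parents.
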