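"""Generate a small synthetic cohort and look at what it contains.

Builds virtual Hdh(Q150) x ogg1 mice with inherited disease alleles,
stuttered fragment-analysis peak tables (tail reference + four brain
regions) and rotarod/grip records, then prints the cohort layout.
"""

import cagtrace as ct

config = ct.CohortConfig(
    seed=42,
    animals_per_cell=4,
    age_groups=((5, 10), (11, 20)),
    genotypes=(ct.GenotypeSpec("Q150/Q150", "+/+"),
               ct.GenotypeSpec("Q150/Q150", "-/-")),
)
cohort = ct.generate_cohort(config)
meta = cohort.metadata()

print(meta.to_string(index=False))
print(f"\n{len(cohort.animals)} animals, {len(cohort.peak_tables)} peak tables "
      f"(1 tail reference + {len(config.tissues)} tissues per animal).")

animal = cohort.animals[0]
table = cohort.birth_table(animal.id)
print(f"\nBirth (tail) trace of {animal.id} "
      f"(inherited alleles {animal.inherited_alleles}):")
for peak in table.peaks[:8]:
    repeats = ct.size_to_repeats(peak.size_bp, config.flank_bp)
    print(f"  {peak.size_bp:8.1f} bp  (~{repeats:5.1f} repeats)  "
          f"height {peak.height:9.1f}")
print("Peaks below the main allele are PCR stutter (one ladder step = 3 bp);")
print("the tallest peak sits at the inherited repeat size.")
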