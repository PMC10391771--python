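"""Generate a synthetic finishing-pig dataset with known ground truth.

Builds a pedigreed population housed ~15 to a pen, simulates daily
feeding-station records (weight, feed intake, visit duration/count) over
95-155 d of age with heritable growth curves and a heritable daily weight
dispersion, injects technical artifacts, and writes everything to CSV.
"""

from pathlib import Path

from resiphen import SimConfig, simulate_dataset

out = Path("scratch/example_sim")
out.mkdir(parents=True, exist_ok=True)

cfg = SimConfig(n_sires=6, n_dams=30, offspring_per_litter=10, n_cg=6, seed=42)
sim = simulate_dataset(cfg, genotypes=True)

sim.records.to_csv(out / "records.csv", index=False)
sim.pedigree.to_csv(out / "pedigree.csv", index=False)
sim.anchors.to_csv(out / "anchors.csv", index=False)
sim.genotypes.to_csv(out / "genotypes.csv")

print(f"animals with records : {sim.records['animal_id'].nunique()}")
print(f"animal-day records   : {len(sim.records)}")
print(f"corrupted cells      : {len(sim.artifact_ledger)} "
      f"({dict(sim.artifact_ledger['kind'].value_counts())})")
print(f"perturbation events  : {len(sim.events)}")
print(f"SNPs simulated       : {sim.genotypes.shape[1]}")
# The artifact ledger lists every corrupted cell, so downstream QC can be
# scored exactly; the truth table carries each animal's curve parameters and
# breeding values.
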