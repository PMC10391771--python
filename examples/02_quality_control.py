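"""Run the full QC cascade and score it against the injected artifacts.

Stages: gross weight limits -> minimum record count -> pen-level RMSE screen
-> rolling median (+ quadratic residual pass) -> gap filter -> pen re-screen
-> feed/behaviour 4-SD limits -> age window & eligibility.
"""

from resiphen import SimConfig, run_qc, score_against_ledger, simulate_dataset

cfg = SimConfig(n_sires=6, n_dams=30, offspring_per_litter=10, n_cg=6, seed=42)
sim = simulate_dataset(cfg)

cleaned, report = run_qc(sim.records)
print(report.summary().to_string(index=False))

score = score_against_ledger(sim.records, cleaned, sim.artifact_ledger)
print(f"\nsensitivity (corrupted weight cells removed): {score['sensitivity']:.1%}")
print(f"clean weight cells removed                  : {score['clean_removed_frac']:.2%}")
# Sensitivity near 100% with <1% collateral removals means the deviation
# traits computed next reflect biology, not scale errors.
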