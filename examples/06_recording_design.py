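"""How robust is each trait to sparser or shorter recording?

Thins each animal's records to 1-in-4 / 1-in-7 / 1-in-14 (about two
records a week down to one a fortnight), recomputes the traits, and
correlates them with the full-data versions; also splits the window into
early/middle/late 20-day periods.
"""

from resiphen import (
    SimConfig, reduced_traits, robustness_correlations, simulate_dataset,
)

cfg = SimConfig(n_sires=8, n_dams=48, offspring_per_litter=10, n_cg=8, seed=5,
                sigma2_av=0.2,
                artifact_rates={"spike": 0, "adaptation": 0, "missing": 0, "gross": 0})
sim = simulate_dataset(cfg)
full = reduced_traits(sim.records, min_days=20)

print("phenotypic correlation with the full 60-day daily data:")
for k in (4, 7, 14):
    thin = reduced_traits(sim.records, keep_every=k, min_days=3)
    row = [f"1-in-{k}:"]
    for col in ("ADG", "lnvar_weight_standardized", "skew_weight", "lag1_weight"):
        r = robustness_correlations(full[col], thin[col], min_overlap=50)["r_p"]
        row.append(f"{col}={r:+.2f}")
    print("  " + "  ".join(row))

early = reduced_traits(sim.records, period="early", min_days=7)
late = reduced_traits(sim.records, period="late", min_days=7)
r = robustness_correlations(early["lnMSE_FI"], late["lnMSE_FI"], min_overlap=50)["r_p"]
print(f"\nlnMSE_FI early vs late period: r_p = {r:.2f}")
# ADG barely moves with thinning (its endpoints survive), the standardized
# ln-variance degrades gracefully, while skewness and lag-1 autocorrelation
# collapse — shape statistics need dense series. A positive early-late
# correlation shows feed-intake variability is a repeatable animal property.
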