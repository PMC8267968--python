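"""Quantify progressive retinal thinning from synthetic OCT profiles.

Simulates a longitudinal wildtype/knockout cohort, samples thickness on
the 1-mm grid (0.5 mm clear of the optic nerve), normalizes to the
2-week wildtype baseline, and fits the knockout trajectory with an
exponential-decay model.
"""

from retphen import oct_thickness as oct
from retphen import simulate as sim

params = sim.OctSimParams(seed=2)
profiles = sim.simulate_oct(params, genotypes=("+/+", "-/-"))

summary = oct.summarize_cohort(profiles)
normed = oct.normalize_series(summary)

print("normalized total thickness (wildtype @ 2 weeks = 1.0):")
for gt in ("+/+", "-/-"):
    rows = normed[normed.genotype == gt].sort_values("age_weeks")
    series = "  ".join(f"{a:>4.0f}wk {v:.3f}" for a, v in
                       zip(rows.age_weeks, rows.mean_norm))
    print(f"  {gt}: {series}")

ko = normed[normed.genotype == "-/-"].sort_values("age_weeks")
fit = oct.fit_degeneration(ko.age_weeks.to_numpy(), ko.mean_norm.to_numpy())
print(f"\ndecay fit: asymptote {fit.asymptote:.3f} (truth {params.asymptote_frac}), "
      f"tau {fit.tau_weeks:.2f} wk (truth {params.tau_weeks})")
print("\nThe knockout retina relaxes to ~78% of baseline by 16 weeks — the")
print("'roughly 80% by four months' regime — while wildtype stays flat at 1.0.")
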