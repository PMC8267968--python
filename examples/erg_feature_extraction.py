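"""Extract a-/b-wave features from a synthetic scotopic ERG cohort.

Simulates wildtype and knockout traces (with 120 Hz oscillatory
potentials and measurement noise), runs the dual-path zero-phase
filtering chain, and normalizes group means to the wildtype response
at the brightest flash.
"""

from retphen import erg
from retphen import simulate as sim

params = sim.ErgSimParams(seed=1)
traces = sim.simulate_erg(params, genotypes=("+/+", "-/-"), n_animals=6)

features = [erg.extract_features(erg.zero_center(tr)) for tr in traces]
table = erg.features_table(features)
normed = erg.normalize_features(table, value_cols=("a_amplitude", "b_absolute"))

truth = params.effective_amplitudes(30.0)
wt = table[(table.genotype == "+/+") & (table.intensity == 30.0)]
print(f"wildtype 30 cd.s/m2 (n={len(wt)}):")
print(f"  a-wave  {wt.a_amplitude.mean():7.1f} uV at {wt.a_latency.mean():5.1f} ms "
      f"(generator truth {-truth['a_amp']:.1f} uV)")
print(f"  b-abs   {wt.b_absolute.mean():7.1f} uV (truth {truth['b_absolute']:.1f} uV)")

print("\nnormalized group means (wildtype @ 30 cd.s/m2 = 1.0):")
cols = ["genotype", "intensity", "b_absolute_norm"]
print(normed[cols].to_string(index=False, float_format=lambda v: f"{v:.3f}"))
print("\nThe knockout's normalized b-wave ~0.08 reflects the generator's severe")
print("rod-pathway loss; amplitudes are read from the unfiltered trace at the")
print("latencies picked on the 235 Hz (a) and 30 Hz (b) zero-phase paths.")
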