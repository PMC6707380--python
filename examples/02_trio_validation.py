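"""Trio validation two ways: the published 12-trio rate table, and a
noiseless synthetic pedigree where inheritance must be perfect."""

from cnvreg import SimulationConfig, simulate, summarize_trio_rates, trio_report
from cnvreg.reference_tables import trio_rates
from cnvreg.calls import filter_supported_calls
from cnvreg.regions import build_cnvrs, filter_min_length, merge_within_sample

# 1. published per-trio rates -> column means and the derived error rate
summary = summarize_trio_rates(trio_rates())
print("published 12-trio table:")
print(f"  mean paternal transmission: {summary['mean_paternal_transmission']:.3f}")
print(f"  mean maternal transmission: {summary['mean_maternal_transmission']:.3f}")
print(f"  mean inheritance:           {summary['mean_inheritance']:.3f}")
print(f"  error rate:                 {100 * summary['error_rate']:.1f}%")
# error rate = 100% - inheritance, valid when de-novo/somatic events are rare

# 2. noiseless simulation: every child CNVR must trace to a parent
sim = simulate(SimulationConfig(seed=3).noiseless())
retained = filter_supported_calls(sim.calls["splitread"], sim.calls["readdepth"])
by_sample = {}
for c in retained:
    by_sample.setdefault(c.sample, []).append(c)
merged = [m for cs in by_sample.values() for m in merge_within_sample(cs)]
cnvrs = filter_min_length(build_cnvrs(merged))
table, sim_summary = trio_report(cnvrs, sim.trios)
print("\nnoiseless simulation (12 trios):")
print(f"  inheritance per trio: {sorted(set(table['inheritance']))}")
print(f"  error rate:           {100 * sim_summary['error_rate']:.1f}%")
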