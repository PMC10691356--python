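"""Generate a synthetic monitoring dataset and look at what it contains.

Builds the built-in toy study design (2 stocks, 4 coastal regions, 6
years, one troll fleet), simulates every observation stream under the
known truth, and prints the resulting table sizes and a few example rows.
"""

import oceanmix as om

scenario = om.default_scenario("toy", seed=42)
bundle, truth = om.simulate_dataset(scenario)

print("Release groups:", len(bundle.releases))
print("CWT recovery rows (sampled strata, zeros included):",
      len(bundle.cwt_recoveries))
print("GSI-sampled strata:", len(bundle.gsi_samples))
print("Run-size estimates:", len(bundle.run_sizes))
print("Landings strata:", len(bundle.landings))
print()
print("First CWT recovery rows — observed tag counts against a 25%")
print("sampling fraction of each stratum's catch:")
print(bundle.cwt_recoveries.head(4).to_string(index=False))
print()
print("One GSI stratum — soft assignment mass per focal stock plus the")
print("non-focal remainder, partitioning the n sampled fish:")
print(bundle.gsi_samples.head(2).to_string(index=False))
print()
print("True summer distribution of the first stock across regions"
      " (south to north):")
idx = scenario.config.index
print({r: round(float(truth.pi[0, idx.season_i('summer'), l]), 3)
       for l, r in enumerate(idx.regions)})
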