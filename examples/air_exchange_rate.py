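"""Air-exchange rate from replicate CO2 tracer-decay measurements.

Simulates six deliberate tracer releases in a room with a true AER of
5.5/h and fits each decay by log-linear regression of the excess over
background.
"""

from bioemit import NoiseModel, aggregate_aer, fit_tracer_decay, generate_scenario, simulate_observations

scenario = generate_scenario(seed=7)
obs = simulate_observations(scenario, NoiseModel(tracer_cv=0.02))

estimates = [fit_tracer_decay(series) for series in obs.tracer_series]
for i, est in enumerate(estimates):
    print(f"release {i + 1}: AER = {est.aer_per_h:.2f} /h  (r^2 = {est.r_squared:.4f})")

agg = aggregate_aer(estimates)
print(f"aggregate: {agg['mean_per_h']:.2f} +/- {agg['sd_per_h']:.2f} /h over {agg['n']} releases")

# The decay rate of a well-mixed tracer IS the air-exchange rate; 2%
# measurement noise on the excess leaves the six-release mean within a few
# percent of the true 5.5/h.
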