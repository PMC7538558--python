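"""Simulate an RGC population viewing a grating and sample its spikes.

Each neuron is a linear-nonlinear unit: a center-surround
(difference-of-Gaussians) receptive field on the 64x64 electrode
lattice, a response latency, a rectifying nonlinearity and a baseline
rate.  Spikes are drawn from a log-Gaussian Cox process around the
deterministic rates, which is also the model the rate-inference stage
assumes.
"""

import numpy as np

from rgcmodes.population import build_population, sample_spikes, simulate_rates
from rgcmodes.stimuli import make_grating_sequence

stim = make_grating_sequence(0.0, 0.023, duration_s=10.0)
pop = build_population(64, seed=0)
rates = simulate_rates(pop, stim)
spikes = sample_spikes(rates, seed=1, electrode_xy=pop.electrode_xy)

print(f"{pop.n_neurons} neurons ({int((pop.polarity > 0).sum())} ON / "
      f"{int((pop.polarity < 0).sum())} OFF)")
print(f"rates: mean {rates.rates.mean():.1f} Hz, peak {rates.rates.max():.1f} Hz "
      f"(baseline {pop.baseline_rate_hz[0]:.1f} Hz)")
print(f"{spikes.n_spikes} spikes in {spikes.duration_s:.0f} s "
      f"({spikes.n_spikes / spikes.duration_s / pop.n_neurons:.1f} Hz/neuron)")

# the 1 Hz drift shows up as a 1 s period in the population rate
popr = rates.rates.mean(axis=0)
x = popr - popr.mean()
ac = np.correlate(x, x, "full")[x.size - 1:]
print(f"population-rate autocorrelation at 1 s lag: {ac[30] / ac[0]:.2f} "
      "(stimulus-locked modulation)")
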