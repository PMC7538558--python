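"""Discover stimulus-locked modes in population activity with an mcRBM.

Runs a scaled-down grating session end to end (simulate -> spikes ->
LGCP rates -> select -> standardize -> train mcRBM -> binary states)
and shows that, without ever seeing the stimulus, the dominant latent
states act as detectors of single grating frames: their state-triggered
stimulus averages correlate strongly with one pure frame, and the
states carry far more stimulus-phase information than a shuffled-label
null.  Runtime ~1 minute.
"""

from rgcmodes.protocols import grating_mode_protocol
from rgcmodes.rbm import TrainConfig

res = grating_mode_protocol(
    seed=0,
    n_neurons=60,
    orientations=(0, 90, 180, 270),
    train_config=TrainConfig(
        n_hidden=12, n_factors=48, n_precision=12, epochs=80,
        learning_rate=2e-3, seed=1,
    ),
)

print(f"kept {res['chain'].V.shape[1]} neurons, "
      f"{res['states'].n_samples} rate samples, "
      f"{len(res['census'])} distinct binary states")
print("\ntop states vs their best-matching stimulus frame:")
for _, row in res["sta_matches"].iterrows():
    print(f"  state {int(row.state_id):>10d} (n={int(row.occupancy):>3d}): "
          f"Pearson r = {row.pearson_r:.3f}")
print(f"\nstimulus-phase NMI: {res['phase_nmi']:.3f}  "
      f"(shuffled-label null 95th pct: {res['null_nmi_p95']:.3f})")
print("r near 1 means a state fires for one grating position; "
      "NMI above the null means the states encode the stimulus phase.")
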