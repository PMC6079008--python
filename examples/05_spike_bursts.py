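"""Dopamine spike-train burst statistics.

Generates bursty and tonic spike trains, segments bursts with the
80/160 ms interspike-interval rule, and pools the per-neuron statistics
into per-animal means.
"""

from colonytrack import (
    SpikeSimConfig,
    animal_firing,
    detect_bursts,
    firing_stats,
    simulate_spike_train,
)

trains = []
for i in range(3):  # bursty neurons from animal "a1"
    sim = simulate_spike_train(SpikeSimConfig(p_burst=0.25, seed=10 + i,
                                              neuron_id=f"n{i}", animal_id="a1"))
    trains.append(sim.train)
for i in range(3):  # mostly tonic neurons from animal "a2"
    sim = simulate_spike_train(SpikeSimConfig(p_burst=0.02, seed=20 + i,
                                              neuron_id=f"n{3 + i}", animal_id="a2"))
    trains.append(sim.train)

print("per neuron (10 min recordings):")
for tr in trains:
    s = firing_stats(tr)
    print(f"  {s.neuron_id} ({s.animal_id}): rate={s.rate_hz:.2f} Hz, "
          f"{s.n_bursts} bursts, %SWB={s.pct_swb:.1f}")

# %SWB = percentage of spikes inside bursts (burst: opened by an ISI
# < 80 ms, closed by an ISI > 160 ms); the per-animal value is the
# unweighted mean over that animal's neurons
print("per animal:")
for rec in animal_firing(trains).itertuples(index=False):
    print(f"  {rec.animal_id}: mean rate={rec.mean_rate_hz:.2f} Hz, "
          f"mean %SWB={rec.mean_pct_swb:.1f} ({rec.n_neurons} neurons)")
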