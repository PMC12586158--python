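"""Cross-correlogram connectivity inference on simulated spike trains.

Simulates three 10-Hz units for 20 minutes: unit 0 drives unit 1 through
a planted 3-ms monosynapse (20% transfer), while unit 2 is independent
but shares a slow rate comodulation with unit 0. The corrected CCG (raw
minus 25-ms-smoothed) recovers the synapse at the 7x flank-SD rule and
rejects the comodulated pair, whose raw CCG is broadly elevated.
"""

from icdecode import ccg, synthdata

spikes = synthdata.simulate_spike_trains(
    {0: 10.0, 1: 10.0, 2: 10.0},
    connections=[(0, 1, 3.0, 0.2)],
    duration_s=1200.0, seed=5,
    comodulation=synthdata.Comodulation(units=(0, 2), depth=0.6,
                                        freq_hz=1.0))

for pre, post, note in [(0, 1, "planted 3-ms synapse"),
                        (0, 2, "comodulated, no synapse")]:
    pair = ccg.SpikeTrainPair(spikes.spikes[pre], spikes.spikes[post],
                              spikes.n_bins)
    res = ccg.correct_ccg(pair)
    called = ccg.call_connection(res)
    print(f"unit {pre} -> {post} ({note}):")
    print(f"  corrected peak {res.peak_value:.5f} at {res.peak_lag_ms} ms, "
          f"threshold {7 * res.flank_sd:.5f} -> "
          f"{'connection' if called else 'no connection'}")

graph = ccg.build_connection_graph(spikes, pairs=[(0, 1), (0, 2)])
print("\nedge table:")
print(graph[["pre", "post", "lag_ms", "is_connection"]].to_string(index=False))
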