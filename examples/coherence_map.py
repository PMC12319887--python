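"""Wavelet transform coherence between the members of one simulated dyad.

Computes the full time-scale coherence map for one channel pair, then the
dyad's complete pair table with band-averaged (0.02-0.10 Hz) means per
experimental condition.  The simulated coupling is strong in full
collaboration, weaker behind the screen, absent when the partners work
individually — the pair-averaged condition means should reproduce that
ordering (a single channel pair is far noisier than the pair average the
statistics actually use).
"""

from dyadcoh import SimulationConfig, make_protocol, simulate_dyad, wtc
from dyadcoh.pipeline import PipelineConfig, dyad_coherence_table, process_recording

timeline = make_protocol(2, 120.0, 80.0, seed=9)
config = SimulationConfig(
    n_lsc=4, n_ssc=2,
    coupling_strength_by_condition={
        "individual": 0.0, "collaboration_screen": 0.4, "collaboration": 0.8,
    },
)
child_rec, mother_rec, _ = simulate_dyad(config, timeline, seed=9)

pipe = PipelineConfig(qc=False, chromophores=("HbO2",))
_, child, _ = process_recording(child_rec, pipe)
_, mother, _ = process_recording(mother_rec, pipe)

cmap = wtc(child.hbo[:, 0], mother.hbo[:, 0], child.fs, min_period=6.0, max_period=90.0)
print(f"coherence map: {cmap.values.shape[0]} scales x {cmap.values.shape[1]} samples, "
      f"frequencies {cmap.freqs.min():.3f}-{cmap.freqs.max():.3f} Hz")

table = dyad_coherence_table(child, mother, timeline, "demo", "channel", pipe)
print(f"dyad table: {len(table)} rows "
      f"({table[['child_unit', 'mother_unit']].drop_duplicates().shape[0]} pairs)")
means = table.groupby("condition")["mean_wtc"].mean().sort_values(ascending=False)
print("pair-averaged band coherence by condition:")
for cond, val in means.items():
    print(f"  {cond:22s} {val:.3f}")
# Higher configured coupling -> higher band coherence; the individual
# condition sits near the chance floor set by smoothing and noise.
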