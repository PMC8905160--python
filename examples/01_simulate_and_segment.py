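"""Generate a culturally structured dataset and segment it into sequences.

Run with: python examples/01_simulate_and_segment.py
"""

import vocalseq as vs

# 3 populations x 3 birds, kept small so the example runs in seconds
config = vs.SyntheticConfig(
    n_populations=3,
    birds_per_population=3,
    sequences_per_bird_mean=8.0,
    sequences_per_bird_sd=2.0,
    alphabet_size_range=(10, 14),
    global_pool_size=30,
    template_length_mean=12.0,
    template_length_sd=3.0,
    template_length_bounds=(4, 25),
)
dataset = vs.generate_dataset(config, seed=42)

sequences, report = vs.segment_dataset(dataset.bouts_by_bird)

print(f"split unit chosen: {report.split_unit!r}")
print(f"sequences retained: {report.n_sequences}")
print(f"whistle units removed: {report.removed_whistle_units}")
print(f"introductory units removed: {report.removed_introductory_units}")
print()
for seq in sequences[:3]:
    print(f"{seq.bird_id} ({seq.population_id}): {' '.join(seq.codes)}")
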