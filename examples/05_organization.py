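"""Within-sequence organization: immediate variety and acoustic contrast.

Run with: python examples/05_organization.py
"""

import math

import vocalseq as vs

config = vs.SyntheticConfig(
    n_populations=3,
    birds_per_population=3,
    sequences_per_bird_mean=10.0,
    sequences_per_bird_sd=2.0,
    alphabet_size_range=(10, 14),
    global_pool_size=30,
    template_length_mean=14.0,
    template_length_sd=3.0,
    template_length_bounds=(4, 25),
)
dataset = vs.generate_dataset(config, seed=42)
sequences, _ = vs.segment_dataset(dataset.bouts_by_bird)

# do birds avoid singing the same unit type twice in a row?
rep = vs.repetition_permutation_test(sequences, n_perm=1000, seed=11)
print(
    f"immediate repeats: observed {rep.observed_rate_pct:.2f}% of units "
    f"vs {rep.perm_mean_rate_pct:.2f}% expected under order shuffling"
)
print(f"  z = {rep.z:.1f}, p = {rep.p:.2g}")
print()

# are consecutive units more acoustically different than chance?
contrast = vs.contrast_permutation_test(
    sequences, n_perm=500, seed=12, group_by=None
)
print(f"{'variable':<22}{'measured':>10}{'expected':>10}{'z':>8}")
for row in contrast:
    if math.isnan(row.z):
        continue
    print(
        f"{row.variable:<22}{row.observed_mean:>10.3f}"
        f"{row.perm_mean:>10.3f}{row.z:>8.1f}"
    )
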