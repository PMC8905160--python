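"""Nested AMOVA on 1 - LSI: how is sequence variation partitioned?

Run with: python examples/03_amova.py
"""

import math

import vocalseq as vs
from vocalseq.amova import amova_nested

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
sequences, _ = vs.segment_dataset(dataset.bouts_by_bird)

matrix = vs.pairwise_lsi(sequences)
result = amova_nested(
    matrix.dissimilarity(),              # 1 - LSI
    [s.bird_id for s in sequences],
    [s.population_id for s in sequences],
    n_perm=999,
    seed=3,
)

print(f"{'source':<28}{'df':>5}{'SSD':>10}{'% var':>8}")
for row in result.as_rows():
    pct = row["pct_variance"]
    pct_txt = f"{pct:>8.1f}" if pct is not None and not math.isnan(pct) else f"{'':>8}"
    print(f"{row['source']:<28}{row['df']:>5}{row['SSD']:>10.3f}{pct_txt}")
print()
print(f"Phi_CT (among populations)        = {result.phi_ct:.3f}"
      f"  p = {result.p_values['phi_ct']:.3g}")
print(f"Phi_SC (birds within populations) = {result.phi_sc:.3f}"
      f"  p = {result.p_values['phi_sc']:.3g}")
print(f"Phi_ST (all structure)            = {result.phi_st:.3f}"
      f"  p = {result.p_values['phi_st']:.3g}")
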