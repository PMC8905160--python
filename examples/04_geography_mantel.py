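"""Geodesic distances between birds and Mantel tests against similarity.

Run with: python examples/04_geography_mantel.py
"""

import numpy as np

import vocalseq as vs
from vocalseq.geography import geodesic_distance, geodesic_matrix, mantel_test

# WGS84 geodesic distance between two coordinates (metres)
d = geodesic_distance(-28.20, 153.10, -28.25, 153.15)
print(f"distance between the two example points: {d:,.0f} m")
print()

config = vs.SyntheticConfig(
    n_populations=3,
    birds_per_population=5,
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

# per-population: mean between-bird LSI vs geographic distance
for pop in sorted({s.population_id for s in sequences}):
    birds = sorted(
        {s.bird_id for s in sequences if s.population_id == pop}
    )
    n = len(birds)
    sim = np.ones((n, n))
    labels = np.asarray(matrix.bird_ids, dtype=object)
    for i in range(n):
        for j in range(i + 1, n):
            ia = np.flatnonzero(labels == birds[i])
            ib = np.flatnonzero(labels == birds[j])
            sim[i, j] = sim[j, i] = matrix.values[np.ix_(ia, ib)].mean()
    geo, _ = geodesic_matrix(dataset.design.coordinates, birds)
    res = mantel_test(sim, geo, n_perm=999, seed=5, alternative="less")
    print(
        f"{pop}: Mantel r = {res.r:+.3f} (one-sided p = {res.p:.3f}, "
        f"{res.n} birds)"
    )
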