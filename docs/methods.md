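# Methods

Statistical model, defaults, and design decisions behind `vocalseq`.
Notation: a *unit* is one classified vocal element; a *sequence* is an
ordered list of unit codes; birds nest within populations.

## 1. Segmentation

Continuous song bouts carry no intrinsic sequence boundaries, so the
package imposes them with a single **split unit**.

**Choice rule.** For each candidate code, compute its relative frequency
among mimetic units separately for every bird; the split unit is the code
that maximizes the *minimum* of these per-bird frequencies, i.e. the code
most reliably common in every single bird. Only codes present in all birds
are candidates (otherwise some birds would yield no sequences). Ties break
by higher mean frequency, then lexicographically, so the choice is
deterministic. An override is available for datasets where no shared code
exists or domain knowledge dictates the boundary.

**Cutting.** Each bout is cut immediately before every occurrence of the
split unit, so every retained sequence begins with it. Two fragments are
discarded as unreliable: the leading fragment (it does not begin with the
split unit — the recording started mid-sequence) and the final sequence of
each bout (the recording may have been truncated). With multi-session
birds, `drop_last="per_bird"` drops only the final sequence of the last
bout instead.

**Filtering.** Whistle-song units and their introductory elements are a
separate, stereotyped song class; they are removed from within the
retained sequences (order of the remaining units preserved) so the
analysis concerns the mimetic sequence alone. Counts of removed units are
reported, and the accounting identity *retained + dropped = number of
split-unit occurrences* is enforced per bird.

## 2. Levenshtein similarity index

For token sequences *a*, *b* (codes compared as whole tokens, never as
characters), the unit-cost Levenshtein distance LD is computed with the
standard two-row dynamic program, and

> LSI(a, b) = 1 − LD(a, b) / max(|a|, |b|).

LSI is 1 for identical sequences, 0 when no alignment saves any edit, and
is symmetric and bounded in [0, 1] (max-length normalization guarantees
LD ≤ max). The all-pairs matrix uses a numba-compiled kernel over
integer-encoded sequences; the pure-Python DP is the reference
implementation, and both are tested against a memoized literal recursion
and an independent C implementation.

Group means are reported for the three comparison groups that partition
all unordered pairs: within individual, between individuals of the same
population, between populations. Default weighting pools all pairs;
`per_bird` weighting first averages within each bird (or bird pair) to
downweight prolific singers.

## 3. Order-permutation null and Z-tests

Composition (which units, how many) and order are confounded in raw LSI.
The null model shuffles unit order independently *within* each sequence,
preserving composition and length exactly, and recomputes the group-mean
LSIs. With `n_perm` permutations (default 1000), each observed group mean
gets

> z = (observed − null mean) / null sd,  two-sided p = erfc(|z| / √2).

Degenerate nulls (zero variance, e.g. all length-1 or single-code
sequences) are flagged with `z = NaN` and a note rather than a misleading
number. Each permutation uses an independent substream spawned from the
seed (`numpy.random.SeedSequence`), so results are reproducible and
order-independent.

## 4. Nested AMOVA

Distance-based analysis of molecular variance (Excoffier, Smouse &
Quattro 1992) on the dissimilarity d = 1 − LSI, with birds nested in
populations. Sums of squared deviations use the identity
SSD(group) = Σ<sub>i<j∈group</sub> d²<sub>ij</sub> / n<sub>group</sub>;
with the unequal-sample-size coefficients n, n′, n″ this yields variance
components σ²<sub>a</sub> (among populations), σ²<sub>b</sub> (among birds
within populations), σ²<sub>c</sub> (within birds) and

- Φ<sub>CT</sub> = σ²<sub>a</sub> / σ²<sub>tot</sub>
- Φ<sub>SC</sub> = σ²<sub>b</sub> / (σ²<sub>b</sub> + σ²<sub>c</sub>)
- Φ<sub>ST</sub> = (σ²<sub>a</sub> + σ²<sub>b</sub>) / σ²<sub>tot</sub>

satisfying (1 − Φ<sub>ST</sub>) = (1 − Φ<sub>SC</sub>)(1 − Φ<sub>CT</sub>).
Distances are squared by default (the variance-component reading);
`square_distances=False` treats the entries as already-squared distances,
and both modes are reported by the pipeline.

**Permutation schemes.** Each Φ gets its own exchangeability scheme:
whole birds are permuted among populations (Φ<sub>CT</sub>), sequences
among birds within their population (Φ<sub>SC</sub>), sequences globally
(Φ<sub>ST</sub>). P-values use (count + 1)/(n_perm + 1); when the number
of distinct arrangements is at most `n_perm`, exact enumeration over all
arrangements replaces sampling and p becomes exact. Negative variance
components (possible under the method-of-moments estimator) are retained
with a warning, not truncated. Designs with one bird per population make
σ²<sub>b</sub> inestimable: Φ<sub>SC</sub> is reported as NaN with a
warning while the population level remains valid.

## 5. Geography

Bird coordinates are WGS84 latitude/longitude. Distances use the Vincenty
inverse formula on the WGS84 ellipsoid (a = 6 378 137 m,
f = 1/298.257223563), with a great-circle fallback for the rare
non-converging antipodal pairs. The Mantel statistic is the Pearson
correlation over lower-triangle entries; the null jointly permutes rows
and columns of the second matrix. The pipeline's default alternative is
"less" (similarity *decreases* with distance); a two-sided p is always
reported alongside. Between-population tests use either a supplied
labelled distance matrix or centroid-to-centroid geodesics.

## 6. Sequence organization

**Immediate repetition.** The count of adjacent same-code pairs among
vocal mimetic units. By default a non-vocal unit between two copies breaks
adjacency (the bird did produce something in between);
`skip_nonvocal_for_adjacency=True` gives the alternative reading. The rate
(% of units) is tested against within-sequence order shuffles with the
same Z-test machinery as the LSI null.

**Acoustic contrast.** For each of seven variables (peak frequency, 5 %
low frequency, 95 % high frequency, 90 % bandwidth, 90 % duration,
aggregate entropy, peak power), the mean absolute difference between
consecutive measured units is computed per sequence, then averaged across
sequences (two-stage averaging, so long sequences do not dominate;
`pooled_pairs=True` pools all consecutive pairs instead). Units missing
measurements are skipped pairwise. Observed contrast is compared to order
shuffles in which each unit's measurements travel with it. Results are
reported per population and for all sequences pooled.

## 7. Synthetic generator

A hierarchy of templates emulates cultural transmission:

1. one **global template** (anchor unit + contrast-biased draws from a
   core alphabet),
2. per-**population** templates derived by symbol edits at rate
   `between_population_divergence`,
3. per-**bird** templates at rate `within_population_noise`,
4. per-**rendition** copies at rate `rendition_noise`.

Edits are symbol-level substitutions, insertions and deletions with equal
shares — the simplest generative process whose output is natural to
analyse with edit distances. Position 0 holds a dedicated anchor unit
shared by all birds (the split unit); it is never edited, so segmentation
structure is preserved by construction.

**Stylistic forces.** `repeat_suppression` ∈ [0, 1] is the probability
that any immediate repetition is resampled — both at draw time and in a
repair pass that catches juxtapositions created by deletions/insertions
(resampling excludes both neighbours, so suppression = 1 guarantees zero
immediate repeats). `contrast_bias` ≥ 0 weights successor draws by
exp(bias · standardized acoustic-profile distance) from the predecessor,
planting above-null acoustic contrast. Each unit type carries a fixed
acoustic profile; measurements are profile means plus Gaussian noise
(scaled by `acoustic_noise_scale`), with the frequency/bandwidth
invariants enforced.

**Realism details.** Each bird's bout ends with a truncated rendition and
half the bouts start with a template tail lacking the anchor, so
segmentation's drop rules do real work and exactly recover the planted
renditions. Whistles (and occasional introductory elements) are inserted
at `whistle_insertion_rate`. Coordinates place birds
`neighbour_spacing_m` apart within populations spaced
`population_spacing_m` apart.

**Defaults** mirror a range-wide field study: 5 populations × 5 birds,
17.9 ± 5.97 sequences per bird, template length 15.1 ± 7.15 (bounded
3–58), population alphabets of 15–37 types from a 60-type pool,
divergence 0.5 / within-population 0.12 / rendition 0.18,
repeat suppression 0.95, contrast bias 1.5, whistle rate 0.045, birds
~300 m apart and populations ~30 km apart.

`expected_lsi_under_noise(rate, length)` gives a closed-form
approximation to the expected template–copy LSI for sanity checks; it is
exact at rate 0 and validated against Monte-Carlo within ±0.05 at rate
0.1.

The returned `truth` record (templates at every level, realized
renditions, profiles, rates) supports parameter-recovery tests: the
pipeline's Φ<sub>CT</sub> increases monotonically with planted divergence
in the sensitive regime (per-symbol divergence ≲ 0.5; beyond that the
population templates are essentially unrelated and Φ<sub>CT</sub>
saturates).

## 8. Numerical and reproducibility choices

- All randomness flows from `numpy.random.SeedSequence`; permutation
  loops spawn one substream per permutation, and the pipeline derives
  per-stage seeds from one master seed. Reruns of the pipeline with the
  same configuration are byte-identical (JSON with sorted keys, no
  timestamps; NaN serialized as null).
- P-values from permutation tests always use (count + 1)/(n_perm + 1),
  bounded away from 0; comparisons use a 1e-15 tolerance so ties are not
  lost to floating-point noise.
- The pairwise-LSI kernel is O(n² · L²) over integer-encoded, padded
  sequences; ~450 sequences (10⁵ pairs) take ~0.1 s after JIT warm-up,
  making 10³-permutation nulls practical.
- Group means and AMOVA validate that each bird maps to exactly one
  population and raise informative errors otherwise.

## 9. Limitations

- The generator's edit process is not a mechanistic model of song
  learning; it is the minimal process matched to edit-distance analysis.
  Rates are per-symbol probabilities, not calendar-time mutation rates.
- LSI treats all substitutions as equally costly; acoustically graded
  confusability between unit types is not modelled.
- AMOVA variance components are method-of-moments estimates; they can be
  negative under weak structure and are reported as such.
- The Mantel test has known sensitivity limits with few objects (5 birds
  per population gives only 119 distinct permutations of relevance);
  p-values at that scale are coarse by construction.
- Segmentation assumes a single split unit adequately bounds sequences;
  songs organized around multiple boundary markers would need the
  override plus custom post-processing.
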