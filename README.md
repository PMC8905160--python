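# vocalseq

Analysis of higher-order structure in animal vocal sequences: segmentation
of continuous song bouts into comparable sequences, edit-distance
similarity with permutation nulls, hierarchical variance partitioning,
geographic correlation, and within-sequence organization statistics —
plus a hierarchical generator of synthetic datasets emulating cultural
transmission, for power analysis and method validation.

## The scientific problem

Some songbirds sing long bouts built from a repertoire of discrete unit
types (e.g. mimicked calls of other species). Two questions arise once the
units themselves are classified:

1. **Is the *order* of units shared?** Unit repertoires may overlap between
   birds, but do birds also agree on the *sequence* in which units are
   delivered — within an individual, within a population, and across
   populations? Shared order that exceeds what unit composition alone
   predicts is evidence for cultural transmission of sequences, not just of
   unit types.
2. **How is sequence variation structured?** How much of the variation
   between sequences lies among populations, among birds within
   populations, and within birds? Does similarity decay with geographic
   distance?
3. **Are sequences internally organized?** Do birds avoid immediate
   repetition of a unit type, and do consecutive units contrast
   acoustically more than a random ordering of the same units would?

`vocalseq` implements the full chain of methods for these questions.

## Methods at a glance

- **Segmentation** — continuous bouts have no given sequence boundaries.
  A single *split unit* is chosen: the mimetic unit type with the largest
  minimum per-bird relative frequency (i.e. consistently common in
  *every* bird). Bouts are cut immediately before each occurrence; the
  leading fragment and the final (possibly truncated) sequence of each
  bout are dropped, then species-specific whistle songs and introductory
  elements are removed from within sequences.
- **Levenshtein similarity index (LSI)** — for token sequences *a*, *b*
  with unit-cost edit distance *LD*:

  `LSI(a, b) = 1 − LD(a, b) / max(|a|, |b|)`

  so 1 means identical order, 0 means nothing shared. The dynamic
  program is implemented in-repo (with a compiled all-pairs kernel) and
  is cross-checked against independent implementations in the test suite.
- **Order-permutation null** — observed group-mean LSI (within
  individual / within population / between populations) is compared to
  the distribution obtained by shuffling unit order *within* each
  sequence, which preserves composition exactly. A Z-test
  (`z = (obs − null mean) / null sd`) quantifies how much signal order
  itself carries.
- **Nested AMOVA** — distance-based analysis of molecular variance
  (Excoffier et al. 1992 formulation) on the 1 − LSI matrix with birds
  nested in populations. Reports sums of squared deviations, variance
  components, percentage of variance per level, and
  Φ<sub>CT</sub> (among populations), Φ<sub>SC</sub> (among birds within
  populations), Φ<sub>ST</sub> (all structure), each with a permutation
  p-value under the appropriate exchangeability scheme (whole birds
  among populations; sequences among birds within populations; sequences
  globally). Exact enumeration replaces sampling when feasible.
- **Geography** — WGS84 geodesic distances (Vincenty inverse formula)
  between bird coordinates, and Monte-Carlo Mantel tests between
  similarity and distance matrices (joint row/column permutation,
  `(count + 1)/(n_perm + 1)` convention).
- **Organization** — the immediate-repetition rate of vocal units and the
  mean absolute acoustic difference between consecutive units (seven
  spectro-temporal variables), each tested against within-sequence order
  shuffles.
- **Synthetic generator** — a global template diverges into population
  templates, then bird templates, then per-rendition copies, via
  symbol-level edits at configurable rates; optional repeat suppression
  and acoustic-contrast bias plant the organizational signatures. Ground
  truth is returned alongside the data, enabling parameter-recovery
  tests.

## Worked example

```python
import vocalseq as vs

# generate a small culturally structured dataset (3 populations x 3 birds)
config = vs.SyntheticConfig(
    n_populations=3, birds_per_population=3,
    sequences_per_bird_mean=8.0, sequences_per_bird_sd=2.0,
    alphabet_size_range=(10, 14), global_pool_size=30,
    template_length_mean=12.0, template_length_sd=3.0,
    template_length_bounds=(4, 25),
)
dataset = vs.generate_dataset(config, seed=42)

# segment bouts into sequences, filter whistles/introductory elements
sequences, report = vs.segment_dataset(dataset.bouts_by_bird)

# all-pairs LSI and sharing by comparison group
matrix = vs.pairwise_lsi(sequences)
gm = vs.group_means(matrix)

# does order carry signal beyond composition?
null = vs.permutation_null_lsi(sequences, n_perm=200, seed=7)
```

Output of `python examples/02_similarity_groups.py` (which runs exactly
this):

```
2016 pairwise comparisons among 64 sequences
  within_individual: mean LSI 0.745 (209 pairs)
  between_individual_same_population: mean LSI 0.555 (444 pairs)
  between_populations: mean LSI 0.244 (1363 pairs)

  within_individual: observed 0.745 vs null 0.252 (z = 66.4, p = 0)
  between_individual_same_population: observed 0.555 vs null 0.230 (z = 64.9, p = 0)
  between_populations: observed 0.244 vs null 0.148 (z = 34.0, p = 6.6e-253)
```

Sharing decays from bird to population to range level, and every group
mean far exceeds its composition-preserving null — the planted cultural
structure is recovered.

The other example scripts cover the remaining capabilities:

| script | shows |
|---|---|
| `examples/01_simulate_and_segment.py` | generation, split-unit choice, segmentation accounting |
| `examples/02_similarity_groups.py` | LSI, group means, order-permutation null |
| `examples/03_amova.py` | nested AMOVA table and Φ statistics |
| `examples/04_geography_mantel.py` | geodesic distances, Mantel tests |
| `examples/05_organization.py` | repetition and acoustic-contrast tests |
| `examples/06_full_pipeline.py` | one-call pipeline with CSV/JSON outputs |

## Command line

A thin CLI wraps the same library calls:

```bash
vocalseq simulate --seed 42 --out data/               # write selection tables
vocalseq run --config run.yaml                        # full pipeline from YAML
vocalseq lsi --help                                   # single-pair LSI
vocalseq amova --help                                 # AMOVA from a matrix CSV
vocalseq mantel --help                                # Mantel from two matrices
vocalseq organization --help                          # repetition + contrast
```

`vocalseq run` reads a YAML `RunConfig` (either a `synthetic:` block or
`selection_tables:` + `population_map:` file inputs) and writes
`sequences.txt`, per-analysis CSV tables, and a `report.json` holding every
statistic, seed, and decision toggle. Reruns with the same configuration
are byte-identical.

## Input formats

- **Selection tables** (tab-separated, Raven-style): one row per unit with
  code, unit class, begin/end time, and optionally the seven acoustic
  measurements (`peak_frequency`, `low_frequency_5pct`,
  `high_frequency_95pct`, `bandwidth_90pct`, `duration_90pct`,
  `aggregate_entropy`, `peak_power`). Column names are configurable via
  `SelectionTableColumns`.
- **Population map** (CSV): `bird_id,population_id`.
- **Coordinates** (CSV): `bird_id,latitude,longitude` (WGS84 degrees).
- **Population distances** (CSV, optional): square labelled matrix in
  metres; otherwise distances are computed from bird-coordinate centroids.
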