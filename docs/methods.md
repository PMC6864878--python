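# Methods

## The retrieval problem

`tricase` implements case retrieval for a case-based reasoning (CBR)
decision-support workflow in crop pest management. A *case* records one
pest incident — pest type and quantity, life-cycle stage, infected area,
crop and growth stage, planting density, and the environment (temperature
interval, humidity, rainfall probability, sunlight, wind speed) — together
with the treatment that resolved it. Given a new incident, the system
must find the most similar past case so its treatment can be reused.
Revision/adaptation of the retrieved solution and any retention policy
beyond appending solved cases are out of scope.

## The triangular similarity measure

Two standardized cases are vectors `OA`, `OB` in R^n. Classical measures
each discard information: cosine similarity ignores magnitudes (all scaled
copies of a vector look identical), and the Euclidean, Manhattan and
Chebyshev distances cannot rank candidates that are equidistant from the
query. The triangular similarity measure (TSM) combines both angle and
magnitude through two triangle areas:

* the triangle spanned by the two vectors, with SAS area
  `S = |OA|·|OB|·sin(θ)/2`, where θ is the included angle;
* a coefficient triangle whose equal legs are
  `L = ED(OA, OB) + | |OA| − |OB| |` (Euclidean distance plus magnitude
  gap) and whose apex angle is θ, with area `K = L²·sin(θ)/2`.

The raw dissimilarity is their product, with an additive floor of 0.001 on
sin²θ so that collinear-but-unequal vectors are still separated:

```
tsm(OA, OB) = L² · (sin²θ + 0.001) · |OA| · |OB| / 4
```

It is symmetric, non-negative, and zero exactly when the vectors
coincide. Raw values are mapped to percent similarity by the inverse
exponential `exp(−tsm)`, a strictly decreasing bijection of [0, ∞) onto
(0, 1]; rankings by raw value (ascending) and percent (descending) are
identical. The baseline distances go through the same conversion. For
cosine, `exp(−cos θ)` would *invert* the similarity ordering, so the
default dialect converts `1 − cos θ`; the inverted form is available as
`cosine_dialect="paper"` for comparison.

Numerical choices: cos θ is computed as `a·b / sqrt((a·a)(b·b))` and
clamped into [−1, 1] (exact ±1 for exactly scaled operands);
sin θ = `sqrt(1 − cos²θ)` rather than `sin(arccos(·))`; identical vectors
are snapped to cos θ = 1 so the identity contract (`percent == 100 %`)
holds exactly in floating point. Zero-magnitude vectors raise a
degenerate-vector error from all angle-dependent kernels rather than
returning a default — the standardizer warns when it produces one (only a
case at every range minimum does). Ties in a ranking are broken by the
smaller case id, making retrieval deterministic and order-invariant.

### A known limit of angle-based separation

For two candidates equidistant from the query, TSM prefers the one at the
smaller included angle *provided the displacement is non-negligible*
(tests use displacements ≥ 0.2·‖query‖). In the limit of vanishing
displacement `d ≪ ‖query‖` the sin²-floor term dominates and the
collinear candidate's leg length (`2d`: distance plus an equal magnitude
gap) can outweigh the angular candidate's, reversing the order. The
spanned-triangle area alone separates equidistant candidates at any
displacement; only the composed measure has this degenerate regime.

## Standardization

Attributes are heterogeneous (counts, lux, Celsius, fractions, ordered
stages), so cases are standardized to an 11-component vector before
comparison, all attributes equally weighted:

| component | kind | default range |
|---|---|---|
| pest_quantity | numeric | 309–458 |
| pest_stage | ordinal | Egg < Larvae < Pupae < Adult |
| infected_area | numeric | 56–168 m² |
| growth_stage | ordinal | Vege < Repro < Ripen |
| planting_density | numeric | 180–525 seeds/m² |
| temp_min / temp_max | interval split | 15–22 / 24–32 °C |
| humidity | numeric | 0.2573–0.8706 |
| rainfall | numeric | 0.1250–0.8290 |
| sunlight | numeric | 831–4830 lux |
| wind_speed | numeric | 0–12 (Beaufort) |

The default scheme is min-max over these schema-declared ranges: range
endpoints map exactly to 0 and 1, ordinals map to their 1-based
life-cycle index scaled over [1, #levels], the temperature interval
contributes its two endpoints as separate components, and identifiers
(pest type, crop name) are excluded — they drive the case filter instead.
Out-of-range values are clipped with a logged warning. A z-score scheme
fitted on a reference case base is available where range endpoints are
unknown; it changes percent values but rarely the induced ranking. The
ordinal codes and the min/max split of the temperature interval are
design choices: the life-cycle order is the only natural ordering, and
the two temperature endpoints carry independent information.

## Synthetic study conditions

The generator emulates the simulated experiment the pipeline was designed
around: 1000 past cases, split evenly between rice planthopper (RP) and
*Chilo suppressalis* (CS) on rice, each attribute drawn uniformly and
independently from the ranges in the table above (wind speed 1–8 in
generation); 300 query cases, 150 per pest. Integer-valued attributes
(counts, densities, lux, degrees Celsius, Beaufort degrees) are drawn as
integers; humidity and rainfall as 4-decimal fractions. Each attribute
uses its own seeded child random stream, so reconfiguring one column
leaves the others bit-identical. Solutions are template strings
("Apply <chemical> at <dose> mL/ha") — opaque payloads.

Because independently drawn queries have no defined "correct" answer, the
benchmark mode draws each query by perturbing a uniformly chosen past
case: every numeric attribute is jittered by a uniform offset within
±`perturbation_scale` of its range (default 0.05), clipped to the range,
ordinals unchanged. The source case id is the query's ground truth, and
the *average precision* of a measure is TP/(TP+FP) — the fraction of
queries whose top-ranked case is their source. At `perturbation_scale=0`
every measure must score 100 % precision at exactly 100 % similarity,
which the test suite asserts at full study scale.

What the generator does **not** model: correlations between weather
variables, pest population dynamics, seasonal structure, or any
relationship between attributes and solutions. Passing benchmarks
therefore demonstrate the geometry and plumbing of retrieval — identity,
separation, ranking correctness, reproducibility — not agronomic
validity on field data. In particular, at the default 5 % jitter *all*
measures recover nearly every source case, so the benchmark separates
measures by retrieved-similarity calibration more than by precision;
measure-ranking differences like those reported for real mixed
workloads emerge only under harder query regimes.

## Problem sizes and reproducibility

Default runs use the full study scale (1000 past cases, 300 queries,
top-1 over ~500 filtered candidates per query); the vectorized comparator
completes the five-measure sweep in a few seconds. Every stochastic
component (generation, perturbation, source choice) derives from a single
master seed via `numpy` `SeedSequence` spawning; identical configurations
are bit-reproducible, and the CLI records seed and intervals in a
manifest from which a run can be replayed.

## Known limitations

* The standardization ranges of the original study are not documented;
  with different ranges the percent values shift (the scheme and ranges
  are configurable for calibration against externally produced numbers).
* The best-effort importer for externally deposited case-base files
  guesses among a JSON document, a delimited table with header, and a
  positional table; an exotic layout will need a custom reader.
* Average precision is top-1 only; k > 1 aggregation, attribute
  weighting, and sub-linear retrieval indexes are intentionally absent.
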