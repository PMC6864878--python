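# tricase

Case retrieval for agricultural pest management with the **triangular
similarity measure** (TSM).

In a case-based reasoning (CBR) decision-support system, past pest
incidents — pest, crop and environment attributes plus the treatment that
worked — are stored as *cases*. When a farmer reports a new incident, the
system retrieves the most similar past case and reuses its treatment.
Retrieval quality hinges entirely on the similarity measure: cosine
similarity ignores vector magnitudes (all scaled copies of a case look
identical), and plain distances cannot rank candidates that are
equidistant from the query.

TSM scores a pair of standardized case vectors `OA`, `OB` by the area of
the triangle they span, weighted by a magnitude-difference coefficient.
With `θ` the included angle and `ED` the Euclidean distance:

```
tsm(OA, OB) = (ED(OA,OB) + | |OA| − |OB| |)² · (sin²θ + 0.001) · |OA|·|OB| / 4
percent     = exp(−tsm)            # 100 % exactly when OA = OB
```

The package provides:

* `tricase.measures` — TSM plus the cosine, Euclidean, Manhattan,
  Chebyshev and Hamming baselines, scalar and vectorized;
* `tricase.case_model` — the feature-value case schema, validation,
  min-max / z-score standardization to an 11-component vector, JSON/CSV
  case-base I/O;
* `tricase.retrieval` — the filter (pest type + crop) → compare → rank
  pipeline with deterministic tie-breaks;
* `tricase.synthetic_cases` — seeded generator of study-scale case bases
  (1000 past cases, half rice planthopper / half *Chilo suppressalis*)
  and perturbed queries with ground truth;
* `tricase.evaluation` — similarity statistics and top-1 average
  precision TP/(TP+FP) across measures;
* a `tricase` CLI (`generate` / `retrieve` / `evaluate` / `compare`).

## Worked example

```python
import tricase as tc

cfg = tc.GenerationConfig(n_past=1000, n_new=300, seed=42, perturbation_scale=0.05)
base = tc.generate_case_base(cfg)
queries, truth = tc.generate_queries(cfg, base, mode="perturbed")

best = tc.retrieve_best(queries[0], base)
print(f"query 1 -> past case {best.case_id} at {100*best.percent:.2f}%: {best.solution}")

summaries, _ = tc.compare_measures(queries, base, ("tsm", "euclidean", "cosine"),
                                   ground_truth=truth)
for s in summaries:
    print(f"{s.measure:9s} mean={100*s.mean_percent:6.2f}%  min={100*s.min_percent:6.2f}%  "
          f"precision={100*s.average_precision:6.2f}%")
```

prints

```
query 1 -> past case 365 at 100.00%: Apply Imidacloprid at 389 mL/ha
tsm       mean=100.00%  min= 99.99%  precision=100.00%
euclidean mean= 93.46%  min= 90.17%  precision=100.00%
cosine    mean= 99.94%  min= 99.74%  precision=100.00%
```

Each of the 300 queries is a 5 %-jittered copy of a known past case;
`precision` is the fraction of queries whose top-ranked case is that
source case, and `mean`/`min` summarize the retrieved top-1 percent
similarities. At this jitter every measure recovers every source; the
measures differ in how *confident* the retrieval looks — TSM keeps
near-identical cases near 100 % while the Euclidean percent decays with
the residual distance.

The same run from the shell:

```sh
tricase generate --n-past 1000 --n-new 300 --seed 42 --out-dir run/
tricase compare --base run/past_cases.json --queries run/new_cases.json \
        --ground-truth run/ground_truth.json --out run/cmp
```

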