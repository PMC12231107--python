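# chemnet

Chemical-genetic screen scoring and seed-gene network inference for
humanized-yeast drug-mechanism studies.

## The problem

A transition-state-analog drug (e.g. an MTAP/MEU1 inhibitor such as
MTDIA) is screened against a yeast gene-deletion library that has been
humanized with a nucleoside transporter so the drug gets into cells.
Three data streams come out of such a study:

* **growth screens** — OD600 time courses and colony-size plate grids
  for thousands of deletion strains, with and without drug (and, for the
  genetic arm, double-mutant arrays crossing the target-gene deletion
  into the library);
* **high-content microscopy** — per-cell GFP intensities of tagged
  proteins against a constitutive RFP reference, with compartment labels;
* **a confidence-scored protein-interaction network** and gene-set
  collections, used to turn hit lists into mechanisms.

`chemnet` implements the quantitative path from raw quantified tables to
ranked mechanisms, with a synthetic-data module that generates every
input with planted ground truth so the whole pipeline is testable
offline.

## What it computes

**Phenotype statistics** (`chemnet.phenotype`) — percent residual growth
(OD600 treated / OD600 vehicle × 100) at the control's mid-log point
(OD600 0.3–0.5); 4-parameter log-logistic dose-response fits,
`r = bottom + (top − bottom)/(1 + (d/IC50)^h)`; the Bliss-style synergy
ratio ((combo/drug A)/(drug B/vehicle) × 100); dye-exclusion viability
(unlabeled/(labeled+unlabeled) × 100); sterol fractions of the
squalene + lanosterol + ergosterol total; Student's t.

**Screen scoring** (`chemnet.screen`) — colony-plate normalization
(interior median polish plus border correction); the SGA epistasis score
((double/query)/(array/wt) × 100, rescaled so a neutral reference double
scores 100); chemical-genetic percent growth per strain; two-stage hit
calling (effect threshold + p < α in ≥ 2 of 3 independent screens, then
validation at < 75% / > 130%).

**Microscopy scoring** (`chemnet.microscopy`) — median per-cell GFP/RFP
ratio change (> 20% flags a hit) and modal-compartment localization
shifts.

**Network analysis** (`chemnet.network`, `chemnet.mapeq`) — STRING-style
edge filtering (combined score ≥ 900, experimental evidence required);
first-order and minimum (Takahashi–Matsuyama Steiner) seed networks;
unnormalized Brandes betweenness; two-level map-equation community
detection; community significance against degree-preserving
edge-rewiring nulls.

**Enrichment** (`chemnet.enrichment`) — exact hypergeometric
over-representation with BH FDR, fold enrichment, the standardized
deviation z = (k − nK/N)/sd, and the combined score z·(−ln p).

## Worked example

Simulate a drug screen with 5 planted sensitive and 5 planted resistant
strains out of 50, score it, and call hits:

```python
from chemnet.synthetic import ScreenTruth, gen_screen_scores
from chemnet.screen import call_hits

strains = tuple(f"s{i:02d}" for i in range(50))
mult = {s: 0.5 for s in strains[:5]}      # sensitive: true growth 50%
mult |= {s: 1.5 for s in strains[5:10]}   # resistant: true growth 150%
truth = ScreenTruth(strains, mult, noise_sd=0.05, replicates=3, seed=11)

calls = call_hits(gen_screen_scores(truth, n_screens=3), stage="screen",
                  thresholds=(75, 130), alpha=0.05, min_screens=2)
print(calls["call"].value_counts().to_dict())
print(sorted(calls.loc[calls.call == "sensitive", "strain"]))
```

prints

```
{'none': 40, 'sensitive': 5, 'resistant': 5}
['s00', 's01', 's02', 's03', 's04']
```

— every planted strain is recovered and nothing else is called
(precision = recall = 1 at the 75/130 thresholds with the 2-of-3 rule).

The full pipeline — simulate, score screens and microscopy, merge hits
into a seed list, extract and annotate the subnetwork, per-community
enrichment — runs from one config:

```sh
chemnet run            # defaults; writes chemnet_run/
chemnet run --config my_study.yaml
```

and writes TSV outputs plus a `manifest.json` whose checksums are
byte-identical across reruns of the same config.

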