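# kinbayes

Kinase inference from dynamic phosphoproteomic time courses.

`kinbayes` is for proteomics groups who profile a signaling response over
time — e.g. a GPCR agonist applied to native tissue, quantified by TMT
LC–MS/MS as log2(treated/vehicle) phosphopeptide ratios at a few early
time points — and want to go from thousands of quantified phosphosites to
a short, ranked list of protein kinases likely to drive each coherent
group of regulated sites.

The pipeline has three stages:

1. **Regulation filter.** A site is called regulated when, at one or more
   time points, a two-sided one-sample Student t-test of its replicate
   log2 ratios against 0 gives *p* < 0.05 **and** its mean log2 ratio
   falls outside the empirical 95% range ±2·max_t SD_t, where SD_t is
   the across-site standard deviation of the ratios at time *t*. The
   product of the two 5% levels, 0.0025, is reported as the expected
   false discovery rate.
2. **Motif / time-course clustering.** Regulated sites are partitioned by
   their 13-mer sequence window (phosphoacceptor at position 0): proline
   at +1 (Group I, proline-directed kinase targets), basic R/K/H at −3
   (Group II, basophilic kinases), S/T/Y at −3/−2 (Group III), remainder
   (Group IV) — then subclustered by the 15-min direction, the time to
   half-maximal response, and the shape of the time course into 15 leaf
   clusters with full decision trails.
3. **Sequential Bayesian kinase ranking.** For each cluster, starting
   from a uniform prior over the kinase registry (1/N, N = 521 for the
   mammalian kinome), Bayes' Rule is applied seven times with likelihood
   vectors built from: three expression datasets, S/T/Y acceptor
   preference, subcellular colocalization, curated activity direction,
   and position-specific motif match. Continuous evidence x becomes a
   likelihood via the complement of the minimum Bayes factor,

       cMBF = 1 − exp(−z*² / 2),   z* = x / pivot,

   with the pivot parameter set to the dataset's intrinsic noise scale
   (1/9 for the S/T/Y step; the estimated Poisson rate of the dot-product
   scores for the colocalization and motif steps). Likelihoods below 0.5
   are reset to 0.5 so missing annotations never eliminate a kinase; the
   curated-activity step instead assigns discrete likelihoods 0.9
   (direction match), 0.1 (mismatch), 0.7 (regulated, direction unknown)
   and 0.5 (no data). Kinases are reported by their probability ratio,
   posterior / (1/N).

Motif-match evidence uses position-specific information content,
IC(a,i) = P(a,i)·log2(P(a,i)/P_ref(a)), dotted between cluster and kinase
matrices at the cluster's signature positions (e.g. +1 for Group I, −3/−2
for Group II.A). Kinases missing from a preference dataset inherit their
nearest kinome-tree neighbor's score.

A fully seeded synthetic-data generator (`kinbayes.simulate`) emulates
every input — replicate ratio tables with realistic per-time noise
(SD 0.104–0.148), planted kinases with sequence motifs, temporal shapes
and consistent evidence tables — so the entire pipeline is testable
offline, with known ground truth.

## Worked example

```python
import kinbayes as kb
from kinbayes.bayes import rank_all_clusters

sites, bundle, truth, registry = kb.simulate_experiment(kb.SimulationConfig(seed=7))
report = kb.regulation_report(sites)
print("half-width:", report.half_width, " regulated:", len(report.regulated_ids))

regulated = [s for s in sites if s.site_id in set(report.regulated_ids)]
rankings = rank_all_clusters(regulated, kb.assign_sites(regulated), bundle, registry)
print(rankings["II.A.1.a"].head(3)[["rank", "kinase", "probability_ratio"]])
```

prints

```
half-width: 0.26  regulated: 38
 rank kinase  probability_ratio
    1  KIN02          11.124257
    2  KIN04           2.827371
    3  KIN20           0.770870
```

Of 500 synthetic sites, 38 pass the dual criteria (the 40 planted minus a
few weak responders, plus occasional false positives). Cluster II.A.1.a —
basic residues at −3 and −2, slow increase — is correctly attributed to
the planted basophilic kinase KIN02: its probability ratio of ~11 means
the seven evidence layers raised its probability 11-fold over the uniform
1/20 prior, about four-fold above the runner-up.

The same stages are available as a CLI:

```
kinbayes run-all --seed 7 --out runs/demo
```

which writes the simulated inputs, the regulation report, cluster
assignments with decision trails, per-cluster ranking tables and a
reproducibility manifest. `kinbayes export-network` converts a curated
edge table into a Cytoscape SIF + attribute file restricted to the
compiled top-5 kinases per cluster.

## Layout

- `src/kinbayes/io.py` — domain types, window centralization, TSV/JSON readers
- `src/kinbayes/regulation.py` — dual-criteria significance filter
- `src/kinbayes/clustering.py` — residue-class motifs, cluster tree, enrichment
- `src/kinbayes/bayes.py` — the seven-step Bayesian ranking engine
- `src/kinbayes/simulate.py` — seeded synthetic experiments with ground truth
- `src/kinbayes/reporting.py`, `cli.py` — top-k compilation, SIF export, CLI

See `docs/methods.md` for the model, parameter and design notes.
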